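"""End-to-end pipeline: simulate -> features -> fit/score -> stats ->
stratify -> trajectories, with a manifest making runs reproducible.

Per-stage seeds are derived from the master seed via numpy SeedSequence
(see :meth:`RunConfig.stage_seed`); two runs with an identical config
produce byte-identical outputs and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GmltwinError, RunConfig
from .cohort import BIOMARKERS, generate_cohort, write_cohort
from .devstats import abnormality_map, column_similarity, kruskal_wallis, rank_top_rois
from .features import build_features
from .manifold import DigitalTwinModel
from .risk import RiskStratifier
from .trajectory import compare_cluster_trajectories, fit_trajectory, pseudotime_scores

logger = logging.getLogger(__name__)

GROUP_PAIRS = [
    ("HC", "RIS-NC"), ("HC", "RIS-C"), ("HC", "MS"),
    ("RIS-NC", "RIS-C"), ("RIS-NC", "MS"), ("RIS-C", "MS"),
]


class PipelineError(GmltwinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str,
                index: bool = True) -> None:
    """CSV writer stamping the generating seed and config hash as a comment."""
    with open(path, "w") as fh:
        fh.write(f"# gmltwin seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=index)


def availability_percentage(n_available: int, n_total: int) -> float:
    """Availability as a percentage rounded to one decimal (94/152 -> 61.8)."""
    if n_total <= 0:
        raise GmltwinError("n_total must be positive")
    return round(100.0 * n_available / n_total, 1)


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort characteristics (the familiar 'Table 1' shape).

    Group sizes, percent female, mean +/- SD age, biomarker yes/no counts
    among non-missing rows and the availability percentage (one decimal).
    """
    if len(records) == 0:
        raise GmltwinError("records is empty")
    rows = []
    for group, sub in records.groupby("group", sort=False):
        row = {
            "group": group,
            "n": len(sub),
            "pct_female": round(100.0 * (sub["sex"] == "F").mean(), 1),
            "age_mean": round(float(sub["age"].mean()), 1),
            "age_sd": round(float(sub["age"].std(ddof=1)), 1) if len(sub) > 1 else 0.0,
        }
        for b in BIOMARKERS:
            vals = sub[b]
            avail = vals.notna() & (vals != "")
            row[f"{b}_yes"] = int((vals == "yes").sum())
            row[f"{b}_no"] = int((vals == "no").sum())
            row[f"{b}_pct_available"] = availability_percentage(int(avail.sum()), len(sub))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Writes, under ``out_dir``: ``cohort/``, ``features/``, ``model/``,
    ``deviations/``, ``stats/``, ``risk/``, ``trajectories/``,
    ``summary.csv`` and ``manifest.json``. Any stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    remain on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    seeds = {s: config.stage_seed(s) for s in
             ("cohort", "manifold", "risk", "trajectory")}

    stage = "simulate"
    try:
        cohort_cfg = type(config.cohort).from_dict(
            {**config.cohort.to_dict(), "seed": seeds["cohort"]})
        records, volumes = generate_cohort(cohort_cfg)
        write_cohort(records, volumes, out / "cohort")
        summary = summarize_cohort(records)
        write_table(summary, out / "summary.csv", seeds["cohort"], cfg_hash)

        stage = "features"
        table = build_features(volumes, records)
        table.save(out / "features")

        stage = "fit"
        ref_mask = (records["cohort"] == "reference").to_numpy()
        reference = table.subset(ref_mask)
        model = DigitalTwinModel(
            reference, records.loc[ref_mask, "age"].to_numpy(),
            k=config.k_neighbors, n_components=config.n_components,
            method=config.embed_method, umap_n_neighbors=config.umap_n_neighbors,
            umap_min_dist=config.umap_min_dist, random_state=seeds["manifold"],
        ).fit()
        model.save(out / "model")

        stage = "score"
        clin_mask = ~ref_mask
        clinical = table.subset(clin_mask)
        dev = model.score(
            clinical, records.loc[clin_mask, "age"].to_numpy(),
            groups=records.loc[clin_mask, "group"].to_numpy(),
        )
        dev.save(out / "deviations")

        stage = "stats"
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        groups = dev.profiles["group"].to_numpy()
        amap = pd.DataFrame({
            g: abnormality_map(dev.z_roi, groups, g)
            for g in pd.unique(groups)
        })
        write_table(amap, stats_dir / "abnormality_map.csv", seeds["cohort"], cfg_hash)
        bag_by_group = [dev.profiles.loc[groups == g, "bag"].to_numpy()
                        for g in ("HC", "RIS-NC", "RIS-C", "MS")]
        H, p_kw = kruskal_wallis(*bag_by_group)
        comparisons = []
        for a, b in GROUP_PAIRS:
            comp = rank_top_rois(dev.z_roi, groups, a, b)
            comparisons.append(comp)
            write_table(comp.table.head(10).set_index("roi"),
                        stats_dir / f"top10_{a}_{b}.csv", seeds["cohort"], cfg_hash)
        write_table(column_similarity(comparisons),
                    stats_dir / "column_similarity.csv", seeds["cohort"], cfg_hash)
        (stats_dir / "bag_test.json").write_text(json.dumps(
            {"kruskal_H": H, "kruskal_p": p_kw,
             "group_median_bag": {g: float(np.median(s))
                                  for g, s in zip(("HC", "RIS-NC", "RIS-C", "MS"),
                                                  bag_by_group)}}, indent=2))

        stage = "stratify"
        risk_dir = out / "risk"
        risk_dir.mkdir(exist_ok=True)
        is_ris = np.isin(groups, ["RIS-NC", "RIS-C"])
        ris_records = records.loc[clin_mask].loc[is_ris].reset_index(drop=True)
        strat = RiskStratifier(
            dev.z_roi.to_numpy()[is_ris],
            ris_records["converted"].to_numpy(dtype=bool),
            subject_ids=list(ris_records["subject_id"]),
            k_clusters=config.k_clusters, n_boot=config.n_boot,
            seed=seeds["risk"], method=config.embed_method,
        ).fit()
        clusters = strat.assignments.to_frame()
        clusters["latent_subgroup"] = ris_records["latent_subgroup"].to_numpy()
        write_table(clusters, risk_dir / "clusters.csv", seeds["risk"], cfg_hash)
        enrich = strat.biomarker_enrichment(ris_records)
        write_table(enrich, risk_dir / "biomarkers.csv", seeds["risk"], cfg_hash)
        covars = pd.DataFrame({
            "age": ris_records["age"].to_numpy(),
            "sex_male": (ris_records["sex"] == "M").astype(float).to_numpy(),
            "bag": dev.profiles["bag"].to_numpy()[is_ris],
            "lesion_load": ris_records["t2_lesion_count"].to_numpy(float),
            "cord_lesion": ris_records["spinal_cord_lesion"].map(
                {"yes": 1.0, "no": 0.0}).to_numpy(float),
        })
        try:
            mfit = strat.membership_model(covars)
            write_table(mfit.coef_table.set_index(["cluster", "covariate"]),
                        risk_dir / "regression.csv", seeds["risk"], cfg_hash)
            regression_note = {"converged": mfit.converged,
                               "separation_flag": mfit.separation_flag}
        except Exception as e:  # ill-conditioned small-sample fits are reported, not fatal
            logger.warning("membership regression failed: %s", e)
            regression_note = {"error": str(e)}
        report = strat.to_json_dict()
        report["regression"] = regression_note
        report["kruskal_bag"] = {"H": H, "p": p_kw}
        (risk_dir / "risk_report.json").write_text(json.dumps(report, indent=2, default=str))

        stage = "trajectories"
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        coords = model.transform(clinical.values)
        scores, k_used = pseudotime_scores(
            coords, groups == "HC", subject_ids=clinical.subject_ids,
            knn_graph_k=config.knn_graph_k)
        scores["group"] = groups
        write_table(scores, traj_dir / "pseudotime.csv", seeds["trajectory"], cfg_hash)
        for roi in config.trajectory_rois:
            fit = fit_trajectory(scores["pseudotime"], dev.z[roi], roi=roi)
            tdf = fit.sampled.copy()
            tdf["roi"] = roi
            tdf["crossing"] = fit.crossing if fit.crossing is not None else np.nan
            write_table(tdf.set_index("pseudotime"),
                        traj_dir / f"trajectory_{roi.replace(' ', '_')}.csv",
                        seeds["trajectory"], cfg_hash)
        # per-cluster onset comparison on the most disease-responsive shared
        # structure, anchored by the HC and MS ends of the progression axis
        cross_roi = "3rd Ventricle"
        cross = compare_cluster_trajectories(
            scores["pseudotime"].to_numpy()[is_ris],
            dev.z[cross_roi].to_numpy()[is_ris],
            strat.assignments.to_numpy(),
            roi=cross_roi, n_boot=50, seed=seeds["trajectory"],
            anchor_scores=scores["pseudotime"].to_numpy()[~is_ris],
            anchor_z=dev.z[cross_roi].to_numpy()[~is_ris])
        write_table(cross, traj_dir / "cluster_crossings.csv",
                    seeds["trajectory"], cfg_hash)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stage_seeds": seeds,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json" and p.suffix != ".pkl"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
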