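"""Seeded synthetic morphometric cohorts.

Generates a lifespan healthy reference plus matched clinical groups
(HC, RIS-NC, RIS-C, MS) with regional brain volumes built from a
multiplicative structural model:

    volume(s, r) = baseline_r * icv_scale(s) * age_factor_r(age_s)
                   * sex_factor_r(sex_s) * disease_factor_r(s) * exp(eps),
    eps ~ Normal(0, noise_sd^2)

Disease raises CSF-space volumes (ventricular enlargement) and lowers a
subset of parenchymal volumes (atrophy), proportionally to a per-group
severity scalar. Each latent RIS subgroup additionally atrophies a distinct
ROI subset, making subgroups geometrically separable, and carries its own
five-year conversion risk; the RIS-C / RIS-NC labels are assigned from the
drawn conversion outcomes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import get_atlas
from .config import CohortConfig, ConfigurationError, CohortDataError

ICV_REF = 1.45e6  # mm^3, reference intracranial volume for scaling
AGE_PIVOT = 40.0  # years, age at which age_factor == 1
_CONVERTER_AGE_SHIFT = -6.0  # converters skew younger, per the cohort profile
_SUBGROUP_SET_SEED = 424_242  # ROI subsets are a design constant, not reseeded

SUBJECT_COLUMNS = [
    "subject_id", "cohort", "group", "age", "sex", "icv",
    "latent_subgroup", "converted", "followup_years", "t2_lesion_count",
    "spinal_cord_lesion", "infratentorial_lesion", "gadolinium_lesion",
    "csf_positive",
]

BIOMARKERS = [
    "spinal_cord_lesion", "infratentorial_lesion", "gadolinium_lesion", "csf_positive",
]


def subgroup_roi_sets(atlas: pd.DataFrame, n_subgroups: int, n_each: int) -> list[np.ndarray]:
    """Disjoint parenchymal ROI index sets, one per latent subgroup.

    Drawn from ROIs without a shared disease effect so the subgroup geometry
    is orthogonal to the severity axis. Fixed internal seed: the sets are part
    of the study design, not of any particular cohort draw.
    """
    eligible = np.flatnonzero((~atlas["ventricular"]) & (atlas["disease_logfx"] == 0.0))
    if n_subgroups * n_each > len(eligible):
        raise ConfigurationError(
            f"{n_subgroups} subgroups x {n_each} ROIs exceed the "
            f"{len(eligible)} eligible parenchymal ROIs"
        )
    rng = np.random.default_rng(_SUBGROUP_SET_SEED)
    chosen = rng.choice(eligible, size=n_subgroups * n_each, replace=False)
    return [np.sort(chosen[i * n_each:(i + 1) * n_each]) for i in range(n_subgroups)]


def structural_means(atlas, age, sex_is_male, icv, severity):
    """Noise-free volume matrix for given demographics and severity.

    All arguments except ``atlas`` are 1-D arrays over subjects; returns the
    (subjects x ROIs) matrix of deterministic volumes (no subgroup term).
    """
    age = np.asarray(age, float)[:, None]
    male = np.asarray(sex_is_male, float)[:, None]
    icv = np.asarray(icv, float)[:, None]
    sev = np.asarray(severity, float)[:, None]
    log_v = (
        np.log(atlas["baseline"].to_numpy())[None, :]
        + np.log(icv / ICV_REF)
        + atlas["age_slope"].to_numpy()[None, :] * (age - AGE_PIVOT)
        + atlas["sex_logfx"].to_numpy()[None, :] * male
        + atlas["disease_logfx"].to_numpy()[None, :] * sev
    )
    return np.exp(log_v)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns ``(records, volumes)``: a subject table (one row per subject,
    :data:`SUBJECT_COLUMNS`) and a volumes table (subject_id index, one
    column per ROI, mm^3). Deterministic given ``config.seed``.
    """
    config.validate()
    atlas = get_atlas()
    if config.n_rois != len(atlas):
        raise ConfigurationError(
            f"n_rois={config.n_rois} unsupported; the atlas defines {len(atlas)} ROIs"
        )
    rng = np.random.default_rng(config.seed)
    sub_sets = subgroup_roi_sets(atlas, config.n_ris_subgroups, config.subgroup_n_rois)

    frames = []
    lo, hi = config.age_range

    def draw_common(n, prefix, rng):
        sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
        icv = rng.normal(1.35e6, 1.0e5, n)
        icv = np.clip(icv, 9.0e5, 2.0e6) * np.where(sex == "M", 1.12, 1.0)
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
        return ids, sex, icv

    # --- reference HC (lifespan) -------------------------------------------
    n = config.n_reference
    ids, sex, icv = draw_common(n, "REF", rng)
    age = rng.uniform(lo, hi, n)
    frames.append(pd.DataFrame({
        "subject_id": ids, "cohort": "reference", "group": "HC",
        "age": age, "sex": sex, "icv": icv,
    }))

    def clinical_age(n, mean):
        a = rng.normal(mean, config.clinical_age_sd, n)
        return np.clip(a, 18.0, 70.0)

    # --- matched clinical HC and MS ----------------------------------------
    for prefix, group in (("HC", "HC"), ("MS", "MS")):
        n = config.n_per_group
        ids, sex, icv = draw_common(n, prefix, rng)
        frames.append(pd.DataFrame({
            "subject_id": ids, "cohort": "clinical", "group": group,
            "age": clinical_age(n, config.clinical_age_mean), "sex": sex, "icv": icv,
        }))

    # --- RIS: latent subgroup -> conversion -> group label ------------------
    n = config.n_per_group
    ids, sex, icv = draw_common(n, "RIS", rng)
    subgroup = rng.integers(0, config.n_ris_subgroups, n)
    risks = np.asarray(config.subgroup_conversion_risks)[subgroup]
    converted = rng.random(n) < risks
    age = np.where(
        converted,
        clinical_age(n, config.clinical_age_mean + _CONVERTER_AGE_SHIFT),
        clinical_age(n, config.clinical_age_mean),
    )
    followup = np.clip(rng.normal(config.followup_mean, config.followup_sd, n), 0.25, 20.0)
    available = rng.random(n) < config.biomarker_availability
    yn = lambda p: np.where(rng.random(n) < p, "yes", "no")
    biomarkers = {
        "spinal_cord_lesion": yn(np.asarray(config.spinal_cord_rates)[subgroup]),
        "infratentorial_lesion": yn(config.infratentorial_rate),
        "gadolinium_lesion": yn(config.gadolinium_rate),
        "csf_positive": yn(config.csf_positive_rate),
    }
    ris = pd.DataFrame({
        "subject_id": ids, "cohort": "clinical",
        "group": np.where(converted, "RIS-C", "RIS-NC"),
        "age": age, "sex": sex, "icv": icv,
        "latent_subgroup": subgroup, "converted": converted,
        "followup_years": followup,
    })
    for b, vals in biomarkers.items():
        # availability gap is subject-level: all four biomarkers jointly missing
        ris[b] = pd.array(np.where(available, vals, None), dtype="string")
    frames.append(ris)

    records = pd.concat(frames, ignore_index=True)
    records["latent_subgroup"] = records.get("latent_subgroup", pd.NA)
    records = records.astype({"latent_subgroup": "Int64"})
    records["converted"] = pd.array(records.get("converted"), dtype="boolean")
    for b in BIOMARKERS:
        if b not in records:
            records[b] = pd.NA
        records[b] = pd.array(records[b], dtype="string")

    # severity and lesion load
    sev_map = config.severity_by_group
    severity = records["group"].map(sev_map).to_numpy(float)
    is_ris = records["group"].str.startswith("RIS").to_numpy()
    scale = np.ones(len(records))
    sg = records["latent_subgroup"].to_numpy(dtype=float, na_value=-1).astype(int)
    scale[is_ris] = np.asarray(config.subgroup_severity_scale)[sg[is_ris]]
    severity = severity * scale
    if config.severity_cv > 0:
        # individuals sit at different points of the disease continuum
        severity = severity * np.exp(rng.normal(0.0, config.severity_cv, len(severity)))
    lam = np.where(records["group"].eq("HC"), 0.0, 4.0 + 14.0 * severity)
    records["t2_lesion_count"] = pd.array(rng.poisson(lam), dtype="Int64")
    records["followup_years"] = records.get("followup_years", np.nan)
    records = records[SUBJECT_COLUMNS]

    # --- volumes ------------------------------------------------------------
    vols = structural_means(
        atlas, records["age"], (records["sex"] == "M").to_numpy(),
        records["icv"], severity,
    )
    # latent-subgroup atrophy on its private ROI subset (RIS only)
    sub_fx = np.zeros_like(vols)
    for g, roi_idx in enumerate(sub_sets):
        rows = np.flatnonzero(is_ris & (sg == g))
        if rows.size:
            sub_fx[np.ix_(rows, roi_idx)] = -config.subgroup_effect_size
    noise = rng.normal(0.0, config.noise_sd, vols.shape) if config.noise_sd > 0 else 0.0
    vols = vols * np.exp(sub_fx + noise)
    volumes = pd.DataFrame(vols, columns=list(atlas["name"]))
    volumes.insert(0, "subject_id", records["subject_id"].to_numpy())
    volumes = volumes.set_index("subject_id")
    return records, volumes


# ---------------------------------------------------------------------------
# CSV round trip

def write_cohort(records: pd.DataFrame, volumes: pd.DataFrame, path) -> None:
    """Write ``subjects.csv`` and ``volumes.csv`` under ``path`` (a directory)."""
    if len(records) != len(volumes):
        raise CohortDataError(
            f"records ({len(records)}) and volumes ({len(volumes)}) row counts differ"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records.to_csv(path / "subjects.csv", index=False)
    volumes.to_csv(path / "volumes.csv")


def read_cohort(path, n_rois: int = 196) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort written by :func:`write_cohort`.

    Raises :class:`CohortDataError` on malformed headers, duplicate subject
    ids, missing/NaN volumes, non-positive volumes or an ROI-column count
    different from ``n_rois``.
    """
    path = Path(path)
    records = pd.read_csv(path / "subjects.csv", dtype={"subject_id": str})
    missing = set(SUBJECT_COLUMNS) - set(records.columns)
    if missing:
        raise CohortDataError(f"subjects.csv missing required columns: {sorted(missing)}")
    if records["subject_id"].duplicated().any():
        dupes = records.loc[records["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortDataError(f"duplicated subject_id values: {dupes[:5]}")
    records = records.astype({"latent_subgroup": "Int64", "t2_lesion_count": "Int64"})
    records["converted"] = (
        records["converted"].map({"True": True, "False": False, True: True, False: False})
    )
    records["converted"] = pd.array(records["converted"], dtype="boolean")
    for b in BIOMARKERS:
        records[b] = pd.array(records[b], dtype="string")

    volumes = pd.read_csv(path / "volumes.csv", index_col="subject_id")
    if volumes.shape[1] != n_rois:
        raise CohortDataError(
            f"volumes.csv has {volumes.shape[1]} ROI columns, expected {n_rois}"
        )
    if volumes.index.duplicated().any():
        raise CohortDataError("duplicated subject_id in volumes.csv")
    if volumes.isna().any().any():
        bad = volumes.columns[volumes.isna().any()][:5].tolist()
        raise CohortDataError(f"NaN volumes in columns {bad}")
    if (volumes.to_numpy() <= 0).any():
        raise CohortDataError("volumes must be strictly positive")
    if list(volumes.index) != list(records["subject_id"]):
        raise CohortDataError("subject order differs between subjects.csv and volumes.csv")
    return records, volumes
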