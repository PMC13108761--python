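"""Configuration objects and named errors for the cohort simulator and pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

GROUPS = ("HC", "RIS-NC", "RIS-C", "MS")


class GmltwinError(Exception):
    """Base class for package errors."""


class ConfigurationError(GmltwinError):
    """Invalid configuration (counts, probabilities, ordering constraints)."""


class CohortDataError(GmltwinError):
    """Malformed cohort files: bad header, duplicate ids, invalid volumes."""


class SchemaError(GmltwinError):
    """Feature/ROI schema violations (unpaired names, dimension mismatch)."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic morphometric cohort.

    The defaults encode the study design this package targets: a lifespan
    healthy reference (the normative database), three matched clinical groups
    of 152 (HC, RIS, MS), four latent RIS subgroups with five-year conversion
    risks spanning 10-39%, a 77% female RIS cohort, and joint biomarker
    availability for 94/152 RIS individuals.

    severity is a dimensionless disease-burden scale multiplying each ROI's
    disease log-effect; it must be strictly increasing over
    HC < RIS-NC < RIS-C < MS.
    """

    seed: int = 0
    n_reference: int = 1000
    n_per_group: int = 152
    n_rois: int = 196
    n_ris_subgroups: int = 4
    subgroup_conversion_risks: Sequence[float] = (0.10, 0.15, 0.25, 0.39)
    severity_by_group: dict = field(
        default_factory=lambda: {"HC": 0.0, "RIS-NC": 0.35, "RIS-C": 0.55, "MS": 1.0}
    )
    noise_sd: float = 0.03
    # per-subject multiplicative dispersion of disease severity (log-normal,
    # coefficient ~ severity_cv): individuals within a group sit at different
    # points of the disease continuum, which is what pseudo-temporal
    # trajectories order
    severity_cv: float = 0.30
    female_fraction: float = 0.77
    age_range: tuple = (20.0, 80.0)
    clinical_age_mean: float = 41.2
    clinical_age_sd: float = 13.8
    # subgroup geometry: each latent subgroup atrophies a distinct ROI subset
    subgroup_effect_size: float = 0.06
    subgroup_n_rois: int = 20
    # per-subgroup multiplier on the shared disease effect; increasing values
    # plant an onset ordering (later subgroups progress faster)
    subgroup_severity_scale: Sequence[float] = (0.80, 0.93, 1.07, 1.20)
    biomarker_availability: float = 94.0 / 152.0
    # spinal-cord lesion rate varies by latent subgroup (planted enrichment);
    # the other biomarkers are homogeneous across subgroups
    spinal_cord_rates: Sequence[float] = (0.15, 0.45, 0.45, 0.25)
    infratentorial_rate: float = 0.40
    gadolinium_rate: float = 0.10
    csf_positive_rate: float = 0.60
    followup_mean: float = 3.3
    followup_sd: float = 3.5

    def __post_init__(self):
        # normalize sequence fields so configs compare equal after file I/O
        self.subgroup_conversion_risks = tuple(self.subgroup_conversion_risks)
        self.subgroup_severity_scale = tuple(self.subgroup_severity_scale)
        self.spinal_cord_rates = tuple(self.spinal_cord_rates)
        self.age_range = tuple(self.age_range)

    def validate(self) -> "CohortConfig":
        if self.n_reference < 0 or self.n_per_group < 0 or self.n_rois <= 0:
            raise ConfigurationError("cohort counts must be non-negative (n_rois positive)")
        if self.n_ris_subgroups < 1:
            raise ConfigurationError("need at least one RIS subgroup")
        risks = list(self.subgroup_conversion_risks)
        if len(risks) != self.n_ris_subgroups:
            raise ConfigurationError(
                f"{self.n_ris_subgroups} subgroups but {len(risks)} conversion risks"
            )
        if not all(0.0 < r < 1.0 for r in risks):
            raise ConfigurationError("conversion risks must lie strictly within (0, 1)")
        sev = [self.severity_by_group.get(g) for g in GROUPS]
        if any(s is None for s in sev):
            raise ConfigurationError(f"severity_by_group must define all of {GROUPS}")
        if not (sev[0] < sev[1] < sev[2] < sev[3]):
            raise ConfigurationError(
                "severity must be strictly increasing over HC < RIS-NC < RIS-C < MS"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.severity_cv < 0:
            raise ConfigurationError("severity_cv must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be a probability")
        if not 0.0 <= self.biomarker_availability <= 1.0:
            raise ConfigurationError("biomarker_availability must be a probability")
        if len(self.subgroup_severity_scale) != self.n_ris_subgroups:
            raise ConfigurationError("subgroup_severity_scale length must match n_ris_subgroups")
        if len(self.spinal_cord_rates) != self.n_ris_subgroups:
            raise ConfigurationError("spinal_cord_rates length must match n_ris_subgroups")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be (low, high) with low < high")
        return self

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroup_conversion_risks"] = list(self.subgroup_conversion_risks)
        d["subgroup_severity_scale"] = list(self.subgroup_severity_scale)
        d["spinal_cord_rates"] = list(self.spinal_cord_rates)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Houses the analysis constants: k = 30 reference neighbors per digital
    twin, K = 4 risk clusters, |z| > 1.96 deviation threshold, and the
    conversion-risk bands (orange >= 10%, red >= 25%). Per-stage seeds are
    derived from ``seed`` via numpy SeedSequence spawning.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    n_components: int = 10
    embed_method: str = "umap"
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    k_neighbors: int = 30
    k_clusters: int = 4
    z_threshold: float = 1.96
    risk_red: float = 0.25
    risk_orange: float = 0.10
    n_boot: int = 2000
    knn_graph_k: int = 10
    trajectory_rois: Sequence[str] = (
        "3rd Ventricle",
        "Left Thalamus Proper",
        "Left Cerebellum Grey Matter",
        "Left Inferior Lateral Ventricle",
    )

    def __post_init__(self):
        self.trajectory_rois = tuple(self.trajectory_rois)

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        if self.k_neighbors < 3:
            raise ConfigurationError("k_neighbors must be >= 3 for local variability")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be positive")
        if not 0.0 <= self.risk_orange < self.risk_red <= 1.0:
            raise ConfigurationError("risk bands must satisfy 0 <= orange < red <= 1")
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be positive")
        if self.embed_method not in ("umap", "pca"):
            raise ConfigurationError("embed_method must be 'umap' or 'pca'")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["trajectory_rois"] = list(self.trajectory_rois)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortConfig.from_dict(kwargs["cohort"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: SeedSequence(seed, hash(stage))."""
        import numpy as np
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.adler32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31 - 1))
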