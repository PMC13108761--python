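"""Synthetic morphometric atlas: 196 named ROIs with generative parameters.

The atlas mimics the output schema of a whole-brain T1 segmentation pipeline
(volBrain/AssemblyNet-style): paired left/right structures, midline ("Sym")
structures, and hierarchical lobar/tissue aggregates, 196 columns in total.
Each ROI carries the parameters the cohort generator needs:

* ``baseline`` — typical adult volume (mm^3) at the reference age,
* ``age_slope`` — per-year change of log-volume (negative for parenchyma,
  positive for CSF spaces),
* ``sex_logfx`` — male-vs-female log-offset beyond head-size scaling,
* ``disease_logfx`` — log-effect per unit disease severity (negative =
  atrophy, positive = enlargement; 0 = unaffected structure).

Parameters are drawn once from an internal fixed RNG so that the atlas is a
constant of the package, independent of any cohort seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# ROI vocabulary

_MIDLINE = [
    "3rd Ventricle",
    "4th Ventricle",
    "5th Ventricle",
    "Brainstem",
    "Pons",
    "Midbrain",
    "Medulla",
    "Optic Chiasm",
    "Corpus Callosum",
    "Cerebellar Vermal Lobules I-V",
    "Cerebellar Vermal Lobules VI-VII",
    "Cerebellar Vermal Lobules VIII-X",
    "CSF (Sym)",
    "Fornix (Sym)",
    "Hypothalamus (Sym)",
    "Pineal Gland (Sym)",
]

_SUBCORTICAL_PAIRS = [
    "Lateral Ventricle",
    "Inferior Lateral Ventricle",
    "Thalamus Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens Area",
    "Ventral DC",
    "Basal Forebrain",
    "Claustrum",
    "Choroid Plexus",
    "Cerebral White Matter",
    "Cerebellum White Matter",
    "Cerebellum Grey Matter",
    "Internal Capsule",
    "Corona Radiata",
]

_LOBAR_PAIRS = [
    "Frontal Lobe GM",
    "Temporal Lobe GM",
    "Parietal Lobe GM",
    "Occipital Lobe GM",
    "Limbic Lobe GM",
    "Insular Lobe GM",
    "Hemisphere GM",
    "Hemisphere WM",
]

_CORTICAL_PAIRS = [
    "Anterior Cingulate Gyrus",
    "Anterior Insula",
    "Anterior Orbital Gyrus",
    "Angular Gyrus",
    "Calcarine Cortex",
    "Central Operculum",
    "Cuneus",
    "Entorhinal Area",
    "Frontal Operculum",
    "Frontal Pole",
    "Fusiform Gyrus",
    "Gyrus Rectus",
    "Inferior Occipital Gyrus",
    "Inferior Temporal Gyrus",
    "Lingual Gyrus",
    "Lateral Orbital Gyrus",
    "Middle Cingulate Gyrus",
    "Medial Frontal Cortex",
    "Middle Frontal Gyrus",
    "Middle Occipital Gyrus",
    "Medial Orbital Gyrus",
    "Postcentral Gyrus Medial Segment",
    "Precentral Gyrus Medial Segment",
    "Superior Frontal Gyrus Medial Segment",
    "Middle Temporal Gyrus",
    "Occipital Pole",
    "Occipital Fusiform Gyrus",
    "Opercular Part of the Inferior Frontal Gyrus",
    "Orbital Part of the Inferior Frontal Gyrus",
    "Posterior Cingulate Gyrus",
    "Precuneus",
    "Parahippocampal Gyrus",
    "Posterior Insula",
    "Parietal Operculum",
    "Postcentral Gyrus",
    "Posterior Orbital Gyrus",
    "Planum Polare",
    "Precentral Gyrus",
    "Planum Temporale",
    "Subcallosal Area",
    "Superior Frontal Gyrus",
    "Supplementary Motor Cortex",
    "Supramarginal Gyrus",
    "Superior Occipital Gyrus",
    "Superior Parietal Lobule",
    "Superior Temporal Gyrus",
    "Temporal Pole",
    "Triangular Part of the Inferior Frontal Gyrus",
    "Transverse Temporal Gyrus",
    "Paracentral Lobule",
    "Olfactory Cortex",
    "Rolandic Operculum",
    "Retrosplenial Cortex",
    "Piriform Cortex",
    "Isthmus Cingulate",
    "Banks of Superior Temporal Sulcus",
    "Lateral Occipitotemporal Gyrus",
    "Dorsolateral Prefrontal Cortex",
    "Ventromedial Prefrontal Cortex",
    "Primary Visual Cortex",
    "Secondary Visual Cortex",
    "Premotor Cortex",
    "Somatosensory Association Cortex",
    "Auditory Association Cortex",
]

#: structures that enlarge (CSF spaces) rather than atrophy with age/disease
_VENTRICULAR_BASES = {
    "Lateral Ventricle",
    "Inferior Lateral Ventricle",
    "Choroid Plexus",
    "3rd Ventricle",
    "4th Ventricle",
    "5th Ventricle",
    "CSF (Sym)",
}

N_ROIS = 2 * (len(_SUBCORTICAL_PAIRS) + len(_LOBAR_PAIRS) + len(_CORTICAL_PAIRS)) + len(_MIDLINE)

_BASELINE_RANGE = {
    "subcortical": (600.0, 9_000.0),
    "lobar": (20_000.0, 120_000.0),
    "cortical": (1_500.0, 15_000.0),
    "midline": (800.0, 15_000.0),
}
# overrides for structures with well-known magnitudes (mm^3)
_BASELINE_OVERRIDES = {
    "Lateral Ventricle": 7_000.0,
    "Inferior Lateral Ventricle": 350.0,
    "3rd Ventricle": 900.0,
    "4th Ventricle": 1_600.0,
    "5th Ventricle": 60.0,
    "Thalamus Proper": 7_200.0,
    "Hippocampus": 3_600.0,
    "Cerebral White Matter": 220_000.0,
    "Cerebellum Grey Matter": 50_000.0,
    "Cerebellum White Matter": 12_000.0,
    "Hemisphere GM": 300_000.0,
    "Hemisphere WM": 230_000.0,
    "Brainstem": 22_000.0,
    "CSF (Sym)": 150_000.0,
}

_ATLAS_RNG_SEED = 196_001  # atlas is a fixed constant, never reseeded


def _pair_rows():
    for base in _SUBCORTICAL_PAIRS:
        yield base, "subcortical"
    for base in _LOBAR_PAIRS:
        yield base, "lobar"
    for base in _CORTICAL_PAIRS:
        yield base, "cortical"


def build_atlas() -> pd.DataFrame:
    """Return the 196-row ROI atlas with generative parameters.

    Columns: ``name, base, hemisphere, category, ventricular, baseline,
    age_slope, sex_logfx, disease_logfx``.
    """
    rng = np.random.default_rng(_ATLAS_RNG_SEED)
    rows = []
    for base, category in _pair_rows():
        ventricular = base in _VENTRICULAR_BASES
        lo, hi = _BASELINE_RANGE[category]
        baseline = _BASELINE_OVERRIDES.get(base, float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        if ventricular:
            age_slope = rng.uniform(0.008, 0.018)
        else:
            age_slope = -rng.uniform(0.001, 0.004)
        sex_logfx = rng.normal(0.0, 0.01)
        # ~half the parenchymal ROIs carry a disease effect; all CSF spaces do
        if ventricular:
            disease_logfx = rng.uniform(0.10, 0.20)
        elif rng.random() < 0.5:
            disease_logfx = -rng.uniform(0.03, 0.09)
        else:
            disease_logfx = 0.0
        # left/right share parameters up to a small lateral jitter
        for hemi in ("Left", "Right"):
            rows.append(
                dict(
                    name=f"{hemi} {base}",
                    base=base,
                    hemisphere=hemi[0],
                    category=category,
                    ventricular=ventricular,
                    baseline=baseline * float(np.exp(rng.normal(0.0, 0.02))),
                    age_slope=age_slope,
                    sex_logfx=sex_logfx,
                    disease_logfx=disease_logfx,
                )
            )
    for name in _MIDLINE:
        ventricular = name in _VENTRICULAR_BASES
        lo, hi = _BASELINE_RANGE["midline"]
        baseline = _BASELINE_OVERRIDES.get(name, float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        if ventricular:
            age_slope = rng.uniform(0.008, 0.018)
            disease_logfx = rng.uniform(0.10, 0.20)
        else:
            age_slope = -rng.uniform(0.001, 0.004)
            disease_logfx = -rng.uniform(0.03, 0.09) if rng.random() < 0.5 else 0.0
        rows.append(
            dict(
                name=name,
                base=name,
                hemisphere="M",
                category="midline",
                ventricular=ventricular,
                baseline=baseline,
                age_slope=age_slope,
                sex_logfx=rng.normal(0.0, 0.01),
                disease_logfx=disease_logfx,
            )
        )
    atlas = pd.DataFrame(rows)
    # ventricular enlargement is the cardinal early change; make the 3rd
    # ventricle the single most disease-responsive structure
    atlas.loc[atlas["name"] == "3rd Ventricle", "disease_logfx"] = 0.25
    assert len(atlas) == N_ROIS == 196
    return atlas


_ATLAS_CACHE: pd.DataFrame | None = None


def get_atlas() -> pd.DataFrame:
    """Cached accessor; the atlas is deterministic and immutable."""
    global _ATLAS_CACHE
    if _ATLAS_CACHE is None:
        _ATLAS_CACHE = build_atlas()
    return _ATLAS_CACHE.copy()


def roi_names() -> list[str]:
    return list(get_atlas()["name"])
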