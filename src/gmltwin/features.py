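"""Feature space for the manifold: ICV-normalized volumes + asymmetry indices.

Each subject contributes 196 head-size-normalized ROI volumes plus one
bounded asymmetry index AI = 2(L - R)/(L + R) per left/right ROI pair.
Features are standardized with center/scale learned on the healthy reference
only and frozen before any clinical subject is transformed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SchemaError

_SCALE_FLOOR = 1e-12


def resolve_pairs(roi_names: list[str]) -> list[tuple[str, str, str]]:
    """Match ``Left X`` / ``Right X`` columns; returns (base, left, right).

    Raises :class:`SchemaError` for a lateral name without its counterpart.
    """
    left = {n[len("Left "):]: n for n in roi_names if n.startswith("Left ")}
    right = {n[len("Right "):]: n for n in roi_names if n.startswith("Right ")}
    unpaired = set(left) ^ set(right)
    if unpaired:
        raise SchemaError(f"unpaired lateral ROI names: {sorted(unpaired)[:5]}")
    return [(b, left[b], right[b]) for b in left]


def asymmetry_index(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """AI = 2(L - R)/(L + R); lies in [-2, 2] for positive volumes."""
    return 2.0 * (left - right) / (left + right)


@dataclass
class FeatureTable:
    """Standardized subject-by-feature matrix with frozen reference scaling.

    ``values`` holds z-standardized features (reference mean/SD); ``is_roi``
    marks the 196 ROI-volume features (asymmetry indices are False) so that
    downstream deviation counting can restrict itself to anatomical ROIs.
    """

    subject_ids: list[str]
    names: list[str]
    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    is_roi: np.ndarray
    reference_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.subject_ids), len(self.names)):
            raise SchemaError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.names)} features"
            )

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def roi_names(self) -> list[str]:
        return [n for n, r in zip(self.names, self.is_roi) if r]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.names)

    def to_original(self, standardized: np.ndarray) -> np.ndarray:
        """Map standardized feature values back to original units."""
        return standardized * self.scale + self.center

    def subset(self, mask) -> "FeatureTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureTable(
            [self.subject_ids[i] for i in idx], self.names, self.values[idx],
            self.center, self.scale, self.is_roi,
            None if self.reference_mask is None else self.reference_mask[idx],
        )

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path / "features.csv")
        meta = {
            "names": self.names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "is_roi": self.is_roi.astype(int).tolist(),
            "reference_mask": None if self.reference_mask is None
            else self.reference_mask.astype(int).tolist(),
        }
        (path / "scaling.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path / "features.csv", index_col="subject_id")
        meta = json.loads((path / "scaling.json").read_text())
        if list(df.columns) != meta["names"]:
            raise SchemaError("features.csv columns do not match scaling.json")
        return cls(
            [str(s) for s in df.index], meta["names"], df.to_numpy(),
            np.asarray(meta["center"]), np.asarray(meta["scale"]),
            np.asarray(meta["is_roi"], bool),
            None if meta["reference_mask"] is None
            else np.asarray(meta["reference_mask"], bool),
        )


def raw_features(volumes: pd.DataFrame, icv: np.ndarray):
    """Unstandardized features: (matrix, names, is_roi mask)."""
    roi_names = list(volumes.columns)
    v = volumes.to_numpy(float)
    normalized = v / np.asarray(icv, float)[:, None]
    pairs = resolve_pairs(roi_names)
    ai_cols, ai_names = [], []
    col = {n: i for i, n in enumerate(roi_names)}
    for base, lname, rname in pairs:
        ai_cols.append(asymmetry_index(v[:, col[lname]], v[:, col[rname]]))
        ai_names.append(f"AI|{base}")
    parts = [normalized]
    if ai_cols:
        parts.append(np.column_stack(ai_cols))
    mat = np.column_stack(parts)
    names = roi_names + ai_names
    is_roi = np.array([True] * len(roi_names) + [False] * len(ai_names))
    return mat, names, is_roi


def build_features(volumes: pd.DataFrame, records: pd.DataFrame,
                   reference_mask: np.ndarray | None = None) -> FeatureTable:
    """Build the standardized feature table for a whole cohort.

    ``reference_mask`` selects the subjects whose mean/SD define the frozen
    scaling (defaults to ``records.cohort == "reference"``). Scaling is
    estimated once on that subset and applied to everybody.
    """
    if reference_mask is None:
        reference_mask = (records["cohort"] == "reference").to_numpy()
    reference_mask = np.asarray(reference_mask, bool)
    if reference_mask.sum() < 2:
        raise SchemaError("need at least 2 reference subjects to learn feature scaling")
    mat, names, is_roi = raw_features(volumes, records["icv"].to_numpy())
    center = mat[reference_mask].mean(axis=0)
    scale = mat[reference_mask].std(axis=0, ddof=1)
    scale = np.maximum(scale, _SCALE_FLOOR)
    values = (mat - center) / scale
    return FeatureTable(list(records["subject_id"]), names, values, center, scale,
                        is_roi, reference_mask)
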