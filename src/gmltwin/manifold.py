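"""Manifold normative model: digital twins, GeoNorm z-scores, brain age gap.

The model learns a low-dimensional embedding of a healthy reference
population (UMAP by default, PCA as a deterministic linear alternative).
A subject is scored by:

1. mapping their feature vector into the embedding,
2. taking the k = 30 nearest reference subjects (Euclidean, embedding space)
   — the neighborhood that defines the subject's *digital twin* (the
   unweighted mean of the neighbors' feature vectors),
3. estimating *local normal variability*: each neighbor is itself twinned via
   leave-one-out (its own k nearest reference neighbors, excluding itself),
   and the per-feature SD of the neighbors' actual-minus-twin residuals is
   the local sigma,
4. GeoNorm z-score: z = (subject - twin) / local_sigma per feature; ROIs with
   |z| > 1.96 are flagged as significant deviations,
5. brain age = mean age of the k neighbors; brain age gap (BAG) = brain age
   minus chronological age.

Follows the statsmodels model/results idiom: ``DigitalTwinModel(...).fit()``
returns a :class:`DigitalTwinResults` which scores subjects and serializes.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import ConfigurationError, SchemaError
from .features import FeatureTable

Z_THRESHOLD = 1.96  # two-sided 5% deviation threshold
SIGMA_FLOOR = 1e-6  # standardized units; guards degenerate neighborhoods


@dataclass
class NeighborSet:
    """The k nearest reference subjects of one query subject."""

    subject_id: str
    neighbor_ids: list[str]
    indices: np.ndarray  # positions in the reference table
    distances: np.ndarray  # nonnegative, ascending

    def __post_init__(self):
        d = np.asarray(self.distances, float)
        if (np.diff(d) < 0).any() or (d < 0).any():
            raise ValueError("distances must be nonnegative and nondecreasing")
        if len(set(self.neighbor_ids)) != len(self.neighbor_ids):
            raise ValueError("duplicate neighbor ids")


@dataclass
class DigitalTwin:
    """Per-feature expected healthy value and local variability (standardized units)."""

    subject_id: str
    twin_values: np.ndarray
    local_sigma: np.ndarray


class DigitalTwinModel:
    """Normative manifold model of a healthy reference population.

    Parameters
    ----------
    reference : FeatureTable
        Feature table restricted to (or masked for) the healthy reference.
    reference_ages : array-like
        Chronological age (years) per reference subject.
    k : int
        Neighbors per digital twin (default 30).
    n_components : int
        Embedding dimension (default 10).
    method : {"umap", "pca"}
        Embedder. UMAP is the default nonlinear choice; PCA is an exact,
        linear fallback whose transform is closed-form.
    """

    def __init__(self, reference: FeatureTable, reference_ages, k: int = 30,
                 n_components: int = 10, method: str = "umap",
                 umap_n_neighbors: int = 15, umap_min_dist: float = 0.1,
                 random_state: int = 0, sigma_floor: float = SIGMA_FLOOR,
                 twin_weighting: str = "uniform"):
        ages = np.asarray(reference_ages, float)
        n = len(reference.subject_ids)
        if ages.shape != (n,):
            raise SchemaError(f"{n} reference subjects but {ages.shape} ages")
        if k < 3:
            raise ConfigurationError("k must be >= 3: local variability needs >= 3 residuals")
        if k >= n:
            raise ConfigurationError(f"k={k} must be smaller than the reference size {n}")
        if method not in ("umap", "pca"):
            raise ConfigurationError("method must be 'umap' or 'pca'")
        if twin_weighting not in ("uniform", "distance"):
            raise ConfigurationError("twin_weighting must be 'uniform' or 'distance'")
        self.twin_weighting = twin_weighting
        self.reference = reference
        self.reference_ages = ages
        self.k = k
        self.n_components = n_components
        self.method = method
        self.umap_n_neighbors = umap_n_neighbors
        self.umap_min_dist = umap_min_dist
        self.random_state = random_state
        self.sigma_floor = sigma_floor

    def fit(self) -> "DigitalTwinResults":
        X = self.reference.values
        if self.method == "umap":
            import umap

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reducer = umap.UMAP(
                    n_components=min(self.n_components, X.shape[1]),
                    n_neighbors=min(self.umap_n_neighbors, X.shape[0] - 1),
                    min_dist=self.umap_min_dist,
                    random_state=self.random_state,
                )
                embedding = np.asarray(reducer.fit_transform(X), float)
        else:
            from sklearn.decomposition import PCA

            reducer = PCA(n_components=min(self.n_components, min(X.shape)),
                          svd_solver="full", random_state=self.random_state)
            embedding = np.asarray(reducer.fit_transform(X), float)
        return DigitalTwinResults(self, reducer, embedding)


class DigitalTwinResults:
    """Fitted normative manifold; scores subjects into deviation profiles."""

    def __init__(self, model: DigitalTwinModel, reducer, embedding: np.ndarray):
        self.model = model
        self.reducer = reducer
        self.embedding = embedding
        self._loo_residuals_cache: np.ndarray | None = None

    # -- embedding ----------------------------------------------------------
    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map feature rows to embedding coordinates.

        Rows identical to a reference row return that row's stored embedding
        (the training embedding is authoritative for training points); other
        rows go through the embedder's out-of-sample transform.
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.model.reference.n_features:
            raise SchemaError(
                f"feature dimension {X.shape[1]} != model's {self.model.reference.n_features}"
            )
        ref = self.model.reference.values
        out = np.empty((X.shape[0], self.embedding.shape[1]))
        need = np.ones(X.shape[0], bool)
        for i, row in enumerate(X):
            hit = np.flatnonzero((ref == row).all(axis=1))
            if hit.size:
                out[i] = self.embedding[hit[0]]
                need[i] = False
        if need.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[need] = np.asarray(self.reducer.transform(X[need]), float)
        return out

    # -- neighbors ----------------------------------------------------------
    def _neighbors_from_coords(self, coords: np.ndarray, exclude: int | None = None):
        d = cdist(coords[None, :], self.embedding)[0]
        if exclude is not None:
            d[exclude] = np.inf
        order = np.argsort(d, kind="stable")  # stable sort = ties to lowest index
        idx = order[: self.model.k]
        return idx, d[idx]

    def find_neighbors(self, subject_features: np.ndarray,
                       subject_id: str = "query") -> NeighborSet:
        """k nearest reference subjects in embedding space.

        If the query is itself a reference subject (matched by id), it is
        excluded from its own neighborhood.
        """
        coords = self.transform(subject_features)[0]
        ref_ids = self.model.reference.subject_ids
        exclude = ref_ids.index(subject_id) if subject_id in ref_ids else None
        idx, dist = self._neighbors_from_coords(coords, exclude)
        return NeighborSet(subject_id, [ref_ids[i] for i in idx], idx, dist)

    # -- leave-one-out residuals --------------------------------------------
    def loo_residuals(self) -> np.ndarray:
        """Per-reference-subject residual (actual - LOO twin), standardized units.

        Reference subject j's twin is the mean of j's own k nearest reference
        neighbors, excluding j itself.
        """
        if self._loo_residuals_cache is None:
            X = self.model.reference.values
            D = cdist(self.embedding, self.embedding)
            np.fill_diagonal(D, np.inf)
            order = np.argsort(D, axis=1, kind="stable")[:, : self.model.k]
            twins = X[order].mean(axis=1)
            self._loo_residuals_cache = X - twins
        return self._loo_residuals_cache

    def build_twin(self, neighbors: NeighborSet) -> DigitalTwin:
        """Digital twin = neighbor mean (unweighted by default; optional
        inverse-distance weighting); sigma = SD of LOO residuals."""
        if self.model.k < 3:
            raise ConfigurationError("local variability undefined for k < 3")
        X = self.model.reference.values
        if self.model.twin_weighting == "distance":
            w = 1.0 / np.maximum(neighbors.distances, 1e-12)
            twin = (w[:, None] * X[neighbors.indices]).sum(axis=0) / w.sum()
        else:
            twin = X[neighbors.indices].mean(axis=0)
        resid = self.loo_residuals()[neighbors.indices]
        sigma = np.maximum(resid.std(axis=0, ddof=1), self.model.sigma_floor)
        return DigitalTwin(neighbors.subject_id, twin, sigma)

    # -- scoring ------------------------------------------------------------
    def geonorm_z(self, subject_features: np.ndarray, twin: DigitalTwin) -> np.ndarray:
        """GeoNorm z = (subject - twin) / local sigma, per feature."""
        x = np.asarray(subject_features, float).ravel()
        if x.shape != twin.twin_values.shape:
            raise SchemaError("feature dimension mismatch between subject and twin")
        return (x - twin.twin_values) / twin.local_sigma

    def brain_age(self, neighbors: NeighborSet, chronological_age: float):
        """(brain age, BAG): mean neighbor age and its gap to chronological age."""
        ba = float(self.model.reference_ages[neighbors.indices].mean())
        return ba, ba - float(chronological_age)

    def score(self, features: FeatureTable, ages, subject_ids=None,
              groups=None) -> "DeviationResults":
        """Score subjects into deviation profiles (z, brain age, BAG, n_abnormal)."""
        ids = subject_ids if subject_ids is not None else features.subject_ids
        ages = np.asarray(ages, float)
        X = features.values
        coords = self.transform(X)
        ref_ids = self.model.reference.subject_ids
        ref_pos = {s: i for i, s in enumerate(ref_ids)}
        is_roi = features.is_roi
        zs, bas, bags, n_abn = [], [], [], []
        for i, sid in enumerate(ids):
            idx, dist = self._neighbors_from_coords(coords[i], ref_pos.get(sid))
            ns = NeighborSet(sid, [ref_ids[j] for j in idx], idx, dist)
            twin = self.build_twin(ns)
            z = self.geonorm_z(X[i], twin)
            ba, bag = self.brain_age(ns, ages[i])
            zs.append(z)
            bas.append(ba)
            bags.append(bag)
            n_abn.append(int((np.abs(z[is_roi]) > Z_THRESHOLD).sum()))
        z = pd.DataFrame(np.asarray(zs), index=pd.Index(ids, name="subject_id"),
                         columns=features.names)
        profiles = pd.DataFrame({
            "subject_id": ids, "age": ages, "brain_age": bas, "bag": bags,
            "n_abnormal": n_abn,
        }).set_index("subject_id")
        if groups is not None:
            profiles.insert(0, "group", np.asarray(groups))
        return DeviationResults(z, profiles, is_roi, Z_THRESHOLD)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "model.pkl", "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "DigitalTwinResults":
        with open(Path(path) / "model.pkl", "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise SchemaError("archive does not contain a DigitalTwinResults")
        return obj


class DeviationResults:
    """Per-subject deviation profiles from a fitted normative model.

    Attributes
    ----------
    z : DataFrame
        Subjects x features GeoNorm z-scores (ROI volumes and asymmetry
        indices; use :attr:`z_roi` for the anatomical-ROI block).
    profiles : DataFrame
        Per subject: age, brain_age, bag, n_abnormal (count of ROI features
        with |z| above the threshold; asymmetry indices are not counted).
    """

    def __init__(self, z: pd.DataFrame, profiles: pd.DataFrame,
                 is_roi: np.ndarray, threshold: float = Z_THRESHOLD):
        self.z = z
        self.profiles = profiles
        self.is_roi = np.asarray(is_roi, bool)
        self.threshold = threshold

    @property
    def z_roi(self) -> pd.DataFrame:
        return self.z.loc[:, self.is_roi]

    def abnormal_rate(self) -> float:
        """Mean fraction of ROI flags over subjects and ROIs."""
        return float((np.abs(self.z_roi.to_numpy()) > self.threshold).mean())

    def summary(self) -> pd.DataFrame:
        """Group-level medians (falls back to whole-cohort if no groups)."""
        p = self.profiles
        if "group" in p.columns:
            return p.groupby("group", sort=False).agg(
                n=("bag", "size"), median_bag=("bag", "median"),
                mean_bag=("bag", "mean"), mean_n_abnormal=("n_abnormal", "mean"),
                median_n_abnormal=("n_abnormal", "median"),
            )
        return p.agg(["median", "mean"])

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.z_roi.to_csv(path / "deviations.csv")
        self.profiles.to_csv(path / "bag.csv")
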