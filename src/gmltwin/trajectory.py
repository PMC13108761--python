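"""Pseudo-temporal progression modeling on the manifold.

Subjects are ordered by a progression score: the graph-geodesic distance
from the healthy-control centroid on a k-NN graph over the embedded cohort
(shortest path with Euclidean edge weights), min-max normalized to [0, 1].
Penalized-spline smooths (GAM, roughness penalty selected by GCV) model ROI
z-scores along this axis; each trajectory is sampled at 10 equally spaced
pseudotimes and the first threshold crossing (|z| >= 1.96) is located by
bisection on the fitted smooth.
"""

from __future__ import annotations

import contextlib
import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .config import ConfigurationError, GmltwinError
from .manifold import Z_THRESHOLD

logger = logging.getLogger(__name__)


class GraphError(GmltwinError):
    """k-NN graph disconnected even at the maximal neighbor count."""


# ---------------------------------------------------------------------------
# pseudotime

def pseudotime_scores(embeddings: np.ndarray, hc_mask, subject_ids=None,
                      knn_graph_k: int = 10, max_k: int | None = None):
    """Geodesic progression scores from the HC centroid.

    Builds a symmetric k-NN graph over all embedded subjects plus the HC
    centroid node, increasing k until the graph is connected, then runs
    Dijkstra from the centroid and min-max normalizes the distances.

    Returns ``(scores, k_used)`` where ``scores`` has columns
    ``geodesic`` (raw graph distance) and ``pseudotime`` (normalized).
    """
    E = np.asarray(embeddings, float)
    hc_mask = np.asarray(hc_mask, bool)
    n = E.shape[0]
    if hc_mask.shape != (n,) or hc_mask.sum() == 0:
        raise ConfigurationError("hc_mask must select >= 1 embedded subject")
    if subject_ids is None:
        subject_ids = [f"S{i}" for i in range(n)]
    centroid = E[hc_mask].mean(axis=0)
    nodes = np.vstack([E, centroid])
    m = nodes.shape[0]
    max_k = max_k if max_k is not None else m - 1
    from scipy.spatial.distance import cdist

    # explicit k-NN graph: self excluded by index, duplicates kept (sklearn's
    # include_self heuristic drops coincident points, which breaks geodesics)
    D = cdist(nodes, nodes)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")

    def graph_at(k):
        rows = np.repeat(np.arange(m), k)
        cols = order[:, :k].ravel()
        # coincident points get an epsilon edge: explicit zeros would be
        # dropped by the sparse graph routines
        w = np.maximum(D[rows, cols], 1e-12)
        return csr_matrix((w, (rows, cols)), shape=(m, m))

    k = min(knn_graph_k, m - 1)
    while True:
        W = graph_at(k)
        W = W.maximum(W.T)  # symmetrize: undirected geodesics
        n_comp, _ = connected_components(W, directed=False)
        if n_comp == 1:
            break
        if k >= max_k:
            raise GraphError(
                f"k-NN graph still has {n_comp} components at k={k}; "
                "the embedded cohort is not connectable"
            )
        k = min(max_k, max(k + 1, int(k * 1.5)))
    if k != knn_graph_k:
        logger.info("pseudotime: raised knn_graph_k to %d for connectivity", k)
    dist = dijkstra(csr_matrix(W), directed=False, indices=m - 1)[:n]
    lo, hi = dist.min(), dist.max()
    pseudo = (dist - lo) / (hi - lo) if hi > lo else np.zeros(n)
    scores = pd.DataFrame({"geodesic": dist, "pseudotime": pseudo},
                          index=pd.Index(subject_ids, name="subject_id"))
    return scores, k


# ---------------------------------------------------------------------------
# GAM trajectories

@dataclass
class TrajectoryFit:
    """Fitted smooth z(t) for one ROI along normalized pseudotime."""

    roi: str
    sampled: pd.DataFrame  # 10 rows: pseudotime, z
    crossing: float | None  # smallest t with |z(t)| >= threshold, None = censored
    alpha: float
    df_used: int
    n_subjects: int
    threshold: float
    _predict: callable = None

    def predict(self, t) -> np.ndarray:
        return self._predict(np.asarray(t, float))


def fit_trajectory(scores, z_values, roi: str = "", n_points: int = 10,
                   threshold: float = Z_THRESHOLD, df: int = 10, degree: int = 3,
                   alpha: float | None = None) -> TrajectoryFit:
    """Penalized-spline smooth of one ROI's z-scores along pseudotime.

    ``alpha=None`` selects the roughness penalty by generalized
    cross-validation. If there are fewer subjects than comfortably support
    the basis dimension, the basis is shrunk (warning logged).
    """
    from statsmodels.gam.api import GLMGam, BSplines

    t = np.asarray(scores, float).ravel()
    y = np.asarray(z_values, float).ravel()
    if t.shape != y.shape:
        raise ConfigurationError("scores and z_values lengths differ")
    n = len(t)
    if n < 8:
        raise ConfigurationError(f"need >= 8 subjects to fit a trajectory (got {n})")
    df_used = df
    if n < 4 * df:
        df_used = max(4, n // 4)
        logger.warning("trajectory %s: basis shrunk from df=%d to %d (n=%d)",
                       roi, df, df_used, n)
    lo, hi = float(t.min()), float(t.max())
    basis = BSplines(t[:, None], df=[df_used], degree=[degree],
                     knot_kwds=[{"lower_bound": lo, "upper_bound": hi}])
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    predict = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ones = np.ones((n, 1))
            if alpha is None:
                gam0 = GLMGam(y, exog=ones, smoother=basis, alpha=[1.0])
                gam0.fit()
                # Nelder-Mead: deterministic (basinhopping draws from the global RNG)
                with contextlib.redirect_stdout(io.StringIO()):
                    alpha = float(gam0.select_penweight(criterion="gcv", method="nm")[0][0])
            res = GLMGam(y, exog=ones, smoother=basis, alpha=[alpha]).fit()

            def predict(ts):
                ts = np.clip(np.atleast_1d(np.asarray(ts, float)), lo, hi)
                return np.asarray(res.predict(exog=np.ones((len(ts), 1)),
                                              exog_smooth=ts[:, None]))

        except PerfectSeparationError:
            # (near-)noiseless response: the penalized IRLS declares perfect
            # separation; an unpenalized least-squares fit on the same basis
            # interpolates it exactly
            import statsmodels.api as sm

            alpha = 0.0
            exog = np.column_stack([np.ones(n), basis.transform(t[:, None])])
            ols = sm.OLS(y, exog).fit()

            def predict(ts):
                ts = np.clip(np.atleast_1d(np.asarray(ts, float)), lo, hi)
                ex = np.column_stack([np.ones(len(ts)), basis.transform(ts[:, None])])
                return np.asarray(ex @ ols.params)

    grid = np.linspace(0.0, 1.0, n_points)
    sampled = pd.DataFrame({"pseudotime": grid, "z": predict(grid)})
    crossing = _first_crossing(predict, lo, hi, threshold)
    return TrajectoryFit(roi, sampled, crossing, alpha, df_used, n,
                         threshold, predict)


def _first_crossing(predict, lo, hi, threshold, n_scan: int = 512,
                    tol: float = 1e-5) -> float | None:
    """Smallest t in [lo, hi] with |z(t)| >= threshold: grid scan + bisection."""
    ts = np.linspace(lo, hi, n_scan)
    g = np.abs(predict(ts)) - threshold
    if g[0] >= 0:
        return float(ts[0])
    above = np.flatnonzero(g >= 0)
    if above.size == 0:
        return None
    i = above[0]
    a, b = ts[i - 1], ts[i]
    while b - a > tol:
        mid = 0.5 * (a + b)
        if np.abs(predict([mid]))[0] >= threshold:
            b = mid
        else:
            a = mid
    return float(b)


def compare_cluster_trajectories(scores, z_values, assignments, roi: str = "",
                                 n_boot: int = 200, seed: int = 0,
                                 anchor_scores=None, anchor_z=None,
                                 **fit_kw) -> pd.DataFrame:
    """Per-cluster threshold-crossing pseudotimes for one ROI.

    Earlier crossing = faster progression. Bootstrap (resampling subjects
    within cluster, refitting the smooth) gives a percentile CI; clusters
    whose smooth never reaches the threshold are reported censored
    (``crossing`` NaN).

    ``anchor_scores`` / ``anchor_z`` optionally supply a shared backbone
    (e.g. the HC and MS subjects) appended to every cluster's fit, so each
    trajectory spans the whole progression axis even when the cluster's own
    members occupy only its middle; the cluster's subjects then bend the
    curve in their range, which is what shifts the crossing.
    """
    t = np.asarray(scores, float).ravel()
    y = np.asarray(z_values, float).ravel()
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ConfigurationError("need >= 2 clusters to compare trajectories")
    if (anchor_scores is None) != (anchor_z is None):
        raise ConfigurationError("anchor_scores and anchor_z must be given together")
    at = np.asarray(anchor_scores, float).ravel() if anchor_scores is not None else np.empty(0)
    ay = np.asarray(anchor_z, float).ravel() if anchor_z is not None else np.empty(0)
    rng = np.random.default_rng(seed)
    rows = []
    for c in uniq:
        sel = labels == c
        fit = fit_trajectory(np.concatenate([t[sel], at]),
                             np.concatenate([y[sel], ay]), roi=roi, **fit_kw)
        # bootstrap refits reuse the point estimate's penalty: re-running the
        # GCV search per resample adds cost but little variance information
        boot_kw = {**fit_kw, "alpha": fit.alpha}
        cross_boot = []
        idx_pool = np.flatnonzero(sel)
        for _ in range(n_boot):
            bs = rng.choice(idx_pool, size=idx_pool.size, replace=True)
            try:
                f = fit_trajectory(np.concatenate([t[bs], at]),
                                   np.concatenate([y[bs], ay]), roi=roi, **boot_kw)
                cross_boot.append(np.nan if f.crossing is None else f.crossing)
            except Exception:
                cross_boot.append(np.nan)
        cb = np.asarray(cross_boot, float)
        ok = cb[~np.isnan(cb)]
        rows.append(dict(
            cluster=c, n=int(sel.sum()),
            crossing=np.nan if fit.crossing is None else fit.crossing,
            censored=fit.crossing is None,
            ci_low=float(np.quantile(ok, 0.025)) if ok.size else np.nan,
            ci_high=float(np.quantile(ok, 0.975)) if ok.size else np.nan,
            n_boot_censored=int(np.isnan(cb).sum()),
        ))
    out = pd.DataFrame(rows).set_index("cluster")
    out["order"] = out["crossing"].rank(method="min")
    return out


def months_from_pseudotime(pseudotime, months_per_unit: float) -> np.ndarray:
    """Optional calendar calibration: months = pseudotime * months_per_unit.

    The mapping from normalized pseudotime to months is not identified by the
    cross-sectional method itself; it must be supplied externally (e.g. from
    longitudinal follow-up)."""
    return np.asarray(pseudotime, float) * float(months_per_unit)
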