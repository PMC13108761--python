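"""Conversion-risk stratification of RIS subjects.

2-D manifold reduction of deviation profiles, k-means clustering (K = 4),
per-cluster conversion rates with percentile-bootstrap 95% CIs, pairwise
Fisher exact tests on converter counts, traffic-light risk labels
(red >= 25%, orange 10-25%), biomarker enrichment (exact K x 2 test with
chi-square fallback) and multinomial logistic adjustment for covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import ConfigurationError, GmltwinError

RISK_RED = 0.25
RISK_ORANGE = 0.10


class TableError(GmltwinError):
    """Invalid contingency table (negative or non-integer cells)."""


# ---------------------------------------------------------------------------
# embedding + clustering

def embed_2d(profiles: np.ndarray, seed: int = 0, method: str = "umap",
             n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """Reduce deviation profiles to 2-D for clustering and display.

    Deterministic given ``seed``. Uses a neighbor-graph manifold reducer
    (UMAP) by default; ``method="pca"`` gives the linear alternative.
    """
    X = np.asarray(profiles, float)
    if X.shape[0] < 4:
        raise ConfigurationError("need at least 4 subjects to embed")
    if method == "umap":
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, random_state=seed,
                                n_neighbors=min(n_neighbors, X.shape[0] - 1),
                                min_dist=min_dist)
            return np.asarray(reducer.fit_transform(X), float)
    elif method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, svd_solver="full").fit_transform(X)
    raise ConfigurationError("method must be 'umap' or 'pca'")


def cluster_kmeans(coordinates: np.ndarray, k: int = 4, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """Best-of-n_init k-means labels (0-based, arbitrary numbering)."""
    X = np.asarray(coordinates, float)
    if k < 1 or k > X.shape[0] // 2:
        raise ConfigurationError(f"k={k} must satisfy 1 <= k <= n/2 (n={X.shape[0]})")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)


def silhouette_k_diagnostic(coordinates: np.ndarray, k_range=range(2, 9),
                            seed: int = 0) -> pd.Series:
    """Mean silhouette score per candidate K — a diagnostic for the fixed
    default K = 4, not an automatic selector."""
    from sklearn.metrics import silhouette_score

    X = np.asarray(coordinates, float)
    out = {}
    for k in k_range:
        if k > X.shape[0] - 1:
            break
        lab = cluster_kmeans(X, k=k, seed=seed)
        out[k] = float(silhouette_score(X, lab))
    return pd.Series(out, name="silhouette")


def renumber_by_rate(labels: np.ndarray, outcomes: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K by ascending conversion rate (report-stable
    numbering, invariant to k-means label permutation)."""
    labels = np.asarray(labels)
    outcomes = np.asarray(outcomes, bool)
    uniq = np.unique(labels)
    rates = [(outcomes[labels == c].mean(), c) for c in uniq]
    order = [c for _, c in sorted(rates, key=lambda t: (t[0], t[1]))]
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([remap[c] for c in labels])


# ---------------------------------------------------------------------------
# rates, CIs, exact tests

def bootstrap_rate_ci(outcomes, n_boot: int = 2000, seed: int = 0,
                      level: float = 0.95) -> tuple[float, float, float]:
    """(rate, lo, hi): percentile bootstrap CI for a binary rate."""
    y = np.asarray(outcomes, float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(n_boot, len(y)))
    boot = y[idx].mean(axis=1)
    a = (1.0 - level) / 2.0
    return float(y.mean()), float(np.quantile(boot, a)), float(np.quantile(boot, 1 - a))


def conversion_rates(assignments, outcomes, n_boot: int = 2000,
                     seed: int = 0) -> pd.DataFrame:
    """Per-cluster conversion rate with percentile-bootstrap 95% CI.

    Clusters of size < 5 are flagged ``unstable`` (the bootstrap CI is then
    dominated by resampling granularity).
    """
    labels = np.asarray(assignments)
    y = np.asarray(outcomes, bool)
    if len(labels) != len(y):
        raise ConfigurationError("assignments and outcomes lengths differ")
    rows = []
    rng = np.random.default_rng(seed)
    for c in np.unique(labels):
        yc = y[labels == c]
        rate, lo, hi = bootstrap_rate_ci(yc, n_boot, int(rng.integers(2**31 - 1)))
        rows.append(dict(cluster=c, n=len(yc), converters=int(yc.sum()),
                         rate=rate, ci_low=lo, ci_high=hi, unstable=len(yc) < 5))
    return pd.DataFrame(rows).set_index("cluster")


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.dtype.kind == "f":
        if not np.allclose(t, np.round(t)):
            raise TableError("contingency table cells must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise TableError("contingency table cells must be nonnegative")
    return t.astype(int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Convention: sum of hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed one.
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise TableError(f"expected a 2x2 table, got shape {t.shape}")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def pairwise_cluster_tests(assignments, outcomes) -> pd.DataFrame:
    """K x K matrix of pairwise Fisher exact p-values on converter counts."""
    labels = np.asarray(assignments)
    y = np.asarray(outcomes, bool)
    uniq = np.unique(labels)
    p = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            ya, yb = y[labels == a], y[labels == b]
            tab = [[ya.sum(), len(ya) - ya.sum()], [yb.sum(), len(yb) - yb.sum()]]
            p.loc[a, b] = p.loc[b, a] = fisher_exact_2x2(tab)
    return p


def label_risk(rates, red: float = RISK_RED, orange: float = RISK_ORANGE) -> list[str]:
    """Traffic-light labels: red if rate >= 25% (inclusive), orange if in
    [10%, 25%), low below."""
    rates = np.asarray(rates, float)
    if ((rates < 0) | (rates > 1)).any():
        raise ConfigurationError("rates must lie in [0, 1]")
    return ["red" if r >= red else "orange" if r >= orange else "low" for r in rates]


def exact_kx2_test(table, max_tables: int = 2_000_000) -> tuple[float, str]:
    """Exact conditional (Freeman-Halton) test for a K x 2 table.

    Enumerates all tables with the observed margins; p is the total
    probability of tables no more probable than the observed one. Falls back
    to the chi-square test (flagged) if the enumeration would exceed
    ``max_tables``.

    Returns (p, method) with method in {"exact", "chi2"}.
    """
    t = _check_table(table)
    if t.ndim != 2 or t.shape[1] != 2:
        raise TableError(f"expected a K x 2 table, got shape {t.shape}")
    if t.shape[0] == 2:
        return fisher_exact_2x2(t), "exact"
    n_rows = t.sum(axis=1)
    m = int(t[:, 0].sum())
    n_total = int(t.sum())

    # rough enumeration budget: compositions of m over K bounded rows
    est = 1.0
    for nk in n_rows[:-1]:
        est *= min(m, nk) + 1
        if est > max_tables:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2 = stats.chi2_contingency(t, correction=False)
            return float(chi2.pvalue), "chi2"

    log_denom = gammaln(n_total + 1) - gammaln(m + 1) - gammaln(n_total - m + 1)

    def logp(xs):
        lp = -log_denom
        for nk, xk in zip(n_rows, xs):
            lp += gammaln(nk + 1) - gammaln(xk + 1) - gammaln(nk - xk + 1)
        return lp

    obs = logp(t[:, 0])
    total = 0.0
    K = len(n_rows)

    def rec(row, remaining, xs):
        nonlocal total
        if row == K - 1:
            if 0 <= remaining <= n_rows[-1]:
                lp = logp(xs + [remaining])
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(n_rows[row + 1:].sum()))
        hi = min(int(n_rows[row]), remaining)
        for x in range(lo, hi + 1):
            rec(row + 1, remaining - x, xs + [x])

    rec(0, m, [])
    return float(min(total, 1.0)), "exact"


def biomarker_enrichment(assignments, records: pd.DataFrame,
                         biomarkers=None) -> pd.DataFrame:
    """Cross-cluster enrichment of binary biomarkers among RIS subjects.

    Missing values are excluded per biomarker (subject-level availability
    gaps); the reported denominators count non-missing subjects. One exact
    K x 2 test per biomarker (chi-square fallback flagged in ``method``).
    """
    from .cohort import BIOMARKERS

    biomarkers = list(biomarkers) if biomarkers is not None else BIOMARKERS
    labels = np.asarray(assignments)
    rows = []
    for b in biomarkers:
        col = records[b].astype("string")
        avail = (col.notna() & (col != "")).to_numpy()
        pos = (col == "yes").fillna(False).to_numpy()
        uniq = np.unique(labels)
        table = []
        cluster_rates = {}
        for c in uniq:
            sel = (labels == c) & avail
            npos = int(pos[sel].sum())
            table.append([npos, int(sel.sum()) - npos])
            cluster_rates[f"rate_c{c}"] = npos / sel.sum() if sel.sum() else np.nan
        tab = np.asarray(table)
        if tab.sum() == 0 or tab[:, 0].sum() in (0, tab.sum()):
            p, method = 1.0, "degenerate"  # biomarker constant across clusters
        else:
            p, method = exact_kx2_test(tab)
        rows.append(dict(biomarker=b, n_available=int(avail.sum()),
                         p_value=p, method=method, **cluster_rates))
    return pd.DataFrame(rows).set_index("biomarker")


# ---------------------------------------------------------------------------
# multinomial membership model

@dataclass
class MembershipFit:
    """Multinomial logistic fit of cluster membership on covariates."""

    coef_table: pd.DataFrame
    converged: bool
    separation_flag: bool
    llf: float
    predicted: np.ndarray

    def summary(self) -> pd.DataFrame:
        return self.coef_table


def multinomial_membership_model(assignments, covariates: pd.DataFrame,
                                 penalized: bool = False,
                                 alpha: float = 1.0) -> MembershipFit:
    """Model cluster membership (reference = lowest cluster) on covariates.

    Complete-case analysis: rows with missing covariates are dropped.
    Possible separation (huge coefficients / non-convergence) is flagged;
    ``penalized=True`` refits with an L1 penalty.
    """
    import statsmodels.api as sm

    labels = np.asarray(assignments)
    X = covariates.copy()
    keep = ~X.isna().any(axis=1).to_numpy()
    X, labels = X[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("need >= 2 clusters for the membership model")
    # encode to 0..K-1 with cluster 1 (lowest) as reference
    uniq = np.unique(labels)
    endog = np.searchsorted(uniq, labels)
    if X.shape[1] == 0:  # intercept-only model
        exog = pd.DataFrame({"const": np.ones(len(endog))})
    else:
        exog = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.MNLogit(endog, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if penalized:
            res = model.fit_regularized(method="l1", alpha=alpha, disp=0)
            converged = True
        else:
            res = model.fit(method="newton", maxiter=200, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
    params = np.asarray(res.params)  # (n_exog, K-1)
    bse = np.asarray(res.bse)
    separation = (not converged) or bool(np.abs(params).max() > 15.0)
    rows = []
    for j, cl in enumerate(uniq[1:]):
        for i, name in enumerate(exog.columns):
            se = bse[i, j]
            zstat = params[i, j] / se if se > 0 else np.nan
            rows.append(dict(cluster=cl, covariate=name, coef=params[i, j],
                             se=se, z=zstat,
                             p_value=2 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else np.nan))
    table = pd.DataFrame(rows)
    predicted = np.asarray(res.predict(exog))
    return MembershipFit(table, converged, separation, float(res.llf), predicted)


# ---------------------------------------------------------------------------
# model/results wrapper

class RiskStratifier:
    """Risk-cluster model over RIS deviation profiles (fit() -> results).

    Parameters
    ----------
    profiles : array-like
        RIS subjects x features matrix (typically the z-score profiles).
    outcomes : array-like of bool
        Conversion outcome per subject.
    k_clusters : int
        Number of clusters (default 4).
    cluster_on : {"embedding", "profiles"}
        Cluster the 2-D embedded coordinates (default) or the full profiles.
    """

    def __init__(self, profiles, outcomes, subject_ids=None, k_clusters: int = 4,
                 n_boot: int = 2000, seed: int = 0, method: str = "umap",
                 cluster_on: str = "embedding", n_init: int = 10):
        self.profiles = np.asarray(profiles, float)
        self.outcomes = np.asarray(outcomes, bool)
        if len(self.profiles) != len(self.outcomes):
            raise ConfigurationError("profiles and outcomes lengths differ")
        if np.isnan(self.profiles).any():
            raise ConfigurationError("profiles contain NaN")
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"S{i}" for i in range(len(self.outcomes))])
        self.k_clusters = k_clusters
        self.n_boot = n_boot
        self.seed = seed
        self.method = method
        self.cluster_on = cluster_on
        self.n_init = n_init

    def fit(self) -> "RiskClusterResults":
        coords = embed_2d(self.profiles, seed=self.seed, method=self.method)
        basis = coords if self.cluster_on == "embedding" else self.profiles
        raw = cluster_kmeans(basis, self.k_clusters, seed=self.seed, n_init=self.n_init)
        assignments = renumber_by_rate(raw, self.outcomes)
        rates = conversion_rates(assignments, self.outcomes, self.n_boot, self.seed)
        rates["risk_label"] = label_risk(rates["rate"])
        fisher = pairwise_cluster_tests(assignments, self.outcomes)
        return RiskClusterResults(self, coords, assignments, rates, fisher)


class RiskClusterResults:
    """Cluster assignments, conversion rates with CIs, Fisher p-matrix, labels."""

    def __init__(self, model: RiskStratifier, coordinates, assignments, rates, fisher):
        self.model = model
        self.coordinates = np.asarray(coordinates)
        self.assignments = pd.Series(assignments,
                                     index=pd.Index(model.subject_ids, name="subject_id"),
                                     name="cluster")
        self.rates = rates
        self.pairwise_fisher = fisher

    def summary(self) -> pd.DataFrame:
        return self.rates

    def biomarker_enrichment(self, records: pd.DataFrame, biomarkers=None) -> pd.DataFrame:
        return biomarker_enrichment(self.assignments.to_numpy(), records, biomarkers)

    def membership_model(self, covariates: pd.DataFrame, **kw) -> MembershipFit:
        return multinomial_membership_model(self.assignments.to_numpy(), covariates, **kw)

    def to_json_dict(self) -> dict:
        return {
            "rates": self.rates.reset_index().to_dict(orient="records"),
            "pairwise_fisher": self.pairwise_fisher.to_dict(),
            "n_subjects": int(len(self.assignments)),
        }
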