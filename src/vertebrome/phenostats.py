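"""Pattern-level statistics for vertebral phenomes.

The workhorse is the global test (Goeman's score test against a
high-dimensional alternative): with a binary group indicator as response
and the per-vertebra values of one element/outcome combination as
covariates, it asks whether the pattern across vertebrae differs between
groups. It is powerful when many correlated covariates each carry a small
effect — exactly the situation for measures distributed along the spine.

For centered response residuals ``e = y - ybar`` and covariate matrix
``X`` (fish x vertebrae), the statistic is the quadratic form

    Q = e' X X' e / k,

the sum of per-vertebra components ``Q_j = (x_j' e)^2 / k``. Covariates
are deliberately not standardized, preserving the covariance-driven
weighting of the test. The default null distribution is the exact
Gaussian-rotation law of the scale-free ratio ``T = Q / (e'e)``: a
mixture of chi-squares with weights given by the eigenvalues of
``C (XX'/k - T I) C`` (``C`` the centering projection), inverted
numerically by Imhof's method. An exact/sampled permutation null is
available as an option. The module also provides per-vertebra covariate
decomposition, skeletal-barcode standard scores, pairwise correlation
profiling, and Royston's multivariate-normality screen.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._quadform import imhof_tail
from .morphometry import MEASURES, Phenome

__all__ = [
    "DEFAULT_VERTEBRA_WINDOW",
    "FeatureCurve",
    "GlobalTestResult",
    "RoystonResult",
    "feature_curve",
    "global_test",
    "covariate_components",
    "standard_scores",
    "correlation_profile",
    "royston_test",
]

#: Vertebra window used by default in pattern analyses (anterior-most 16).
DEFAULT_VERTEBRA_WINDOW: tuple[int, ...] = tuple(range(1, 17))

_MAX_EXACT_PERMUTATIONS = 20_000


@dataclass
class FeatureCurve:
    """One element/outcome combination across fish and vertebrae.

    ``matrix`` is n fish x k vertebrae; ``groups`` holds the per-fish
    group labels (exactly two distinct values for testing).
    """

    matrix: np.ndarray
    groups: np.ndarray
    feature: str = ""
    vertebrae: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be n x k with k >= 1")
        if len(self.groups) != self.matrix.shape[0]:
            raise ValueError("one group label per fish required")


@dataclass
class GlobalTestResult:
    """Global-test outcome with its per-vertebra decomposition."""

    statistic: float
    p: float
    per_vertebra: pd.DataFrame
    feature: str = ""
    method: str = "asymptotic"
    group_sizes: tuple[int, int] = (0, 0)


@dataclass
class RoystonResult:
    H: float
    p: float
    edf: float


def feature_curve(
    phenomes: list[Phenome],
    feature: str,
    vertebrae: tuple[int, ...] = DEFAULT_VERTEBRA_WINDOW,
    max_missing_frac: float = 0.25,
) -> FeatureCurve:
    """Extract one feature's fish x vertebra matrix from a cohort.

    The analysis is restricted to the intersection of vertebrae present
    (non-missing) in all retained fish within the window; fish missing
    more than ``max_missing_frac`` of the window are excluded with a
    warning.
    """
    if feature not in MEASURES:
        raise KeyError(f"unknown measure {feature!r}")
    keep = []
    for ph in phenomes:
        present = [
            v
            for v in vertebrae
            if v in ph.table.index and np.isfinite(ph.table.loc[v, feature])
        ]
        if len(present) < (1.0 - max_missing_frac) * len(vertebrae):
            warnings.warn(
                f"{ph.fish_id}: missing >{max_missing_frac:.0%} of the vertebra "
                "window; excluded",
                stacklevel=2,
            )
            continue
        keep.append((ph, set(present)))
    if not keep:
        raise ValueError("no fish retained in the vertebra window")
    common = sorted(set(vertebrae).intersection(*(s for _, s in keep)))
    if not common:
        raise ValueError("no vertebrae shared by all retained fish")
    mat = np.array([[ph.table.loc[v, feature] for v in common] for ph, _ in keep])
    groups = np.array([ph.group for ph, _ in keep])
    return FeatureCurve(mat, groups, feature=feature, vertebrae=tuple(common))


# ---------------------------------------------------------------------------
# Global test
# ---------------------------------------------------------------------------

def _encode_groups(groups: np.ndarray) -> np.ndarray:
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq.tolist()}")
    y = (groups == uniq[1]).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("constant response: both groups must be non-empty")
    return y


def _component_statistics(X: np.ndarray, e: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    return (X.T @ e) ** 2 / k


def _ratio_p(X: np.ndarray, e: np.ndarray, q: float) -> float:
    """Exact Gaussian-rotation p of the ratio statistic q = e'Re / e'e."""
    n = X.shape[0]
    R = X @ X.T / X.shape[1]
    C = np.eye(n) - 1.0 / n
    t = q / (e @ e)
    lams = np.linalg.eigvalsh(C @ (R - t * np.eye(n)) @ C)
    return imhof_tail(lams, 0.0)


def global_test(
    curve: FeatureCurve,
    method: str = "asymptotic",
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> GlobalTestResult:
    """Test whether a vertebral pattern differs between two groups.

    ``method='asymptotic'`` (default) inverts the chi-square-mixture null
    numerically; ``method='permutation'`` permutes group labels, by exact
    enumeration when the number of distinct assignments is at most 20,000
    and by ``n_perm`` random draws otherwise.
    """
    X = curve.matrix
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values in the analyzed vertebra range")
    y = _encode_groups(curve.groups)
    n, k = X.shape
    e = y - y.mean()
    comp = _component_statistics(X, e)
    q = float(comp.sum())

    if method == "asymptotic":
        p = _ratio_p(X, e, q)
        # component tests are single-covariate global tests; their raw
        # statistic is (x_j'e)^2 = k * comp[j]
        comp_p = np.array([_ratio_p(X[:, [j]], e, k * comp[j]) for j in range(k)])
    elif method == "permutation":
        n1 = int(y.sum())
        xe_all = X.T  # k x n
        from math import comb

        def stats_for(yperm):
            ep = yperm - yperm.mean()
            c = (xe_all @ ep) ** 2 / k
            return c

        if comb(n, n1) <= _MAX_EXACT_PERMUTATIONS:
            assigns = itertools.combinations(range(n), n1)
            perm_q = []
            perm_comp = []
            for pos in assigns:
                yp = np.zeros(n)
                yp[list(pos)] = 1.0
                c = stats_for(yp)
                perm_comp.append(c)
                perm_q.append(c.sum())
            perm_q = np.array(perm_q)
            perm_comp = np.array(perm_comp)
            p = float((perm_q >= q - 1e-12).mean())
            comp_p = (perm_comp >= comp[None, :] - 1e-12).mean(axis=0)
        else:
            gen = (
                rng
                if isinstance(rng, np.random.Generator)
                else np.random.default_rng(rng)
            )
            hits = np.zeros(k + 1)
            for _ in range(n_perm):
                yp = gen.permutation(y)
                c = stats_for(yp)
                hits[:k] += c >= comp - 1e-12
                hits[k] += c.sum() >= q - 1e-12
            p = float((hits[k] + 1) / (n_perm + 1))
            comp_p = (hits[:k] + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    vert = curve.vertebrae or tuple(range(1, k + 1))
    per_vertebra = pd.DataFrame(
        {"statistic": comp, "p": comp_p}, index=pd.Index(vert, name="vertebra")
    )
    n1 = int(y.sum())
    return GlobalTestResult(
        statistic=q,
        p=float(p),
        per_vertebra=per_vertebra,
        feature=curve.feature,
        method=method,
        group_sizes=(n - n1, n1),
    )


def covariate_components(result: GlobalTestResult, alpha: float = 0.05) -> list[int]:
    """Vertebrae whose component p-value falls below ``alpha`` (unadjusted)."""
    sig = result.per_vertebra.index[result.per_vertebra["p"] < alpha]
    return list(sig)


# ---------------------------------------------------------------------------
# Skeletal barcodes
# ---------------------------------------------------------------------------

def standard_scores(
    phenome: Phenome,
    controls: list[Phenome],
    measures: tuple[str, ...] = MEASURES,
    vertebrae: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Skeletal-barcode standard scores of one fish against a control pool.

    For each measure, ``z = (value - m) / s`` where ``m`` and ``s`` are
    the mean and SD of that measure pooled over all vertebrae and all
    control fish. Returns a vertebra x measure matrix; measures with zero
    pooled control SD are flagged as NaN with a warning.
    """
    if not controls:
        raise ValueError("control population must be non-empty")
    table = phenome.table if vertebrae is None else phenome.table.loc[list(vertebrae)]
    out = pd.DataFrame(index=table.index, columns=list(measures), dtype=float)
    for m in measures:
        pooled = np.concatenate(
            [
                c.table[m].to_numpy()
                if vertebrae is None
                else c.table.loc[list(vertebrae), m].to_numpy()
                for c in controls
            ]
        )
        pooled = pooled[np.isfinite(pooled)]
        mu = pooled.mean()
        sd = pooled.std()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"zero control SD for {m}: scores undefined", stacklevel=2)
            out[m] = np.nan
        else:
            out[m] = (table[m] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Correlation profiling
# ---------------------------------------------------------------------------

def correlation_profile(
    phenomes: list[Phenome],
    vertebrae: tuple[int, ...] | None = None,
    measures: tuple[str, ...] = MEASURES,
    min_fish: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Absolute pairwise Pearson correlations of all vertebra x measure pairs.

    Each (measure, vertebra) measurement becomes a vector across fish;
    fish with a missing value in either member of a pair are excluded from
    that pair. Measurements observed in fewer than ``min_fish`` fish are
    dropped with a warning. The matrix is ordered by average-linkage
    hierarchical clustering of the distance ``1 - |rho|`` (cosmetic).
    Returns the ordered matrix and the median off-diagonal ``|rho|``.
    """
    if len(phenomes) < 3:
        raise ValueError("need at least 3 fish for correlation profiling")
    if vertebrae is None:
        vertebrae = tuple(
            sorted(set().union(*(set(ph.table.index) for ph in phenomes)))
        )
    cols = {}
    for m in measures:
        for v in vertebrae:
            vals = [
                ph.table.loc[v, m] if v in ph.table.index else np.nan
                for ph in phenomes
            ]
            cols[f"{m}@v{v}"] = vals
    wide = pd.DataFrame(cols, index=[ph.fish_id for ph in phenomes])
    n_obs = wide.notna().sum(axis=0)
    dropped = n_obs[n_obs < min_fish].index
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} measurements observed in < {min_fish} fish",
            stacklevel=2,
        )
        wide = wide.drop(columns=dropped)
    corr = wide.corr(method="pearson", min_periods=min_fish).abs()

    # order by average-linkage clustering of 1 - |rho|
    filled = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(filled, 1.0)
    dist = squareform(1.0 - filled, checks=False)
    order = hierarchy.leaves_list(hierarchy.average(dist))
    ordered = corr.iloc[order, order]

    off = ordered.to_numpy()[~np.eye(len(ordered), dtype=bool)]
    median_abs = float(np.nanmedian(off))
    return ordered, median_abs


# ---------------------------------------------------------------------------
# Royston multivariate-normality screen
# ---------------------------------------------------------------------------

def royston_test(data: np.ndarray) -> RoystonResult:
    """Royston's H test for multivariate normality.

    Combines per-variable Shapiro-Wilk statistics (through their normal
    equivalent deviates) with an equivalent-degrees-of-freedom correction
    for inter-variable correlation; H is referred to a chi-square with
    ``edf`` degrees of freedom. Requires more observations than variables
    (subset the variables otherwise) and n >= 4.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n, k = data.shape
    if n <= k:
        raise ValueError(
            f"n={n} observations for k={k} variables: the test requires n > k; "
            "analyze subsets of variables"
        )
    if n < 4:
        raise ValueError("Royston's test requires n >= 4")

    # normal equivalent deviate of each Shapiro-Wilk p-value
    z = np.empty(k)
    for j in range(k):
        p_sw = stats.shapiro(data[:, j]).pvalue
        p_sw = float(np.clip(p_sw, 1e-300, 1 - 1e-16))
        z[j] = -stats.norm.ppf(p_sw)
    r_j = stats.norm.ppf(0.5 * stats.norm.cdf(-z)) ** 2

    if k == 1:
        edf = 1.0
    else:
        u = np.log(n)
        lam, mu_c = 5.0, 0.715
        v = 0.21364 + 0.015124 * u**2 - 0.0018034 * u**3
        corr = np.corrcoef(data, rowvar=False)
        iu = np.triu_indices(k, 1)
        r = corr[iu]
        c = r**lam * (1.0 - (mu_c / v) * (1.0 - r) ** mu_c)
        cbar = float(np.mean(c))
        edf = k / (1.0 + (k - 1) * cbar)

    H = edf * float(np.sum(r_j)) / k
    p = float(stats.chi2.sf(H, edf))
    return RoystonResult(H=H, p=p, edf=float(edf))
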