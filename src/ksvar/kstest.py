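"""Two-sample Kolmogorov-Smirnov machinery for small cohorts.

This module holds the statistical core of the package: the scaled-MAD
variability metric, a two-sample KS test with exact small-sample
p-values (including a permutation route that stays exact in the presence
of tied values), the expression-level test, the variability test on
absolute deviations from each group's median, and the four-way gene
classification that separates level changes from variability changes.

Exactness strategy
------------------
For tie-free samples with ``n*m <= exact_limit`` the p-value is the
standard exact two-sided probability ``P(D' >= D)`` from the
distribution-free path-counting recursion.  Tied observations break that
recursion, so with ties the permutation distribution of D is evaluated
directly: by exhaustive enumeration of all C(n+m, n) group assignments
when that count fits the enumeration budget, otherwise by a seeded
Monte-Carlo sample of permutations with an add-one correction.  Beyond
``exact_limit`` the asymptotic Kolmogorov distribution is used.

Note that for even group sizes the two central order statistics are
always equidistant from the group median, so the variability test input
contains ties by construction and routinely takes the permutation route.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata, ValidationError

DEFAULT_ALPHA = 0.01
#: exact p-values whenever n*m is at most this (covers 10 vs 10 easily)
EXACT_LIMIT = 10_000
#: enumerate all C(n+m, n) assignments up to this count (C(20,10)=184756)
ENUM_BUDGET = 200_000
#: Monte-Carlo permutations when enumeration exceeds the budget
MC_PERMUTATIONS = 100_000

LABELS = ("de_low_var", "dysregulated_var", "both_flagged", "neither")


# ---------------------------------------------------------------------------
# Spread metric
# ---------------------------------------------------------------------------

def scaled_mad(x) -> float:
    """Median absolute deviation divided by the median.

    Dimensionless spread measure comparable across expression magnitudes.
    Undefined (NaN) when the median is zero; such genes are excluded from
    spread summaries but not from the KS tests.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValidationError("scaled_mad requires at least one value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if med == 0:
        return math.nan
    return mad / med


def abs_deviations(x) -> np.ndarray:
    """Absolute deviations of each value from the vector's median."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValidationError("abs_deviations requires at least one value")
    return np.abs(x - np.median(x))


# ---------------------------------------------------------------------------
# Two-sample KS test
# ---------------------------------------------------------------------------

def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| over the pooled support."""
    pooled = np.unique(np.concatenate([x, y]))
    cx = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    cy = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.abs(cx - cy).max())


@lru_cache(maxsize=8)
def _enum_cumsum(n: int, m: int) -> np.ndarray:
    """Cumulative group-x indicator along the sorted pool for every one of
    the C(n+m, n) assignments; shared across genes with equal group sizes."""
    N = n + m
    K = math.comb(N, n)
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(N), n)),
        dtype=np.intp,
        count=K * n,
    ).reshape(K, n)
    Z = np.zeros((K, N), dtype=np.int16)
    np.put_along_axis(Z, idx, 1, axis=1)
    return np.cumsum(Z, axis=1, dtype=np.int16)


def _max_d_scaled(cum: np.ndarray, last: np.ndarray, n: int, m: int) -> np.ndarray:
    # D*n*m = max over evaluation points of |cum*(n+m) - pos*n|, all integer
    pos = ((last + 1) * n).astype(np.int32)
    c = cum[:, last].astype(np.int32)
    return np.abs(c * (n + m) - pos).max(axis=1)


def _permutation_pvalue(x, y, d_obs, enum_budget, n_mc, rng) -> float:
    n, m = x.size, y.size
    N = n + m
    pooled = np.sort(np.concatenate([x, y]))
    # right-continuous ECDFs only need evaluation at the last index of each
    # run of tied values
    last = np.flatnonzero(np.r_[pooled[1:] != pooled[:-1], True])
    d_obs_scaled = int(round(d_obs * n * m))
    if math.comb(N, n) <= enum_budget:
        cum = _enum_cumsum(n, m)
        d_all = _max_d_scaled(cum, last, n, m)
        return float(np.count_nonzero(d_all >= d_obs_scaled) / d_all.size)
    rng = np.random.default_rng(rng)
    base = np.r_[np.ones(n, dtype=np.int16), np.zeros(m, dtype=np.int16)]
    Z = rng.permuted(np.tile(base, (n_mc, 1)), axis=1)
    cum = np.cumsum(Z, axis=1, dtype=np.int16)
    d_all = _max_d_scaled(cum, last, n, m)
    # add-one correction keeps the Monte-Carlo p-value strictly positive
    return float((np.count_nonzero(d_all >= d_obs_scaled) + 1) / (d_all.size + 1))


# exact p for tie-free data depends on (n, m, D) only; memoise across genes
_exact_cache: dict[tuple[int, int, int], float] = {}


def ks_two_sample(
    x,
    y,
    *,
    exact_limit: int = EXACT_LIMIT,
    enum_budget: int = ENUM_BUDGET,
    n_mc: int = MC_PERMUTATIONS,
    rng=None,
) -> tuple[float, float]:
    """Two-sided two-sample KS test; returns ``(D, p)``.

    See the module docstring for how exact, permutation and asymptotic
    p-values are selected.  ``rng`` seeds the Monte-Carlo fallback only.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValidationError("ks_two_sample requires at least two values per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("ks_two_sample requires finite values")
    n, m = x.size, y.size
    d = _ks_statistic(x, y)
    if n * m <= exact_limit:
        has_ties = np.unique(np.concatenate([x, y])).size < n + m
        if not has_ties:
            key = (n, m, int(round(d * n * m)))
            if key not in _exact_cache:
                # the path-counting recursion can fail for some (n, m, D);
                # scipy then silently switches to the asymptotic formula,
                # in which case enumeration restores exactness
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    p = float(stats.ks_2samp(x, y, method="exact").pvalue)
                if any("method=asymp" in str(c.message) for c in caught):
                    p = _permutation_pvalue(x, y, d, enum_budget, n_mc, 0 if rng is None else rng)
                _exact_cache[key] = p
            p = _exact_cache[key]
        else:
            p = _permutation_pvalue(x, y, d, enum_budget, n_mc, 0 if rng is None else rng)
    else:
        p = float(stats.ks_2samp(x, y, method="asymp").pvalue)
    return d, min(p, 1.0)


def ks_expression_test(values_case, values_control, **kwargs) -> tuple[float, float]:
    """KS test applied directly to the per-group expression values of one
    gene: a difference in expression level."""
    return ks_two_sample(values_case, values_control, **kwargs)


def ks_variability_test(values_case, values_control, **kwargs) -> tuple[float, float]:
    """KS test on absolute deviations from each group's own median: a
    difference in spread that ignores location.

    Deviations are rounded to 1e-9 before the comparison so that the
    test is exactly invariant under location shifts despite
    floating-point jitter in the median subtraction; on the log2(TPM+1)
    scale genuinely distinct deviations are never that close, and tied
    values are handled exactly by the permutation route.
    """
    dev_case = np.round(abs_deviations(values_case), 9)
    dev_control = np.round(abs_deviations(values_control), 9)
    return ks_two_sample(dev_case, dev_control, **kwargs)


# ---------------------------------------------------------------------------
# Per-gene records and classification
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "median_case",
    "median_control",
    "scaled_mad_case",
    "scaled_mad_control",
    "variability_ratio",
    "D_expr",
    "p_expr",
    "D_var",
    "p_var",
    "q_expr",
    "q_var",
    "label",
]


def ks_test_genes(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    alpha: float = DEFAULT_ALPHA,
    rng=None,
    **ks_kwargs,
) -> pd.DataFrame:
    """Run both KS tests for every gene of a log-scale matrix.

    Returns one row per gene: group medians, scaled MADs, the case/control
    variability ratio, both KS statistics and p-values, BH-adjusted
    q-values (reported for transparency; classification uses the raw
    p-values), and the classification label at ``alpha``.
    """
    if matrix.units != "log2TPM1p":
        raise ValidationError("ks_test_genes expects a log2TPM1p matrix")
    meta.check_matches(matrix)
    case = matrix.values[meta.case_ids].to_numpy()
    control = matrix.values[meta.control_ids].to_numpy()
    rows = np.empty((matrix.n_genes, 9), dtype=float)
    for g in range(matrix.n_genes):
        xc, xk = case[g], control[g]
        d_e, p_e = ks_expression_test(xc, xk, rng=rng, **ks_kwargs)
        d_v, p_v = ks_variability_test(xc, xk, rng=rng, **ks_kwargs)
        sm_c = scaled_mad(xc)
        sm_k = scaled_mad(xk)
        ratio = sm_c / sm_k if sm_k != 0 and not math.isnan(sm_k) else math.nan
        rows[g] = (
            np.median(xc), np.median(xk), sm_c, sm_k, ratio, d_e, p_e, d_v, p_v,
        )
    df = pd.DataFrame(
        rows,
        index=matrix.gene_ids,
        columns=RECORD_COLUMNS[:9],
    )
    df["q_expr"] = multipletests(df["p_expr"], method="fdr_bh")[1]
    df["q_var"] = multipletests(df["p_var"], method="fdr_bh")[1]
    df.index.name = "gene_id"
    return classify_genes(df, alpha=alpha)


def classify_genes(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Assign each gene exactly one label from the 2x2 significance rule.

    ``de_low_var``: expression test significant, variability test not —
    a level change with comparable spread.  ``dysregulated_var``: only
    the variability test significant — a spread change at similar level.
    ``both_flagged``: both significant.  ``neither``: neither.
    Significance is strict (p < alpha); p equal to alpha is not
    significant.
    """
    sig_e = records["p_expr"].to_numpy() < alpha
    sig_v = records["p_var"].to_numpy() < alpha
    label = np.select(
        [sig_e & ~sig_v, ~sig_e & sig_v, sig_e & sig_v],
        ["de_low_var", "dysregulated_var", "both_flagged"],
        default="neither",
    )
    out = records.copy()
    out["label"] = label
    return out


@dataclass
class DirectionSplit:
    """Direction breakdown of the classified genes.

    Level-change genes split by the sign of (median_case -
    median_control); variability genes by the sign of (scaled_mad_case -
    scaled_mad_control).  Exact zero differences land in the tie buckets.
    """

    up_case: set
    down_case: set
    de_ties: set
    var_up_case: set
    var_up_control: set
    var_ties: set


def split_by_direction(records: pd.DataFrame) -> DirectionSplit:
    if "label" not in records.columns:
        raise ValidationError("records must be classified before splitting by direction")
    de = records[records["label"] == "de_low_var"]
    dmed = de["median_case"] - de["median_control"]
    dys = records[records["label"] == "dysregulated_var"]
    dmad = dys["scaled_mad_case"] - dys["scaled_mad_control"]
    return DirectionSplit(
        up_case=set(de.index[dmed > 0]),
        down_case=set(de.index[dmed < 0]),
        de_ties=set(de.index[dmed == 0]),
        var_up_case=set(dys.index[dmad > 0]),
        var_up_control=set(dys.index[dmad < 0]),
        var_ties=set(dys.index[(dmad == 0) | dmad.isna()]),
    )


def direction_labels(records: pd.DataFrame, which: str = "de_low_var") -> dict[str, str]:
    """Map each labelled gene to ``up``/``down`` (case relative to control);
    exact ties map to ``tie``."""
    if which == "de_low_var":
        sub = records[records["label"] == "de_low_var"]
        diff = sub["median_case"] - sub["median_control"]
    elif which == "dysregulated_var":
        sub = records[records["label"] == "dysregulated_var"]
        diff = sub["scaled_mad_case"] - sub["scaled_mad_control"]
    else:
        raise ValidationError(f"unknown record class {which!r}")
    out: dict[str, str] = {}
    for gene, d in diff.items():
        out[gene] = "tie" if (d == 0 or math.isnan(d)) else ("up" if d > 0 else "down")
    return out
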