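"""Signature-level statistics downstream of the gene classification.

Covers the 2x2 Pearson chi-square on direction contingency (no
continuity correction), standardized PCA of a gene signature, Spearman
correlation of signature genes against clinical covariates with
pairwise deletion, and relative expression profiling of risk genes
across cell types with t-based confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, SampleMetadata, ValidationError


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    p: float
    df: int = 1


def chi_square_2x2(table) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, one degree of freedom, without
    Yates continuity correction; expected counts from the margins."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("both margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(table=t.astype(int), chi2=float(chi2), p=float(p), df=int(df))


def direction_contingency(
    pd_direction: Mapping[str, str],
    celltype_direction: Mapping[str, str],
) -> np.ndarray:
    """Cross-tabulate two up/down labelings of the same gene set.

    Rows: first axis up/down; columns: second axis up/down.  Genes with
    a ``tie`` on either axis are excluded with a warning.
    """
    if set(pd_direction) != set(celltype_direction):
        raise ValidationError("the two direction maps must cover the same gene set")
    if not pd_direction:
        raise ValidationError("direction maps must not be empty")
    table = np.zeros((2, 2), dtype=int)
    ties = []
    idx = {"up": 0, "down": 1}
    for gene, d1 in pd_direction.items():
        d2 = celltype_direction[gene]
        if d1 not in idx or d2 not in idx:
            ties.append(gene)
            continue
        table[idx[d1], idx[d2]] += 1
    if ties:
        warnings.warn(f"{len(ties)} genes with tied direction excluded", stacklevel=2)
    return table


def pca_signature(
    matrix: ExpressionMatrix,
    meta: SampleMetadata | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over a standardized gene signature.

    The matrix should already be restricted to the signature genes on the
    log2(TPM+1) scale.  Each gene is standardized across samples (mean 0,
    variance 1); zero-variance genes are dropped with a warning.  Samples
    are the observations.  Component signs follow a deterministic
    convention: the largest-magnitude gene loading of each component is
    positive.  Returns (projections, explained-variance ratios); when
    metadata is given the projections carry a ``group`` column.
    """
    if matrix.units != "log2TPM1p":
        raise ValidationError("pca_signature expects a log2TPM1p matrix")
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    if matrix.n_genes < 2:
        raise ValidationError("the signature must hold at least two genes")
    vals = matrix.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes", stacklevel=2)
    if keep.sum() < 2:
        raise ValidationError("fewer than two genes with non-zero variance")
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    x = z.T  # samples x genes
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(x)
    # deterministic sign: largest |loading| positive per component
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            proj[:, j] *= -1.0
            pca.components_[j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    out = pd.DataFrame(proj, index=matrix.sample_ids, columns=cols)
    out.index.name = "sample_id"
    if meta is not None:
        meta.check_matches(matrix)
        out["group"] = meta.table.loc[out.index, "group"]
    return out, pca.explained_variance_ratio_


def spearman_clinical(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    meta: SampleMetadata,
    covariates: Sequence[str] | None = None,
    min_pairs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x covariate Spearman correlations with pairwise deletion.

    Ranks use midranks for ties.  Pairs with fewer than ``min_pairs``
    complete observations, or a constant covariate/gene over the complete
    pairs, are reported as NaN.  Returns ``(rho, n_pairs)`` frames.
    """
    if matrix.units not in ("TPM", "log2TPM1p"):
        raise ValidationError("spearman_clinical expects TPM or log2TPM1p values")
    meta.check_matches(matrix)
    genes = list(genes)
    missing = set(genes) - set(matrix.gene_ids)
    if missing:
        raise ValidationError(f"genes absent from matrix: {sorted(missing)[:10]}")
    if covariates is None:
        covariates = [c for c in meta.table.columns if c != "group"]
    expr = matrix.values.loc[genes, matrix.sample_ids]
    if matrix.units == "TPM":
        expr = np.log2(expr + 1.0)
    rho = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene_id"), columns=covariates)
    npairs = pd.DataFrame(0, index=rho.index, columns=covariates, dtype=int)
    for cov in covariates:
        c = meta.covariate(cov).loc[matrix.sample_ids].to_numpy(dtype=float)
        ok = np.isfinite(c)
        npairs[cov] = int(ok.sum())
        if ok.sum() < min_pairs or np.unique(c[ok]).size < 2:
            continue
        for gene in genes:
            e = expr.loc[gene].to_numpy(dtype=float)[ok]
            if np.unique(e).size < 2:
                continue
            rho.loc[gene, cov] = stats.spearmanr(e, c[ok]).statistic
    return rho, npairs


@dataclass
class RiskGeneProfile:
    """Per-gene per-cell-type expression summary for a risk-gene list.

    ``table`` is long-form: gene_id, cell_type, n, mean_tpm, mean_log2,
    ci_low, ci_high (t-based 95% interval on log2(TPM+1)).  ``category``
    maps each profiled gene to monocyte_enriched / microglia_enriched /
    shared; ``missing`` lists genes absent from at least one matrix;
    ``below_min_tpm`` lists genes under the display threshold in every
    cell type (kept in the category counts, excluded from the CI table).
    """

    table: pd.DataFrame
    category: pd.Series
    missing: list[str]
    below_min_tpm: list[str]


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    mean = float(values.mean())
    n = values.size
    if n < 2:
        return mean, math.nan, math.nan
    sem = values.std(ddof=1) / math.sqrt(n)
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1) * sem)
    return mean, mean - half, mean + half


def risk_gene_profile(
    matrices: Mapping[str, ExpressionMatrix],
    genes: Iterable[str],
    min_tpm: float = 2.0,
    fold: float = 2.0,
    reference: str = "monocyte_control",
    comparator: str = "microglia",
) -> RiskGeneProfile:
    """Profile a gene list across cell-type matrices (TPM units).

    Enrichment categories compare group means of TPM: a gene is
    ``monocyte_enriched`` when the reference mean exceeds ``fold`` times
    the comparator mean, ``microglia_enriched`` for the converse, and
    ``shared`` otherwise.  Confidence intervals are t-based on
    log2(TPM+1).
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("risk gene list must not be empty")
    for name in (reference, comparator):
        if name not in matrices:
            raise ValidationError(f"matrix {name!r} is required for categorisation")
    for name, m in matrices.items():
        if m.units != "TPM":
            raise ValidationError(f"matrix {name!r} must be in TPM units")
    missing = sorted(
        {g for g in genes for m in matrices.values() if g not in m.gene_ids}
    )
    if missing:
        warnings.warn(f"{len(missing)} risk genes missing from at least one matrix", stacklevel=2)
    profiled = [g for g in genes if g not in set(missing)]
    rows = []
    mean_tpm: dict[str, dict[str, float]] = {}
    for name, m in matrices.items():
        mean_tpm[name] = {}
        for gene in profiled:
            tpm = m.values.loc[gene].to_numpy(dtype=float)
            mean_tpm[name][gene] = float(tpm.mean())
            mean_log2, lo, hi = _t_ci(np.log2(tpm + 1.0))
            rows.append(
                {
                    "gene_id": gene,
                    "cell_type": name,
                    "n": tpm.size,
                    "mean_tpm": float(tpm.mean()),
                    "mean_log2": mean_log2,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    category = {}
    below = []
    for gene in profiled:
        ref = mean_tpm[reference][gene]
        comp = mean_tpm[comparator][gene]
        if ref > fold * comp:
            category[gene] = "monocyte_enriched"
        elif comp > fold * ref:
            category[gene] = "microglia_enriched"
        else:
            category[gene] = "shared"
        if all(mean_tpm[name][gene] <= min_tpm for name in matrices):
            below.append(gene)
    table = pd.DataFrame(rows)
    if len(table):
        table = table[~table["gene_id"].isin(below)].reset_index(drop=True)
    cat = pd.Series(category, name="category")
    cat.index.name = "gene_id"
    return RiskGeneProfile(table=table, category=cat, missing=missing, below_min_tpm=below)
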