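"""Baseline differential-expression calling and cross-validation robustness.

The baseline caller pairs a per-gene two-sided Wilcoxon rank-sum test on
log2(TPM+1) with Benjamini-Hochberg FDR control and a mean fold-change
filter.  It is a deliberately generic stand-in for count-model callers:
the robustness machinery accepts any callable with the same signature,
so a negative-binomial backend can be plugged in externally.

Robustness is probed with leave-some-out cohorts: each fold removes a
fixed number of samples per group at random, the caller (or the KS
expression test) is re-run on the retained samples, and gene lists are
compared through pairwise overlap matrices.  A gene is *robust* when its
KS expression p-value stays below the robustness threshold in every fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata, ValidationError
from .kstest import ks_expression_test


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_call(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    fc_cutoff: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum + BH + fold-change differential-expression caller.

    Works on a TPM matrix; the test runs on log2(TPM+1), the fold change
    on group means of TPM with a pseudocount of 1.  A gene is called when
    its BH q-value is below ``fdr`` *and* its absolute log2 fold change
    reaches ``log2(fc_cutoff)``.  Returns per-gene ``log2fc``, ``p``,
    ``q`` and a boolean ``called`` column.
    """
    if matrix.units != "TPM":
        raise ValidationError("de_call expects a TPM matrix")
    meta.check_matches(matrix)
    case_ids, control_ids = meta.case_ids, meta.control_ids
    if len(case_ids) < 3 or len(control_ids) < 3:
        raise ValidationError("de_call requires at least three samples per group")
    case = matrix.values[case_ids].to_numpy()
    control = matrix.values[control_ids].to_numpy()
    log_case = np.log2(case + 1.0)
    log_control = np.log2(control + 1.0)
    res = stats.mannwhitneyu(log_case, log_control, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    q = bh_adjust(p)
    log2fc = np.log2(case.mean(axis=1) + 1.0) - np.log2(control.mean(axis=1) + 1.0)
    called = (q < fdr) & (np.abs(log2fc) >= math.log2(fc_cutoff))
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "called": called},
        index=matrix.gene_ids,
    )
    out.index.name = "gene_id"
    return out


@dataclass
class Fold:
    """One leave-some-out cohort: the excluded ids per group and the
    retained sample ids in matrix order."""

    excluded_case: list[str]
    excluded_control: list[str]
    retained: list[str]


def make_cv_folds(
    meta: SampleMetadata,
    k: int = 5,
    n_excl: int = 2,
    seed: int | None = None,
) -> list[Fold]:
    """``k`` folds, each excluding ``n_excl`` random samples per group.

    Exclusions are drawn without replacement within a fold and
    independently across folds (folds may overlap).  ``n_excl = 0``
    reproduces the full cohort in every fold.
    """
    case_ids, control_ids = meta.case_ids, meta.control_ids
    if n_excl < 0 or k <= 0:
        raise ValidationError("k must be positive and n_excl non-negative")
    if n_excl >= len(case_ids) or n_excl >= len(control_ids):
        raise ValidationError("n_excl must be smaller than each group size")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(k):
        exc_case = sorted(rng.choice(case_ids, size=n_excl, replace=False).tolist())
        exc_control = sorted(rng.choice(control_ids, size=n_excl, replace=False).tolist())
        dropped = set(exc_case) | set(exc_control)
        retained = [s for s in meta.sample_ids if s not in dropped]
        folds.append(Fold(exc_case, exc_control, retained))
    return folds


def overlap_matrix(sets: Sequence[Iterable]) -> np.ndarray:
    """Pairwise intersection sizes; diagonal holds the set sizes."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValidationError("overlap_matrix needs at least two sets")
    k = len(sets)
    out = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            out[i, j] = out[j, i] = len(sets[i] & sets[j])
    return out


def cross_validate_caller(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    folds: Sequence[Fold],
    caller: Callable[..., pd.DataFrame] = de_call,
    **caller_kwargs,
) -> tuple[set, list[set], pd.DataFrame]:
    """Run a DE caller on the full cohort and on every fold.

    Returns the full-cohort gene set, the per-fold sets, and the
    (k+1)x(k+1) overlap matrix with the full cohort as the first
    row/column.
    """
    full = set(_called_genes(caller(matrix, meta, **caller_kwargs)))
    fold_sets = []
    for fold in folds:
        sub_meta = meta.subset(fold.retained)
        sub_matrix = matrix.subset_samples(fold.retained)
        fold_sets.append(set(_called_genes(caller(sub_matrix, sub_meta, **caller_kwargs))))
    names = ["full"] + [f"fold_{i + 1}" for i in range(len(folds))]
    mat = overlap_matrix([full, *fold_sets])
    return full, fold_sets, pd.DataFrame(mat, index=names, columns=names)


def _called_genes(result: pd.DataFrame) -> list:
    if "called" not in result.columns:
        raise ValidationError("caller result must have a boolean 'called' column")
    return result.index[result["called"]].tolist()


def ks_cv_robustness(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    gene_set: Iterable[str],
    folds: Sequence[Fold],
    p_threshold: float = 0.05,
    **ks_kwargs,
) -> tuple[set, pd.Series]:
    """Re-test genes on every fold; robust iff max fold p < threshold.

    For each gene the KS expression p-value is recomputed on each fold's
    retained samples.  Returns the robust gene set and the per-gene
    maximum fold p-value.  The threshold is strict.
    """
    genes = list(gene_set)
    missing = set(genes) - set(matrix.gene_ids)
    if missing:
        raise ValidationError(f"genes absent from matrix: {sorted(missing)[:10]}")
    max_p = pd.Series(np.nan, index=pd.Index(genes, name="gene_id"), dtype=float)
    if not genes:
        return set(), max_p
    fold_groups = []
    for fold in folds:
        sub = meta.subset(fold.retained)
        fold_groups.append((sub.case_ids, sub.control_ids))
    vals = matrix.values
    for gene in genes:
        row = vals.loc[gene]
        worst = 0.0
        for case_ids, control_ids in fold_groups:
            _, p = ks_expression_test(
                row[case_ids].to_numpy(), row[control_ids].to_numpy(), **ks_kwargs
            )
            worst = max(worst, p)
        max_p.loc[gene] = worst
    robust = set(max_p.index[max_p < p_threshold])
    return robust, max_p
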