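"""Expression-matrix containers, TSV input/output and matrix transforms.

The convention throughout the package is genes as rows and samples as
columns.  A matrix carries a unit tag with three states:

``counts``
    raw read counts per gene body;
``TPM``
    transcripts per kilobase million, i.e. length-normalised expression
    where every sample sums to a common scale;
``log2TPM1p``
    ``log2(TPM + pseudocount)``, the scale on which the statistical tests
    and all downstream summaries operate.

All tables are plain tab-separated text with a header row: the expression
matrix has the gene identifier in the first column and one column per
sample; gene annotations are ``gene_id, symbol, biotype, length_bp``;
sample metadata is ``sample_id, group`` followed by clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNITS = ("counts", "TPM", "log2TPM1p")

#: canonical clinical covariate columns, in metadata-file order
COVARIATES = (
    "age",
    "disease_duration",
    "UPDRS_III",
    "LEDD",
    "TNFa",
    "IL6",
    "IL8",
    "CRP",
    "monocyte_count",
)

ANNOTATION_COLUMNS = ("symbol", "biotype", "length_bp")


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression table with unit tag and annotations.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    units
        One of ``counts``, ``TPM`` or ``log2TPM1p``.
    annotations
        Optional per-gene table (index gene_id) with columns ``symbol``,
        ``biotype`` and ``length_bp``.  May cover a superset of the genes
        in ``values``; every gene in ``values`` must be covered whenever
        an operation needs annotations.
    """

    values: pd.DataFrame
    units: str = "TPM"
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic structure ---------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}; expected one of {UNITS}")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(vals).any():
            bad = self.values.index[np.isnan(vals).any(axis=1)][:5].tolist()
            raise ValidationError(f"missing expression values in rows {bad}")
        if self.units in ("counts", "TPM") and (vals < 0).any():
            bad = self.values.index[(vals < 0).any(axis=1)][:5].tolist()
            raise ValidationError(f"negative {self.units} values in rows {bad}")
        if self.annotations is not None:
            ann = self.annotations
            missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
            if missing_cols:
                raise ValidationError(f"annotation table lacks columns {sorted(missing_cols)}")
            _check_unique(ann.index, "annotation gene ids")
            if (pd.to_numeric(ann["length_bp"], errors="coerce") <= 0).any():
                raise ValidationError("annotation length_bp must be positive")

    def annotations_for_all_genes(self) -> pd.DataFrame:
        """Annotations restricted to the matrix genes; error on gaps."""
        if self.annotations is None:
            raise ValidationError("gene annotations are required but absent")
        missing = self.gene_ids.difference(self.annotations.index)
        if len(missing):
            raise ValidationError(f"genes without annotation: {missing[:10].tolist()}")
        return self.annotations.loc[self.gene_ids]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.units, self.annotations)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.units, self.annotations)


@dataclass
class SampleMetadata:
    """Per-sample group labels and clinical covariates.

    ``table`` is indexed by sample id, carries a mandatory ``group``
    column with values ``case``/``control`` (both groups non-empty) and
    numeric covariate columns.  Missing covariate values are NaN.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.table.index, "sample ids")
        if "group" not in self.table.columns:
            raise ValidationError("metadata must have a 'group' column")
        groups = set(self.table["group"].unique())
        if not groups <= {"case", "control"}:
            raise ValidationError(f"unknown group labels: {sorted(groups - {'case', 'control'})}")
        if groups != {"case", "control"}:
            raise ValidationError("both 'case' and 'control' groups must be non-empty")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def case_ids(self) -> list[str]:
        return self.table.index[self.table["group"] == "case"].tolist()

    @property
    def control_ids(self) -> list[str]:
        return self.table.index[self.table["group"] == "control"].tolist()

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise ValidationError(f"covariate {name!r} absent from metadata")
        return pd.to_numeric(self.table[name], errors="coerce")

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must have exactly one metadata row."""
        missing = matrix.sample_ids.difference(self.table.index)
        if len(missing):
            raise ValidationError(f"samples without metadata: {missing.tolist()}")

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, units: str, annotations: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene id, header row samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(df, units=units, annotations=annotations)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    for col in tab.columns:
        if col != "group":
            tab[col] = pd.to_numeric(tab[col], errors="coerce")
    return SampleMetadata(tab)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def counts_to_tpm(matrix: ExpressionMatrix, lengths: pd.Series | None = None, scale: float = 1e6) -> ExpressionMatrix:
    """Length-normalise raw counts to TPM.

    Per sample, ``TPM_g = scale * (count_g / length_g) / sum_h(count_h / length_h)``,
    so each sample column sums to ``scale`` (1e6 by default).  ``lengths``
    defaults to the ``length_bp`` annotation column.
    """
    if matrix.units != "counts":
        raise ValidationError(f"counts_to_tpm expects counts, got {matrix.units}")
    if lengths is None:
        lengths = matrix.annotations_for_all_genes()["length_bp"]
    lengths = pd.to_numeric(lengths.loc[matrix.gene_ids])
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = matrix.values.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total rate: {zero}")
    tpm = rate.div(totals, axis=1) * scale
    return ExpressionMatrix(tpm, units="TPM", annotations=matrix.annotations)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(TPM + pseudocount)``; the analysis scale."""
    if matrix.units != "TPM":
        raise ValidationError(f"log_transform expects TPM, got {matrix.units}")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    logv = np.log2(matrix.values + pseudocount)
    return ExpressionMatrix(logv, units="log2TPM1p", annotations=matrix.annotations)


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 10.0, min_samples: int = 1) -> ExpressionMatrix:
    """Keep genes expressed at ``threshold`` TPM or greater (inclusive) in
    at least ``min_samples`` samples."""
    if matrix.units != "TPM":
        raise ValidationError(f"filter_expressed expects TPM, got {matrix.units}")
    keep = (matrix.values >= threshold).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.units, matrix.annotations)


def exclude_biotypes(matrix: ExpressionMatrix, biotypes=frozenset({"snoRNA", "miRNA"})) -> ExpressionMatrix:
    """Drop genes whose annotated biotype is in ``biotypes`` (small-RNA
    decoys by default); gene order otherwise preserved."""
    biotypes = set(biotypes)
    if not biotypes:
        return matrix
    ann = matrix.annotations_for_all_genes()
    keep = ~ann["biotype"].isin(biotypes)
    if not keep.any():
        warnings.warn("biotype exclusion removed every gene", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep.to_numpy()], matrix.units, matrix.annotations)


def rank_top_genes(matrix: ExpressionMatrix, k: int) -> list[str]:
    """Top-``k`` genes by mean expression across samples, descending;
    ties broken lexicographically by gene id."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > matrix.n_genes:
        raise ValidationError(f"k={k} exceeds the number of genes ({matrix.n_genes})")
    means = matrix.values.mean(axis=1)
    order = means.to_frame("mean").assign(gene=means.index)
    order = order.sort_values(["mean", "gene"], ascending=[False, True])
    return order.index[:k].tolist()
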