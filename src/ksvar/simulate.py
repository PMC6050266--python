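"""Synthetic two-group expression data with planted effects.

The generator emulates the structure of a small case-control bulk
RNA-seq cohort on the scale the analysis consumes: per gene, log2
expression is drawn as Normal(mu_g, sigma_g) per sample and
exponentiated to TPM.  Three gene classes are planted:

``null``
    identical distribution in both groups;
``mean_shift``
    one group's mean raised by ``lfc`` log2 units (a >= 2-fold median
    shift at the default ``lfc=2`` ... ``lfc=1`` is 2-fold);
``var_shift``
    one group's standard deviation multiplied by ``vif``, symmetrically
    about the group mean, so the two group medians agree by construction
    — the configuration the variability test is designed to detect.

Planted genes always receive an expressed-level baseline (a spread
change in a gene below the detection filter would be unobservable);
null genes clear the 10-TPM filter with probability ``frac_expressed``.
A small fraction of null genes is annotated as snoRNA/miRNA decoys to
exercise the biotype exclusion.  Clinical covariates are drawn at
magnitudes typical for an early-course Parkinson cohort (ages near 60,
UPDRS-III motor scores in the teens, disease duration under three
years) and can afterwards be coupled to a gene signature with a target
Spearman correlation via :func:`simulate_clinical`.

Library-size effects, batch effects and gene-gene correlation are
deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ExpressionMatrix, SampleMetadata, ValidationError

GENE_CLASSES = ("null", "mean_shift", "var_shift")


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` is indexed by gene id with columns ``gene_class``,
    ``affected_group`` (empty for null genes), ``lfc``, ``vif``, ``mu``
    and ``sigma`` (baseline log2 mean and sd).
    """

    table: pd.DataFrame
    seed: int
    n_case: int
    n_control: int

    def genes_of_class(self, gene_class: str) -> list[str]:
        if gene_class not in GENE_CLASSES:
            raise ValidationError(f"unknown gene class {gene_class!r}")
        return self.table.index[self.table["gene_class"] == gene_class].tolist()


def _sample_ids(n_case: int, n_control: int) -> tuple[list[str], list[str]]:
    case = [f"case_{i + 1:02d}" for i in range(n_case)]
    control = [f"control_{i + 1:02d}" for i in range(n_control)]
    return case, control


def simulate_matrix(
    n_genes: int,
    n_case: int = 10,
    n_control: int = 10,
    *,
    frac_mean_shift: float = 0.05,
    frac_var_shift: float = 0.10,
    lfc: float = 2.0,
    vif: float = 3.0,
    sigma: float | tuple[float, float] = 0.3,
    frac_expressed: float = 0.85,
    frac_decoy: float = 0.04,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Generate a TPM matrix, sample metadata and the planted truth.

    Parameters
    ----------
    n_genes, n_case, n_control
        Matrix dimensions; at least three samples per group.
    frac_mean_shift, frac_var_shift
        Fractions of genes receiving a mean shift / variance inflation;
        non-negative with sum at most one.
    lfc
        Log2 mean shift added to the affected group of mean_shift genes.
    vif
        Factor multiplying the affected group's log-scale sd of
        var_shift genes (>= 1).
    sigma
        Baseline log2-scale sd; a scalar, or a ``(low, high)`` range
        sampled uniformly per gene.
    frac_expressed
        Probability that a null gene gets a high-expression baseline
        (log2 TPM around 6) rather than a near-silent one.
    frac_decoy
        Fraction of null genes annotated as snoRNA/miRNA decoys.
    seed
        Single global seed; all internal streams derive from it.
    """
    if n_case < 3 or n_control < 3:
        raise ValidationError("at least three samples per group are required")
    if frac_mean_shift < 0 or frac_var_shift < 0 or frac_mean_shift + frac_var_shift > 1:
        raise ValidationError("shift fractions must be non-negative and sum to at most 1")
    if lfc <= 0:
        raise ValidationError("lfc must be positive")
    if vif < 1:
        raise ValidationError("vif must be at least 1")
    rng = np.random.default_rng(seed)

    n_ms = int(round(frac_mean_shift * n_genes))
    n_vs = int(round(frac_var_shift * n_genes))
    classes = np.array(
        ["mean_shift"] * n_ms + ["var_shift"] * n_vs + ["null"] * (n_genes - n_ms - n_vs)
    )
    rng.shuffle(classes)
    planted = classes != "null"

    # baselines: planted genes always expressed, null genes per frac_expressed
    expressed = planted | (rng.random(n_genes) < frac_expressed)
    mu = np.where(
        expressed,
        rng.normal(6.0, 1.5, n_genes),
        rng.normal(0.5, 1.0, n_genes),
    )
    if np.isscalar(sigma):
        sig = np.full(n_genes, float(sigma))
    else:
        lo, hi = sigma
        sig = rng.uniform(lo, hi, n_genes)
    if (sig <= 0).any():
        raise ValidationError("sigma must be positive")

    affected = np.where(planted, rng.choice(["case", "control"], n_genes), "")

    case_ids, control_ids = _sample_ids(n_case, n_control)
    n_samples = n_case + n_control
    loc = np.tile(mu[:, None], (1, n_samples))
    scale = np.tile(sig[:, None], (1, n_samples))
    case_cols = np.arange(n_case)
    control_cols = np.arange(n_case, n_samples)
    ms = classes == "mean_shift"
    vs = classes == "var_shift"
    for cols, grp in ((case_cols, "case"), (control_cols, "control")):
        hit = affected == grp
        loc[np.ix_(ms & hit, cols)] += lfc
        scale[np.ix_(vs & hit, cols)] *= vif
    log2_expr = loc + scale * rng.standard_normal((n_genes, n_samples))
    tpm = np.exp2(log2_expr)

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    values = pd.DataFrame(tpm, index=gene_ids, columns=case_ids + control_ids)

    biotype = np.full(n_genes, "protein_coding", dtype=object)
    null_idx = np.flatnonzero(~planted)
    n_decoy = int(round(frac_decoy * null_idx.size))
    if n_decoy:
        decoys = rng.choice(null_idx, size=n_decoy, replace=False)
        half = n_decoy // 2
        biotype[decoys[:half]] = "snoRNA"
        biotype[decoys[half:]] = "miRNA"
    annotations = pd.DataFrame(
        {
            "symbol": gene_ids,
            "biotype": biotype,
            "length_bp": rng.integers(500, 100_001, n_genes),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    matrix = ExpressionMatrix(values, units="TPM", annotations=annotations)
    meta = _baseline_metadata(case_ids, control_ids, rng)
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "gene_class": classes,
                "affected_group": affected,
                "lfc": np.where(ms, lfc, 0.0),
                "vif": np.where(vs, vif, 1.0),
                "mu": mu,
                "sigma": sig,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        seed=seed,
        n_case=n_case,
        n_control=n_control,
    )
    return matrix, meta, truth


def _baseline_metadata(case_ids, control_ids, rng) -> SampleMetadata:
    """Covariates as independent noise at realistic clinical magnitudes;
    disease-specific fields are NaN for controls."""
    n_case, n_control = len(case_ids), len(control_ids)
    n = n_case + n_control
    nan_ctrl = np.r_[np.ones(n_case), np.full(n_control, np.nan)]
    tab = pd.DataFrame(index=pd.Index(case_ids + control_ids, name="sample_id"))
    tab["group"] = ["case"] * n_case + ["control"] * n_control
    tab["age"] = rng.normal(60.0, 4.0, n)
    tab["disease_duration"] = nan_ctrl * rng.uniform(0.5, 3.0, n)
    tab["UPDRS_III"] = nan_ctrl * rng.gamma(5.0, 3.1, n)
    tab["LEDD"] = nan_ctrl * rng.gamma(2.5, 124.0, n)
    tab["TNFa"] = rng.lognormal(2.0, 0.4, n)
    tab["IL6"] = rng.lognormal(0.9, 0.5, n)
    tab["IL8"] = rng.lognormal(2.2, 0.4, n)
    tab["CRP"] = rng.lognormal(0.5, 0.6, n)
    tab["monocyte_count"] = rng.normal(0.5, 0.08, n)
    return SampleMetadata(tab)


# ---------------------------------------------------------------------------
# Clinical covariate coupling
# ---------------------------------------------------------------------------

def _expected_spearman(r: float, n: int) -> float:
    # expectation of the Spearman coefficient for a bivariate normal with
    # Pearson correlation r at sample size n (Moran's small-sample formula)
    return 6.0 / (math.pi * (n + 1)) * (math.asin(r) + (n - 2) * math.asin(r / 2.0))


def _latent_pearson_for(rho_target: float, n: int) -> float:
    """Latent Pearson correlation whose expected Spearman coefficient at
    sample size n equals ``rho_target`` (magnitudes; sign handled by the
    caller)."""
    if rho_target >= 1.0:
        return 1.0
    if rho_target <= 0.0:
        return 0.0
    return float(optimize.brentq(lambda r: _expected_spearman(r, n) - rho_target, 0.0, 1.0))


#: covariates coupled to the signature and whether they exist for controls
DEFAULT_COUPLED = ("disease_duration", "UPDRS_III", "IL6")
_CASE_ONLY = frozenset({"disease_duration", "UPDRS_III", "LEDD"})


def simulate_clinical(
    meta: SampleMetadata,
    signature: list[str],
    matrix: ExpressionMatrix,
    rho_target: float = -0.7,
    seed: int = 0,
    coupled: tuple[str, ...] = DEFAULT_COUPLED,
) -> SampleMetadata:
    """Couple selected covariates to mean signature-gene expression.

    Each coupled covariate is regenerated as a monotone function of the
    per-sample mean log2(TPM+1) over ``signature`` plus Gaussian noise.
    The noise level is calibrated through a Gaussian-copula construction
    so the realised Spearman correlation averages ``rho_target`` at the
    available sample size; with ``|rho_target| = 1`` the covariate is an
    exact monotone transform.  Case-only covariates (disease duration,
    UPDRS-III, LEDD) are coupled over the case samples; the rest over
    all samples.  Uncoupled covariates are left untouched.
    """
    if not signature:
        raise ValidationError("signature gene list must not be empty")
    if abs(rho_target) > 1:
        raise ValidationError("rho_target must lie in [-1, 1]")
    missing = set(signature) - set(matrix.gene_ids)
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {sorted(missing)[:10]}")
    if matrix.units == "TPM":
        logv = np.log2(matrix.values.loc[list(signature)] + 1.0)
    elif matrix.units == "log2TPM1p":
        logv = matrix.values.loc[list(signature)]
    else:
        raise ValidationError("simulate_clinical expects a TPM or log2TPM1p matrix")
    score = logv.mean(axis=0)  # per-sample mean signature expression

    rng = np.random.default_rng(seed)
    tab = meta.table.copy()
    sign = 1.0 if rho_target >= 0 else -1.0
    for cov in coupled:
        if cov not in tab.columns:
            raise ValidationError(f"coupled covariate {cov!r} absent from metadata")
        ids = meta.case_ids if cov in _CASE_ONLY else list(meta.sample_ids)
        s = score.loc[ids].to_numpy()
        n = len(ids)
        base = pd.to_numeric(tab.loc[ids, cov])
        loc = float(np.nanmean(base))
        spread = float(np.nanstd(base))
        if not np.isfinite(loc):
            loc = 0.0
        if not np.isfinite(spread) or spread == 0:
            spread = 1.0
        if abs(rho_target) == 1.0:
            z = (s - s.mean()) / (s.std() or 1.0)
            latent = sign * z
        else:
            r = _latent_pearson_for(abs(rho_target), n)
            ranks = stats.rankdata(s)
            z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
            z = (z - z.mean()) / (z.std() or 1.0)
            latent = sign * (r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n))
        tab[cov] = np.nan
        tab.loc[ids, cov] = loc + spread * latent
    return SampleMetadata(tab)


def simulate_comparator(
    truth: SyntheticTruth,
    n_samples: int = 10,
    delta_sd: float = 1.5,
    prefix: str = "comp",
    seed: int = 0,
) -> ExpressionMatrix:
    """A companion cell-type matrix over the same genes.

    Per gene, the log2 mean is offset from the cohort baseline by a
    Normal(0, ``delta_sd``) cell-type effect, so roughly half the genes
    are higher and half lower than the source cohort — a stand-in for a
    second myeloid population (e.g. microglia versus monocytes) in fully
    synthetic runs.
    """
    if n_samples < 2:
        raise ValidationError("comparator needs at least two samples")
    rng = np.random.default_rng(seed)
    tab = truth.table
    n_genes = len(tab)
    delta = rng.normal(0.0, delta_sd, n_genes)
    mu = tab["mu"].to_numpy() + delta
    sig = tab["sigma"].to_numpy()
    log2_expr = mu[:, None] + sig[:, None] * rng.standard_normal((n_genes, n_samples))
    values = pd.DataFrame(
        np.exp2(log2_expr),
        index=tab.index,
        columns=[f"{prefix}_{i + 1:02d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(values, units="TPM")
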