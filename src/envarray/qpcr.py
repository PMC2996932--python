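"""Standard-curve efficiencies and efficiency-corrected ΔCt fold changes.

A dilution series of template yields a standard curve ``Ct = intercept +
slope * log10(dilution)`` with ``slope < 0`` for an amplifying assay; the
per-cycle amplification efficiency is ``E = 10**(-1/slope) - 1`` (E = 1
means perfect doubling, slope ≈ -3.32).  Relative expression between two
conditions is then computed against a reference gene (16S rRNA here, since
it tracks organism abundance) with the efficiency-corrected ΔCt formula::

    fold = (1 + E_target)**ΔCt_target / (1 + E_reference)**ΔCt_reference

with ``ΔCt = mean Ct(plankton) - mean Ct(biofilm)`` so that genes induced
in the biofilm give fold > 1.  With E = 1 on both assays this reduces
exactly to the classic 2**(ΔΔCt).  The fold's SD comes from first-order
(delta-method) propagation of the replicate Ct scatter; a bootstrap
alternative is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REFERENCE_GENE = "16S"


class QpcrError(ValueError):
    """Unusable qPCR input (degenerate dilution series, non-amplifying assay...)."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10(dilution) and the implied efficiency."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    gene: str | None = None

    def summary(self) -> str:
        return (
            f"StandardCurve(gene={self.gene}, slope={self.slope:.4f}, "
            f"intercept={self.intercept:.3f}, r2={self.r_squared:.5f}, "
            f"E={self.efficiency:.4f})"
        )


@dataclass(frozen=True)
class QpcrFold:
    """Efficiency-corrected fold change of one gene against the reference."""

    gene_id: str
    fold: float
    sd: float
    reference_gene: str = REFERENCE_GENE
    delta_ct_target: float = np.nan
    delta_ct_reference: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold) or self.fold <= 0:
            raise ValueError(f"fold must be positive and finite, got {self.fold}")

    @property
    def log2_fold(self) -> float:
        return float(np.log2(self.fold))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency ``E = 10**(-1/slope) - 1`` from a curve slope.

    A perfect-doubling assay has slope -1/log10(2) ≈ -3.3219 → E = 1; the
    efficiency tends to 0 as the slope steepens to -∞.  Non-negative slopes
    are rejected as non-amplifying.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise QpcrError(f"non-amplifying assay: slope must be < 0, got {slope}")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(
    dilution: np.ndarray, ct: np.ndarray, gene: str | None = None
) -> StandardCurve:
    """Ordinary least squares of Ct on log10(dilution) over all wells.

    Requires at least two distinct dilution levels; a non-negative slope is
    flagged as non-amplifying.
    """
    dilution = np.asarray(dilution, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if dilution.shape != ct.shape:
        raise QpcrError("dilution and Ct arrays must align")
    if np.any(dilution <= 0):
        raise QpcrError("dilutions must be positive fractions")
    if len(np.unique(dilution)) < 2:
        raise QpcrError("need >= 2 distinct dilution levels for a standard curve")
    x = np.log10(dilution)
    fit = stats.linregress(x, ct)
    efficiency = efficiency_from_slope(fit.slope)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency,
        gene=gene,
    )


def _delta_ct(ct_plankton: np.ndarray, ct_biofilm: np.ndarray,
              biofilm_positive: bool) -> tuple[float, float]:
    """Mean Ct difference and its variance from replicate scatter."""
    cp = np.asarray(ct_plankton, dtype=float)
    cb = np.asarray(ct_biofilm, dtype=float)
    if cp.size == 0 or cb.size == 0:
        raise QpcrError("need Ct replicates for both conditions")
    delta = float(cp.mean() - cb.mean())
    if not biofilm_positive:
        delta = -delta
    var = 0.0
    for arr in (cp, cb):
        if arr.size > 1:
            var += float(arr.var(ddof=1)) / arr.size
    return delta, var


def fold_change(
    ct_target_plankton: np.ndarray,
    ct_target_biofilm: np.ndarray,
    ct_reference_plankton: np.ndarray,
    ct_reference_biofilm: np.ndarray,
    e_target: float,
    e_reference: float,
    gene_id: str = "target",
    reference_gene: str = REFERENCE_GENE,
    biofilm_positive: bool = True,
    sd_method: str = "delta",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> QpcrFold:
    """Efficiency-corrected ΔCt fold change with an SD.

    ``ΔCt = mean Ct(plankton) - mean Ct(biofilm)`` for both assays (flip
    with ``biofilm_positive=False``), then ``fold = (1+E_t)**ΔCt_t /
    (1+E_r)**ΔCt_r``.  ``sd_method`` is ``"delta"`` (first-order
    propagation of the triplicate Ct scatter, the default) or
    ``"bootstrap"`` (resampling wells within each condition).
    """
    for name, e in (("target", e_target), ("reference", e_reference)):
        if not 0 < e <= 1.2:
            raise QpcrError(f"{name} efficiency outside (0, 1.2]: {e}")
    if ct_reference_plankton is None or ct_reference_biofilm is None:
        raise QpcrError("missing reference-gene Ct values")

    d_t, var_t = _delta_ct(ct_target_plankton, ct_target_biofilm, biofilm_positive)
    d_r, var_r = _delta_ct(ct_reference_plankton, ct_reference_biofilm, biofilm_positive)
    lt, lr = np.log(1.0 + e_target), np.log(1.0 + e_reference)
    fold = float(np.exp(lt * d_t - lr * d_r))

    if sd_method == "delta":
        sd = fold * float(np.sqrt(lt**2 * var_t + lr**2 * var_r))
    elif sd_method == "bootstrap":
        rng = rng if rng is not None else np.random.default_rng(0)
        groups = [np.asarray(a, dtype=float) for a in (
            ct_target_plankton, ct_target_biofilm,
            ct_reference_plankton, ct_reference_biofilm)]
        boots = np.empty(n_boot)
        for i in range(n_boot):
            means = [rng.choice(g, size=g.size, replace=True).mean() for g in groups]
            dt = (means[0] - means[1]) if biofilm_positive else (means[1] - means[0])
            dr = (means[2] - means[3]) if biofilm_positive else (means[3] - means[2])
            boots[i] = np.exp(lt * dt - lr * dr)
        sd = float(boots.std(ddof=1))
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")

    return QpcrFold(
        gene_id=gene_id, fold=fold, sd=sd, reference_gene=reference_gene,
        delta_ct_target=d_t, delta_ct_reference=d_r,
    )


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct well table CSV (columns gene, condition, replicate, dilution, ct)."""
    table = pd.read_csv(path)
    required = {"gene", "condition", "replicate", "dilution", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise QpcrError(f"{path}: missing columns {sorted(missing)}")
    return table


def analyze_ct_table(
    wells: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    sd_method: str = "delta",
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, StandardCurve], list[QpcrFold]]:
    """Full qPCR workflow over a well table.

    Fits one standard curve per gene from the ``condition == "standard"``
    wells, then computes each target gene's efficiency-corrected fold
    change from the biofilm/plankton sample wells against the reference.
    """
    genes = list(dict.fromkeys(wells["gene"]))
    if reference_gene not in genes:
        raise QpcrError(f"reference gene {reference_gene!r} absent from Ct table")

    curves: dict[str, StandardCurve] = {}
    for gene in genes:
        std = wells[(wells["gene"] == gene) & (wells["condition"] == "standard")]
        if len(std) == 0:
            raise QpcrError(f"no dilution series for gene {gene!r}")
        curves[gene] = fit_standard_curve(std["dilution"], std["ct"], gene=gene)

    def _cts(gene: str, condition: str) -> np.ndarray:
        sel = wells[(wells["gene"] == gene) & (wells["condition"] == condition)]
        return sel["ct"].to_numpy()

    ref_p, ref_b = _cts(reference_gene, "plankton"), _cts(reference_gene, "biofilm")
    folds = [
        fold_change(
            _cts(gene, "plankton"), _cts(gene, "biofilm"), ref_p, ref_b,
            curves[gene].efficiency, curves[reference_gene].efficiency,
            gene_id=gene, reference_gene=reference_gene,
            sd_method=sd_method, rng=rng,
        )
        for gene in genes if gene != reference_gene
    ]
    return curves, folds


def concordance_report(
    gene_calls: pd.DataFrame,
    qpcr_folds: list[QpcrFold] | pd.DataFrame,
    campaigns: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene array-vs-qPCR comparison and the sign-agreement fraction.

    ``gene_calls`` is the tiered gene table from
    :func:`envarray.selection.run_selection`; the array estimate per gene is
    the mean of its campaign log2 ratios.  Agreement means the array log2
    ratio and the qPCR log2 fold share a sign.  An empty overlap yields an
    empty table, a warning, and NaN agreement.
    """
    if isinstance(qpcr_folds, pd.DataFrame):
        qp = qpcr_folds[["gene_id", "fold"]].copy()
    else:
        qp = pd.DataFrame({"gene_id": [f.gene_id for f in qpcr_folds],
                           "fold": [f.fold for f in qpcr_folds]})
    if campaigns is None:
        campaigns = [c for c in gene_calls.columns
                     if c not in {"gene_id", "n_probes", "n_detected", "detected_anywhere", "tier"}]
    array_log2 = gene_calls[campaigns].mean(axis=1, skipna=True)
    calls = pd.DataFrame({"gene_id": gene_calls["gene_id"], "array_log2_ratio": array_log2})
    merged = calls.merge(qp, on="gene_id", how="inner")
    if len(merged) == 0:
        log.warning("concordance_report: no overlap between array calls and qPCR genes")
        return merged.assign(qpcr_log2_fold=[], sign_agree=[]), float("nan")
    merged["qpcr_log2_fold"] = np.log2(merged["fold"])
    merged["sign_agree"] = np.sign(merged["array_log2_ratio"]) == np.sign(merged["qpcr_log2_fold"])
    agreement = float(merged["sign_agree"].mean())
    return merged.drop(columns="fold"), agreement
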