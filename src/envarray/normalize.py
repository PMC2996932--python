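"""Within-array normalization of two-color expression ratios.

The per-spot statistics live in MA space: ``M = log2(biofilm/plankton)`` and
``A = (log2 biofilm + log2 plankton)/2``, both computed on
background-subtracted foregrounds.  Normalization proceeds in two steps:

1. **LOWESS dye-bias correction** — a locally weighted degree-1 regression
   of M on A (tricube kernel, bisquare robustifying iterations) estimates
   the intensity-dependent dye bias, which is subtracted from M.
2. **Abundance correction** — when the hybridized RNA is a community
   extract, the target organism's share of it may differ between samples.
   Subtracting ``log2(r)``, where ``r`` is the organism's biofilm/plankton
   abundance ratio measured at a reference phylochip probe, removes this
   confound so that the corrected M reflects per-cell expression change.

The two steps interact: a *centering* LOWESS (the classic form, default for
:func:`lowess_normalize`) absorbs any constant offset — including the
``log2(r)`` confound — into the trend, which silently assumes the bulk of
genes is unchanged and the organism equally represented.  When an external
abundance measurement is available, that assumption is not needed:
``preserve_level=True`` removes only the A-dependent *shape* of the trend
and leaves the global level to be anchored by the abundance correction.
:func:`normalize_array` picks the appropriate composition automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from envarray.io import ArrayExperiment
from envarray.pam import ReferenceRatio
from envarray.selection import detect_spots

log = logging.getLogger(__name__)

MIN_LOWESS_POINTS = 10


class LowessError(ValueError):
    """Raised when a LOWESS fit is impossible (too few usable points)."""


@dataclass(frozen=True)
class LowessParams:
    """Smoother settings: tricube kernel, local degree-1 fits.

    span
        Fraction of points in each local neighborhood, in (0, 1].
    robust_iters
        Number of bisquare reweighting passes down-weighting outliers.
    """

    span: float = 0.4
    robust_iters: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.robust_iters < 0:
            raise ValueError(f"robust_iters must be >= 0, got {self.robust_iters}")


def background_subtract(spots: pd.DataFrame) -> pd.DataFrame:
    """Per-channel background subtraction, floored at zero.

    Adds ``fg_biofilm``/``fg_plankton`` columns (``max(f - b, 0)``).  Spots
    floored to zero in a channel get undefined M/A downstream.
    """
    out = spots.copy()
    out["fg_biofilm"] = np.maximum(out["f_biofilm"] - out["b_biofilm"], 0.0)
    out["fg_plankton"] = np.maximum(out["f_plankton"] - out["b_plankton"], 0.0)
    return out


def ma_values(fg_biofilm: np.ndarray, fg_plankton: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MA coordinates; NaN wherever either corrected foreground is zero."""
    fb = np.asarray(fg_biofilm, dtype=float)
    fp = np.asarray(fg_plankton, dtype=float)
    ok = (fb > 0) & (fp > 0)
    A = np.full(fb.shape, np.nan)
    M = np.full(fb.shape, np.nan)
    lb, lp = np.log2(fb[ok]), np.log2(fp[ok])
    A[ok] = (lb + lp) / 2.0
    M[ok] = lb - lp
    return A, M


def lowess_fit(A: np.ndarray, M: np.ndarray, params: LowessParams | None = None) -> np.ndarray:
    """Fitted LOWESS trend of M on A, evaluated at each input point.

    Local degree-1 weighted least squares over the span-nearest neighbors
    in A with tricube weights and ``robust_iters`` bisquare passes.  Points
    with non-finite A or M receive NaN trend values and do not influence
    the fit.  Fewer than 10 usable points is an error.
    """
    params = params or LowessParams()
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    ok = np.isfinite(A) & np.isfinite(M)
    if ok.sum() < MIN_LOWESS_POINTS:
        raise LowessError(f"need >= {MIN_LOWESS_POINTS} finite (A, M) points, got {int(ok.sum())}")
    trend = np.full(A.shape, np.nan)
    trend[ok] = _sm_lowess(
        M[ok], A[ok], frac=params.span, it=params.robust_iters, return_sorted=False
    )
    return trend


def lowess_normalize(
    array: ArrayExperiment | pd.DataFrame,
    params: LowessParams | None = None,
    preserve_level: bool = False,
    background_factor: float = 3.0,
) -> pd.DataFrame:
    """Background-correct and LOWESS-normalize one array.

    Returns a per-probe table with ``probe_id, A, M_raw, trend, M_lowess,
    detected, flag``.  Flagged spots are excluded from the fit (their trend
    is interpolated from the fitted curve) but still reported.

    With ``preserve_level=False`` the full trend (including its constant
    level) is subtracted — the classic centering normalization.  With
    ``preserve_level=True`` the trend mean is added back, so only the
    A-dependent dye-bias shape is removed and the global log-ratio level
    survives for a subsequent abundance correction.
    """
    spots = array.spots if isinstance(array, ArrayExperiment) else array
    spots = background_subtract(spots)
    A, M = ma_values(spots["fg_biofilm"].to_numpy(), spots["fg_plankton"].to_numpy())
    detected = detect_spots(spots, background_factor)
    unflagged = (spots["flag"].to_numpy() == 0) & np.isfinite(A) & np.isfinite(M)

    trend = np.full(A.shape, np.nan)
    trend[unflagged] = lowess_fit(A[unflagged], M[unflagged], params)
    # flagged spots: evaluate the fitted curve at their A by interpolation
    needs = np.isfinite(A) & np.isfinite(M) & ~unflagged
    if needs.any():
        order = np.argsort(A[unflagged])
        trend[needs] = np.interp(A[needs], A[unflagged][order], trend[unflagged][order])

    level = float(np.nanmean(trend[unflagged])) if preserve_level else 0.0
    m_lowess = M - trend + level
    return pd.DataFrame(
        {
            "probe_id": spots["probe_id"].to_numpy(),
            "A": A,
            "M_raw": M,
            "trend": trend,
            "M_lowess": m_lowess,
            "detected": detected,
            "flag": spots["flag"].to_numpy(),
        }
    )


def abundance_correct(probes: pd.DataFrame, ref: ReferenceRatio | float) -> pd.DataFrame:
    """Subtract ``log2(r)`` from every probe's M — a uniform, order-preserving shift.

    ``ref`` is a :class:`~envarray.pam.ReferenceRatio` from the phylochip
    (or a bare positive ratio).  The shift is applied to ``M_lowess`` (or
    ``M_raw`` if no LOWESS column is present) and stored as ``M_corrected``.
    """
    if ref is None:
        raise ValueError("abundance correction requires a reference ratio")
    r = ref.r if isinstance(ref, ReferenceRatio) else float(ref)
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"reference ratio must be positive and finite, got {r}")
    out = probes.copy()
    base = "M_lowess" if "M_lowess" in out.columns else "M_raw"
    out["M_corrected"] = out[base] - np.log2(r)
    return out


def normalize_array(
    array: ArrayExperiment,
    params: LowessParams | None = None,
    ref_ratio: ReferenceRatio | float | None = None,
    background_factor: float = 3.0,
    preserve_level: bool | None = None,
) -> pd.DataFrame:
    """Full within-array normalization pipeline.

    Background subtraction → LOWESS → (optional) abundance correction.
    When a reference ratio is supplied, the LOWESS step defaults to
    preserve-level mode so the externally measured ``r`` — not the
    unchanged-majority assumption — anchors the global ratio level; the
    two corrections then compose without double-counting the confound.
    Without a reference ratio the classic centering LOWESS is used and
    ``M_corrected`` is left undefined (NaN).
    """
    if preserve_level is None:
        preserve_level = ref_ratio is not None
    probes = lowess_normalize(array, params, preserve_level=preserve_level,
                              background_factor=background_factor)
    if ref_ratio is not None:
        probes = abundance_correct(probes, ref_ratio)
    else:
        probes["M_corrected"] = np.nan
    return probes


def plot_ma(probes: pd.DataFrame, ax=None, corrected: bool = False):
    """MA plot of a normalized-probe table with the fitted trend overlaid.

    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ycol = "M_corrected" if corrected and probes["M_corrected"].notna().any() else "M_raw"
    ax.scatter(probes["A"], probes[ycol], s=4, alpha=0.4, label=ycol)
    if not corrected:
        order = np.argsort(probes["A"].to_numpy())
        ax.plot(probes["A"].to_numpy()[order], probes["trend"].to_numpy()[order],
                color="crimson", lw=1.5, label="LOWESS trend")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("A (mean log2 intensity)")
    ax.set_ylabel("M (log2 biofilm/plankton)")
    ax.legend(frameon=False)
    return ax
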