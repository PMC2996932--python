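"""Active-community profiling from a phylochip (PAM) hybridization.

The prokaryotic acidophile microarray (PAM) carries oligonucleotide probes
targeting the rRNA of known acidophiles.  Hybridizing the two-color labeled
total RNA of a biofilm and a plankton sample to it yields, per taxon probe,
a detection call in each sample and a log2 biofilm/plankton signal ratio —
a profile of the metabolically *active* community (rRNA signal, not cell
counts; no absolute abundances are claimed).

Two outputs feed the rest of the pipeline:

- a per-taxon community profile with a dominance class per probe
  (biofilm-dominant / plankton-dominant / similar / undetected);
- the **reference-strain abundance ratio** ``r``: the biofilm/plankton
  signal ratio of the probe targeting the organism whose genomic array is
  used for expression profiling (probe ``LEP439`` by default).  This ratio
  calibrates the abundance correction in :mod:`envarray.normalize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from envarray.io import ArrayExperiment

log = logging.getLogger(__name__)

REFERENCE_PROBE = "LEP439"

DOMINANCE_CLASSES = ("biofilm", "plankton", "similar", "undetected")


class ReferenceProbeError(ValueError):
    """Reference probe missing or undetected — abundance correction impossible."""


@dataclass(frozen=True)
class ReferenceRatio:
    """Strain abundance ratio biofilm/plankton at the reference probe."""

    r: float
    probe_id: str = REFERENCE_PROBE
    campaign: str = "NA"

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or self.r <= 0:
            raise ValueError(f"reference ratio must be positive and finite, got {self.r}")

    @property
    def log2_r(self) -> float:
        return float(np.log2(self.r))


def taxon_signals(
    pam_array: ArrayExperiment,
    taxon_map: pd.Series | None = None,
    background_factor: float = 3.0,
) -> pd.DataFrame:
    """Background-subtracted per-probe signals and per-channel detection calls.

    Detection reuses the expression-array rule — foreground strictly greater
    than ``background_factor`` × background — applied per channel here, since
    each channel is an independent sample on the phylochip.  Signals are
    floored at zero; the log2 ratio is defined only where both floored
    signals are positive.  Probes absent from ``taxon_map`` are retained as
    ``"unassigned"`` with a warning.
    """
    spots = pam_array.spots
    sig_b = np.maximum(spots["f_biofilm"] - spots["b_biofilm"], 0.0).to_numpy()
    sig_p = np.maximum(spots["f_plankton"] - spots["b_plankton"], 0.0).to_numpy()
    det_b = (spots["f_biofilm"] > background_factor * spots["b_biofilm"]).to_numpy()
    det_p = (spots["f_plankton"] > background_factor * spots["b_plankton"]).to_numpy()
    ratio = np.full(len(spots), np.nan)
    ok = (sig_b > 0) & (sig_p > 0)
    ratio[ok] = np.log2(sig_b[ok] / sig_p[ok])

    out = pd.DataFrame(
        {
            "probe_id": spots["probe_id"].to_numpy(),
            "signal_biofilm": sig_b,
            "signal_plankton": sig_p,
            "detected_biofilm": det_b,
            "detected_plankton": det_p,
            "log2_ratio": ratio,
        }
    )
    if taxon_map is not None:
        taxa = taxon_map.reindex(out["probe_id"])
        n_missing = int(taxa.isna().sum())
        if n_missing:
            log.warning("%d PAM probes absent from taxon layout, kept as unassigned", n_missing)
        out.insert(1, "taxon", taxa.fillna("unassigned").to_numpy())
    return out


def dominance_classify(log2_ratio, threshold: float = 1.0):
    """Classify a finite log2 biofilm/plankton ratio into a dominance class.

    ``>= +threshold`` → biofilm-dominant, ``<= -threshold`` →
    plankton-dominant, otherwise similar; boundary values fall into the
    dominant class.  Non-finite ratios map to ``"undetected"``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    arr = np.asarray(log2_ratio, dtype=float)
    out = np.full(arr.shape, "similar", dtype=object)
    out[arr >= threshold] = "biofilm"
    out[arr <= -threshold] = "plankton"
    out[~np.isfinite(arr)] = "undetected"
    if np.ndim(log2_ratio) == 0:
        return out.item()
    return out


def community_profile(
    pam_array: ArrayExperiment,
    taxon_map: pd.Series,
    threshold: float = 1.0,
    background_factor: float = 3.0,
) -> pd.DataFrame:
    """Per-taxon active-community profile.

    Multiple spots per taxon are summarized by the median (robust to single
    bad spots).  A taxon undetected in both samples is ``"undetected"``; one
    detected in a single sample is dominant there even though its finite
    ratio is undefined.
    """
    sig = taxon_signals(pam_array, taxon_map, background_factor)
    grouped = sig.groupby("taxon", sort=True)
    prof = pd.DataFrame(
        {
            "detected_biofilm": grouped["detected_biofilm"].any(),
            "detected_plankton": grouped["detected_plankton"].any(),
            "log2_ratio": grouped["log2_ratio"].median(),
        }
    )
    dom = np.asarray(dominance_classify(prof["log2_ratio"].to_numpy(), threshold), dtype=object)
    only_b = prof["detected_biofilm"] & ~prof["detected_plankton"]
    only_p = ~prof["detected_biofilm"] & prof["detected_plankton"]
    neither = ~prof["detected_biofilm"] & ~prof["detected_plankton"]
    dom[only_b.to_numpy()] = "biofilm"
    dom[only_p.to_numpy()] = "plankton"
    dom[neither.to_numpy()] = "undetected"
    prof["dominance"] = dom
    return prof.reset_index()


def reference_abundance_ratio(
    pam_array: ArrayExperiment,
    probe_id: str = REFERENCE_PROBE,
    background_factor: float = 3.0,
) -> ReferenceRatio:
    """Extract the reference-strain abundance ratio ``r`` from a PAM array.

    ``r`` is the background-subtracted biofilm/plankton signal ratio of the
    reference probe; with replicate spots, the median of spot-level ratios.
    Spots must be detected in *both* channels to contribute; if the probe is
    missing or undetected in either channel everywhere, normalization is
    impossible and :class:`ReferenceProbeError` is raised.
    """
    sig = taxon_signals(pam_array, None, background_factor)
    ref = sig[sig["probe_id"] == probe_id]
    if len(ref) == 0:
        raise ReferenceProbeError(f"reference probe {probe_id!r} absent from PAM array")
    usable = ref[
        ref["detected_biofilm"] & ref["detected_plankton"]
        & (ref["signal_biofilm"] > 0) & (ref["signal_plankton"] > 0)
    ]
    if len(usable) == 0:
        raise ReferenceProbeError(
            f"reference probe {probe_id!r} not detected in both samples; "
            "abundance normalization impossible"
        )
    r = float(np.median(usable["signal_biofilm"] / usable["signal_plankton"]))
    return ReferenceRatio(r=r, probe_id=probe_id, campaign=pam_array.campaign)
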