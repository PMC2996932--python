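"""Detection and fold-change selection of differentially expressed probes/genes.

The procedure is deliberately threshold-based (no p-values, no moderated
statistics): a probe is *detected* when its foreground exceeds a multiple of
the background in at least one channel, and selection tiers are defined by
fold-change criteria applied per sampling campaign, treating campaigns as
experimental replicates:

- **candidate** — |ratio| ≥ ``fold_threshold`` in at least one campaign;
- **robust** — |ratio| > ``fold_threshold`` in *every* campaign, with a
  consistent direction, indicating regulation tied to lifestyle rather than
  to campaign-specific conditions;
- **pathway_relaxed** — for genes flagged as members of well-characterized
  pathways, a ratio between ``relaxed_threshold`` and ``fold_threshold`` in
  every campaign (direction-consistent) is also accepted;
- **expressed_both** — detected but meeting no fold criterion;
- **not_detected** — no detected probe.

Down-regulation is handled symmetrically (ratio ≤ 1/threshold).  All rules
operate on log2 ratios after normalization (see :mod:`envarray.normalize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TIERS = (
    "robust_biofilm",
    "robust_plankton",
    "candidate",
    "pathway_relaxed",
    "expressed_both",
    "not_detected",
)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the detection/selection rules.

    background_factor
        Detection requires foreground strictly greater than this multiple
        of the background in at least one channel.
    fold_threshold
        Main induction-ratio threshold (ratio scale).  The one-campaign
        candidate rule is inclusive (a "minimal" ratio); the every-campaign
        robust rule is strict (a ratio "higher than" the threshold).
    relaxed_threshold
        Lower bound of the pathway-relaxed band, ratio scale.
    require_both_campaigns
        If True (default) the robust rule needs a ratio in every campaign;
        probes missing a campaign are skipped with a log entry.
    """

    background_factor: float = 3.0
    fold_threshold: float = 2.0
    relaxed_threshold: float = 1.5
    require_both_campaigns: bool = True

    def __post_init__(self) -> None:
        if self.background_factor <= 1:
            raise ValueError("background_factor must exceed 1")
        if not 1 < self.relaxed_threshold < self.fold_threshold:
            raise ValueError("need 1 < relaxed_threshold < fold_threshold")


def detect_probe(f_biofilm, b_biofilm, f_plankton, b_plankton, background_factor: float = 3.0):
    """True iff foreground > factor × background in at least one channel (strict)."""
    fb = np.asarray(f_biofilm, dtype=float)
    fp = np.asarray(f_plankton, dtype=float)
    bb = np.asarray(b_biofilm, dtype=float)
    bp = np.asarray(b_plankton, dtype=float)
    return (fb > background_factor * bb) | (fp > background_factor * bp)


def detect_spots(spots: pd.DataFrame, background_factor: float = 3.0) -> np.ndarray:
    """Vectorized detection call over a spot table."""
    return detect_probe(
        spots["f_biofilm"], spots["b_biofilm"],
        spots["f_plankton"], spots["b_plankton"],
        background_factor,
    )


def _log_threshold(config: SelectionConfig) -> float:
    return float(np.log2(config.fold_threshold))


def select_candidates(ratios: pd.DataFrame, config: SelectionConfig | None = None) -> pd.Index:
    """Probes whose |log2 ratio| meets the fold threshold in >= 1 campaign.

    ``ratios`` is a probe × campaign table of log2 ratios; NaN marks a
    campaign without a usable measurement (such probes are evaluated on
    the campaigns they have; all-NaN probes are skipped and logged).
    Inclusive comparison, both directions.
    """
    config = config or SelectionConfig()
    t = _log_threshold(config)
    vals = ratios.to_numpy(dtype=float)
    skipped = int(np.all(~np.isfinite(vals), axis=1).sum())
    if skipped:
        log.info("select_candidates: %d probes skipped (no campaign ratio)", skipped)
    with np.errstate(invalid="ignore"):
        hit = np.any(np.abs(vals) >= t, axis=1)
    return ratios.index[hit]


def select_robust(ratios: pd.DataFrame, config: SelectionConfig | None = None) -> pd.Index:
    """Probes beyond the fold threshold in *every* campaign, same direction.

    Strict comparison.  Probes with a missing campaign are skipped (logged)
    when ``require_both_campaigns`` is set.
    """
    config = config or SelectionConfig()
    t = _log_threshold(config)
    vals = ratios.to_numpy(dtype=float)
    complete = np.all(np.isfinite(vals), axis=1)
    if config.require_both_campaigns:
        skipped = int((~complete).sum())
        if skipped:
            log.info("select_robust: %d probes skipped (missing campaign ratio)", skipped)
        usable = complete
    else:
        usable = np.any(np.isfinite(vals), axis=1)
    with np.errstate(invalid="ignore"):
        up = np.all(np.where(np.isfinite(vals), vals > t, not config.require_both_campaigns), axis=1)
        down = np.all(np.where(np.isfinite(vals), vals < -t, not config.require_both_campaigns), axis=1)
    hit = usable & (up | down)
    return ratios.index[hit]


def combine_replicates(tables: list[tuple[str, pd.DataFrame]]) -> dict[str, pd.DataFrame]:
    """Average technical replicates within each campaign at the probe level.

    ``tables`` is a list of ``(campaign, normalized_probe_table)`` pairs.
    Within a campaign, M values (``M_corrected`` where available, else
    ``M_lowess``) are averaged with the mean, A likewise; a probe counts as
    detected if it is detected on at least one replicate array.
    Returns ``{campaign: DataFrame(probe_id, A, M, detected)}``.
    """
    by_campaign: dict[str, list[pd.DataFrame]] = {}
    for campaign, table in tables:
        by_campaign.setdefault(campaign, []).append(table)
    out: dict[str, pd.DataFrame] = {}
    for campaign, reps in by_campaign.items():
        frames = []
        for table in reps:
            mcol = "M_corrected" if ("M_corrected" in table.columns
                                     and table["M_corrected"].notna().any()) else "M_lowess"
            det = table["detected"] if "detected" in table.columns else table["detected_flag"].astype(bool)
            frames.append(pd.DataFrame({
                "probe_id": table["probe_id"],
                "A": table["A"],
                "M": table[mcol],
                "detected": det.to_numpy(),
            }))
        stacked = pd.concat(frames)
        grouped = stacked.groupby("probe_id", sort=True)
        out[campaign] = pd.DataFrame({
            "A": grouped["A"].mean(),
            "M": grouped["M"].mean(),
            "detected": grouped["detected"].any(),
        }).reset_index()
    return out


def probe_ratio_table(per_campaign: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.Series]:
    """Wide probe × campaign table of log2 ratios plus a detected-anywhere flag."""
    campaigns = sorted(per_campaign)
    ratio = pd.DataFrame({
        c: per_campaign[c].set_index("probe_id")["M"] for c in campaigns
    })
    detected = pd.DataFrame({
        c: per_campaign[c].set_index("probe_id")["detected"] for c in campaigns
    }).fillna(False).any(axis=1)
    detected = detected.reindex(ratio.index, fill_value=False)
    return ratio, detected


def aggregate_to_genes(
    ratios: pd.DataFrame,
    detected: pd.Series,
    probe_map: pd.Series,
) -> pd.DataFrame:
    """Aggregate probe-level log2 ratios to genes.

    Gene-level ratio per campaign = median of the M values of the gene's
    *detected* probes (redundant probe coverage makes the median a cheap
    guard against single bad spots).  Probes absent from ``probe_map`` are
    treated as unassigned and excluded from gene calls.  Genes with zero
    detected probes are reported with NaN ratios and
    ``detected_anywhere=False``.
    """
    genes = probe_map.reindex(ratios.index)
    assigned = genes.notna()
    det = detected.reindex(ratios.index, fill_value=False)
    use = assigned & det

    work = ratios[use].copy()
    work["gene_id"] = genes[use]
    agg = work.groupby("gene_id").median(numeric_only=True)
    counts = work.groupby("gene_id").size()

    all_genes = pd.Index(sorted(probe_map.unique()), name="gene_id")
    out = agg.reindex(all_genes)
    out["n_probes"] = probe_map.groupby(probe_map.values).size().reindex(all_genes).fillna(0).astype(int)
    out["n_detected"] = counts.reindex(all_genes).fillna(0).astype(int)
    out["detected_anywhere"] = out["n_detected"] > 0
    return out.reset_index()


def classify_genes(
    gene_calls: pd.DataFrame,
    config: SelectionConfig | None = None,
    pathway_flags: set[str] | None = None,
    campaigns: list[str] | None = None,
) -> pd.DataFrame:
    """Assign a selection tier to each gene (see module docstring for tiers)."""
    config = config or SelectionConfig()
    pathway_flags = pathway_flags or set()
    if campaigns is None:
        campaigns = [c for c in gene_calls.columns
                     if c not in {"gene_id", "n_probes", "n_detected", "detected_anywhere"}]
    t = _log_threshold(config)
    rl = float(np.log2(config.relaxed_threshold))
    vals = gene_calls[campaigns].to_numpy(dtype=float)
    detected = gene_calls["detected_anywhere"].to_numpy(dtype=bool)
    flagged = gene_calls["gene_id"].isin(pathway_flags).to_numpy()

    complete = np.all(np.isfinite(vals), axis=1)
    with np.errstate(invalid="ignore"):
        robust_up = complete & np.all(vals > t, axis=1)
        robust_down = complete & np.all(vals < -t, axis=1)
        candidate = np.any(np.abs(vals) >= t, axis=1)
        relax_up = complete & np.all((vals >= rl) & (vals < t), axis=1)
        relax_down = complete & np.all((vals <= -rl) & (vals > -t), axis=1)

    tier = np.full(len(gene_calls), "expressed_both", dtype=object)
    tier[flagged & (relax_up | relax_down)] = "pathway_relaxed"
    tier[candidate] = "candidate"
    tier[robust_up] = "robust_biofilm"
    tier[robust_down] = "robust_plankton"
    tier[~detected] = "not_detected"

    out = gene_calls.copy()
    out["tier"] = tier
    return out


def run_selection(
    tables: list[tuple[str, pd.DataFrame]],
    probe_map: pd.Series,
    config: SelectionConfig | None = None,
    pathway_flags: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.Index]]:
    """Replicate averaging → probe selection → gene aggregation → tiering.

    Returns the tiered gene table and the probe-level candidate/robust sets.
    """
    config = config or SelectionConfig()
    per_campaign = combine_replicates(tables)
    ratios, detected = probe_ratio_table(per_campaign)
    detected_ratios = ratios[detected]
    probe_sets = {
        "candidate": select_candidates(detected_ratios, config),
        "robust": select_robust(detected_ratios, config),
    }
    genes = aggregate_to_genes(ratios, detected, probe_map)
    genes = classify_genes(genes, config, pathway_flags, campaigns=sorted(per_campaign))
    return genes, probe_sets
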