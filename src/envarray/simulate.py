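"""Truth-tagged synthetic data for the whole pipeline.

Generates expression arrays, phylochip (PAM) arrays and qPCR Ct tables with
known ground truth, so every downstream stage — normalization, selection,
community profiling, ΔCt fold changes — can be validated against the values
that produced the data.

Generative model for one expression-array spot (probe p of gene g, campaign
c, channels biofilm/plankton)::

    S_plankton = x_g * a_p                       baseline × probe affinity
    S_biofilm  = S_plankton * 2**fc_gc * r_c     expression change × abundance
    S_biofilm *= 2**(+bias(A)/2)                 intensity-dependent dye bias,
    S_plankton*= 2**(-bias(A)/2)                 split so A itself is unmoved
    S_ch      *= 2**eps_ch,  eps ~ N(0, noise_sd)  per-channel log2 noise
    F_ch       = B_ch + S_ch,  B ~ N(bg_mean, bg_sd) clipped at 0

where ``fc_gc = true_log2_fc_g + N(0, campaign_jitter_sd)`` (campaigns act
as jittered replicates of a shared gene effect), ``r_c`` is the organism's
biofilm/plankton abundance ratio in campaign c, and ``bias`` is a
polynomial in centered A — the canonical LOWESS-removable structure,
applied half-up/half-down so that it perturbs M but not A.  At zero noise
the raw background-subtracted log2 ratio of a spot is exactly
``fc_gc + log2(r_c) + bias(A)``.

Everything is driven by a single integer seed through per-stage
``SeedSequence`` children, so identical configs produce byte-identical
output files regardless of which generators are invoked.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from envarray.io import ArrayExperiment, SPOT_COLUMNS, write_gpr, write_probe_map
from envarray.pam import REFERENCE_PROBE

# stage indices for SeedSequence spawning
_STAGE_TRUTH, _STAGE_ARRAYS, _STAGE_PAM, _STAGE_QPCR = range(4)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic campaign.

    Defaults emulate two field campaigns ("2004", "2005") of biofilm vs
    plankton hybridizations: the organism is equally represented in both
    samples in 2004 and twice as abundant in the 2005 biofilm; 2005 carries
    technical replicates; genes are covered redundantly by 1–4 probes
    (mean ≈ 2.5, i.e. 2–3× genome coverage); 70% of genes are null and the
    rest carry symmetric log2 effects spanning the 1.5×–2× selection regime
    and beyond.
    """

    n_genes: int = 500
    probes_per_gene_mean: float = 2.5
    abundance_ratio_by_campaign: dict[str, float] = field(
        default_factory=lambda: {"2004": 1.0, "2005": 2.0}
    )
    #: ascending polynomial coefficients of the dye bias (log2 units) in
    #: (A - dye_bias_center); the default odd cubic has ~zero mean over the
    #: intensity distribution and |bias| up to ~1 log2 at the extremes.
    dye_bias_coeffs: tuple[float, ...] = (0.0, 0.1, 0.0, 0.01)
    dye_bias_center: float = 10.0
    background_mean: float = 120.0
    background_sd: float = 15.0
    noise_sd: float = 0.15          # per-channel multiplicative noise, log2 units
    campaign_jitter_sd: float = 0.2  # campaign-level wobble of the shared gene effect
    null_fraction: float = 0.7
    effect_range: tuple[float, float] = (0.585, 2.5)  # |log2 fc| of non-null genes
    tech_replicates_2005: int = 2
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    probe_affinity_sd: float = 0.3   # log2 spread between probes of one gene
    amplification_bias_sd: float = 0.0  # optional per-gene amplification factor (log2 sd)
    # phylochip
    pam_noise_sd: float = 0.1
    pam_spots_per_probe: int = 4
    #: intensity units per abundance unit; keeps the brightest probe of the
    #: default community below the 16-bit scanner ceiling
    pam_scale: float = 800.0
    # qPCR
    qpcr_efficiency: float = 0.95
    ct_sd: float = 0.1
    qpcr_dilutions: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4)
    qpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 1.0 <= self.probes_per_gene_mean <= 4.0:
            raise ConfigError("probes_per_gene_mean must lie in [1, 4]")
        if not self.abundance_ratio_by_campaign:
            raise ConfigError("need at least one campaign")
        for campaign, r in self.abundance_ratio_by_campaign.items():
            if r <= 0:
                raise ConfigError(f"abundance ratio for {campaign} must be > 0, got {r}")
        for name in ("noise_sd", "campaign_jitter_sd", "background_sd", "pam_noise_sd",
                     "ct_sd", "amplification_bias_sd", "probe_affinity_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.null_fraction <= 1:
            raise ConfigError("null_fraction must lie in [0, 1]")
        if self.tech_replicates_2005 < 1 or self.qpcr_replicates < 1:
            raise ConfigError("replicate counts must be >= 1")
        if not 0 < self.qpcr_efficiency <= 1.2:
            raise ConfigError(f"qpcr_efficiency must lie in (0, 1.2], got {self.qpcr_efficiency}")
        if len(set(self.qpcr_dilutions)) < 2:
            raise ConfigError("need >= 2 distinct qPCR dilutions")

    # -- campaign helpers -------------------------------------------------
    @property
    def campaigns(self) -> list[str]:
        return sorted(self.abundance_ratio_by_campaign)

    def replicates(self, campaign: str) -> int:
        return self.tech_replicates_2005 if campaign == "2005" else 1

    def dye_bias(self, A: np.ndarray) -> np.ndarray:
        """Dye bias in log2 units as a function of A."""
        return np.polynomial.polynomial.polyval(
            np.asarray(A, dtype=float) - self.dye_bias_center, self.dye_bias_coeffs
        )

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        data = dataclasses.asdict(self)
        data["dye_bias_coeffs"] = list(self.dye_bias_coeffs)
        data["effect_range"] = list(self.effect_range)
        data["qpcr_dilutions"] = list(self.qpcr_dilutions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("dye_bias_coeffs", "effect_range", "qpcr_dilutions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    genes
        One row per gene: ``gene_id, true_log2_fc, campaign_jitter_sd,
        n_probes``.
    probe_map
        probe_id → gene_id mapping (every probe maps to exactly one gene).
    """

    genes: pd.DataFrame
    probe_map: pd.Series

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probe_map.index)

    def probes_of(self, gene_id: str) -> list[str]:
        return list(self.probe_map.index[self.probe_map == gene_id])


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw per-gene fold changes and the redundant probe coverage map.

    Fold changes come from a mixture: a point mass at 0 with probability
    ``null_fraction``, otherwise a uniform magnitude over ``effect_range``
    with a random sign.  Probes per gene are ``1 + Binomial(3, (m-1)/3)``,
    i.e. support {1..4} with mean ``m = probes_per_gene_mean``.
    """
    rng = _rng(config, _STAGE_TRUTH)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    null = rng.random(n) < config.null_fraction
    lo, hi = config.effect_range
    magnitude = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    fc = np.where(null, 0.0, sign * magnitude)

    p = (config.probes_per_gene_mean - 1.0) / 3.0
    n_probes = 1 + rng.binomial(3, p, size=n)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_log2_fc": fc,
            "campaign_jitter_sd": config.campaign_jitter_sd,
            "n_probes": n_probes,
        }
    )
    probe_ids, probe_genes = [], []
    k = 0
    for gid, count in zip(gene_ids, n_probes):
        for _ in range(count):
            probe_ids.append(f"P{k:06d}")
            probe_genes.append(gid)
            k += 1
    probe_map = pd.Series(probe_genes, index=probe_ids, name="gene_id")
    return SyntheticTruth(genes=genes, probe_map=probe_map)


def generate_expression_arrays(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[list[ArrayExperiment], pd.DataFrame]:
    """Simulate every hybridization of the study design.

    Returns the arrays (one per campaign × technical replicate; biofilm on
    the Cy5/635 channel, plankton on Cy3/532) and a gene × campaign table of
    the *realized* log2 effects (shared effect + campaign jitter) — the
    truth sidecar against which campaign-level estimates are judged.
    """
    rng = _rng(config, _STAGE_ARRAYS)
    genes = truth.genes
    probe_map = truth.probe_map
    n_genes, n_probes = len(genes), len(probe_map)
    gene_index = pd.Series(np.arange(n_genes), index=genes["gene_id"])
    g_of_p = gene_index[probe_map.values].to_numpy()

    x_g = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    a_p = 2.0 ** rng.normal(0.0, config.probe_affinity_sd, n_probes)
    if config.amplification_bias_sd > 0:
        # amplification preference distorts both channels alike; M unaffected
        x_g = x_g * 2.0 ** rng.normal(0.0, config.amplification_bias_sd, n_genes)

    campaigns = config.campaigns
    jitter = rng.normal(0.0, config.campaign_jitter_sd, size=(n_genes, len(campaigns)))
    fc_gc = genes["true_log2_fc"].to_numpy()[:, None] + jitter
    effects = pd.DataFrame(fc_gc, index=genes["gene_id"], columns=campaigns).reset_index()

    arrays: list[ArrayExperiment] = []
    for ci, campaign in enumerate(campaigns):
        r = config.abundance_ratio_by_campaign[campaign]
        s_p0 = x_g[g_of_p] * a_p
        s_b0 = s_p0 * 2.0 ** fc_gc[g_of_p, ci] * r
        A0 = 0.5 * (np.log2(s_b0) + np.log2(s_p0))
        half_bias = 2.0 ** (config.dye_bias(A0) / 2.0)
        s_b0 = s_b0 * half_bias
        s_p0 = s_p0 / half_bias
        for rep in range(1, config.replicates(campaign) + 1):
            eps_b = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd else 0.0
            eps_p = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd else 0.0
            b_b = np.clip(rng.normal(config.background_mean, config.background_sd, n_probes), 0, None)
            b_p = np.clip(rng.normal(config.background_mean, config.background_sd, n_probes), 0, None)
            spots = pd.DataFrame(
                {
                    "probe_id": probe_map.index,
                    "f_biofilm": b_b + s_b0 * 2.0 ** eps_b,
                    "b_biofilm": b_b,
                    "f_plankton": b_p + s_p0 * 2.0 ** eps_p,
                    "b_plankton": b_p,
                    "flag": 0,
                }
            )[SPOT_COLUMNS].reset_index(drop=True)
            arrays.append(ArrayExperiment(campaign, str(rep), spots))
    return arrays, effects


# --------------------------------------------------------------------------
# phylochip


def default_community(config: SimulationConfig, campaign: str) -> pd.DataFrame:
    """A realistic acidophile community table for one campaign.

    Columns: ``taxon, group, probe_id, biofilm, plankton`` (relative
    abundances, arbitrary units).  The reference strain's biofilm/plankton
    ratio equals the campaign's configured abundance ratio; the remaining
    taxa mimic an iron-oxidizer-dominated community with a few
    lifestyle-skewed members.
    """
    r = config.abundance_ratio_by_campaign[campaign]
    rows = [
        # taxon, group, probe, plankton abundance, biofilm/plankton ratio
        ("L. ferrooxidans RT32a", "Nitrospira", REFERENCE_PROBE, 30.0, r),
        ("L. ferriphilum", "Nitrospira", "LEP636", 18.0, 1.2),
        ("L. ferrodiazotrophum", "Nitrospira", "LEP440", 2.0, 4.0),
        ("A. ferrooxidans", "Gammaproteobacteria", "THIO820", 35.0, 1.0),
        ("Acidimicrobium spp.", "Actinobacteria H-GC", "ACM995", 6.0, 0.5),
        ("Sulfobacillus spp.", "Firmicutes", "SUL228", 4.0, 0.4),
        ("Acidobacterium spp.", "Acidobacteria", "ACDB658", 3.0, 1.5),
        ("Acidiphilium spp.", "Alphaproteobacteria", "ACD821", 5.0, 0.5),
        ("Thiomonas spp.", "Betaproteobacteria", "TM2-647", 2.5, 0.6),
        ("Ferroplasma spp.", "Euryarchaeota", "FER656", 1.5, 1.0),
        ("Thermoplasma spp.", "Euryarchaeota", "TP564", 0.5, 0.0),
    ]
    table = pd.DataFrame(rows, columns=["taxon", "group", "probe_id", "plankton", "ratio"])
    table["biofilm"] = table["plankton"] * table["ratio"]
    return table.drop(columns="ratio")


def generate_pam_array(
    abundance: pd.DataFrame,
    config: SimulationConfig,
    campaign: str = "2004",
    cross_hyb: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ArrayExperiment, pd.Series]:
    """Simulate one two-color PAM hybridization from a community table.

    Per-taxon probe signal is proportional to abundance, plus an optional
    cross-hybridization contribution ``signal_probe += C[probe_taxon, x] *
    abundance_x`` (a scalar matrix standing in for imperfect sequence
    specificity).  The reference strain must be present.  Each probe is
    printed ``pam_spots_per_probe`` times.  Returns the array and the
    probe → taxon map.
    """
    required = {"taxon", "probe_id", "biofilm", "plankton"}
    if not required <= set(abundance.columns):
        raise ConfigError(f"abundance table needs columns {sorted(required)}")
    if REFERENCE_PROBE not in set(abundance["probe_id"]):
        raise ReferenceStrainMissing(
            f"abundance table lacks the reference strain probe {REFERENCE_PROBE!r}"
        )
    rng = rng if rng is not None else _rng(config, _STAGE_PAM)

    a = abundance.set_index("taxon")
    signals = {}
    for sample in ("biofilm", "plankton"):
        direct = a[sample].to_numpy(dtype=float)
        total = direct.copy()
        if cross_hyb is not None:
            C = cross_hyb.reindex(index=a.index, columns=a.index).fillna(0.0).to_numpy()
            total = direct + C @ direct
        signals[sample] = config.pam_scale * total

    n_taxa = len(a)
    reps = config.pam_spots_per_probe
    idx = np.repeat(np.arange(n_taxa), reps)

    def channel(sample: str) -> tuple[np.ndarray, np.ndarray]:
        s = signals[sample][idx]
        if config.pam_noise_sd:
            s = s * 2.0 ** rng.normal(0.0, config.pam_noise_sd, len(idx))
        b = np.clip(rng.normal(config.background_mean, config.background_sd, len(idx)), 0, None)
        return b + s, b

    f_b, b_b = channel("biofilm")
    f_p, b_p = channel("plankton")
    spots = pd.DataFrame(
        {
            "probe_id": a["probe_id"].to_numpy()[idx],
            "f_biofilm": f_b,
            "b_biofilm": b_b,
            "f_plankton": f_p,
            "b_plankton": b_p,
            "flag": 0,
        }
    )[SPOT_COLUMNS]
    array = ArrayExperiment(campaign, "1", spots, kind="pam")
    taxon_map = pd.Series(a.index.to_numpy(), index=a["probe_id"].to_numpy(), name="taxon")
    return array, taxon_map


class ReferenceStrainMissing(ConfigError):
    """The community table lacks the strain used for expression profiling."""


def generate_pam_arrays(
    config: SimulationConfig,
    abundances: dict[str, pd.DataFrame] | None = None,
    cross_hyb: pd.DataFrame | None = None,
) -> dict[str, tuple[ArrayExperiment, pd.Series]]:
    """One PAM hybridization per campaign (default communities if none given)."""
    rng = _rng(config, _STAGE_PAM)
    out = {}
    for campaign in config.campaigns:
        table = (abundances or {}).get(campaign)
        if table is None:
            table = default_community(config, campaign)
        out[campaign] = generate_pam_array(table, config, campaign, cross_hyb, rng)
    return out


# --------------------------------------------------------------------------
# qPCR

QPCR_REFERENCE_GENE = "16S"


def generate_qpcr(
    truth: SyntheticTruth,
    config: SimulationConfig,
    gene_ids: list[str] | None = None,
    efficiencies: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dilution-series standards and sample triplicates.

    Standard-curve wells follow ``Ct = intercept - log10(dilution) /
    log10(1+E) + N(0, ct_sd)``.  Sample wells encode the gene's true fold
    change against the 16S reference: the reference amplifies equally in
    both conditions, while the target's plankton-vs-biofilm Ct difference is
    ``fc * ln 2 / ln(1+E)``, so the efficiency-corrected ΔCt formula
    recovers ``2**fc`` exactly at zero noise.

    By default the five genes with the strongest |true effect| are assayed
    (a typical validation panel).  Returns the well table (columns ``gene,
    condition, replicate, dilution, ct``) and a truth sidecar with each
    gene's true fold and efficiency.
    """
    rng = _rng(config, _STAGE_QPCR)
    genes = truth.genes.set_index("gene_id")
    if gene_ids is None:
        gene_ids = list(genes["true_log2_fc"].abs().sort_values(ascending=False).index[:5])
    missing = [g for g in gene_ids if g not in genes.index]
    if missing:
        raise ConfigError(f"unknown genes for qPCR: {missing}")
    efficiencies = efficiencies or {}

    rows = []
    sidecar = []
    for gene in [QPCR_REFERENCE_GENE, *gene_ids]:
        E = float(efficiencies.get(gene, config.qpcr_efficiency))
        if not 0 < E <= 1.2:
            raise ConfigError(f"efficiency for {gene} outside (0, 1.2]: {E}")
        slope = -1.0 / np.log10(1.0 + E)
        fc = 0.0 if gene == QPCR_REFERENCE_GENE else float(genes.loc[gene, "true_log2_fc"])
        intercept = rng.uniform(18.0, 24.0)
        for dilution in config.qpcr_dilutions:
            for rep in range(1, config.qpcr_replicates + 1):
                ct = intercept + slope * np.log10(dilution) + rng.normal(0.0, config.ct_sd)
                rows.append((gene, "standard", rep, dilution, ct))
        ct_biofilm = intercept
        ct_plankton = intercept + fc * np.log(2.0) / np.log(1.0 + E)
        for rep in range(1, config.qpcr_replicates + 1):
            rows.append((gene, "biofilm", rep, 1.0,
                         ct_biofilm + rng.normal(0.0, config.ct_sd)))
            rows.append((gene, "plankton", rep, 1.0,
                         ct_plankton + rng.normal(0.0, config.ct_sd)))
        sidecar.append((gene, E, 2.0 ** fc))

    wells = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "dilution", "ct"])
    truth_table = pd.DataFrame(sidecar, columns=["gene", "true_efficiency", "true_fold"])
    return wells, truth_table


# --------------------------------------------------------------------------
# dataset emission


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study to ``outdir`` and return a manifest.

    Emits the config (YAML), truth tables, probe map, one GPR per
    hybridization (intensities quantized to 16-bit integers, as a scanner
    would), the PAM arrays and taxon layout, and the qPCR well table.
    Identical config ⇒ byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    manifest["config"] = config.to_yaml(outdir / "config.yaml")

    truth = generate_truth(config)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    manifest["truth_genes"] = outdir / "truth_genes.tsv"
    manifest["probe_map"] = write_probe_map(truth.probe_map, outdir / "probe_map.tsv")

    arrays, effects = generate_expression_arrays(truth, config)
    effects.to_csv(outdir / "campaign_effects.tsv", sep="\t", index=False)
    manifest["campaign_effects"] = outdir / "campaign_effects.tsv"
    for array in arrays:
        name = f"expr_{array.campaign}_r{array.replicate}.gpr"
        manifest[name] = write_gpr(array, outdir / name, quantize=True)

    pam = generate_pam_arrays(config)
    layouts = []
    for campaign, (array, taxon_map) in pam.items():
        name = f"pam_{campaign}.gpr"
        manifest[name] = write_gpr(array, outdir / name, quantize=True)
        layouts.append(taxon_map)
    manifest["pam_layout"] = write_probe_map(
        layouts[0], outdir / "pam_layout.tsv", columns=("probe_id", "taxon")
    )

    wells, qpcr_truth = generate_qpcr(truth, config)
    wells.to_csv(outdir / "qpcr_ct.csv", index=False)
    qpcr_truth.to_csv(outdir / "qpcr_truth.tsv", sep="\t", index=False)
    manifest["qpcr_ct"] = outdir / "qpcr_ct.csv"
    manifest["qpcr_truth"] = outdir / "qpcr_truth.tsv"
    return manifest
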