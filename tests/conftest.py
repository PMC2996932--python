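import numpy as np
import pandas as pd
import pytest

from envarray import ArrayExperiment, SimulationConfig, SyntheticTruth


def make_config(**overrides) -> SimulationConfig:
    """A small, fast configuration; overrides replace individual fields."""
    base = dict(n_genes=60, seed=7)
    base.update(overrides)
    return SimulationConfig(**base)


def quiet_config(**overrides) -> SimulationConfig:
    """Noise-free, bias-free, single-campaign settings for closed-form checks."""
    base = dict(
        n_genes=40,
        noise_sd=0.0,
        pam_noise_sd=0.0,
        campaign_jitter_sd=0.0,
        dye_bias_coeffs=(0.0,),
        abundance_ratio_by_campaign={"2004": 1.0},
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def make_truth(fold_changes, probes_per_gene=1) -> SyntheticTruth:
    """Hand-built truth with exactly the given per-gene log2 fold changes."""
    gene_ids = [f"G{i:05d}" for i in range(len(fold_changes))]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_log2_fc": np.asarray(fold_changes, dtype=float),
            "campaign_jitter_sd": 0.0,
            "n_probes": probes_per_gene,
        }
    )
    probes, targets = [], []
    k = 0
    for gid in gene_ids:
        for _ in range(probes_per_gene):
            probes.append(f"P{k:06d}")
            targets.append(gid)
            k += 1
    return SyntheticTruth(genes=genes, probe_map=pd.Series(targets, index=probes, name="gene_id"))


def make_array(f_b, b_b, f_p, b_p, probe_ids=None, flag=0, campaign="2004", kind="expression"):
    """Spot-level ArrayExperiment from plain intensity vectors."""
    f_b = np.atleast_1d(np.asarray(f_b, dtype=float))
    n = len(f_b)
    spots = pd.DataFrame(
        {
            "probe_id": probe_ids if probe_ids is not None else [f"P{i:06d}" for i in range(n)],
            "f_biofilm": f_b,
            "b_biofilm": np.broadcast_to(np.asarray(b_b, dtype=float), (n,)),
            "f_plankton": np.broadcast_to(np.asarray(f_p, dtype=float), (n,)),
            "b_plankton": np.broadcast_to(np.asarray(b_p, dtype=float), (n,)),
            "flag": np.broadcast_to(np.asarray(flag), (n,)),
        }
    )
    return ArrayExperiment(campaign, "1", spots, kind=kind)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
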