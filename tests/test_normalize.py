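"""Background subtraction, LOWESS dye-bias removal, abundance correction."""

import numpy as np
import pandas as pd
import pytest

from envarray import (
    LowessError,
    LowessParams,
    ReferenceRatio,
    abundance_correct,
    background_subtract,
    generate_expression_arrays,
    generate_truth,
    lowess_fit,
    lowess_normalize,
    ma_values,
    normalize_array,
)
from conftest import make_array, make_config, make_truth


def lowess_oracle(x, y, span=0.4, robust_iters=3):
    """Independent LOWESS: per-point tricube-weighted normal-equation solves
    over the span-nearest neighbors, with bisquare robustifying passes."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    robust_w = np.ones(n)
    fitted = np.empty(n)
    for _ in range(robust_iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:k]
            dmax = d[idx].max()
            if dmax == 0:
                w = np.ones(k)
            else:
                w = (1 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
            w = w * robust_w[idx]
            X = np.column_stack([np.ones(k), x[idx] - x[i]])
            W = np.diag(w)
            beta = np.linalg.lstsq(X.T @ W @ X, X.T @ W @ y[idx], rcond=None)[0]
            fitted[i] = beta[0]
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s == 0:
            break
        robust_w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fitted


class TestBackgroundSubtract:
    def test_plain_and_floored_subtraction(self):
        array = make_array([500, 50], 100, [300, 300], 100)
        out = background_subtract(array.spots)
        assert out["fg_biofilm"].tolist() == [400.0, 0.0]
        assert out["fg_plankton"].tolist() == [200.0, 200.0]

    def test_elementwise_max_oracle_on_200_spots(self, rng):
        f = rng.uniform(0, 1000, 200)
        b = rng.uniform(0, 300, 200)
        array = make_array(f, b, f[::-1], b[::-1])
        out = background_subtract(array.spots)
        assert np.array_equal(out["fg_biofilm"], np.maximum(f - b, 0))

    def test_zeroed_channel_gives_undefined_ma(self):
        A, M = ma_values(np.array([0.0, 4.0]), np.array([2.0, 2.0]))
        assert np.isnan(A[0]) and np.isnan(M[0])
        assert A[1] == pytest.approx(1.5) and M[1] == pytest.approx(1.0)


class TestLowessFit:
    def test_zero_and_constant_m_are_interpolated_exactly(self, rng):
        a = rng.uniform(5, 15, 100)
        assert np.allclose(lowess_fit(a, np.zeros(100)), 0.0, atol=1e-12)
        trend = lowess_fit(a, np.full(100, 2.5))
        assert np.allclose(trend, 2.5, atol=1e-9)

    def test_linear_m_recovered_pointwise_against_wls_oracle(self, rng):
        """Noise-free M = 0.5·A: the fitted trend and the independent
        per-point weighted least-squares oracle agree with the line."""
        a = np.sort(rng.uniform(5, 15, 120))
        m = 0.5 * a
        params = LowessParams(span=0.4, robust_iters=3)
        trend = lowess_fit(a, m, params)
        oracle = lowess_oracle(a, m, span=0.4, robust_iters=3)
        interior = (a > np.quantile(a, 0.1)) & (a < np.quantile(a, 0.9))
        assert np.allclose(trend[interior], 0.5 * a[interior], atol=1e-6)
        assert np.allclose(oracle[interior], 0.5 * a[interior], atol=1e-6)

    def test_smoother_matches_oracle_on_noisy_curve(self, rng):
        a = np.sort(rng.uniform(0, 10, 150))
        m = np.sin(a / 2) + rng.normal(0, 0.05, 150)
        trend = lowess_fit(a, m, LowessParams(span=0.5, robust_iters=2))
        oracle = lowess_oracle(a, m, span=0.5, robust_iters=2)
        interior = (a > np.quantile(a, 0.1)) & (a < np.quantile(a, 0.9))
        assert np.max(np.abs(trend[interior] - oracle[interior])) < 0.05

    def test_fewer_than_ten_points_rejected(self):
        with pytest.raises(LowessError):
            lowess_fit(np.arange(9.0), np.arange(9.0))

    def test_nan_points_excluded_but_reported(self, rng):
        a = rng.uniform(5, 15, 50)
        m = np.zeros(50)
        a[3] = np.nan
        trend = lowess_fit(a, m)
        assert np.isnan(trend[3]) and np.isfinite(np.delete(trend, 3)).all()


class TestLowessNormalize:
    def _biased_array(self, n_genes, seed=19, **overrides):
        cfg = make_config(
            n_genes=n_genes, null_fraction=1.0, campaign_jitter_sd=0.0,
            noise_sd=0.1, abundance_ratio_by_campaign={"2004": 1.0},
            dye_bias_coeffs=(0.0, 0.05, 0.0, 0.0085), seed=seed, **overrides,
        )
        arrays, _ = generate_expression_arrays(generate_truth(cfg), cfg)
        return arrays[0]

    def test_cubic_dye_bias_removed_per_decile(self):
        """Injected cubic bias leaves per-A-decile mean M_lowess within ±0.05."""
        probes = lowess_normalize(self._biased_array(400))
        dec = pd.qcut(probes["A"], 10)
        decile_means = probes.groupby(dec, observed=True)["M_lowess"].mean()
        assert decile_means.abs().max() < 0.05

    def test_bias_free_array_is_near_noop(self):
        cfg = make_config(n_genes=400, null_fraction=1.0, campaign_jitter_sd=0.0,
                          noise_sd=0.1, dye_bias_coeffs=(0.0,),
                          abundance_ratio_by_campaign={"2004": 1.0}, seed=23)
        arrays, _ = generate_expression_arrays(generate_truth(cfg), cfg)
        probes = lowess_normalize(arrays[0])
        assert (probes["M_lowess"] - probes["M_raw"]).abs().mean() < 0.02

    def test_adding_constant_shifts_trend_not_residual(self):
        """Centering equivariance: M + c moves the trend by c and leaves
        M_lowess untouched."""
        array = self._biased_array(150)
        base = lowess_normalize(array)
        shifted = array.spots.copy()
        shifted["f_biofilm"] = shifted["b_biofilm"] + 4 * (
            shifted["f_biofilm"] - shifted["b_biofilm"])  # +2 log2 on every M
        moved = lowess_normalize(make_array(
            shifted["f_biofilm"], shifted["b_biofilm"],
            shifted["f_plankton"], shifted["b_plankton"],
            probe_ids=shifted["probe_id"]))
        assert np.allclose(moved["trend"], base["trend"] + 2.0, atol=1e-8)
        assert np.allclose(moved["M_lowess"], base["M_lowess"], atol=1e-8)

    def test_preserve_level_keeps_global_ratio_scale(self):
        """With preserve_level the bulk M level survives the smoothing."""
        array = self._biased_array(200)
        spots = array.spots.copy()
        spots["f_biofilm"] = spots["b_biofilm"] + 2 * (spots["f_biofilm"] - spots["b_biofilm"])
        array = make_array(spots["f_biofilm"], spots["b_biofilm"],
                           spots["f_plankton"], spots["b_plankton"],
                           probe_ids=spots["probe_id"])
        centered = lowess_normalize(array, preserve_level=False)
        anchored = lowess_normalize(array, preserve_level=True)
        assert abs(centered["M_lowess"].mean()) < 0.05
        assert anchored["M_lowess"].mean() == pytest.approx(1.0, abs=0.05)

    def test_flagged_spots_excluded_from_fit_but_reported(self):
        array = self._biased_array(150)
        spots = array.spots.copy()
        # poison three spots and flag them: the fit must not move
        spots.loc[:2, "f_biofilm"] = spots.loc[:2, "b_biofilm"] + 10_000_000
        spots.loc[:2, "flag"] = -50
        flagged = make_array(spots["f_biofilm"], spots["b_biofilm"],
                             spots["f_plankton"], spots["b_plankton"],
                             probe_ids=spots["probe_id"], flag=spots["flag"])
        out = lowess_normalize(flagged)
        clean = lowess_normalize(make_array(
            array.spots["f_biofilm"][3:], array.spots["b_biofilm"][3:],
            array.spots["f_plankton"][3:], array.spots["b_plankton"][3:],
            probe_ids=array.spots["probe_id"][3:]))
        assert np.isfinite(out.loc[:2, "M_lowess"]).all()  # reported
        assert np.allclose(out["trend"][3:], clean["trend"], atol=1e-9)  # unaffected


class TestAbundanceCorrect:
    def test_r2_shifts_every_probe_down_one_log2(self, rng):
        probes = pd.DataFrame({"probe_id": ["p1", "p2"], "M_lowess": [2.0, -0.5]})
        out = abundance_correct(probes, ReferenceRatio(r=2.0, campaign="2005"))
        assert out["M_corrected"].tolist() == [1.0, -1.5]

    def test_r1_is_identity(self):
        probes = pd.DataFrame({"probe_id": ["p1"], "M_lowess": [0.7]})
        out = abundance_correct(probes, 1.0)
        assert out["M_corrected"].tolist() == [0.7]

    def test_rank_order_preserved(self, rng):
        probes = pd.DataFrame({"probe_id": [f"p{i}" for i in range(50)],
                               "M_lowess": rng.normal(size=50)})
        out = abundance_correct(probes, 3.7)
        assert (out["M_corrected"].rank() == probes["M_lowess"].rank()).all()

    @pytest.mark.parametrize("bad", [None, 0.0, -2.0, np.nan])
    def test_missing_or_invalid_ratio_rejected(self, bad):
        probes = pd.DataFrame({"probe_id": ["p1"], "M_lowess": [0.0]})
        with pytest.raises(ValueError):
            abundance_correct(probes, bad)

    def test_correction_order_is_immaterial(self):
        """LOWESS-then-shift equals shift-then-LOWESS for the final M,
        since the abundance term is constant."""
        truth = generate_truth(make_config(n_genes=150, seed=31))
        cfg = make_config(n_genes=150, seed=31,
                          abundance_ratio_by_campaign={"2004": 2.0})
        arrays, _ = generate_expression_arrays(truth, cfg)
        after = abundance_correct(
            lowess_normalize(arrays[0], preserve_level=True), 2.0)["M_corrected"]
        # shift first: divide the biofilm foreground by r, then smooth
        spots = arrays[0].spots.copy()
        spots["f_biofilm"] = spots["b_biofilm"] + (spots["f_biofilm"] - spots["b_biofilm"]) / 2.0
        before = lowess_normalize(
            make_array(spots["f_biofilm"], spots["b_biofilm"],
                       spots["f_plankton"], spots["b_plankton"],
                       probe_ids=spots["probe_id"]),
            preserve_level=True)["M_lowess"]
        assert np.allclose(after, before, atol=1e-8)


class TestFullNormalization:
    def test_zero_noise_pipeline_hits_closed_form(self):
        """fc=1 with r=2, no noise/bias: M_lowess ≈ 2 (preserve-level) and
        M_corrected ≈ 1."""
        truth = make_truth([1.0] * 20, probes_per_gene=2)
        cfg = make_config(noise_sd=0.0, campaign_jitter_sd=0.0, dye_bias_coeffs=(0.0,),
                          abundance_ratio_by_campaign={"2005": 2.0}, probe_affinity_sd=0.3)
        arrays, _ = generate_expression_arrays(truth, cfg)
        probes = normalize_array(arrays[0], ref_ratio=ReferenceRatio(r=2.0, campaign="2005"))
        assert np.allclose(probes["M_lowess"], 2.0, atol=1e-9)
        assert np.allclose(probes["M_corrected"], 1.0, atol=1e-9)

    def test_end_to_end_fold_change_recovery(self):
        """Dye bias on, r=2, noise_sd=0.15: gene-level median |error| of
        M_corrected against the true log2 fold change stays below 0.15."""
        cfg = make_config(n_genes=300, seed=41, noise_sd=0.15,
                          abundance_ratio_by_campaign={"2004": 1.0, "2005": 2.0})
        truth = generate_truth(cfg)
        arrays, _ = generate_expression_arrays(truth, cfg)
        per_gene = []
        for array in arrays:
            r = cfg.abundance_ratio_by_campaign[array.campaign]
            probes = normalize_array(array, ref_ratio=r)
            probes = probes[probes["detected"]]
            gene = probes.assign(gene_id=truth.probe_map.reindex(probes["probe_id"]).to_numpy())
            per_gene.append(gene.groupby("gene_id")["M_corrected"].median())
        est = pd.concat(per_gene, axis=1).mean(axis=1)
        err = est - truth.genes.set_index("gene_id")["true_log2_fc"].reindex(est.index)
        assert err.abs().median() < 0.15

    def test_without_reference_ratio_m_corrected_is_undefined(self):
        truth = make_truth([0.0] * 30)
        cfg = make_config(noise_sd=0.05, abundance_ratio_by_campaign={"2004": 1.0})
        arrays, _ = generate_expression_arrays(truth, cfg)
        probes = normalize_array(arrays[0])
        assert probes["M_corrected"].isna().all()
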