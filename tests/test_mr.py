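"""Summary-data MR: harmonization, ratio estimates with second-order
SEs, IVW pooling, Cochran Q, weighted median, biomarker rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrphewas.instruments import InstrumentSNP, scale_to_sd
from mrphewas.mr import (
    RatioEstimate,
    cochran_q,
    harmonize,
    ivw_meta,
    ratio_estimate,
    rescale_to_biomarker,
    ratios_for_biomarker,
    weighted_median,
)
from mrphewas.phewas import AssociationEstimate


def _instrument(rsid="rs1", ea="A", oa="G", iron=0.3, scale=1.0):
    beta = {
        "serum_iron": iron,
        "log10_ferritin": scale * 0.2,
        "transferrin": -scale * 0.25,
        "transferrin_saturation": scale * 0.35,
    }
    se = {k: 0.02 for k in beta}
    return InstrumentSNP(rsid, ea, oa, 0.3, beta, se)


def _assoc(rsid="rs1", beta=0.1, se=0.05, ea="A", pid="280.1"):
    return AssociationEstimate(rsid, pid, beta, se, 0.05, 500, 5000, ea)


class TestScaleToSd:
    @pytest.mark.parametrize(
        "absolute,expected", [(6.1, 1.0), (0.0, 0.0), (3.05, 0.5)]
    )
    def test_division_by_population_sd(self, absolute, expected):
        beta, se = scale_to_sd(absolute, absolute / 2 if absolute else 1.0)
        assert beta == pytest.approx(expected)

    def test_se_scales_identically(self):
        beta, se = scale_to_sd(6.1, 0.61)
        assert se == pytest.approx(0.1)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            scale_to_sd(1.0, 0.1, sd_serum_iron=0.0)


class TestHarmonize:
    def test_aligned_pair_unchanged(self):
        inst, out = harmonize(_instrument(), _assoc(ea="A", beta=0.10))
        assert out.beta == 0.10 and out.effect_allele == "A"

    def test_flipped_alleles_negate_outcome_beta(self):
        inst, out = harmonize(_instrument(), _assoc(ea="G", beta=0.10))
        assert out.beta == -0.10
        assert out.effect_allele == "A"
        assert out.se == 0.05

    def test_rsid_mismatch_is_error(self):
        with pytest.raises(ValueError, match="rsid"):
            harmonize(_instrument(rsid="rs1"), _assoc(rsid="rs2"))

    def test_incompatible_alleles_are_hard_error(self):
        with pytest.raises(ValueError, match="incompatible"):
            harmonize(_instrument(ea="A", oa="G"), _assoc(ea="T"))


class TestRatio:
    def test_null_numerator(self):
        r = ratio_estimate(0.5, 0.05, 0.0, 0.04)
        assert r.beta_mr == 0.0
        assert r.se_mr == pytest.approx(0.04 / 0.5)

    def test_worked_second_order_example(self):
        r = ratio_estimate(0.5, 0.05, 0.1, 0.05)
        assert r.beta_mr == pytest.approx(0.2)
        assert r.se_mr == pytest.approx(math.sqrt(0.01 + 0.0004), rel=1e-12)

    def test_zero_exposure_uncertainty_reduces_to_first_order(self):
        r = ratio_estimate(0.5, 0.0, 0.1, 0.05)
        assert r.se_mr == pytest.approx(0.05 / 0.5)

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            ratio_estimate(0.0, 0.05, 0.1, 0.05)

    def test_second_order_se_matches_monte_carlo(self):
        """For strong instruments (|gamma|/se > 10) the two-term delta SE
        tracks the empirical SD of simulated ratios within 5%."""
        rng = np.random.default_rng(2024)
        n_draw = 10**6
        for _ in range(100):
            g = rng.uniform(0.15, 0.6) * rng.choice([-1, 1])
            sg = abs(g) / rng.uniform(10.5, 40)
            G = rng.normal(0, 0.2)
            sG = rng.uniform(0.01, 0.1)
            sim = rng.normal(G, sG, n_draw) / rng.normal(g, sg, n_draw)
            analytic = ratio_estimate(g, sg, G, sG).se_mr
            assert analytic == pytest.approx(sim.std(), rel=0.05)


class TestIVWAndQ:
    def test_identical_estimates_pool_to_equal_weight_closed_form(self):
        rs = [RatioEstimate(f"s{i}", 0.12, 0.06) for i in range(3)]
        ivw = ivw_meta(rs)
        assert ivw.beta == pytest.approx(0.12, rel=1e-12)
        assert ivw.se == pytest.approx(0.06 / math.sqrt(3), rel=1e-12)
        assert ivw.q_stat == pytest.approx(0.0, abs=1e-20)
        assert ivw.q_p == pytest.approx(1.0)

    def test_hand_computed_triple(self):
        rs = [RatioEstimate(f"s{i}", b, 0.1) for i, b in enumerate([0.1, 0.2, 0.3])]
        ivw = ivw_meta(rs)
        assert ivw.beta == pytest.approx(0.2, rel=1e-12)
        assert ivw.se == pytest.approx(0.1 / math.sqrt(3), rel=1e-12)
        q, df, p = cochran_q(rs, ivw)
        assert q == pytest.approx(2.0, rel=1e-12)
        assert df == 2
        assert p == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_ci_brackets_estimate(self):
        ivw = ivw_meta([RatioEstimate("a", 0.1, 0.2), RatioEstimate("b", 0.4, 0.1)])
        assert ivw.ci_low < ivw.beta < ivw.ci_high

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta([RatioEstimate("a", 0.1, 0.1)])

    def test_q_null_rejection_rate_is_nominal(self):
        """Q at P<0.05 rejects ~5% of homogeneous (no-pleiotropy) triples."""
        rng = np.random.default_rng(7)
        ses = np.array([0.12, 0.09, 0.05])
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            betas = rng.normal(0.2, ses)
            rs = [RatioEstimate(f"s{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
            if ivw_meta(rs).q_p < 0.05:
                rejections += 1
        half_width = 1.96 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < half_width

    @given(
        st.lists(
            st.tuples(
                st.floats(-1, 1, allow_nan=False),
                st.floats(0.01, 0.5, allow_nan=False),
            ),
            min_size=2,
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_pooling_never_loses_precision(self, pairs):
        rs = [RatioEstimate(f"s{i}", b, s) for i, (b, s) in enumerate(pairs)]
        assert ivw_meta(rs).se <= min(r.se_mr for r in rs) + 1e-15


class TestWeightedMedian:
    def test_equal_weights_hit_middle_estimate(self):
        # breakpoints (1/6, 1/2, 5/6): the midpoint lands exactly on the
        # second estimate
        from mrphewas.mr import _weighted_median_point

        est = _weighted_median_point(np.array([0.1, 0.2, 0.4]), np.ones(3))
        assert est == pytest.approx(0.2, rel=1e-12)

    def test_hand_interpolated_unequal_weights(self):
        # ratios (0.1, 0.2, 0.4), normalized weights (0.5, 0.25, 0.25):
        # breakpoints (0.25, 0.625, 0.875) -> 0.1 + 0.1*(0.25/0.375)
        from mrphewas.mr import _weighted_median_point

        est = _weighted_median_point(
            np.array([0.1, 0.2, 0.4]), np.array([0.5, 0.25, 0.25])
        )
        assert est == pytest.approx(0.1 + 0.1 * (0.25 / 0.375), rel=1e-12)

    def test_dominant_weight_clamps_to_that_instrument(self):
        from mrphewas.mr import _weighted_median_point

        est = _weighted_median_point(
            np.array([-0.5, 0.2, 0.9]), np.array([0.01, 0.98, 0.01])
        )
        assert est == pytest.approx(0.2)

    def test_bootstrap_is_seed_reproducible(self):
        args = ([0.3, 0.2, 0.25], [0.02] * 3, [0.05, 0.04, 0.06], [0.02] * 3)
        a = weighted_median(*args, n_boot=300, seed=5)
        b = weighted_median(*args, n_boot=300, seed=5)
        assert (a.beta, a.se_boot, a.p) == (b.beta, b.se_boot, b.p)
        c = weighted_median(*args, n_boot=300, seed=6)
        assert c.se_boot != a.se_boot

    def test_robust_to_minority_pleiotropy(self):
        """With >50% of weight on valid instruments, the weighted median
        stays near the true effect despite one pleiotropic outlier."""
        rng = np.random.default_rng(11)
        true = 0.25
        gammas = np.array([0.33, 0.19, 0.18])
        sg = np.array([0.016, 0.012, 0.009])
        hits = 0
        for rep in range(50):
            G_true = true * gammas
            G_true = G_true + np.array([0.0, 0.0, 0.15])  # pleiotropy on one SNP
            sG = np.array([0.02, 0.02, 0.04])  # outlier down-weighted
            G_obs = rng.normal(G_true, sG)
            wm = weighted_median(gammas, sg, G_obs, sG, n_boot=300, seed=rep)
            hits += abs(wm.beta - true) < 3 * wm.se_boot
        assert hits / 50 >= 0.9

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([0.3, 0.2], [0.02] * 2, [0.1, 0.1], [0.02] * 2)

    def test_tiny_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([0.3] * 3, [0.02] * 3, [0.1] * 3, [0.02] * 3, n_boot=50)


class TestRescaling:
    def _setup(self, scale=0.5):
        insts = [
            _instrument("rs1", iron=0.33, scale=scale),
            _instrument("rs2", iron=0.19, scale=scale),
            _instrument("rs3", iron=0.18, scale=scale),
        ]
        outs = [
            _assoc("rs1", beta=-0.033),
            _assoc("rs2", beta=-0.019),
            _assoc("rs3", beta=-0.018),
        ]
        return insts, outs

    def test_serum_iron_scaling_is_identity_with_primary(self):
        insts, outs = self._setup()
        direct = ivw_meta(ratios_for_biomarker(insts, outs, "serum_iron"))
        rescaled = rescale_to_biomarker(insts, outs, "serum_iron")
        assert rescaled.beta == direct.beta and rescaled.se == direct.se

    def test_transferrin_scaling_flips_sign(self):
        insts, outs = self._setup()
        iron = rescale_to_biomarker(insts, outs, "serum_iron")
        transferrin = rescale_to_biomarker(insts, outs, "transferrin")
        assert iron.beta < 0 < transferrin.beta

    def test_half_magnitude_denominator_doubles_log_or(self):
        # ferritin betas = half the iron betas for every instrument
        insts = [
            InstrumentSNP(
                f"rs{i}", "A", "G", 0.3,
                beta={
                    "serum_iron": b, "log10_ferritin": b / 2,
                    "transferrin": -b, "transferrin_saturation": b,
                },
                se={k: 0.02 for k in (
                    "serum_iron", "log10_ferritin", "transferrin", "transferrin_saturation"
                )},
            )
            for i, b in enumerate([0.33, 0.19, 0.18])
        ]
        outs = [_assoc(f"rs{i}", beta=-0.03 * b / 0.33) for i, b in enumerate([0.33, 0.19, 0.18])]
        iron = rescale_to_biomarker(insts, outs, "serum_iron")
        ferritin = rescale_to_biomarker(insts, outs, "log10_ferritin")
        assert ferritin.beta == pytest.approx(2 * iron.beta, rel=1e-9)

    def test_missing_biomarker_is_error(self):
        insts, outs = self._setup()
        with pytest.raises(ValueError):
            rescale_to_biomarker(insts, outs, "hepcidin")


class TestAlleleFlipInvariance:
    @pytest.mark.parametrize("g,G", [(0.3, 0.1), (-0.2, 0.05), (0.5, -0.3)])
    def test_joint_negation_preserves_ratio(self, g, G):
        a = ratio_estimate(g, 0.02, G, 0.03)
        b = ratio_estimate(-g, 0.02, -G, 0.03)
        assert b.beta_mr == pytest.approx(a.beta_mr, rel=1e-12)
        assert b.se_mr == pytest.approx(a.se_mr, rel=1e-12)

    def test_outcome_only_negation_negates_ratio(self):
        a = ratio_estimate(0.3, 0.02, 0.1, 0.03)
        b = ratio_estimate(0.3, 0.02, -0.1, 0.03)
        assert b.beta_mr == pytest.approx(-a.beta_mr, rel=1e-12)
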