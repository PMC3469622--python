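"""Fold-change math, t-tests vs reference oracles, Storey q-values."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phosquant.stats import (
    build_labelfree_matrix,
    build_silac_matrix,
    cap_display,
    cv_percent,
    estimate_pi0,
    flag_significant,
    labelfree_centered_logfc,
    paired_t_silac,
    reproducibility_stats,
    storey_qvalues,
    unpaired_t_vs_min,
)


class TestCenteredLogfc:
    def test_constant_series_is_zero(self):
        out = labelfree_centered_logfc(np.full(8, 3.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_two_point_example(self):
        out = labelfree_centered_logfc(np.array([1.0, 100.0]))
        np.testing.assert_allclose(out, [-1.0, 1.0], atol=1e-12)

    def test_blanks_propagate_and_centering_uses_defined_only(self):
        out = labelfree_centered_logfc(np.array([1.0, np.nan, 100.0]))
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [-1.0, 1.0], atol=1e-12)

    def test_all_blank_stays_blank(self):
        out = labelfree_centered_logfc(np.full(4, np.nan))
        assert np.all(np.isnan(out))

    @given(
        areas=st.lists(st.floats(1e-3, 1e6), min_size=2, max_size=12)
    )
    @settings(max_examples=50, deadline=None)
    def test_centered_values_sum_to_zero(self, areas):
        out = labelfree_centered_logfc(np.asarray(areas))
        assert abs(np.nansum(out)) < 1e-9


class TestCapDisplay:
    def test_thousandfold_capped_at_hundredfold(self):
        assert cap_display(3.0, 100.0) == pytest.approx(2.0)
        assert cap_display(-3.0, 100.0) == pytest.approx(-2.0)

    def test_within_cap_unchanged(self):
        v = math.log10(30.0)
        assert cap_display(v, 50.0) == pytest.approx(v)

    @given(v=st.floats(-10, 10), cap=st.floats(1.5, 1000))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, v, cap):
        once = cap_display(v, cap)
        assert cap_display(once, cap) == pytest.approx(once)


class TestCv:
    def test_identical_replicates(self):
        assert cv_percent(np.array([5.0, 5.0, 5.0])) == 0.0

    def test_one_two_three(self):
        assert cv_percent(np.array([1.0, 2.0, 3.0])) == pytest.approx(50.0)

    def test_single_replicate_undefined(self):
        assert math.isnan(cv_percent(np.array([1.0, np.nan, np.nan])))


def oracle_two_sample_p(x, y):
    """Pooled-variance Student t computed from first principles."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * sps.t.sf(abs(t), nx + ny - 2)


class TestUnpairedT:
    def test_identical_groups_p_one(self):
        v = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        p, ref, _ = unpaired_t_vs_min(v)
        assert ref == 0  # tie -> earliest timepoint
        assert p[0] == 1.0 and p[1] == 1.0

    def test_zero_variance_distinct_means_degenerate(self):
        v = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        p, _ref, degen = unpaired_t_vs_min(v)
        assert math.isnan(p[1]) and degen[1]

    def test_matches_first_principles_oracle(self):
        lo = np.array([10.0, 12.0, 11.0])
        hi = np.array([20.0, 19.0, 22.0])
        p, ref, _ = unpaired_t_vs_min(np.vstack([lo, hi]))
        assert ref == 0
        assert p[1] == pytest.approx(oracle_two_sample_p(hi, lo), abs=1e-6)

    def test_reference_is_min_mean_timepoint(self):
        v = np.array([[5.0, 6.0, 7.0], [1.0, 2.0, 3.0], [9.0, 9.0, 10.0]])
        _p, ref, _ = unpaired_t_vs_min(v)
        assert ref == 1


class TestPairedT:
    def test_equal_channels_p_one(self):
        h = np.array([10.0, 20.0, 30.0])
        assert paired_t_silac(h, h) == (1.0, False)

    def test_constant_fold_change_degenerate(self):
        l = np.array([10.0, 20.0, 40.0])
        p, degen = paired_t_silac(2.0 * l, l)
        assert p is None and degen

    def test_matches_first_principles_oracle(self):
        h = np.array([20.0, 19.0, 22.0])
        l = np.array([10.0, 12.0, 11.0])
        d = np.log10(h) - np.log10(l)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        expected = 2 * sps.t.sf(abs(t), len(d) - 1)
        p, _ = paired_t_silac(h, l)
        assert p == pytest.approx(expected, abs=1e-6)

    def test_equal_per_replicate_offsets_cancel(self):
        """Multiplying both channels of a replicate by a common factor (an
        injection offset) leaves the paired p-value unchanged."""
        h = np.array([210.0, 195.0, 185.0])
        l = np.array([100.0, 104.0, 99.0])
        offsets = np.array([0.5, 1.7, 3.0])
        p_plain, _ = paired_t_silac(h, l)
        p_offset, _ = paired_t_silac(h * offsets, l * offsets)
        assert p_offset == pytest.approx(p_plain, abs=1e-12)


def brute_force_qvalues(p, pi0=1.0):
    """O(m^2) stepwise minimum with ranks = #{p_k <= p_j}; oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank = np.sum(p <= p[j])
                candidates.append(pi0 * m * p[j] / rank)
        q[i] = min(min(candidates), 1.0)
    return q


class TestStoreyQvalues:
    def test_single_p_of_one(self):
        np.testing.assert_allclose(storey_qvalues(np.array([1.0]), pi0=1.0), [1.0])

    def test_matches_brute_force_oracle_pi0_fixed(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=200)
        got = storey_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(got, brute_force_qvalues(p), atol=1e-9)

    def test_brute_force_with_ties(self):
        p = np.array([0.01, 0.01, 0.5, 0.5, 0.2, 1.0, 0.0])
        np.testing.assert_allclose(
            storey_qvalues(p, pi0=1.0), brute_force_qvalues(p), atol=1e-12
        )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, plist):
        p = np.asarray(plist)
        q = storey_qvalues(p, pi0=1.0)
        assert np.all(q <= 1.0 + 1e-12) and np.all(q >= 0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_smoother_near_one_under_null(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=2000)
        assert estimate_pi0(p) == pytest.approx(1.0, abs=0.1)

    def test_pi0_below_one_with_signal(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=1000), rng.beta(0.1, 10, size=1000)])
        assert estimate_pi0(p) < 0.9

    def test_small_sample_falls_back_to_one(self):
        assert estimate_pi0(np.array([0.5] * 50)) == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([1.5]))

    def test_empty_input(self):
        assert len(storey_qvalues(np.array([]))) == 0


class TestFlagSignificant:
    def test_strict_threshold(self):
        q = np.array([0.019, 0.02, 0.021, np.nan])
        np.testing.assert_array_equal(
            flag_significant(q), [True, False, False, False]
        )


class TestReproducibility:
    def test_identical_replicates(self):
        arr = np.tile(np.array([[2.0, 2.0, 2.0]]), (10, 1))
        out = reproducibility_stats(arr)
        assert np.allclose(out["mean"], 0.0)
        assert np.allclose(out["sd"], 0.0)
        assert np.allclose(out["frac_in_range"], 1.0)

    def test_closed_form_in_range_fraction(self):
        """Log-normal replicate noise: the in-range fraction matches the
        normal-CDF prediction built from the observed ratio-of-ratios SD."""
        rng = np.random.default_rng(5)
        sigma = 0.2
        n = 4000
        # ratio per replicate = exp(eps_h - eps_l), eps ~ N(0, sigma)
        ratios = np.exp(
            rng.normal(0, sigma, (n, 3)) - rng.normal(0, sigma, (n, 3))
        )
        out = reproducibility_stats(ratios)
        for _, row in out.iterrows():
            predicted = sps.norm.cdf(0.6 / row["sd"]) - sps.norm.cdf(-0.6 / row["sd"])
            assert row["frac_in_range"] == pytest.approx(predicted, abs=0.03)
            assert row["mean"] == pytest.approx(0.0, abs=0.03)

    def test_requires_complete_triples(self):
        with pytest.raises(ValueError):
            reproducibility_stats(np.full((5, 3), np.nan))


class TestMatrixBuilders:
    @pytest.fixture()
    def quant(self):
        rows = []
        rng = np.random.default_rng(3)
        for pep in ("a", "b"):
            for tp in range(4):
                for rep in range(3):
                    base = 1000.0 * (tp + 1) if pep == "a" else 5000.0
                    noise = rng.lognormal(0, 0.05)
                    for ch, scale in (("light", 1.0), ("heavy", 0.5)):
                        rows.append(dict(
                            peptide_id=pep, channel=ch, timepoint=tp,
                            replicate=rep, raw_area=base * scale * noise,
                            spike_area=2000.0, norm_area=base * scale * noise / 2000.0,
                        ))
        return pd.DataFrame(rows)

    def test_labelfree_rows_center_to_zero(self, quant):
        m = build_labelfree_matrix(quant, 4)
        sums = m.values.sum(axis=1, skipna=True)
        assert np.allclose(sums, 0.0, atol=1e-9)
        assert m.capped.abs().to_numpy().max() <= math.log10(100.0) + 1e-12

    def test_silac_matrix_recovers_half_ratio(self, quant):
        m = build_silac_matrix(quant, 4)
        vals = m.values.to_numpy()
        np.testing.assert_allclose(vals, math.log10(0.5), atol=1e-6)

    def test_blank_cells_carry_no_statistics(self, quant):
        quant.loc[
            (quant["peptide_id"] == "a") & (quant["timepoint"] == 2), "raw_area"
        ] = np.nan
        quant.loc[
            (quant["peptide_id"] == "a") & (quant["timepoint"] == 2), "norm_area"
        ] = np.nan
        lf = build_labelfree_matrix(quant, 4)
        assert bool(lf.blank.loc["a", 2])
        assert math.isnan(lf.p.loc["a", 2])
        assert not bool(lf.significant.loc["a", 2])
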