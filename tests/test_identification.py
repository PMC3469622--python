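"""Score/ppm gates, decoy FDR machinery and non-redundant assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosquant.identification import (
    FilterPolicy,
    apply_observation_rule,
    assemble_nonredundant,
    estimate_decoy_fdr,
    filter_psms,
    passes_score_filters,
    threshold_for_fdr,
)


def _psm(engine="A", charge=2, score=3.0, ppm=0.0):
    theo = 1000.0
    return dict(
        charge=charge, engine=engine, score=score,
        theo_mass=theo, obs_mass=theo * (1 + ppm * 1e-6),
    )


class TestScoreFilters:
    @pytest.mark.parametrize(
        "psm,expected",
        [
            (_psm("A", 2, 2.0, 3.0), False),   # strict inequality at +2 > 2.0
            (_psm("A", 2, 2.01, 3.0), True),
            (_psm("A", 1, 1.5, 0.0), False),
            (_psm("A", 1, 1.6, 0.0), True),
            (_psm("A", 3, 2.5, 0.0), False),
            (_psm("B", 2, 10.5, 19.9), True),  # Mowse > 10 and |ppm| < 20
            (_psm("B", 2, 10.0, 0.0), False),
            (_psm("A", 1, 1.6, 25.0), False),  # ppm gate
            (_psm("A", 1, 1.6, -25.0), False),
            (_psm("A", 4, 99.0, 0.0), False),  # charge screening
        ],
    )
    def test_gate_examples(self, psm, expected):
        assert passes_score_filters(psm, FilterPolicy()) is expected

    def test_ppm_boundary_strict(self):
        # masses chosen so the computed error is exactly 20.0 ppm in floats
        at_20 = dict(charge=2, engine="A", score=5.0, theo_mass=1e6,
                     obs_mass=1000020.0)
        below = dict(charge=2, engine="A", score=5.0, theo_mass=1e6,
                     obs_mass=1000019.0)
        assert not passes_score_filters(at_20, FilterPolicy())
        assert passes_score_filters(below, FilterPolicy())

    @given(
        score=st.floats(0.0, 10.0),
        bump=st.floats(0.01, 5.0),
        charge=st.sampled_from([1, 2, 3]),
    )
    @settings(max_examples=50, deadline=None)
    def test_acceptance_monotone_in_score(self, score, bump, charge):
        policy = FilterPolicy()
        low = _psm("A", charge, score, 1.0)
        high = _psm("A", charge, score + bump, 1.0)
        if passes_score_filters(low, policy):
            assert passes_score_filters(high, policy)


class TestDecoyFdr:
    @pytest.mark.parametrize(
        "t,d,expected",
        [(1000, 0, 0.0), (995, 5, 0.01), (0, 10, 1.0), (0, 0, 0.0)],
    )
    def test_estimator(self, t, d, expected):
        assert estimate_decoy_fdr(t, d) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_decoy_fdr(-1, 0)


def brute_force_threshold(psms: pd.DataFrame, target: float) -> float:
    """Exhaustive scan over every unique cutoff; oracle for threshold_for_fdr."""
    scores = psms["score"].to_numpy(float)
    decoy = psms["decoy"].to_numpy(bool)
    feasible = []
    for cutoff in np.unique(scores):
        acc = scores >= cutoff
        d, t = int((decoy & acc).sum()), int((~decoy & acc).sum())
        if estimate_decoy_fdr(t, d) <= target:
            feasible.append(cutoff)
    return min(feasible) if feasible else math.inf


class TestThresholdForFdr:
    def test_separable_case(self):
        rows = [_psm("A", 2, 10.0) | {"decoy": False} for _ in range(50)]
        rows += [_psm("A", 2, 1.0) | {"decoy": True} for _ in range(50)]
        df = pd.DataFrame(rows)
        thr = threshold_for_fdr(df, FilterPolicy(fdr_target=0.005))
        assert 1.0 < thr["A"] <= 10.0

    def test_matches_exhaustive_oracle_on_fixture(self, psm_fixture_12row):
        for target in (0.005, 0.1, 0.2, 0.3, 0.5):
            policy = FilterPolicy(fdr_target=target)
            got = threshold_for_fdr(psm_fixture_12row, policy)["A"]
            assert got == brute_force_threshold(psm_fixture_12row, target)

    def test_vacuous_target_accepts_all(self, psm_fixture_12row):
        thr = threshold_for_fdr(psm_fixture_12row, FilterPolicy(fdr_target=0.999))
        assert thr["A"] == psm_fixture_12row["score"].min()

    def test_monotone_in_target(self, psm_fixture_12row):
        thresholds = [
            threshold_for_fdr(psm_fixture_12row, FilterPolicy(fdr_target=t))["A"]
            for t in (0.5, 0.3, 0.2, 0.1, 0.005)
        ]
        assert thresholds == sorted(thresholds)  # lowering target never lowers cutoff

    def test_unreachable_target_returns_inf(self):
        rows = [_psm("A", 2, 5.0) | {"decoy": True} for _ in range(10)]
        df = pd.DataFrame(rows)
        assert threshold_for_fdr(df, FilterPolicy(fdr_target=0.005))["A"] == math.inf


class TestAssembly:
    def _rows(self):
        def row(seq, mods, engine, score, tp, pid):
            return dict(
                psm_id=pid, peptide_id=pid, sequence=seq, mods=mods, charge=2,
                engine=engine, score=score, obs_mass=1000.0, theo_mass=1000.0,
                decoy=False, timepoint=tp, replicate=0, channel="light",
            )
        # 9 PSMs / 4 unique (sequence, site-set) keys
        return pd.DataFrame([
            row("AAYK", "2:79.9663:phospho", "A", 3.0, 0, "p1"),
            row("AAYK", "2:79.9663:phospho", "B", 30.0, 1, "p1"),
            row("AAYK", "2:79.9663:phospho", "A", 3.5, 2, "p1"),
            row("AYAK", "1:79.9663:phospho", "A", 2.8, 0, "p2"),
            row("AYAK", "1:79.9663:phospho", "A", 2.9, 0, "p2"),
            row("YAYK", "0:79.9663:phospho", "A", 3.1, 3, "p3"),
            row("YAYK", "2:79.9663:phospho", "B", 25.0, 3, "p4"),  # other site
            row("YAYK", "2:79.9663:phospho", "B", 28.0, 4, "p4"),
            row("YAYK", "0:79.9663:phospho", "B", 26.0, 5, "p3"),
        ])

    def test_fixture_collapses_to_four_keys(self):
        out = assemble_nonredundant(self._rows())
        assert len(out) == 4
        aayk = out[out["sequence"] == "AAYK"].iloc[0]
        assert aayk["best_score_A"] == 3.5
        assert aayk["best_score_B"] == 30.0
        assert aayk["observed_timepoints"] == "0,1,2"

    def test_same_sequence_different_site_kept_separate(self):
        out = assemble_nonredundant(self._rows())
        assert (out["sequence"] == "YAYK").sum() == 2

    def test_idempotent_and_never_grows(self):
        rows = self._rows()
        out = assemble_nonredundant(rows)
        assert len(out) <= len(rows)
        again = assemble_nonredundant(rows)
        pd.testing.assert_frame_equal(out, again)


class TestObservationRule:
    @pytest.mark.parametrize(
        "tps,expected",
        [("0,1,2,3", True), ("0,1,2", False), ("0,1,2,3,4,5,6,7", True), ("", False)],
    )
    def test_four_of_eight(self, tps, expected):
        entry = {"observed_timepoints": tps}
        assert apply_observation_rule(entry, FilterPolicy()) is expected

    def test_duplicate_timepoints_count_once(self):
        assert not apply_observation_rule([0, 0, 1, 2], FilterPolicy())


def test_filter_psms_removes_decoys_and_respects_gates(small_experiment):
    _, run = small_experiment
    accepted = filter_psms(run.psms)
    assert not accepted["decoy"].any()
    assert set(accepted["engine"]) <= {"A", "B"}
    merged = accepted.merge(
        run.psms[["psm_id", "score"]], on="psm_id", suffixes=("", "_orig")
    )
    assert np.allclose(merged["score"], merged["score_orig"])
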