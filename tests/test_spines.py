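"""Spine turnover, density, morphology and persistence statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plasticity import spines as sp
from plasticity.synthetic import SpineSimParams, simulate_spine_tracks

from conftest import BASELINES, SESSIONS, make_table


def counts_for(counts, prev, curr, dendrite="d0"):
    for c in counts:
        if c.session_prev == prev and c.session_curr == curr and c.dendrite_id == dendrite:
            return c
    raise KeyError((prev, curr, dendrite))


class TestTransitions:
    def test_all_stable_pair(self):
        table = make_table({f"s{i}": [1, 1] for i in range(10)}, sessions=["B1", "B2"])
        c = counts_for(sp.classify_transitions(table, ["B1", "B2"]), "B1", "B2")
        assert (c.n_stable, c.n_eliminated, c.n_formed) == (10, 0, 0)

    def test_hand_counted_mixture(self):
        # 50 spines at B1; 45 survive to B2; 3 new ones appear at B2
        codes = {f"old{i}": [1, 1] for i in range(45)}
        codes.update({f"gone{i}": [1, 0] for i in range(5)})
        codes.update({f"new{i}": [0, 1] for i in range(3)})
        table = make_table(codes, sessions=["B1", "B2"])
        c = counts_for(sp.classify_transitions(table, ["B1", "B2"]), "B1", "B2")
        assert c.n_prev == 50
        assert c.n_stable == 45
        assert c.n_eliminated == 5
        assert c.n_formed == 3
        assert c.n_curr == 48

    def test_reappearance_counts_as_formation(self):
        table = make_table({"s": [1, 0, 1]}, sessions=["B1", "B2", "3d"])
        counts = sp.classify_transitions(table, ["B1", "B2", "3d"])
        first = counts_for(counts, "B1", "B2")
        second = counts_for(counts, "B2", "3d")
        assert first.n_eliminated == 1 and first.n_formed == 0
        assert second.n_formed == 1 and second.n_eliminated == 0

    def test_single_session_rejected(self):
        table = make_table({"s": [1]}, sessions=["B1"])
        with pytest.raises(ValueError, match="two sessions"):
            sp.classify_transitions(table, ["B1"])

    def test_unknown_session_named(self):
        table = make_table({"s": [1, 1]}, sessions=["B1", "X9"])
        with pytest.raises(ValueError, match="X9"):
            sp.classify_transitions(table, ["B1", "B2"])

    def test_conservation_and_recursion_on_simulated_tables(self):
        params = SpineSimParams(
            n_dendrites=20,
            spines_per_dendrite_mean=15,
            elimination_prob_per_session={s: 0.1 for s in SESSIONS[1:]},
            formation_rate_per_session={s: 0.08 for s in SESSIONS[1:]},
            seed=11,
        )
        table, _ = simulate_spine_tracks(params)
        for c in sp.classify_transitions(table, SESSIONS):
            assert c.n_stable + c.n_eliminated == c.n_prev
            assert c.n_stable + c.n_formed == c.n_curr
            assert c.n_curr == c.n_prev - c.n_eliminated + c.n_formed

    def test_row_order_and_relabeling_invariance(self):
        params = SpineSimParams(n_dendrites=5, seed=3,
                                elimination_prob_per_session={"3d": 0.5})
        table, _ = simulate_spine_tracks(params)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        relabeled = shuffled.assign(spine_id="x_" + shuffled["spine_id"])
        a = sp.turnover_rates(sp.classify_transitions(table, SESSIONS))
        b = sp.turnover_rates(sp.classify_transitions(relabeled, SESSIONS))
        pd.testing.assert_frame_equal(
            a.sort_values(["dendrite_id", "session_prev"]).reset_index(drop=True),
            b.sort_values(["dendrite_id", "session_prev"]).reset_index(drop=True),
        )


class TestDensityAndRates:
    def test_hand_density(self):
        table = make_table({f"s{i}": [1, 1] for i in range(24)}, sessions=["B1", "B2"])
        d = sp.spine_density(table, "B1")
        assert d.loc[0, "density_per_um"] == pytest.approx(24 / 60)

    def test_zero_spines_density(self):
        table = make_table({"s": [1, 0]}, sessions=["B1", "B2"])
        d = sp.spine_density(table, "B2")
        assert d.loc[0, "density_per_um"] == 0.0

    def test_nonpositive_length_rejected(self):
        table = make_table({"s": [1, 1]}, sessions=["B1", "B2"], length_um=-1.0)
        with pytest.raises(ValueError):
            sp.spine_density(table, "B1")

    def test_hand_rates(self):
        c = sp.TransitionCounts("d0", "B1", "B2", n_prev=50, n_stable=45,
                                n_eliminated=5, n_formed=0, n_curr=45)
        rates = sp.turnover_rates([c])
        assert rates.loc[0, "elimination_rate_pct"] == pytest.approx(10.0)
        assert rates.loc[0, "formation_rate_pct"] == 0.0
        assert rates.loc[0, "stable_fraction_pct"] == pytest.approx(90.0)

    def test_empty_previous_session_is_undefined_not_error(self):
        c = sp.TransitionCounts("d0", "B1", "B2", 0, 0, 0, 0, 0)
        rates = sp.turnover_rates([c])
        assert math.isnan(rates.loc[0, "elimination_rate_pct"])
        agg = sp.aggregate(rates, ["elimination_rate_pct"])
        assert agg.loc[0, "n"] == 0 and agg.loc[0, "n_excluded"] == 1


def persistence_oracle(code, baseline_idx, denominator):
    """Independent enumeration of the persistence index definition."""
    n = len(code)
    pre_existing = all(code[i] == 1 for i in baseline_idx)
    if pre_existing:
        if denominator == "post_baseline":
            scored = [code[i] for i in range(max(baseline_idx) + 1, n)]
        else:
            scored = [code[i] for i in range(min(baseline_idx), n)]
    else:
        birth = code.index(1)
        scored = code[birth + 1:] if denominator == "post_baseline" else code[birth:]
    return sum(scored) / len(scored) if scored else float("nan")


class TestPersistence:
    def test_always_present_spine(self, sessions, baselines):
        table = make_table({"s": [1] * 8})
        rec = sp.persistence_index(table, "d0", "s", sessions, baselines)
        assert rec.spine_class == "pre_existing"
        assert rec.persistence_index == 1.0

    def test_pre_existing_alternating_code(self):
        # baselines 1,1 then post-baseline 1,0,1,0 -> 0.5
        table = make_table({"s": [1, 1, 1, 0, 1, 0]}, sessions=SESSIONS[:6])
        rec = sp.persistence_index(table, "d0", "s", SESSIONS[:6], BASELINES)
        assert rec.persistence_index == pytest.approx(0.5)

    def test_newly_formed_examples(self):
        # born at session index 2 of 7; present at all four later sessions
        table = make_table({"s": [0, 0, 1, 1, 1, 1, 1]}, sessions=SESSIONS[:7])
        rec = sp.persistence_index(table, "d0", "s", SESSIONS[:7], BASELINES)
        assert rec.spine_class == "newly_formed"
        assert rec.birth_session == "3d"
        assert rec.persistence_index == 1.0
        # present at the next session only -> 1 of 4
        table = make_table({"s": [0, 0, 1, 1, 0, 0, 0]}, sessions=SESSIONS[:7])
        rec = sp.persistence_index(table, "d0", "s", SESSIONS[:7], BASELINES)
        assert rec.persistence_index == pytest.approx(0.25)

    def test_birth_at_final_session_is_undefined(self):
        table = make_table({"s": [0, 0, 0, 1]}, sessions=SESSIONS[:4])
        rec = sp.persistence_index(table, "d0", "s", SESSIONS[:4], BASELINES)
        assert math.isnan(rec.persistence_index)

    @pytest.mark.parametrize("denominator", ["post_baseline", "all_sessions"])
    def test_matches_exhaustive_enumeration(self, denominator):
        """Every binary code of length <= 6 agrees with the brute-force oracle."""
        baseline_idx = [0, 1]
        for n in range(2, 7):
            for code in itertools.product([0, 1], repeat=n):
                if sum(code) == 0:
                    continue
                _, _, got = sp.persistence_from_code(
                    np.array(code), baseline_idx, denominator
                )
                want = persistence_oracle(list(code), baseline_idx, denominator)
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)

    def test_persistence_table_matches_per_spine(self):
        params = SpineSimParams(
            n_dendrites=4,
            elimination_prob_per_session={s: 0.2 for s in SESSIONS[1:]},
            formation_rate_per_session={s: 0.1 for s in SESSIONS[1:]},
            seed=5,
        )
        table, _ = simulate_spine_tracks(params)
        bulk = sp.persistence_table(table, SESSIONS, BASELINES)
        sample = bulk.sample(20, random_state=1)
        for _, row in sample.iterrows():
            rec = sp.persistence_index(
                table, row["dendrite_id"], row["spine_id"], SESSIONS, BASELINES
            )
            assert rec.spine_class == row["spine_class"]
            if math.isnan(rec.persistence_index):
                assert math.isnan(row["persistence_index"])
            else:
                assert rec.persistence_index == pytest.approx(row["persistence_index"])


class TestMorphologyAndAggregate:
    def test_hand_fractions(self):
        codes = {f"m{i}": [1] for i in range(6)}
        table = pd.concat(
            [
                make_table({f"m{i}": [1, 1] for i in range(6)}, sessions=["B1", "B2"]),
                make_table({f"t{i}": [1, 1] for i in range(3)}, sessions=["B1", "B2"], morph="thin"),
                make_table({"st0": [1, 1]}, sessions=["B1", "B2"], morph="stubby"),
            ],
            ignore_index=True,
        )
        del codes
        frac = sp.morphology_fractions(table, "B1", "d0")
        assert frac == pytest.approx({"mushroom": 0.6, "thin": 0.3, "stubby": 0.1})
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_session_undefined(self):
        table = make_table({"s": [1, 0]}, sessions=["B1", "B2"])
        frac = sp.morphology_fractions(table, "B2", "d0")
        assert all(math.isnan(v) for v in frac.values())

    def test_missing_labels_listed(self):
        table = make_table({"s1": [1, 1], "s2": [1, 1]}, sessions=["B1", "B2"])
        table.loc[table["spine_id"] == "s2", "morph_type"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            sp.morphology_fractions(table, "B1", "d0")

    def test_aggregate_closed_form(self):
        df = pd.DataFrame({"dendrite_id": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
        agg = sp.aggregate(df, ["v"])
        assert agg.loc[0, "mean"] == pytest.approx(2.0)
        assert agg.loc[0, "sem"] == pytest.approx(0.5774, abs=1e-4)

    def test_aggregate_single_value_sem_undefined(self):
        df = pd.DataFrame({"dendrite_id": ["a"], "v": [4.2]})
        agg = sp.aggregate(df, ["v"])
        assert agg.loc[0, "mean"] == pytest.approx(4.2)
        assert math.isnan(agg.loc[0, "sem"])
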