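"""DEG merging, model-profile machinery with exact permutation null, ddCt."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cublink as cl
from cublink.expression import (
    DEFAULT_GROUPS,
    assign_profiles,
    call_directions,
    group_response_vectors,
    profile_report,
)

import oracles


def deg_table(calls: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """gene -> (log2fc, p_adj)."""
    return pd.DataFrame(
        [
            {"gene_id": g, "log2fc": lfc, "p": p, "p_adj": p}
            for g, (lfc, p) in calls.items()
        ]
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_merge_common_sets_are_intersections():
    a = deg_table({"g1": (2, 0.01), "g2": (2, 0.01), "g3": (2, 0.01), "g4": (0.1, 0.5)})
    b = deg_table({"g2": (1.5, 0.02), "g3": (3, 0.001), "g5": (2, 0.01), "g4": (0.2, 0.9)})
    merged = cl.merge_degs(a, b)
    assert merged.common_up == ("g2", "g3")
    assert merged.n_up == 2 and merged.n_down == 0


def test_merge_reports_direction_conflicts():
    a = deg_table({"g1": (2, 0.01), "g2": (-2, 0.01)})
    b = deg_table({"g1": (-2, 0.01), "g2": (-3, 0.001)})
    merged = cl.merge_degs(a, b)
    assert merged.conflicts == ("g1",)
    assert merged.common_down == ("g2",)
    assert "g1" not in merged.common_up + merged.common_down


def test_merge_is_commutative():
    a, b, _ = cl.simulate_deg_tables(200, 12, 9, 5, 5, 3, seed=4)
    m1, m2 = cl.merge_degs(a, b), cl.merge_degs(b, a)
    assert m1.common_up == m2.common_up
    assert m1.common_down == m2.common_down
    assert m1.conflicts == m2.conflicts


def test_merge_recovers_planted_counts_exactly():
    a, b, truth = cl.simulate_deg_tables(1000, 25, 18, 10, 10, 5, seed=9)
    merged = cl.merge_degs(a, b)
    planted = truth.planted_degs["contrast"]
    assert merged.common_up == planted["common_up"]
    assert merged.common_down == planted["common_down"]
    assert merged.conflicts == planted["conflict"]


def test_merge_requires_overlapping_universes():
    a = deg_table({"g1": (2, 0.01)})
    b = deg_table({"h1": (2, 0.01)})
    with pytest.raises(ValueError):
        cl.merge_degs(a, b)


def test_direction_thresholds():
    df = call_directions(
        deg_table({"a": (2, 0.01), "b": (0.5, 0.01), "c": (2, 0.2), "d": (-1.0, 0.049)})
    )
    assert dict(zip(df.gene_id, df.direction)) == {
        "a": "up", "b": "ns", "c": "ns", "d": "down",
    }


# ---------------------------------------------------------------------------
# profile machinery
# ---------------------------------------------------------------------------


def test_candidate_profile_counts():
    assert len(cl.candidate_profiles(4, 1)) == 27
    assert len(cl.candidate_profiles(4, 2)) == 125
    for pat in cl.candidate_profiles(4, 2):
        assert pat[0] == 0
        assert all(abs(pat[i + 1] - pat[i]) <= 2 for i in range(3))


def test_profile_selection_matches_independent_greedy():
    mine = [p.pattern for p in cl.stem_profiles(4, 2, 50)]
    assert mine == oracles.greedy_profiles(4, 2, 50)
    assert (0,) * 4 not in mine
    assert len(set(mine)) == 50
    # byte-identical serialization across runs
    again = [p.pattern for p in cl.stem_profiles(4, 2, 50)]
    assert str(mine) == str(again)


def test_profile_selection_rejects_oversized_m():
    with pytest.raises(ValueError):
        cl.stem_profiles(4, 1, 27)  # only 26 non-flat candidates


def test_rescue_profile_is_the_stress_spike():
    profs = cl.stem_profiles(4, 2, 50)
    rid = cl.rescue_profile_id(profs)
    pattern = profs[rid].pattern
    assert pattern[0] == pattern[1] == pattern[3] == 0
    assert pattern[2] > 0


def test_exact_shape_match_assignment():
    profs = cl.stem_profiles(4, 2, 50)
    patterns = np.array([p.pattern for p in profs], float)
    idx = assign_profiles(np.array([[0, 0, 2, 0]]), patterns)
    assert profs[idx[0]].pattern == (0, 0, 1, 0)
    # constant gene unassigned
    assert assign_profiles(np.array([[1.0, 1, 1, 1]]), patterns)[0] == -1


def test_assignment_matches_oracle_loop(rng):
    profs = cl.stem_profiles(4, 2, 50)
    patterns = [p.pattern for p in profs]
    v = rng.normal(size=(100, 4))
    mine = assign_profiles(v, np.array(patterns, float))
    for row, got in zip(v, mine):
        assert got == oracles.assign_gene(tuple(row), patterns)


def test_exact_permutation_null_hand_enumerable():
    """With spike profiles at each position, a spike gene's 24 permutations
    split 12/6/6: positions 1-3 attract 6 permutations each, and the six
    spike-at-baseline permutations tie across all profiles and break to the
    lowest profile id.  The package's expected counts must reproduce the
    independent full enumeration."""
    patterns = [(0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]
    profs = [cl.ProfileModel(i, p) for i, p in enumerate(patterns)]
    # balanced library sizes so CPM keeps the constant gene exactly flat
    counts = pd.DataFrame(
        {
            "Control_r1": [100, 100, 800],
            "LZ04_r1": [100, 100, 800],
            "CaCl2_r1": [800, 100, 100],
            "CaCl2+LZ04_r1": [100, 100, 800],
        },
        index=["gene_a", "gene_b", "gene_fill"],
    )
    groups = pd.Series({f"{g}_r1": g for g in DEFAULT_GROUPS})
    tested, assignment = cl.assign_and_test_profiles(counts, groups, profs)
    assert assignment["gene_a"] == 1  # spike at the CaCl2 position
    assert assignment["gene_b"] == -1  # constant gene unassigned
    v = group_response_vectors(counts, groups)
    # hand-enumerable single-gene shares for the spike gene
    shares = oracles.exact_permutation_expectation([tuple(v.loc["gene_a"])], patterns)
    assert shares == pytest.approx([12 / 24, 6 / 24, 6 / 24])
    # package expectation equals the oracle enumeration over all assigned genes
    assigned_vecs = [tuple(v.loc[g]) for g in v.index if assignment[g] >= 0]
    expected = oracles.exact_permutation_expectation(assigned_vecs, patterns)
    for prof, exp in zip(tested, expected):
        assert prof.expected == pytest.approx(exp * len(assigned_vecs), abs=1e-12)


def test_permutation_expectations_sum_to_one_over_assigned(rng):
    profs = cl.stem_profiles(4, 2, 20)
    sim = cl.simulate_counts(100, seed=5)
    tested, assignment = cl.assign_and_test_profiles(sim.counts, sim.groups, profs)
    n_assigned = int((assignment >= 0).sum())
    assert sum(p.n_assigned for p in tested) == n_assigned
    assert sum(p.expected for p in tested) == pytest.approx(n_assigned, rel=1e-9)


def test_planted_rescue_profile_significant_and_matches_oracle():
    profs = cl.stem_profiles(4, 2, 50)
    sim = cl.simulate_counts(600, planted={(0, 0, 1, 0): 60}, effect=2.0, seed=33)
    tested, assignment = cl.assign_and_test_profiles(sim.counts, sim.groups, profs)
    rid = cl.rescue_profile_id(tested)
    assert tested[rid].significant
    assert tested[rid].p_value < 0.05
    # oracle recomputation of the assigned count
    v = group_response_vectors(sim.counts, sim.groups)
    patterns = [p.pattern for p in profs]
    oracle_count = sum(
        oracles.assign_gene(tuple(row), patterns) == rid for row in v.to_numpy()
    )
    assert tested[rid].n_assigned == oracle_count
    planted = set(sim.truth.planted_profiles["0,0,1,0"])
    recovery = np.mean([assignment[g] == rid for g in planted])
    assert recovery > 0.5  # dispersion 0.1 caps recovery well below 1


def test_rescue_profile_rarely_significant_under_pure_noise():
    profs = cl.stem_profiles(4, 2, 50)
    hits = 0
    for seed in range(20):
        sim = cl.simulate_counts(400, seed=900 + seed)
        tested, _ = cl.assign_and_test_profiles(sim.counts, sim.groups, profs)
        hits += tested[cl.rescue_profile_id(tested)].significant
    assert hits <= 2


def test_profile_report_shape():
    profs = cl.stem_profiles(4, 2, 10)
    sim = cl.simulate_counts(80, seed=2)
    tested, _ = cl.assign_and_test_profiles(sim.counts, sim.groups, profs)
    rep = profile_report(tested)
    assert list(rep.columns) == [
        "profile_id", "pattern", "n_assigned", "expected", "p_adj", "significant",
    ]
    assert len(rep) == 10


def test_missing_baseline_group_raises():
    sim = cl.simulate_counts(20, seed=1)
    groups = sim.groups.replace("Control", "Mock")
    with pytest.raises(ValueError, match="Control"):
        cl.assign_and_test_profiles(sim.counts, groups, cl.stem_profiles(4, 2, 10))


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------


def ct_rows(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


def test_ddct_worked_examples():
    ct = ct_rows(
        [
            ("c1", "Control", "GAPDH", 18.0), ("c1", "Control", "tg", 21.0),
            ("c2", "Control", "GAPDH", 18.5), ("c2", "Control", "tg", 21.5),
            ("t1", "CaCl2", "GAPDH", 18.2), ("t1", "CaCl2", "tg", 20.2),  # ddct -1
            ("t2", "CaCl2", "GAPDH", 18.0), ("t2", "CaCl2", "tg", 23.0),  # ddct +2
        ]
    )
    out = cl.ddct_fold_change(ct).set_index("sample")
    assert out.loc["c1", "fold"] == pytest.approx(1.0)  # dct equals control mean
    assert out.loc["t1", "fold"] == pytest.approx(2.0)
    assert out.loc["t2", "fold"] == pytest.approx(0.25)


def test_ddct_control_geometric_mean_fold_is_one():
    ct = cl.simulate_ct_table({"tg": {"CaCl2": 4.0}}, noise_sd=0.3, seed=8)
    out = cl.ddct_fold_change(ct)
    control = out[out.group == "Control"]
    geo = math.exp(np.mean(np.log(control["fold"])))
    assert geo == pytest.approx(1.0, abs=1e-12)


def test_ddct_invariant_to_global_ct_shift():
    ct = cl.simulate_ct_table({"tg": {"CaCl2": 4.0}}, noise_sd=0.2, seed=3)
    shifted = ct.copy()
    shifted["ct"] = shifted["ct"] + 5.0  # same shift on target and reference
    a = cl.ddct_fold_change(ct)["fold"].to_numpy()
    b = cl.ddct_fold_change(shifted)["fold"].to_numpy()
    assert a == pytest.approx(b, abs=1e-9)


def test_ddct_drops_samples_without_reference():
    ct = ct_rows(
        [
            ("c1", "Control", "GAPDH", 18.0), ("c1", "Control", "tg", 21.0),
            ("t1", "CaCl2", "tg", 20.0),  # no reference measurement
        ]
    )
    with pytest.warns(UserWarning, match="t1"):
        out = cl.ddct_fold_change(ct)
    assert set(out["sample"]) == {"c1"}


def test_ddct_recovers_simulated_folds_exactly():
    truth = {"BGLU40": {"CaCl2": 4.0, "CaCl2+LZ04": 1.5}, "HNL": {"CaCl2": 2.0}}
    out = cl.ddct_fold_change(cl.simulate_ct_table(truth, seed=5))
    means = out.groupby(["gene", "group"])["fold"].mean()
    assert means.loc[("BGLU40", "CaCl2")] == pytest.approx(4.0)
    assert means.loc[("BGLU40", "CaCl2+LZ04")] == pytest.approx(1.5)
    assert means.loc[("HNL", "CaCl2")] == pytest.approx(2.0)
    assert means.loc[("HNL", "LZ04")] == pytest.approx(1.0)
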