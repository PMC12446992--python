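"""RSCU, ENC, SCUO, PR2, the expected-ENC curve, and index summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cublink as cl
from cublink.cds_io import BaseComposition
from cublink.genetic_code import CODON_INDEX

import oracles
from conftest import counts_from, single_codon_counts, uniform_counts


def random_counts(seed: int, scale: int = 30) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = np.zeros(64, dtype=np.int64)
    for c in cl.STANDARD_CODE.sense_codons:
        x[CODON_INDEX[c]] = rng.integers(0, scale)
    return x


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def test_rscu_hand_example():
    v = cl.rscu(counts_from({"GCA": 3, "GCT": 1}))
    assert v.values[CODON_INDEX["GCA"]] == pytest.approx(3.0)
    assert v.values[CODON_INDEX["GCT"]] == pytest.approx(1.0)
    assert v.values[CODON_INDEX["GCC"]] == pytest.approx(0.0)
    assert np.isnan(v.values[CODON_INDEX["AAA"]])  # unobserved family flagged


def test_rscu_uniform_usage_is_all_ones(code):
    v = cl.rscu(uniform_counts(code))
    finite = v.values[np.isfinite(v.values)]
    assert np.allclose(finite, 1.0)
    assert v.informative_mask.sum() == 59


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_rscu_family_sums_equal_family_size(seed):
    code = cl.STANDARD_CODE
    v = cl.rscu(random_counts(seed), code)
    for codons in code.families.values():
        vals = v.values[[CODON_INDEX[c] for c in codons]]
        if np.isfinite(vals).all():
            assert vals.sum() == pytest.approx(len(codons), abs=1e-9)


def test_genome_rscu_equals_pooled_count_oracle(organism_pair):
    table = organism_pair["query_counts"]
    mine = cl.genome_rscu(table).as_dict()
    pooled = {c: int(n) for c, n in zip(cl.CODONS, table.pooled()) if n}
    expected = oracles.rscu(pooled)
    assert set(mine) == set(expected)
    for c in expected:
        assert mine[c] == pytest.approx(expected[c], abs=1e-12)


def test_genome_rscu_table_layout(organism_pair):
    df = cl.genome_rscu_table(
        {"query": organism_pair["query_counts"], "partner": organism_pair["partner_counts"]}
    )
    assert list(df.columns) == ["amino_acid", "codon", "query", "partner"]
    assert len(df) == 61
    # singleton families are 1 by definition when observed
    assert df.loc[df.codon == "ATG", ["query", "partner"]].to_numpy() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


def test_enc_single_codon_per_family_is_20(code):
    assert cl.enc(single_codon_counts(code)).enc == pytest.approx(20.0)


def test_enc_homozygosity_hand_example():
    # Lys AAA=3, AAG=1: F = (4 * 0.625 - 1) / 3 = 0.5
    value = cl.enc(counts_from({"AAA": 3, "AAG": 1}))
    assert value.family_means[2] == pytest.approx(0.5)
    assert not value.defined  # other degeneracy classes unobserved


def test_enc_uniform_10000_codons_near_61(code):
    per = 10000 // 61
    assert cl.enc(uniform_counts(code, per)).enc == pytest.approx(61.0, abs=0.5)


def test_enc_imputes_missing_threefold_class(code):
    x = uniform_counts(code, 10)
    for c in code.families["I"]:
        x[CODON_INDEX[c]] = 0
    value = cl.enc(x)
    assert value.defined
    assert value.imputed_classes == (3,)
    assert value.family_means[3] == pytest.approx(
        (value.family_means[2] + value.family_means[4]) / 2
    )


def test_enc_never_increases_as_family_bias_grows(rng):
    # shifting counts within a family toward its dominant codon never
    # increases ENC (homozygosity can only grow)
    for _ in range(20):
        x = random_counts(int(rng.integers(1 << 30)), scale=20) + 1
        aa = list(cl.STANDARD_CODE.multi_families)[int(rng.integers(18))]
        codons = cl.STANDARD_CODE.families[aa]
        idx = [CODON_INDEX[c] for c in codons]
        target = max(idx, key=lambda i: x[i])
        others = [i for i in idx if i != target]
        prev = cl.enc(x).enc
        while any(x[i] > 0 for i in others):
            for i in others:
                if x[i] > 0:
                    x[i] -= 1
                    x[target] += 1
            cur = cl.enc(x).enc
            assert cur <= prev + 1e-9
            prev = cur


@pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
def test_enc_expected_curve_values(s, expected):
    assert cl.enc_expected_curve(s) == pytest.approx(expected)


def test_enc_expected_curve_rejects_out_of_range():
    with pytest.raises(ValueError):
        cl.enc_expected_curve(1.5)


# ---------------------------------------------------------------------------
# SCUO
# ---------------------------------------------------------------------------


def test_scuo_limits(code):
    assert cl.scuo(single_codon_counts(code)).scuo == pytest.approx(1.0)
    assert cl.scuo(uniform_counts(code, 5)).scuo == pytest.approx(0.0)


def test_scuo_lysine_hand_example():
    # H = -(0.75 log2 0.75 + 0.25 log2 0.25) = 0.8113; O = 1 - H
    assert cl.scuo(counts_from({"AAA": 3, "AAG": 1})).scuo == pytest.approx(0.1887, abs=1e-4)


def test_scuo_undefined_without_multi_codon_families():
    assert not cl.scuo(counts_from({"ATG": 5, "TGG": 2})).defined


def test_scuo_and_enc_anticorrelate_on_bias_gradient(code):
    # 50-step gradient from uniform usage to one codon per family
    encs, scuos = [], []
    for step in range(50):
        lam = step / 49
        x = np.zeros(64)
        for codons in code.families.values():
            idx = [CODON_INDEX[c] for c in codons]
            k = len(idx)
            p = (1 - lam) * np.ones(k) / k
            p[0] += lam
            x[idx] = np.round(600 * p / k)
        encs.append(cl.enc(x).enc)
        scuos.append(cl.scuo(x).scuo)
    from scipy.stats import spearmanr

    rho = spearmanr(encs, scuos).statistic
    assert rho < -0.95


# ---------------------------------------------------------------------------
# PR2
# ---------------------------------------------------------------------------


def _comp(a3, c3, g3, t3):
    return BaseComposition(
        gc=0.5, gc1=0.5, gc2=0.5, gc3=0.5,
        a3=a3, c3=c3, g3=g3, t3=t3,
        a3_ff=a3, c3_ff=c3, g3_ff=g3, t3_ff=t3,
        n_codons=a3 + c3 + g3 + t3,
    )


def test_pr2_center_is_boundary():
    p = cl.pr2_point(_comp(2, 3, 3, 2))
    assert (p.x, p.y) == (0.5, 0.5)
    assert p.quadrant == "boundary"


def test_pr2_hand_example():
    p = cl.pr2_point(_comp(a3=1, c3=1, g3=3, t3=3))
    assert (p.x, p.y) == (0.75, 0.25)
    assert p.quadrant == "bottom-right"


def test_pr2_zero_denominator_is_undefined():
    p = cl.pr2_point(_comp(a3=2, c3=0, g3=0, t3=2))
    assert math.isnan(p.x) and not p.defined
    assert p.quadrant == "undefined"


def test_pr2_matches_sequence_oracle(rng):
    for _ in range(10):
        seq = oracles.random_gene(rng, 200)
        p = cl.pr2_point(cl.base_composition(seq))
        ox, oy = oracles.pr2(seq)
        assert p.x == pytest.approx(ox) and p.y == pytest.approx(oy)


# ---------------------------------------------------------------------------
# summaries and index correlations
# ---------------------------------------------------------------------------


def test_index_table_and_correlations_match_covariance_oracle():
    rng = np.random.default_rng(11)
    seqs = [cl.CodingSequence(f"g{i}", oracles.random_gene(rng, 150)) for i in range(200)]
    df = cl.gene_index_table(seqs)
    summary, r, p = cl.index_summary_and_correlations(df)
    assert summary.loc["gc", "min"] >= 0 and summary.loc["gc", "max"] <= 1
    for a in ("enc", "gc3", "scuo"):
        assert r.loc[a, a] == pytest.approx(1.0)
        for b in ("enc", "gc3"):
            pair = df[[a, b]].dropna()
            orr, orp = oracles.pearson(pair[a], pair[b])
            assert r.loc[a, b] == pytest.approx(orr, abs=1e-10)
            assert p.loc[a, b] == pytest.approx(orp, abs=1e-10)


def test_negated_index_correlates_minus_one():
    rng = np.random.default_rng(3)
    import pandas as pd

    df = pd.DataFrame({"a": rng.normal(size=50)})
    df["b"] = -df["a"]
    _, r, _ = cl.index_summary_and_correlations(df, columns=["a", "b"])
    assert r.loc["a", "b"] == pytest.approx(-1.0)


def test_correlations_undefined_below_three_pairs():
    import pandas as pd

    df = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, np.nan, 2.0]})
    _, r, _ = cl.index_summary_and_correlations(df, columns=["a", "b"])
    assert np.isnan(r.loc["a", "b"])
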