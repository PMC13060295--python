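import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_pair_stats
from kmerrates.estimators import (
    estimate_all,
    observe,
    q_cc,
    q_mash,
    q_obl,
    q_pc,
    q_pp,
    q_wi,
)
from kmerrates.kmer_core import build_spectrum, d1_table
from kmerrates.mutation import MutationParams, mutate, r_of_q
from kmerrates.synthetic import random_sequence

dna = st.text(alphabet="ACGT", min_size=4, max_size=60)


def pair_obs(s, t, k):
    return observe(build_spectrum(s, k), build_spectrum(t, k))


def test_observe_worked_example():
    obs = pair_obs("AAAA", "AATA", 2)
    assert (obs.L, obs.Ipp, obs.Npp, obs.Npc, obs.Icc, obs.union_size) == (
        3, 1, 2, 2, 1, 3,
    )


def test_observe_identity_pair():
    s = random_sequence(300, 0)
    obs = pair_obs(s, s, 5)
    spec = build_spectrum(s, 5)
    assert obs.Npp == obs.Npc == 0
    assert obs.Ipp == spec.distinct
    assert obs.Icc == spec.L


def test_observe_k_mismatch():
    with pytest.raises(ValueError, match="k mismatch"):
        observe(build_spectrum("ACGT", 2), build_spectrum("ACGT", 3))


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_observe_agrees_with_naive_multiset_oracle(seed):
    s = random_sequence(150, seed)
    t = mutate(s, MutationParams(0.15, seed + 1))
    obs = pair_obs(s, t, 4)
    naive = naive_pair_stats(s, t, 4)
    for field, value in naive.items():
        assert getattr(obs, field) == value, field


@pytest.mark.parametrize(
    "fn,expected",
    [(q_obl, 2 / 3), (q_mash, 0.5), (q_pp, 2 / 3), (q_pc, 2 / 3), (q_wi, 2 / 3)],
)
def test_plugin_formulas_on_worked_example(fn, expected):
    res = fn(pair_obs("AAAA", "AATA", 2))
    assert res.q_hat == pytest.approx(expected, abs=1e-12)
    assert res.r_hat == r_of_q(res.q_hat, 2)


def test_identity_pair_gives_zero_everywhere():
    # k large enough that all k-mers are distinct, so even the
    # intersection-based obl estimator sees Ipp = L
    s = random_sequence(200, 3)
    obs = pair_obs(s, s, 12)
    d1sum = d1_table(build_spectrum(s, 12))
    for res in estimate_all(obs, d1sum).values():
        assert res.q_hat == 0.0
        assert res.r_hat == 0.0


def test_disjoint_pair_saturates_at_one():
    # distinct-k-mer sequences with nothing shared: every estimator
    # caps at q = 1 (on a repetitive s, pp alone would stay below 1
    # because novel *distinct* k-mers number fewer than L)
    s, t = random_sequence(60, 1), random_sequence(60, 2)
    obs = pair_obs(s, t, 12)
    assert obs.Ipp == 0 and obs.Npp == obs.L
    d1sum = d1_table(build_spectrum(s, 12))
    for res in estimate_all(obs, d1sum).values():
        assert res.q_hat == 1.0
        assert res.r_hat == 1.0


def test_pc_exceeds_pp_on_doubled_novel_kmer():
    """Two copies of a k-mer mutating to the same new k-mer:
    pp counts it once, pc twice."""
    s = "AACAACAAC"  # AAC occurs 3x at k=3
    t = "AATAACAAT"  # two copies became AAT
    obs = pair_obs(s, t, 3)
    assert obs.Npc > obs.Npp
    assert q_pc(obs).q_hat > q_pp(obs).q_hat


def test_cc_equals_pc_without_close_neighbors():
    s = "AAAAAA"  # single k-mer, C = 0
    t = mutate(s, MutationParams(0.3, 5))
    obs = pair_obs(s, t, 3)
    d1sum = d1_table(build_spectrum(s, 3))
    assert d1sum.weighted_sum_C == 0
    assert q_cc(obs, d1sum).q_hat == q_pc(obs).q_hat


def test_cc_correction_is_strictly_positive():
    s = "AATAA"  # spectrum {AA, AT, TA} has HD-1 neighbors -> C > 0
    d1sum = d1_table(build_spectrum(s, 2))
    assert d1sum.weighted_sum_C > 0
    t = "AATCA"
    obs = pair_obs(s, t, 2)
    assert 0 < q_pc(obs).q_hat < 1
    assert q_cc(obs, d1sum).q_hat > q_pc(obs).q_hat


def test_cc_blowup_limit():
    """q_pc capped at 1 => r_pc = 1 => correction vanishes, q_cc = 1."""
    obs = pair_obs("AATAA", "CCGCC", 2)
    assert q_pc(obs).q_hat == 1.0
    d1sum = d1_table(build_spectrum("AATAA", 2))
    assert q_cc(obs, d1sum).q_hat == 1.0


@given(st.integers(0, 10_000), st.floats(0.01, 0.9))
@settings(max_examples=30, deadline=None)
def test_all_estimates_in_unit_interval_and_roundtrip(seed, r):
    s = random_sequence(120, seed)
    t = mutate(s, MutationParams(r, seed + 1))
    obs = pair_obs(s, t, 5)
    d1sum = d1_table(build_spectrum(s, 5))
    for res in estimate_all(obs, d1sum).values():
        assert 0.0 <= res.q_hat <= 1.0
        assert res.r_hat == r_of_q(res.q_hat, 5)


def test_pc_and_cc_monotone_in_npc():
    """Holding s fixed, increasing Npc never decreases q_pc or q_cc."""
    from dataclasses import replace

    obs = pair_obs("AATAA", "AATCA", 2)
    d1sum = d1_table(build_spectrum("AATAA", 2))
    prev_pc = prev_cc = -1.0
    for npc in range(0, obs.L + 1):
        o = replace(obs, Npc=npc)
        pc = q_pc(o).q_hat
        cc = q_cc(o, d1sum).q_hat
        assert pc >= prev_pc
        assert cc >= prev_cc - 1e-12
        prev_pc, prev_cc = pc, cc
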