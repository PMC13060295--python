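import numpy as np
import pytest

from kmerrates.estimators import observe, q_cc, q_pc, q_pp
from kmerrates.kmer_core import build_spectrum, d1_table
from kmerrates.mutation import MutationParams, mutate
from kmerrates.sketching import (
    hash_kmers,
    load_sketch,
    q_cc_theta,
    q_pc_theta,
    q_pp_theta,
    save_sketch,
    sketch_spectrum,
    sketched_observations,
)
from kmerrates.synthetic import random_sequence


def test_theta_one_retains_everything():
    spec = build_spectrum(random_sequence(500, 0), 8)
    sk = sketch_spectrum(spec, 1.0, 42)
    assert sk.retained == spec.counts
    assert sk.full_L == spec.L


def test_tiny_theta_eventually_empty():
    spec = build_spectrum(random_sequence(200, 1), 8)
    sk = sketch_spectrum(spec, 1e-12, 42)
    assert sk.retained == {}


def test_theta_out_of_range():
    spec = build_spectrum("ACGTACGT", 3)
    for theta in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            sketch_spectrum(spec, theta, 0)


def test_retained_fraction_concentrates_at_theta():
    """Mean retained fraction over many hash seeds is ~theta."""
    spec = build_spectrum(random_sequence(3000, 2), 10)
    theta = 0.3
    m = spec.distinct
    n_seeds = 400
    fracs = [
        len(sketch_spectrum(spec, theta, seed).retained) / m
        for seed in range(n_seeds)
    ]
    se = np.sqrt(theta * (1 - theta) / (m * n_seeds))
    assert abs(np.mean(fracs) - theta) < 5 * se


def test_hashes_are_deterministic_and_seed_sensitive():
    kmers = [random_sequence(12, i) for i in range(50)]
    h1 = hash_kmers(kmers, 12, 7)
    assert np.array_equal(h1, hash_kmers(kmers, 12, 7))
    assert not np.array_equal(h1, hash_kmers(kmers, 12, 8))


def test_long_kmer_hash_path():
    """k > 32 takes the digest-based path; still deterministic."""
    kmers = [random_sequence(40, i) for i in range(10)]
    h1 = hash_kmers(kmers, 40, 3)
    assert np.array_equal(h1, hash_kmers(kmers, 40, 3))
    assert len(set(h1.tolist())) == 10


def test_incompatible_sketches_rejected():
    spec = build_spectrum(random_sequence(100, 0), 6)
    a = sketch_spectrum(spec, 0.5, 1)
    for b in (
        sketch_spectrum(spec, 0.5, 2),
        sketch_spectrum(spec, 0.4, 1),
        sketch_spectrum(build_spectrum(random_sequence(100, 0), 7), 0.5, 1),
    ):
        with pytest.raises(ValueError):
            sketched_observations(a, b)


def test_theta_one_observations_match_unsketched():
    s = random_sequence(400, 3)
    t = mutate(s, MutationParams(0.1, 4))
    spec_s, spec_t = build_spectrum(s, 9), build_spectrum(t, 9)
    full = observe(spec_s, spec_t)
    sk = sketched_observations(
        sketch_spectrum(spec_s, 1.0, 0), sketch_spectrum(spec_t, 1.0, 0)
    )
    assert sk == full


def test_sketched_observations_match_naive_on_retained():
    s = random_sequence(600, 5)
    t = mutate(s, MutationParams(0.2, 6))
    spec_s, spec_t = build_spectrum(s, 8), build_spectrum(t, 8)
    sk_s = sketch_spectrum(spec_s, 0.4, 11)
    sk_t = sketch_spectrum(spec_t, 0.4, 11)
    obs = sketched_observations(sk_s, sk_t)
    cs, ct = sk_s.retained, sk_t.retained
    new = set(ct) - set(cs)
    assert obs.Npp == len(new)
    assert obs.Npc == sum(ct[x] for x in new)
    assert obs.Ipp == len(set(cs) & set(ct))
    assert obs.Icc == sum(
        min(cs.get(x, 0), ct.get(x, 0)) for x in set(cs) | set(ct)
    )
    assert obs.L == spec_s.L  # full L, not sketched size


def test_theta_one_estimators_bit_identical():
    s = random_sequence(500, 7)
    t = mutate(s, MutationParams(0.12, 8))
    spec_s, spec_t = build_spectrum(s, 10), build_spectrum(t, 10)
    d1sum = d1_table(spec_s)
    full = observe(spec_s, spec_t)
    sk = sketched_observations(
        sketch_spectrum(spec_s, 1.0, 0), sketch_spectrum(spec_t, 1.0, 0)
    )
    assert q_pp_theta(sk, 1.0).q_hat == q_pp(full).q_hat
    assert q_pc_theta(sk, 1.0).q_hat == q_pc(full).q_hat
    assert q_cc_theta(sk, 1.0, d1sum).q_hat == q_cc(full, d1sum).q_hat


def test_capping_at_one():
    from kmerrates.estimators import Observations

    obs = Observations(k=5, L=100, Ipp=0, Npp=80, Npc=90, Icc=0, union_size=100)
    theta = 0.5  # theta*L = 50 < Npp
    assert q_pp_theta(obs, theta).q_hat == 1.0
    assert q_pc_theta(obs, theta).q_hat == 1.0
    # capped pc => r_pc = 1 => correction vanishes
    from kmerrates.kmer_core import D1Summary

    assert q_cc_theta(obs, theta, D1Summary(d1={}, weighted_sum_C=1000)).q_hat == 1.0


def test_sketch_json_roundtrip(tmp_path):
    spec = build_spectrum(random_sequence(300, 9), 7)
    sk = sketch_spectrum(spec, 0.3, 123, C_full=77)
    path = tmp_path / "sketch.json"
    save_sketch(sk, path)
    assert load_sketch(path) == sk
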