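"""Synthetic sequence generators for testing and benchmarking.

Three families, all pure functions of their parameters plus a seed:

* i.i.d. uniform random sequences — the repeat-free baseline;
* all-distinct-k-mer sequences — realizations of the idealized regime
  in which every k-mer of s is unique (optionally with a minimum
  pairwise Hamming distance, which kills the d1 correction term);
* tandem-repeat arrays — a surrogate for alpha-satellite centromeric
  DNA: one random monomer (171 bp by default, the alpha-satellite
  monomer length) copied many times, with divergence accumulating
  *along* the array (each copy is a mutated descendant of the previous
  one, emulating the homogenized structure of satellite arrays where
  neighboring copies share recent ancestry and sequence variants recur
  across many copies), plus a final light round of *recent* private
  substitutions over the whole array (variants not yet shared by
  homogenization).  The defaults — 585 copies x 171 bp, 0.12% per-copy
  step divergence, 0.04% recent divergence — give a ~100 kbp array
  whose 30-mer spectrum matches the repetitiveness profile of real
  centromeric satellite extractions: ~4,000 distinct 30-mers, ~70%
  occurring more than once, ~2 Hamming-distance-1 neighbors per
  k-mer — the regime where intersection-based estimators break down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_core import build_spectrum, d1_table
from .mutation import MutationParams, decode, mutate


@dataclass(frozen=True)
class RepeatArraySpec:
    """Parameters of the tandem-repeat surrogate."""

    monomer_length: int = 171
    n_copies: int = 585
    per_copy_divergence: float = 0.0012
    recent_divergence: float = 0.0004
    seed: int = 0


def random_sequence(length: int, seed: int) -> str:
    """i.i.d. uniform ACGT string; deterministic given seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return decode(rng.integers(0, 4, size=length, dtype=np.int8))


def tandem_repeat_sequence(spec: RepeatArraySpec) -> str:
    """Tandem array of serially diverged copies of one random monomer.

    Copy i is copy i-1 passed through the substitution process at rate
    ``per_copy_divergence`` (copy 0 mutates the founder monomer), so a
    variant introduced in one copy persists in its descendants — the
    pattern produced by the homogenization processes that shape real
    satellite arrays, and the reason variant k-mers occur in several
    copies rather than once.  A final pass at ``recent_divergence``
    adds private substitutions that no other copy shares (mutations
    younger than the last homogenization event); these contribute the
    singleton k-mers seen in real arrays.  With both divergences 0 the
    result is a perfect array whose distinct k-mer set (for any k up
    to the monomer length) has at most ``monomer_length`` members.
    """
    ss = np.random.SeedSequence(spec.seed)
    monomer_seed, copies_seed, recent_seed = (
        int(s.generate_state(1)[0]) for s in ss.spawn(3)
    )
    monomer = random_sequence(spec.monomer_length, monomer_seed)
    if spec.per_copy_divergence == 0.0:
        array = monomer * spec.n_copies
    else:
        copy_seeds = np.random.SeedSequence(copies_seed).generate_state(spec.n_copies)
        copies = []
        current = monomer
        for s in copy_seeds:
            current = mutate(current, MutationParams(spec.per_copy_divergence, int(s)))
            copies.append(current)
        array = "".join(copies)
    if spec.recent_divergence > 0.0:
        array = mutate(array, MutationParams(spec.recent_divergence, recent_seed))
    return array


def repeat_surrogate_stats(sequence: str, k: int = 30) -> dict[str, float]:
    """Repetitiveness self-check statistics of a generated array.

    Returns the fraction of distinct k-mers occurring at least twice
    and the mean number of Hamming-distance-1 neighbors per distinct
    k-mer.  The default surrogate parameters were frozen so that the
    first exceeds 0.5 and the second is at least 1.
    """
    spec = build_spectrum(sequence, k)
    multi = sum(1 for c in spec.counts.values() if c >= 2)
    d1 = d1_table(spec)
    m = spec.distinct
    return {
        "distinct": m,
        "frac_multi_occurrence": multi / m,
        "mean_d1_neighbors": sum(d1.d1.values()) / m,
    }


def distinct_kmer_sequence(
    length: int,
    k: int,
    min_pairwise_hd: int = 1,
    seed: int = 0,
    max_tries: int = 1000,
) -> str:
    """Rejection-sample a sequence whose k-mers are all distinct.

    With ``min_pairwise_hd >= 2`` the distinct k-mers must additionally
    be pairwise at that Hamming distance or more (O(L^2) check,
    intended for test-sized inputs; min_pairwise_hd = 3 guarantees the
    d1 constant C = 0).  Feasible only when length is small relative to
    4^k; raises after ``max_tries`` rejections.
    """
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_tries):
        s = random_sequence(length, int(child.generate_state(1)[0]))
        spec = build_spectrum(s, k)
        if spec.distinct != spec.L:
            continue
        if min_pairwise_hd >= 2 and not _pairwise_hd_ok(
            list(spec.counts), min_pairwise_hd
        ):
            continue
        return s
    raise RuntimeError(
        f"could not build a distinct-k-mer sequence in {max_tries} tries; "
        "reduce length, increase k, or relax min_pairwise_hd"
    )


def _pairwise_hd_ok(kmers: list[str], min_hd: int) -> bool:
    for i, a in enumerate(kmers):
        for b in kmers[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) < min_hd:
                return False
    return True
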