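"""FracMinHash sketching and the sketched estimators.

A FracMinHash sketch retains exactly the k-mers whose (seeded) 64-bit
hash falls below ``theta`` times the hash range — a random theta-fraction
of the k-mer universe, shared between any two sketches built with the
same (k, theta, seed).  The novel-k-mer statistics computed on the
retained sets scale down by theta in expectation, so dividing the
sketched counts by ``theta * L`` gives estimators with exactly the same
bias as their unsketched counterparts; only the variance grows as theta
shrinks.  Because a sketched statistic can exceed ``theta * L``, the
sketched estimators are capped at 1.

The cc correction constant ``C = sum occ(tau, s) * d1(tau, s)`` cannot
be recovered from a sketch; it is precomputed from the full source
spectrum and stored alongside the sketch as a single number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .estimators import EstimateResult, Observations, _result
from .kmer_core import D1Summary, KmerSpectrum

_MASK64 = (1 << 64) - 1
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _splitmix64(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        z = (z + _GOLDEN).astype(np.uint64)
        z = (z ^ (z >> np.uint64(30))) * _M1
        z = (z ^ (z >> np.uint64(27))) * _M2
        return z ^ (z >> np.uint64(31))


def hash_kmers(kmers: Sequence[str], k: int, hash_seed: int) -> np.ndarray:
    """Seeded 64-bit hashes of k-mers, stable across platforms and runs.

    For k <= 32 the k-mer is packed into a 2-bit-per-base integer and
    passed through a splitmix64-style finalizer, fully vectorized; for
    larger k a keyed blake2b digest is used.
    """
    if len(kmers) == 0:
        return np.empty(0, dtype=np.uint64)
    seed_mix = _splitmix64(np.uint64(hash_seed & _MASK64))
    if k <= 32:
        buf = np.frombuffer("".join(kmers).encode("ascii"), dtype=np.uint8)
        codes = _CODE[buf].reshape(len(kmers), k).astype(np.uint64)
        powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
        with np.errstate(over="ignore"):
            packed = (codes * powers).sum(axis=1, dtype=np.uint64)
        return _splitmix64(packed ^ seed_mix)
    key = int(seed_mix).to_bytes(8, "little")
    out = np.empty(len(kmers), dtype=np.uint64)
    for i, kmer in enumerate(kmers):
        digest = hashlib.blake2b(kmer.encode("ascii"), digest_size=8, key=key).digest()
        out[i] = int.from_bytes(digest, "little")
    return out


@dataclass(frozen=True)
class Sketch:
    """FracMinHash-retained subset of a spectrum.

    ``full_L`` is the k-mer count of the *unsketched* source sequence —
    the sketched estimators divide by ``theta * full_L``, and sequence
    length is observable even when only a sketch is kept.  ``C_full``
    optionally carries the precomputed cc correction constant.
    """

    k: int
    theta: float
    hash_seed: int
    full_L: int
    retained: Dict[str, int]
    C_full: int | None = None


def sketch_spectrum(
    spec: KmerSpectrum,
    theta: float,
    hash_seed: int,
    C_full: int | None = None,
) -> Sketch:
    """Retain the k-mers whose normalized hash is below theta.

    The threshold test is exact integer arithmetic:
    ``hash(tau) < floor(theta * 2**64)``; theta = 1 retains everything.
    Occurrence counts are carried over unchanged.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    if theta == 1.0:
        retained = dict(spec.counts)
    else:
        kmers = list(spec.counts)
        hashes = hash_kmers(kmers, spec.k, hash_seed)
        threshold = np.uint64(int(theta * (1 << 64)))
        keep = hashes < threshold
        retained = {kmer: spec.counts[kmer] for kmer, ok in zip(kmers, keep) if ok}
    return Sketch(
        k=spec.k, theta=theta, hash_seed=hash_seed, full_L=spec.L,
        retained=retained, C_full=C_full,
    )


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    if a.theta != b.theta:
        raise ValueError(f"theta mismatch: {a.theta} != {b.theta}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("hash seed mismatch: sketches use different hash universes")


def sketched_observations(sk_s: Sketch, sk_t: Sketch) -> Observations:
    """Pair statistics restricted to the retained k-mer sets.

    The ``L`` field carries the full (unsketched) L of the source,
    which the theta-estimators need for their ``theta * L`` denominator.
    """
    _check_compatible(sk_s, sk_t)
    cs, ct = sk_s.retained, sk_t.retained
    Ipp = Icc = Npp = Npc = 0
    for tau, occ_t in ct.items():
        occ_s = cs.get(tau)
        if occ_s is None:
            Npp += 1
            Npc += occ_t
        else:
            Ipp += 1
            Icc += min(occ_s, occ_t)
    return Observations(
        k=sk_s.k, L=sk_s.full_L, Ipp=Ipp, Npp=Npp, Npc=Npc, Icc=Icc,
        union_size=len(cs) + Npp,
    )


def q_pp_theta(obs_theta: Observations, theta: float) -> EstimateResult:
    """Sketched novelty estimator q = Npp_theta / (theta * L), capped at 1."""
    return _result("pp_theta", obs_theta.Npp / (theta * obs_theta.L), obs_theta.k)


def q_pc_theta(obs_theta: Observations, theta: float) -> EstimateResult:
    """Sketched count-novelty estimator q = Npc_theta / (theta * L), capped at 1."""
    return _result("pc_theta", obs_theta.Npc / (theta * obs_theta.L), obs_theta.k)


def q_cc_theta(
    obs_theta: Observations,
    theta: float,
    d1sum_full: D1Summary | int,
    k: int | None = None,
) -> EstimateResult:
    """Sketched plug-in corrected estimator.

    ``d1sum_full`` (or the bare constant C) must come from the FULL
    unsketched source spectrum — it is precomputed before sketching.
    """
    if k is None:
        k = obs_theta.k
    C = d1sum_full if isinstance(d1sum_full, int) else d1sum_full.weighted_sum_C
    r_pc = q_pc_theta(obs_theta, theta).r_hat
    L = obs_theta.L
    q_base = min(1.0, obs_theta.Npc / (theta * L))
    corr = (1.0 - r_pc) ** (k - 1) * (r_pc / (3.0 * L)) * C
    return _result("cc_theta", q_base + corr, k)


def save_sketch(sketch: Sketch, path) -> None:
    """Write a sketch as a small JSON document (sketch once, compare many)."""
    doc = {
        "k": sketch.k,
        "theta": sketch.theta,
        "hash_seed": sketch.hash_seed,
        "full_L": sketch.full_L,
        "C_full": sketch.C_full,
        "retained": sorted(sketch.retained.items()),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_sketch(path) -> Sketch:
    with open(path) as fh:
        doc = json.load(fh)
    return Sketch(
        k=doc["k"], theta=doc["theta"], hash_seed=doc["hash_seed"],
        full_L=doc["full_L"], retained={km: c for km, c in doc["retained"]},
        C_full=doc.get("C_full"),
    )
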