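"""Simple substitution mutation process.

Each position of the source string is, independently, left unchanged
with probability ``1 - r`` and otherwise replaced by one of the three
other nucleotides, each with probability ``r/3``.  Under this model a
k-mer survives unmutated with probability ``(1-r)^k``; the complement

    q = 1 - (1 - r)^k

is the probability that a k-mer window contains at least one
substitution.  Estimators are derived for q and mapped back to r with
the inverse formula ``r = 1 - (1 - q)^(1/k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationParams:
    """Substitution rate and RNG stream identifier.

    ``seed`` fully determines the realized mutation; replicate i of an
    experiment should pass an independent substream seed (see
    :func:`kmerrates.evaluation.replicate_seed`).
    """

    r: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")


def encode(sequence: str) -> np.ndarray:
    """Map an ACGT string to int8 codes 0..3; reject anything else."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes < 0).any():
        bad = chr(raw[int(np.argmax(codes < 0))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def mutate(sequence: str, params: MutationParams) -> str:
    """Apply the substitution process to a clean ACGT string.

    Deterministic given (sequence, r, seed).  A substituted character is
    never equal to the original: the replacement is drawn as a cyclic
    offset of 1..3 from the original 2-bit code, which is uniform over
    the three alternatives.
    """
    codes = encode(sequence.upper())
    rng = np.random.default_rng(params.seed)
    u = rng.random(codes.size)
    offsets = rng.integers(1, 4, size=codes.size, dtype=np.int8)
    hit = u < params.r
    out = codes.copy()
    out[hit] = (codes[hit] + offsets[hit]) % 4
    return decode(out)


def q_of_r(r: float, k: int) -> float:
    """Probability q = 1 - (1-r)^k that a k-mer mutates."""
    return 1.0 - (1.0 - r) ** k


def r_of_q(q: float, k: int) -> float:
    """Inverse formula r = 1 - (1-q)^(1/k); input clamped into [0, 1]."""
    q = min(1.0, max(0.0, q))
    return 1.0 - (1.0 - q) ** (1.0 / k)
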