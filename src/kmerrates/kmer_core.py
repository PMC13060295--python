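"""k-mer spectra and Hamming-neighborhood machinery.

A *spectrum* is the multiset of k-mers of a DNA sequence: the set of
distinct k-mers together with their occurrence counts and the total
number of counted k-mer positions ``L``.  The repeat-aware estimators
additionally need, for every k-mer tau in the spectrum, the number
``d1(tau)`` of *other* spectrum members at Hamming distance exactly 1,
and the occurrence-weighted sum ``C = sum_tau occ(tau) * d1(tau)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List

DNA_ALPHABET = "ACGT"
_VALID = frozenset(DNA_ALPHABET)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSpectrum:
    """Distinct k-mers of a sequence with occurrence counts.

    Attributes
    ----------
    k : int
        k-mer size.
    L : int
        Number of counted k-mer positions (``|s| - k + 1`` for a clean
        sequence; windows containing non-ACGT characters are excluded).
    counts : dict
        Maps each distinct k-mer to its positive occurrence count.
    """

    k: int
    L: int
    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("invalid k: must be >= 1")
        if self.L != sum(self.counts.values()):
            raise ValueError("L must equal the sum of occurrence counts")

    @property
    def distinct(self) -> int:
        return len(self.counts)

    def kmers(self):
        return self.counts.keys()

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def occ(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass(frozen=True)
class D1Summary:
    """Per-k-mer counts of Hamming-distance-1 neighbors within a spectrum.

    ``weighted_sum_C`` is the constant ``sum_tau occ(tau) * d1(tau)`` that
    the count-count estimator plugs into its bias-correction term; it is
    a property of the source sequence alone and survives sketching.
    """

    d1: Dict[str, int]
    weighted_sum_C: int


def build_spectrum(sequence: str, k: int, canonical: bool = False) -> KmerSpectrum:
    """Count every length-``k`` window of ``sequence`` over {A,C,G,T}.

    Input is uppercased first (soft-masked FASTA is common).  Windows
    containing any non-ACGT character (N runs, IUPAC ambiguity codes)
    are skipped and do not contribute to ``L``.

    With ``canonical=True`` each window is replaced by the
    lexicographic minimum of itself and its reverse complement before
    counting — appropriate for double-stranded genome comparison (ANI
    mode), not for the strand-fixed mutation model.
    """
    if k < 1:
        raise ValueError("invalid k: must be >= 1")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(
            f"sequence too short: length {len(sequence)} < k={k}"
        )
    counts: Counter[str] = Counter()
    if _VALID.issuperset(sequence):
        # clean fast path
        it = (sequence[i : i + k] for i in range(len(sequence) - k + 1))
    else:
        it = _valid_windows(sequence, k)
    if canonical:
        counts.update(min(w, reverse_complement(w)) for w in it)
    else:
        counts.update(it)
    L = sum(counts.values())
    return KmerSpectrum(k=k, L=L, counts=dict(counts))


def _valid_windows(sequence: str, k: int):
    """Yield k-windows consisting solely of ACGT characters."""
    n = len(sequence)
    # index of the most recent invalid character at or before each position
    last_bad = -1
    for i, ch in enumerate(sequence):
        if ch not in _VALID:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            yield sequence[start : i + 1]


def merge_spectra(spectra: List[KmerSpectrum]) -> KmerSpectrum:
    """Pool spectra of independent records (contigs) into one.

    No k-mer spans a record boundary; counts are summed and L pooled.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    k = spectra[0].k
    if any(sp.k != k for sp in spectra):
        raise ValueError("cannot merge spectra with different k")
    counts: Counter[str] = Counter()
    for sp in spectra:
        counts.update(sp.counts)
    return KmerSpectrum(k=k, L=sum(sp.L for sp in spectra), counts=dict(counts))


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length k-mers differ."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length k-mers")
    return sum(x != y for x, y in zip(a, b))


def hd1_neighbors(kmer: str):
    """Yield the 3k single-substitution neighbors of a k-mer."""
    for i, orig in enumerate(kmer):
        for base in DNA_ALPHABET:
            if base != orig:
                yield kmer[:i] + base + kmer[i + 1 :]


def d1_table(spec: KmerSpectrum) -> D1Summary:
    """Compute d1(tau) for every tau in the spectrum and the constant C.

    Two-pass hash-table algorithm: the spectrum's key set is the table;
    for each tau the 3k single-substitution neighbors are generated and
    tested for membership.  tau itself is never counted (distance 0).
    Runtime is O(distinct * 3k); no need for anything fancier at the
    scales this package targets (<~1e5 distinct 30-mers).
    """
    members = spec.counts
    d1: Dict[str, int] = {}
    C = 0
    for tau, occ in members.items():
        n = sum(1 for nb in hd1_neighbors(tau) if nb in members)
        d1[tau] = n
        C += occ * n
    return D1Summary(d1=d1, weighted_sum_C=C)


def dj_counts(tau: str, spec: KmerSpectrum) -> List[int]:
    """Counts of spectrum members at Hamming distance exactly j from tau.

    Returns a vector indexed j = 1..k (position 0 holds j=1).  tau
    itself (distance 0) is excluded.  Brute force over all spectrum
    members — used only by the exact-expectation oracle on tiny inputs.
    """
    if len(tau) != spec.k:
        raise ValueError("k-mer length does not match spectrum k")
    out = [0] * spec.k
    for nu in spec.counts:
        d = hamming_distance(tau, nu)
        if d >= 1:
            out[d - 1] += 1
    return out
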