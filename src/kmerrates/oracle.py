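"""Exact expectations by exhaustive enumeration of mutation outcomes.

On a tiny source string s (|s| <= 12) every possible mutated string t
can be enumerated together with its probability under the substitution
model, giving exact values of E[N^pc], E[q^pc] etc. with no Monte Carlo
error.  These serve as an independent check of two closed-form results:

* the exact expectation of the novel-k-mer count,

      E[N^pc] = L*q - sum_{tau in sp(s)} occ(tau, s) * R(tau, s),

  where R_j(tau, s) = d_j(tau, s) * (1-r)^(k-j) * (r/3)^j is the
  probability that tau mutates onto a spectrum member at Hamming
  distance j, and R = sum_{j=1..k} R_j; and

* the bias of the pc estimator that follows from it,

      E[q^pc] - q = - sum_j sum_tau occ(tau, s) * R_j(tau, s) / L,

  which is non-positive everywhere (pc underestimates q) and zero
  exactly when no spectrum member can mutate onto another.

Statistics are computed through the same kmer_core/estimators code
paths used in production; enumeration is double precision (outcome
probabilities down to (r/3)^12 ~ 1e-19 are representable, and the
checks are equalities of short sums, so 1e-9 tolerances are ample).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Tuple

from .estimators import observe, q_pc, q_pp
from .kmer_core import DNA_ALPHABET, build_spectrum, dj_counts
from .mutation import q_of_r

MAX_ENUM_LENGTH = 12

_STATISTICS = ("Npp", "Npc", "Icc", "Ipp", "q_pc", "q_pp")


@dataclass(frozen=True)
class ExactExpectation:
    value: float
    n_outcomes: int


def enumerate_outcomes(s: str, r: float) -> Iterator[Tuple[str, float]]:
    """Yield every mutated string with its probability under rate r.

    Probability of outcome t is the product over positions of (1-r) if
    t_i == s_i else r/3; the 4^|s| probabilities sum to one.
    """
    if len(s) > MAX_ENUM_LENGTH:
        raise ValueError(
            f"string too long for enumeration: |s|={len(s)} > {MAX_ENUM_LENGTH}"
        )
    keep = 1.0 - r
    sub = r / 3.0
    for chars in product(DNA_ALPHABET, repeat=len(s)):
        p = 1.0
        for orig, new in zip(s, chars):
            p *= keep if new == orig else sub
        yield "".join(chars), p


def exact_E(s: str, k: int, r: float, statistic: str) -> ExactExpectation:
    """Exact expectation of a pair statistic over all mutation outcomes."""
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; one of {_STATISTICS}")
    spec_s = build_spectrum(s, k)
    total = 0.0
    n = 0
    for t, p in enumerate_outcomes(s, r):
        if p == 0.0:
            n += 1
            continue
        obs = observe(spec_s, build_spectrum(t, k))
        if statistic == "q_pc":
            value = q_pc(obs).q_hat
        elif statistic == "q_pp":
            value = q_pp(obs).q_hat
        else:
            value = getattr(obs, statistic)
        total += p * value
        n += 1
    return ExactExpectation(value=total, n_outcomes=n)


def _R_terms(s: str, k: int, r: float):
    """Yield (occ(tau), [R_1..R_k]) for every tau in sp(s)."""
    spec = build_spectrum(s, k)
    keep = 1.0 - r
    sub = r / 3.0
    for tau, occ in spec.counts.items():
        dj = dj_counts(tau, spec)
        Rj = [dj[j - 1] * keep ** (k - j) * sub ** j for j in range(1, k + 1)]
        yield occ, Rj


def lemma1_rhs(s: str, k: int, r: float) -> float:
    """Closed form L*q - sum_tau occ(tau, s) * R(tau, s) for E[N^pc]."""
    spec = build_spectrum(s, k)
    correction = sum(occ * sum(Rj) for occ, Rj in _R_terms(s, k, r))
    return spec.L * q_of_r(r, k) - correction


def theorem1_bias(s: str, k: int, r: float) -> float:
    """Closed-form bias of the pc estimator; always <= 0."""
    spec = build_spectrum(s, k)
    return -sum(occ * sum(Rj) for occ, Rj in _R_terms(s, k, r)) / spec.L


def residuals(s: str, k: int, r: float) -> dict[str, float]:
    """Enumeration-vs-closed-form residuals for one tiny instance.

    Returns the absolute differences |E[N^pc] - closed form| and
    |(E[q^pc] - q) - closed-form bias|; both should vanish to ~1e-9.
    """
    e_npc = exact_E(s, k, r, "Npc").value
    e_qpc = exact_E(s, k, r, "q_pc").value
    return {
        "lemma_residual": abs(e_npc - lemma1_rhs(s, k, r)),
        "bias_residual": abs((e_qpc - q_of_r(r, k)) - theorem1_bias(s, k, r)),
        "bias": theorem1_bias(s, k, r),
    }
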