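"""Point estimators of the k-mer mutation probability q (and hence r).

Six estimators operate on the summary statistics of a pair of spectra
(sp(s), sp(t)), where t is modeled as a mutated copy of s:

========  ==============  ===========================================
name      setting         q-hat formula
========  ==============  ===========================================
obl       presence only   (L - Ipp) / L
mash      presence only   (1 - J) / (1 + J),  J = Jaccard(sp(s),sp(t))
pp        presence only   Npp / L
pc        presence+count  Npc / L
wi        count+count     1 - Icc / L
cc        count+count     pc + HD-1 bias-correction term
========  ==============  ===========================================

``Npp = |sp(t) \\ sp(s)|`` counts the *novel* distinct k-mers of t;
``Npc`` weights them by their occurrence count in t.  Novelty-based
estimators are robust to repeats: a mutation inside a repeated k-mer
still creates a novel k-mer even though it does not shrink the
intersection, so intersection-based formulas (obl, mash, wi)
systematically underestimate q on repetitive sequences.

The cc estimator additionally corrects for mutations that land on a
k-mer already present in s at Hamming distance one — the dominant term
of the negative bias of pc (see :mod:`kmerrates.oracle`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .kmer_core import D1Summary, KmerSpectrum
from .mutation import r_of_q

ESTIMATOR_NAMES = ("obl", "mash", "pp", "pc", "wi", "cc")


@dataclass(frozen=True)
class Observations:
    """Raw pair statistics from which all estimators are computed.

    ``L`` is always the k-mer count of the *source* sequence s (the
    mutation model defines L from s; for unequal-length ANI pairs the
    first/query sequence plays the role of s).
    """

    k: int
    L: int
    Ipp: int  # |sp(s) & sp(t)|
    Npp: int  # |sp(t) - sp(s)|
    Npc: int  # sum of occ(tau, t) over tau in sp(t) - sp(s)
    Icc: int  # sum over tau of min(occ(tau,s), occ(tau,t))
    union_size: int  # |sp(s) | sp(t)|


@dataclass(frozen=True)
class EstimateResult:
    name: str
    q_hat: float  # capped into [0, 1]
    r_hat: float  # r_of_q(q_hat, k)


def _result(name: str, q_hat: float, k: int) -> EstimateResult:
    q_hat = min(1.0, max(0.0, q_hat))
    return EstimateResult(name=name, q_hat=q_hat, r_hat=r_of_q(q_hat, k))


def observe(spec_s: KmerSpectrum, spec_t: KmerSpectrum) -> Observations:
    """Extract the pair statistics Ipp, Npp, Npc, Icc from two spectra."""
    if spec_s.k != spec_t.k:
        raise ValueError(f"k mismatch: {spec_s.k} != {spec_t.k}")
    cs, ct = spec_s.counts, spec_t.counts
    Ipp = 0
    Icc = 0
    Npp = 0
    Npc = 0
    for tau, occ_t in ct.items():
        occ_s = cs.get(tau)
        if occ_s is None:
            Npp += 1
            Npc += occ_t
        else:
            Ipp += 1
            Icc += min(occ_s, occ_t)
    union = len(cs) + Npp
    return Observations(
        k=spec_s.k, L=spec_s.L, Ipp=Ipp, Npp=Npp, Npc=Npc, Icc=Icc,
        union_size=union,
    )


def q_obl(obs: Observations) -> EstimateResult:
    """Intersection-based estimator q = (L - Ipp) / L."""
    return _result("obl", (obs.L - obs.Ipp) / obs.L, obs.k)


def q_mash(obs: Observations) -> EstimateResult:
    """Jaccard-transform estimator q = (1 - J) / (1 + J).

    Evaluated as (U - I) / (U + I) with U = union size, I = Ipp — the
    same quantity, but a single integer-ratio division, so that in the
    k-span regime (U = 2L - I) the result is bit-identical to
    (L - I) / L.
    """
    U, I = obs.union_size, obs.Ipp
    if U == 0:
        return _result("mash", 0.0, obs.k)
    return _result("mash", (U - I) / (U + I), obs.k)


def q_pp(obs: Observations) -> EstimateResult:
    """Novel-distinct-k-mer estimator q = Npp / L."""
    return _result("pp", obs.Npp / obs.L, obs.k)


def q_pc(obs: Observations) -> EstimateResult:
    """Novel-k-mer-count estimator q = Npc / L."""
    return _result("pc", obs.Npc / obs.L, obs.k)


def q_wi(obs: Observations) -> EstimateResult:
    """Weighted-intersection estimator q = 1 - Icc / L."""
    return _result("wi", 1.0 - obs.Icc / obs.L, obs.k)


def q_cc(obs: Observations, d1sum: D1Summary, k: int | None = None) -> EstimateResult:
    """Plug-in corrected estimator.

    Starts from q_pc and adds back the leading (Hamming-distance-1)
    term of its negative bias, evaluated at the plug-in rate
    r_pc = r_of_q(q_pc):

        q_cc = Npc/L + (1 - r_pc)^(k-1) * (r_pc / (3L)) * C,

    where C = sum_tau occ(tau, s) * d1(tau, s) is precomputed from the
    source spectrum (``d1sum`` must come from the same s as ``obs``).
    When q_pc was capped at 1, r_pc = 1 and the correction vanishes, so
    q_cc = 1 — consistent blow-up behavior.
    """
    if k is None:
        k = obs.k
    r_pc = q_pc(obs).r_hat
    corr = (1.0 - r_pc) ** (k - 1) * (r_pc / (3.0 * obs.L)) * d1sum.weighted_sum_C
    return _result("cc", obs.Npc / obs.L + corr, k)


def estimate_all(
    obs: Observations,
    d1sum: D1Summary | None = None,
    names=ESTIMATOR_NAMES,
) -> dict[str, EstimateResult]:
    """Run the requested estimators on one observation set."""
    out: dict[str, EstimateResult] = {}
    for name in names:
        if name == "cc":
            if d1sum is None:
                raise ValueError("cc estimator requires a D1Summary of s")
            out[name] = q_cc(obs, d1sum)
        else:
            out[name] = {
                "obl": q_obl, "mash": q_mash, "pp": q_pp,
                "pc": q_pc, "wi": q_wi,
            }[name](obs)
    return out
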