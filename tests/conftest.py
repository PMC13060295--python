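from collections import Counter

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from kmerrates.kmer_core import build_spectrum
from kmerrates.synthetic import RepeatArraySpec, tandem_repeat_sequence


def naive_pair_stats(s: str, t: str, k: int) -> dict:
    """Independent set/multiset recomputation of the pair statistics.

    Deliberately avoids the package's observe() aggregation path.
    """
    cs = Counter(s[i : i + k] for i in range(len(s) - k + 1))
    ct = Counter(t[i : i + k] for i in range(len(t) - k + 1))
    inter = set(cs) & set(ct)
    new = set(ct) - set(cs)
    return {
        "L": sum(cs.values()),
        "Ipp": len(inter),
        "Npp": len(new),
        "Npc": sum(ct[x] for x in new),
        "Icc": sum(min(cs[x], ct[x]) for x in set(cs) | set(ct)),
        "union_size": len(set(cs) | set(ct)),
    }


@pytest.fixture(scope="session")
def surrogate():
    """Default ~100 kbp repeat-array surrogate (session-cached)."""
    return tandem_repeat_sequence(RepeatArraySpec(seed=0))


@pytest.fixture(scope="session")
def surrogate_spectrum(surrogate):
    return build_spectrum(surrogate, 30)
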