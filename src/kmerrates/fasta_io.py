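"""FASTA ingestion and the ANI application layer.

Multi-record files are treated as multi-contig genomes: k-mers are
extracted per record (never spanning a record boundary) and pooled
into one spectrum; L is the pooled window count.

ANI between two genomes is estimated as 1 - r_hat, using the sketched
presence-count and count-count estimators.  Real genomes are
double-stranded, so ANI mode defaults to canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement) — a
deliberate deviation from the strand-fixed mutation model, overridable.
A pair is flagged *uncomputable* when an estimator saturates at
r_hat = 1 (ANI 0), which happens when the sketched spectra share
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from Bio import SeqIO

from .estimators import observe
from .kmer_core import KmerSpectrum, build_spectrum, d1_table, merge_spectra
from .sketching import (
    q_cc_theta,
    q_pc_theta,
    sketch_spectrum,
    sketched_observations,
)

ANI_DEFAULT_K = 19
ANI_DEFAULT_THETA = 0.01


@dataclass(frozen=True)
class AniResult:
    query_id: str
    reference_id: str
    ani_pc: float
    ani_cc: float
    uncomputable: bool


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read (id, sequence) pairs; uppercases soft-masked lowercase.

    Both LF and CRLF dialects parse identically.  An empty file yields
    an empty list; a non-empty file whose first record-start is missing
    is rejected with the offending line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA at line {lineno}: "
                    "expected a '>' header before sequence data"
                )
            break
        else:
            return []
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, records: List[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_spectrum(path, k: int, canonical: bool = False) -> Tuple[str, KmerSpectrum]:
    """Pooled spectrum of a (possibly multi-contig) FASTA genome."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    spectra = []
    for rid, seq in records:
        if len(seq) >= k:
            spectra.append(build_spectrum(seq, k, canonical=canonical))
    if not spectra:
        raise ValueError(f"{path}: no k-mers extracted (every record shorter than k)")
    return records[0][0], merge_spectra(spectra)


def ani_pair(
    spec_q: KmerSpectrum,
    spec_r: KmerSpectrum,
    theta: float,
    hash_seed: int,
    query_id: str = "query",
    reference_id: str = "reference",
) -> AniResult:
    """One-directional ANI estimate with the query as the source s."""
    C_full = d1_table(spec_q).weighted_sum_C
    if theta >= 1.0:
        obs = observe(spec_q, spec_r)
        theta_eff = 1.0
    else:
        sk_q = sketch_spectrum(spec_q, theta, hash_seed)
        sk_r = sketch_spectrum(spec_r, theta, hash_seed)
        obs = sketched_observations(sk_q, sk_r)
        theta_eff = theta
    r_pc = q_pc_theta(obs, theta_eff).r_hat
    r_cc = q_cc_theta(obs, theta_eff, C_full).r_hat
    return AniResult(
        query_id=query_id,
        reference_id=reference_id,
        ani_pc=1.0 - r_pc,
        ani_cc=1.0 - r_cc,
        uncomputable=(r_pc >= 1.0 or r_cc >= 1.0),
    )


def symmetrized(a: AniResult, b: AniResult) -> AniResult:
    """Mean of the two directions; symmetric by construction."""
    return AniResult(
        query_id=a.query_id,
        reference_id=a.reference_id,
        ani_pc=0.5 * (a.ani_pc + b.ani_pc),
        ani_cc=0.5 * (a.ani_cc + b.ani_cc),
        uncomputable=a.uncomputable or b.uncomputable,
    )
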