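"""Gene-family membership calling for detoxification families (GST/COE/CYP).

Membership of a transcript in a curated gene family (e.g. glutathione
S-transferases or carboxylesterases, using the brown marmorated stink bug's
curated protein sets as queries) is decided from the top high-scoring
segment pair of its best protein alignment against the transcript's longest
six-frame ORF. All five criteria must hold:

* bit score >= 75,
* subject length >= 100 aa,
* hit length / subject length >= 0.90,
* hit length / query length >= 0.75 (query length = longest-ORF length, aa),
* positives / hit length >= 0.80.

The module also provides the supporting bookkeeping used around such calls:
six-frame longest-ORF extraction, collapse of protein sequences to unique
strings, best-hit grouping of P450 candidate tables, and locus-mapping
summaries (how many proteins splice-aligned to a reference genome, and to
how many distinct loci).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .tiering import AlignmentSummary

__all__ = [
    "FamilyThresholds",
    "FamilyCall",
    "call_family",
    "longest_orf",
    "dedup_proteins",
    "cluster_by_best_hit",
    "summarize_loci",
]


@dataclass(frozen=True)
class FamilyThresholds:
    min_bitscore: float = 75.0
    min_subject_aa: int = 100
    min_hit_subject_ratio: float = 0.90
    min_hit_query_ratio: float = 0.75
    min_positive_frac: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_hit_subject_ratio", "min_hit_query_ratio", "min_positive_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_bitscore <= 0:
            raise ValueError("min_bitscore must be > 0")


@dataclass(frozen=True)
class FamilyCall:
    """Membership decision for one transcript, with the failed criteria."""

    transcript_id: str
    family: str
    member: bool
    bitscore: float
    hit_subject_ratio: float
    hit_query_ratio: float
    positive_frac: float
    failed: tuple[str, ...] = ()


def call_family(
    a: AlignmentSummary, t: FamilyThresholds = FamilyThresholds(), label: str = "GST"
) -> FamilyCall:
    """Decide family membership from the query's top HSP.

    ``a.qlen`` is the longest-ORF length in amino acids. Records every
    criterion that failed, so near-misses are auditable.
    """
    if a.qlen < 1 or a.slen < 1:
        raise ValueError(f"{a.qseqid}: query and subject lengths must be positive")
    hs = a.length / a.slen
    hq = a.length / a.qlen
    pf = a.positive / a.length
    failed = []
    if a.bitscore < t.min_bitscore:
        failed.append("min_bitscore")
    if a.slen < t.min_subject_aa:
        failed.append("min_subject_aa")
    if hs < t.min_hit_subject_ratio:
        failed.append("min_hit_subject_ratio")
    if hq < t.min_hit_query_ratio:
        failed.append("min_hit_query_ratio")
    if pf < t.min_positive_frac:
        failed.append("min_positive_frac")
    return FamilyCall(
        transcript_id=a.qseqid,
        family=label,
        member=not failed,
        bitscore=a.bitscore,
        hit_subject_ratio=hs,
        hit_query_ratio=hq,
        positive_frac=pf,
        failed=tuple(failed),
    )


def longest_orf(nt_seq: str, require_start: bool = False) -> str:
    """Longest ORF across all six reading frames, as an amino-acid string.

    An ORF is the longest stop-free stretch beginning at any codon; a start
    codon is not required unless ``require_start``. Standard genetic code.
    Trailing partial codons are ignored. Ties resolve to the earliest frame
    scanned (forward frames 0,1,2 then reverse 0,1,2).
    """
    best = ""
    seq = Seq(nt_seq.upper())
    for strand in (seq, seq.reverse_complement()):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            if len(sub) < 3:
                continue
            aa = str(sub.translate())
            for segment in aa.split("*"):
                if require_start:
                    idx = segment.find("M")
                    segment = segment[idx:] if idx >= 0 else ""
                if len(segment) > len(best):
                    best = segment
    return best


def dedup_proteins(
    seqs: Mapping[str, str],
) -> tuple[list[str], dict[str, str]]:
    """Collapse protein sequences by exact string identity.

    ``seqs`` maps transcript id -> protein sequence. Returns the unique
    sequences (in first-seen order) and a transcript -> sequence map covering
    every input. Empty sequences are rejected.
    """
    if not seqs:
        raise ValueError("protein sequence set must be nonempty")
    unique: "OrderedDict[str, None]" = OrderedDict()
    mapping: dict[str, str] = {}
    for tid, seq in seqs.items():
        if not seq:
            raise ValueError(f"{tid}: empty protein sequence")
        unique.setdefault(seq, None)
        mapping[tid] = seq
    return list(unique), mapping


def cluster_by_best_hit(
    rows: Iterable[tuple[str, str, int]],
) -> dict[str, list[str]]:
    """Group queries by shared best-hit subject.

    ``rows`` are ``(query_id, subject_id, query_length)`` triples with one
    best hit per query (duplicate query ids are an error). Within each group
    queries are ordered by descending length (ties by id, deterministic),
    mirroring the practice of taking each group's longest member as its
    representative.
    """
    seen: set[str] = set()
    groups: dict[str, list[tuple[str, int]]] = {}
    for q, s, qlen in rows:
        if q in seen:
            raise ValueError(f"duplicate query id {q!r}")
        seen.add(q)
        groups.setdefault(s, []).append((q, qlen))
    return {
        s: [q for q, _ in sorted(members, key=lambda m: (-m[1], m[0]))]
        for s, members in groups.items()
    }


def summarize_loci(mapping: pd.DataFrame) -> tuple[int, int]:
    """Count aligned proteins and the distinct loci they align to.

    ``mapping`` needs columns ``protein_id``, ``locus_id``, ``aligned``
    (bool). Returns ``(n_aligned, n_distinct_loci)`` over aligned rows only.
    """
    aligned = mapping[mapping["aligned"].astype(bool)]
    return len(aligned), int(aligned["locus_id"].nunique())
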