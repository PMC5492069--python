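"""Gold/silver/bronze annotation-confidence tiers from protein alignments.

Each assembled transcript is classified by its best protein hit (a BLASTX-
style alignment summary) into one of four confidence tiers:

* **gold** — transcript >= 300 nt, a single HSP against a reference protein
  of >= 100 aa, >= 75% of aligned residues positively similar, and hit
  length >= 90% of the subject length;
* **silver** — transcript >= 100 nt with a hit spanning >= 75% of the
  subject protein's length;
* **bronze** — transcript >= 100 nt with a hit covering >= 30% of the
  subject's length;
* **untiered** — everything else (including transcripts with no hit).

Precedence is gold > silver > bronze. "Positively similar" follows BLAST
tabular semantics: the ``positive`` column divided by the aligned length.
Query lengths are the post-QC transcript lengths in nucleotides (the 300 and
100 nt floors are stated on the transcript, not its translation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AlignmentSummary",
    "TierThresholds",
    "TIER_LABELS",
    "classify_tier",
    "best_hits",
    "tier_table",
    "read_hits_tsv",
]

TIER_LABELS = ("gold", "silver", "bronze", "untiered")

#: Required columns of the alignment-summary dialect (BLAST outfmt-6
#: extension: qseqid qlen sseqid slen length positive bitscore n_hsps).
HIT_COLUMNS = ("qseqid", "qlen", "sseqid", "slen", "length", "positive", "bitscore", "n_hsps")


@dataclass(frozen=True)
class AlignmentSummary:
    """One query-vs-protein hit summary.

    ``length`` counts aligned columns (aa), ``positive`` the positively
    similar aligned residues, ``n_hsps`` the number of HSPs in the hit.
    ``qlen`` is in nucleotides for transcript queries; family calling reuses
    this type with ``qlen`` in amino acids (longest-ORF length).
    """

    qseqid: str
    qlen: int
    sseqid: str
    slen: int
    length: int
    positive: int
    bitscore: float
    n_hsps: int = 1

    def validate(self) -> "AlignmentSummary":
        if self.length < 1:
            raise ValueError(f"{self.qseqid}: hit length must be >= 1")
        if self.slen < 1 or self.qlen < 1:
            raise ValueError(f"{self.qseqid}: query/subject lengths must be >= 1")
        if self.positive > self.length:
            raise ValueError(f"{self.qseqid}: positives exceed aligned length")
        if self.n_hsps < 1:
            raise ValueError(f"{self.qseqid}: n_hsps must be >= 1")
        return self


@dataclass(frozen=True)
class TierThresholds:
    gold_min_query_nt: int = 300
    gold_min_subject_aa: int = 100
    gold_min_positive_frac: float = 0.75
    gold_min_hit_subject_ratio: float = 0.90
    silver_min_query_nt: int = 100
    silver_min_subject_cov: float = 0.75
    bronze_min_query_nt: int = 100
    bronze_min_subject_cov: float = 0.30

    def __post_init__(self) -> None:
        for name in ("gold_min_positive_frac", "gold_min_hit_subject_ratio",
                     "silver_min_subject_cov", "bronze_min_subject_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.silver_min_subject_cov <= self.bronze_min_subject_cov:
            raise ValueError("silver coverage floor must exceed bronze's")


def classify_tier(a: AlignmentSummary, t: TierThresholds = TierThresholds()) -> str:
    """Classify one alignment summary into gold/silver/bronze/untiered."""
    cov = a.length / a.slen
    if (
        a.qlen >= t.gold_min_query_nt
        and a.n_hsps == 1
        and a.slen >= t.gold_min_subject_aa
        and a.positive / a.length >= t.gold_min_positive_frac
        and cov >= t.gold_min_hit_subject_ratio
    ):
        return "gold"
    if a.qlen >= t.silver_min_query_nt and cov >= t.silver_min_subject_cov:
        return "silver"
    if a.qlen >= t.bronze_min_query_nt and cov >= t.bronze_min_subject_cov:
        return "bronze"
    return "untiered"


def best_hits(hits: Iterable[AlignmentSummary]) -> dict[str, AlignmentSummary]:
    """Pick each query's best hit: highest bitscore, ties to the
    lexicographically smallest subject id (deterministic)."""
    best: dict[str, AlignmentSummary] = {}
    for h in hits:
        cur = best.get(h.qseqid)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (h.bitscore == cur.bitscore and h.sseqid < cur.sseqid)
        ):
            best[h.qseqid] = h
    return best


def tier_table(
    hits: Iterable[AlignmentSummary],
    thresholds: TierThresholds = TierThresholds(),
    transcript_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Classify every transcript by its best hit.

    ``transcript_ids``, when given, enumerates the full transcript set so
    hitless transcripts are counted as untiered. Returns a label Series
    indexed by transcript id plus per-tier counts.
    """
    chosen = best_hits(hits)
    labels: dict[str, str] = {q: classify_tier(h, thresholds) for q, h in chosen.items()}
    if transcript_ids is not None:
        labels = {tid: labels.get(tid, "untiered") for tid in transcript_ids}
    series = pd.Series(labels, dtype="object", name="tier")
    counts = {lab: int((series == lab).sum()) for lab in TIER_LABELS}
    return series, counts


def read_hits_tsv(path) -> list[AlignmentSummary]:
    """Read an alignment-summary TSV (columns of :data:`HIT_COLUMNS`).

    Malformed rows raise with the 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hits table missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                AlignmentSummary(
                    qseqid=str(row.qseqid),
                    qlen=int(row.qlen),
                    sseqid=str(row.sseqid),
                    slen=int(row.slen),
                    length=int(row.length),
                    positive=int(row.positive),
                    bitscore=float(row.bitscore),
                    n_hsps=int(row.n_hsps),
                ).validate()
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"hits table line {i}: {exc}") from exc
    return out


def hits_to_frame(hits: Sequence[AlignmentSummary]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)
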