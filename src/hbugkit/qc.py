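"""Post-assembly transcript cleanup.

De novo assemblers leave residual artifacts on putative unique transcripts
(PUTs): poly-A/T tails from oligo-dT priming, very short fragments, and
cloning-vector carry-over. This module implements the three cleanup stages
applied to such an assembly, in order:

1. :func:`clip_polyat` — remove a terminal homopolymer tail (poly-A at the
   3' end, poly-T at the 5' end) of at least ``min_tail_run`` bases;
2. :func:`filter_length` — keep transcripts of at least ``min_length`` nt
   (200 bp by default), applied after clipping;
3. :func:`purge_contaminated` — drop every transcript with a vector-screen
   match categorized Strong or Moderate; Weak and None matches never cause
   removal.

Vector matches are categorized with the NCBI VecScreen score ladder: a match
is *terminal* when it starts within ``terminal_window`` nt of the 5' end or
ends within ``terminal_window`` nt of the 3' end, and the Strong/Moderate/
Weak thresholds differ between terminal and internal matches. The ladder is
configurable; the defaults are VecScreen's published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "TranscriptRecord",
    "VectorMatch",
    "QcConfig",
    "QcError",
    "clip_polyat",
    "filter_length",
    "categorize_vector_match",
    "annotate_matches",
    "purge_contaminated",
    "run_qc",
]

_ALPHABET = frozenset("ACGTN")


class QcError(ValueError):
    """Invalid QC configuration or inconsistent inputs."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript: unique identifier plus nucleotide sequence.

    Sequences are over {A, C, G, T, N}. Freshly ingested records must be
    non-empty; tail clipping may legitimately empty a record that consists
    of a single homopolymer run (the length filter removes it downstream).
    """

    id: str
    seq: str

    def validate(self) -> "TranscriptRecord":
        if not self.id:
            raise QcError("transcript id must be nonempty")
        if len(self.seq) < 1:
            raise QcError(f"transcript {self.id!r}: sequence must be nonempty")
        bad = set(self.seq.upper()) - _ALPHABET
        if bad:
            raise QcError(f"transcript {self.id!r}: invalid characters {sorted(bad)}")
        return self

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class VectorMatch:
    """A vector-screen hit on a transcript.

    ``start``/``end`` are a 0-based half-open interval on the transcript;
    ``category`` is one of Strong/Moderate/Weak/None per the score ladder.
    """

    transcript_id: str
    score: int
    start: int
    end: int
    category: str = "None"


@dataclass(frozen=True)
class QcConfig:
    """Cleanup thresholds.

    min_tail_run: minimum homopolymer run length clipped from an end (nt).
    min_length: minimum post-clipping transcript length retained (nt).
    terminal_window: distance from a sequence end within which a vector
        match counts as terminal (nt).
    *_terminal / *_internal: VecScreen score ladder; within each position
        class Strong > Moderate > Weak is enforced.
    """

    min_tail_run: int = 5
    min_length: int = 200
    terminal_window: int = 25
    strong_terminal: int = 24
    moderate_terminal: int = 19
    weak_terminal: int = 16
    strong_internal: int = 30
    moderate_internal: int = 25
    weak_internal: int = 23

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise QcError("min_length: must be >= 1")
        if self.min_tail_run < 1:
            raise QcError("min_tail_run: must be >= 1")
        if self.terminal_window < 0:
            raise QcError("terminal_window: must be >= 0")
        if not (self.strong_terminal > self.moderate_terminal > self.weak_terminal):
            raise QcError("terminal thresholds must satisfy strong > moderate > weak")
        if not (self.strong_internal > self.moderate_internal > self.weak_internal):
            raise QcError("internal thresholds must satisfy strong > moderate > weak")


def _leading_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def clip_polyat(rec: TranscriptRecord, cfg: QcConfig = QcConfig()) -> TranscriptRecord:
    """Clip a 5' poly-T and/or 3' poly-A tail of >= ``min_tail_run`` nt.

    Exact homopolymer runs only (N never counts toward a run), applied once
    per end; interior bases are untouched. Idempotent: after removing the
    maximal run the new terminal base is by construction not part of a
    qualifying run.
    """
    seq = rec.seq
    lead = _leading_run(seq, "T")
    if lead >= cfg.min_tail_run:
        seq = seq[lead:]
    trail = _leading_run(seq[::-1], "A")
    if trail >= cfg.min_tail_run:
        seq = seq[: len(seq) - trail]
    if seq == rec.seq:
        return rec
    return replace(rec, seq=seq)


def filter_length(
    records: Iterable[TranscriptRecord], min_length: int = 200
) -> list[TranscriptRecord]:
    """Keep transcripts with length >= ``min_length`` nt, preserving order."""
    if min_length < 1:
        raise QcError("min_length: must be >= 1")
    return [r for r in records if len(r) >= min_length]


def categorize_vector_match(
    score: int, start: int, end: int, seq_len: int, cfg: QcConfig = QcConfig()
) -> str:
    """Categorize one vector match as Strong/Moderate/Weak/None.

    A match is terminal when it starts within ``terminal_window`` nt of the
    5' end or ends within ``terminal_window`` nt of the 3' end; the terminal
    ladder is then applied, otherwise the internal one.
    """
    if not (0 <= start < end <= seq_len):
        raise QcError(
            f"match interval [{start}, {end}) outside sequence of length {seq_len}"
        )
    terminal = start < cfg.terminal_window or (seq_len - end) < cfg.terminal_window
    if terminal:
        strong, moderate, weak = cfg.strong_terminal, cfg.moderate_terminal, cfg.weak_terminal
    else:
        strong, moderate, weak = cfg.strong_internal, cfg.moderate_internal, cfg.weak_internal
    if score >= strong:
        return "Strong"
    if score >= moderate:
        return "Moderate"
    if score >= weak:
        return "Weak"
    return "None"


def annotate_matches(
    records: Sequence[TranscriptRecord],
    matches: Iterable[VectorMatch],
    cfg: QcConfig = QcConfig(),
) -> list[VectorMatch]:
    """Attach a score-ladder category to each raw vector match.

    Raises on a match referencing an unknown transcript id.
    """
    lengths = {r.id: len(r) for r in records}
    out = []
    for m in matches:
        if m.transcript_id not in lengths:
            raise QcError(f"vector match references unknown transcript {m.transcript_id!r}")
        cat = categorize_vector_match(m.score, m.start, m.end, lengths[m.transcript_id], cfg)
        out.append(replace(m, category=cat))
    return out


def purge_contaminated(
    records: Sequence[TranscriptRecord], matches: Iterable[VectorMatch]
) -> list[TranscriptRecord]:
    """Drop every transcript carrying >= 1 Strong or Moderate vector match."""
    known = {r.id for r in records}
    contaminated = set()
    for m in matches:
        if m.transcript_id not in known:
            raise QcError(f"vector match references unknown transcript {m.transcript_id!r}")
        if m.category in ("Strong", "Moderate"):
            contaminated.add(m.transcript_id)
    return [r for r in records if r.id not in contaminated]


@dataclass
class QcReport:
    """Record counts entering/leaving each cleanup stage."""

    n_input: int = 0
    n_clipped: int = 0
    n_after_length: int = 0
    n_purged: int = 0
    n_output: int = 0
    rows: list = field(default_factory=list)


def run_qc(
    records: Sequence[TranscriptRecord],
    matches: Iterable[VectorMatch] = (),
    cfg: QcConfig = QcConfig(),
) -> tuple[list[TranscriptRecord], QcReport]:
    """Full cleanup: clip tails, filter on length, purge vector hits.

    Vector matches are re-categorized against the *clipped* sequence lengths;
    matches on transcripts that the length filter already removed are ignored.
    """
    report = QcReport(n_input=len(records))
    clipped = [clip_polyat(r, cfg) for r in records]
    report.n_clipped = sum(1 for a, b in zip(records, clipped) if a.seq != b.seq)
    kept = filter_length(clipped, cfg.min_length)
    report.n_after_length = len(kept)
    kept_ids = {r.id for r in kept}
    relevant = [m for m in matches if m.transcript_id in kept_ids]
    annotated = annotate_matches(kept, relevant, cfg)
    out = purge_contaminated(kept, annotated)
    report.n_purged = len(kept) - len(out)
    report.n_output = len(out)
    return out, report
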