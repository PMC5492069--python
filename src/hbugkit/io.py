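"""File-format plumbing: FASTA via Biopython, tables as headered TSV, and a
minimal OBO writer for the toy ontology. All outputs are plain text."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .goslim import OntologyGraph
from .qc import QcError, TranscriptRecord, VectorMatch
from .tiering import AlignmentSummary, HIT_COLUMNS, hits_to_frame


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts, enforcing unique non-empty ids and valid alphabet."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise QcError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq).upper()).validate())
    return records


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_vector_matches(path) -> list[VectorMatch]:
    """Vector matches as TSV with columns transcript_id, score, start, end."""
    df = pd.read_csv(path, sep="\t")
    return [
        VectorMatch(
            transcript_id=str(r.transcript_id),
            score=int(r.score),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def write_vector_matches(matches: Sequence[VectorMatch], path) -> None:
    pd.DataFrame(
        [(m.transcript_id, m.score, m.start, m.end) for m in matches],
        columns=["transcript_id", "score", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def write_hits(hits: Sequence[AlignmentSummary], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV (transcript, length, 2nd, 4th, female, male) ->
    (counts indexed by transcript, effective lengths)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str}).set_index("transcript")
    lengths = df.pop("length").astype(float)
    return df, lengths


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths)
    out.index.name = "transcript"
    out.to_csv(path, sep="\t")


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize the ontology as a minimal OBO subset (id/name/namespace/is_a)."""
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(graph.aspect):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        lines.append(f"namespace: {graph.aspect[term]}")
        for _, parent in sorted(graph.graph.out_edges(term)):
            lines.append(f"is_a: {parent} ! synthetic term {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_pfam2go(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_pfam2go(pfam2go: pd.DataFrame, path) -> None:
    pfam2go.to_csv(path, sep="\t", index=False)
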