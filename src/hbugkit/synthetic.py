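"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this pipeline are a de novo Trinity assembly, BLAST tabular
summaries against NR, Pfam domain tables, the Gene Ontology, and RSEM count
estimates — none of which can be regenerated at desk scale. This module
fabricates small but structurally faithful stand-ins with a truth table, so
each downstream stage can be tested as a round trip:

* transcripts with optional 3' poly-A / 5' poly-T tails and planted decoy
  vector segments (the decoys are a bundled synthetic set, not UniVec);
* alignment-summary tables engineered so each transcript satisfies exactly
  its planted tier's rule and fails all stricter tiers;
* four-sample count matrices (2nd, 4th, female, male) drawn Poisson around
  planted TPM targets, including planted fold changes and exact-zero rows
  exercising the undefined/±inf contrast sentinels;
* a three-aspect toy ontology of rooted is_a DAGs plus a pfam2go-style map.

Everything is driven by one integer seed through ``numpy``'s Generator;
identical configurations produce byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .goslim import OntologyGraph
from .qc import VectorMatch
from .tiering import AlignmentSummary

__all__ = [
    "SimConfig",
    "TranscriptTruth",
    "SimConfigError",
    "gen_transcripts",
    "gen_alignment_table",
    "gen_counts",
    "gen_ontology",
    "vector_matches_from_truth",
]

#: Synthetic vector decoys planted into contaminated transcripts. These are
#: arbitrary fixed strings standing in for cloning-vector sequence; they are
#: not drawn from UniVec.
VECTOR_DECOYS = (
    "GCTAGCCAGCTTGGGTCTCCCTATAGTGAGTCGTATTAATTTCGATAAGCCAG",
    "CTGGCGTAATAGCGAAGAGGCCCGCACCGATCGCCCTTCCCAACAGTTGCGCA",
    "AGCGCCCAATACGCAAACCGCCTCTCCCCGCGCGTTGGCCGATTCATTAATGC",
)

_TIERS = ("gold", "silver", "bronze", "untiered")


class SimConfigError(ValueError):
    """A SimConfig field is out of range or internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for fixture generation.

    Defaults emulate the survey's setting: four samples (2nd and 4th instar
    nymphs, adult female, adult male), transcripts long enough to clear the
    200 bp filter, a tier mix over gold/silver/bronze/untiered, and a mean
    sequencing depth of 500 counts per transcript (the depth at which the
    fold-change recovery tolerance of ±0.5 log2 units is stated).

    ``de_spec`` plants fold changes: (transcript index, fold, contrast)
    with contrast one of '4th:2nd', 'female:male', 'adults:nymphs'.
    ``zero_expr_frac`` of transcripts get exact zeros in designated samples
    to exercise contrast sentinels.
    """

    seed: int = 0
    n_transcripts: int = 100
    length_range: tuple[int, int] = (250, 1500)
    polyA_prob: float = 0.3
    vector_prob: float = 0.1
    tier_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_samples: int = 4
    de_spec: tuple[tuple[int, float, str], ...] = ()
    zero_expr_frac: float = 0.0
    mean_depth: float = 500.0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise SimConfigError("n_transcripts: must be >= 0")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise SimConfigError("length_range: need 1 <= min <= max")
        for name in ("polyA_prob", "vector_prob", "zero_expr_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name}: must be in [0, 1]")
        if len(self.tier_mix) != 4 or any(p < 0 for p in self.tier_mix):
            raise SimConfigError("tier_mix: four nonnegative proportions required")
        if abs(sum(self.tier_mix) - 1.0) > 1e-9:
            raise SimConfigError("tier_mix: proportions must sum to 1")
        if self.n_samples != 4:
            raise SimConfigError("n_samples: fixed four-sample design (2nd, 4th, female, male)")
        if self.mean_depth <= 0:
            raise SimConfigError("mean_depth: must be > 0")
        for idx, fold, contrast in self.de_spec:
            if not 0 <= idx < self.n_transcripts:
                raise SimConfigError(f"de_spec: transcript index {idx} out of range")
            if fold <= 0:
                raise SimConfigError("de_spec: fold must be > 0")
            if contrast not in ("4th:2nd", "2nd:4th", "female:male", "adults:nymphs"):
                raise SimConfigError(f"de_spec: unknown contrast {contrast!r}")


@dataclass
class TranscriptTruth:
    """Ground truth for one generated transcript."""

    transcript_id: str
    core_length: int
    tier: str
    family_member: bool = False
    go_terms: tuple[str, ...] = ()
    fold_changes: dict = field(default_factory=dict)
    tail_length: int = 0
    tail_end: str = ""  # '5p' (poly-T) or '3p' (poly-A), '' if none
    vector_interval: Optional[tuple[int, int]] = None  # on the clipped sequence
    vector_score: int = 0
    zero_samples: tuple[str, ...] = ()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _no_terminal_runs(seq: str) -> str:
    # Guarantee planted cores carry no accidental clippable tails so the
    # recorded tail length is exactly what the clipper removes.
    s = list(seq)
    if s and s[0] == "T":
        s[0] = "C"
    if s and s[-1] == "A":
        s[-1] = "G"
    return "".join(s)


def gen_transcripts(config: SimConfig):
    """Generate transcripts plus their truth table.

    Returns ``(records, truth)`` where ``records`` is a list of
    ``(transcript_id, sequence)`` pairs (FASTA-ready, unique ids) and
    ``truth`` maps transcript id -> :class:`TranscriptTruth`. Tier labels
    are drawn from ``tier_mix``; cores destined for gold are at least
    300 nt and all others at least 100 nt so the planted tier is attainable.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, TranscriptTruth] = {}
    tiers = rng.choice(_TIERS, size=config.n_transcripts, p=list(config.tier_mix))
    lo, hi = config.length_range
    for i in range(config.n_transcripts):
        tid = f"PUT{i:05d}"
        tier = str(tiers[i])
        floor = 300 if tier == "gold" else 100
        length = int(rng.integers(lo, hi + 1))
        length = max(length, floor)
        core = _no_terminal_runs(_random_seq(rng, length))
        row = TranscriptTruth(transcript_id=tid, core_length=len(core), tier=tier)

        if rng.random() < config.vector_prob:
            decoy = VECTOR_DECOYS[int(rng.integers(0, len(VECTOR_DECOYS)))]
            pos = int(rng.integers(0, len(core) - len(decoy) + 1)) if len(core) > len(decoy) else 0
            core = core[:pos] + decoy + core[pos + len(decoy):]
            core = _no_terminal_runs(core)
            row.vector_interval = (pos, pos + len(decoy))
            # scores straddle the Strong/Moderate bands of the default ladder
            row.vector_score = int(rng.integers(25, 41))
        row.core_length = len(core)

        seq = core
        if rng.random() < config.polyA_prob:
            tail_len = int(rng.integers(5, 16))
            if rng.random() < 0.5:
                seq = core + "A" * tail_len
                row.tail_end = "3p"
            else:
                seq = "T" * tail_len + core
                row.tail_end = "5p"
            row.tail_length = tail_len

        records.append((tid, seq))
        truth[tid] = row
    return records, truth


def vector_matches_from_truth(truth: dict[str, TranscriptTruth]) -> list[VectorMatch]:
    """Vector-screen records for every planted decoy segment.

    Coordinates refer to the clipped (core) sequence, matching a screen run
    after tail clipping as in the real pipeline order.
    """
    out = []
    for tid in sorted(truth):
        row = truth[tid]
        if row.vector_interval is not None:
            start, end = row.vector_interval
            out.append(VectorMatch(transcript_id=tid, score=row.vector_score,
                                   start=start, end=end))
    return out


def gen_alignment_table(
    truth: dict[str, TranscriptTruth], config: SimConfig
) -> list[AlignmentSummary]:
    """Engineer one alignment summary per tiered transcript.

    Each transcript planted gold/silver/bronze receives a hit satisfying
    exactly that tier's rule and failing all stricter tiers; untiered
    transcripts receive either no row or a hit failing every tier. Query
    lengths are the truth's core (post-clip) lengths.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows: list[AlignmentSummary] = []
    for tid in sorted(truth):
        row = truth[tid]
        qlen = row.core_length
        bits = float(np.round(rng.uniform(80, 400), 1))
        subject = f"ref|{tid}hit"
        if row.tier == "gold":
            # single HSP, coverage >= .90, positives >= .75
            slen = int(rng.integers(100, 301))
            length = max(int(np.ceil(0.95 * slen)), int(np.ceil(0.90 * slen)))
            positive = int(np.ceil(0.85 * length))
            rows.append(AlignmentSummary(tid, qlen, subject, slen, length, positive, bits, 1))
        elif row.tier == "silver":
            # coverage in [.75, .90) with a second HSP, so gold is excluded
            slen = int(rng.integers(100, 301))
            length = int(np.floor(0.80 * slen))
            positive = int(np.ceil(0.85 * length))
            rows.append(AlignmentSummary(tid, qlen, subject, slen, length, positive, bits, 2))
        elif row.tier == "bronze":
            # coverage in [.30, .75)
            slen = int(rng.integers(100, 301))
            length = int(np.floor(0.50 * slen))
            positive = int(np.ceil(0.85 * length))
            rows.append(AlignmentSummary(tid, qlen, subject, slen, length, positive, bits, 1))
        else:
            if rng.random() < 0.5:
                continue  # no hit at all
            slen = int(rng.integers(200, 301))
            length = max(1, int(np.floor(0.20 * slen)))  # coverage < .30
            positive = int(np.ceil(0.85 * length))
            rows.append(AlignmentSummary(tid, qlen, subject, slen, length, positive, bits, 1))
    return rows


def _target_tpm_matrix(truth: dict[str, TranscriptTruth], config: SimConfig) -> pd.DataFrame:
    from .expression import SAMPLES  # local import to avoid a cycle

    ids = sorted(truth)
    base = pd.DataFrame(1.0, index=ids, columns=list(SAMPLES))
    for idx, fold, contrast in config.de_spec:
        tid = f"PUT{idx:05d}"
        if contrast == "female:male":
            base.loc[tid, "female"] *= fold
        elif contrast == "4th:2nd":
            base.loc[tid, "4th"] *= fold
        elif contrast == "2nd:4th":
            base.loc[tid, "2nd"] *= fold
        else:  # adults:nymphs
            base.loc[tid, ["female", "male"]] *= fold
        truth[tid].fold_changes[contrast] = float(np.log2(fold))
    # normalize each sample to TPM scale
    return base.div(base.sum(axis=0), axis=1) * 1e6


def gen_counts(
    truth: dict[str, TranscriptTruth], config: SimConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson counts for the four samples around planted TPM targets.

    Returns ``(counts, effective_lengths)`` indexed by transcript id. The
    Poisson mean for transcript i in sample s is proportional to
    ``target_tpm[i, s] * length_i``, scaled so the per-transcript mean count
    is ``mean_depth``. A ``zero_expr_frac`` subset is zeroed in designated
    samples (alternating female-only and female+male) to exercise the ±inf
    and undefined sentinels. No dispersion model: the study has no
    replication, so none is implied.
    """
    from .expression import SAMPLES

    rng = np.random.default_rng(config.seed + 2)
    ids = sorted(truth)
    if not ids:
        return (pd.DataFrame(columns=list(SAMPLES), dtype=int),
                pd.Series(dtype=float, name="length"))
    lengths = pd.Series({t: float(truth[t].core_length) for t in ids}, name="length")
    target = _target_tpm_matrix(truth, config)
    rel = target.mul(lengths, axis=0)
    # scale each sample so the average count per transcript is mean_depth
    scale = config.mean_depth * len(ids) / rel.sum(axis=0)
    mean = rel.mul(scale, axis=1)

    n_zero = int(round(config.zero_expr_frac * len(ids)))
    zero_ids = [str(x) for x in rng.choice(ids, size=n_zero, replace=False)] if n_zero else []
    for k, tid in enumerate(zero_ids):
        samples = ("female",) if k % 2 == 0 else ("female", "male")
        truth[tid].zero_samples = samples
        mean.loc[tid, list(samples)] = 0.0

    # Poisson with mean 0 is identically 0, so the planted zeros are exact.
    counts = pd.DataFrame(
        rng.poisson(mean.to_numpy()), index=ids, columns=list(SAMPLES)
    )
    return counts, lengths


def gen_ontology(n_per_aspect: int = 20, depth: int = 3, seed: int = 0):
    """A toy three-aspect ontology plus a pfam2go-style map.

    Builds one rooted is_a DAG per aspect with ``depth`` layers under the
    root; every non-root term has at least one parent in the previous layer
    and, with probability 0.3, a second parent (diamonds). Returns
    ``(OntologyGraph, pfam2go DataFrame)``; the map associates synthetic
    Pfam accessions with zero or more terms.
    """
    if n_per_aspect < 1 or depth < 1:
        raise SimConfigError("n_per_aspect and depth must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    aspect: dict[str, str] = {}
    roots: dict[str, str] = {}
    counter = 0
    all_terms: list[str] = []
    from .goslim import ASPECTS

    for asp in ASPECTS:
        counter += 1
        root = f"GO:{counter:07d}"
        g.add_node(root)
        aspect[root] = asp
        roots[asp] = root
        layers: list[list[str]] = [[root]]
        remaining = n_per_aspect
        for d in range(1, depth + 1):
            width = max(1, remaining // (depth - d + 1))
            if d == depth:
                width = remaining
            layer = []
            for _ in range(width):
                counter += 1
                term = f"GO:{counter:07d}"
                g.add_node(term)
                aspect[term] = asp
                parent = layers[-1][int(rng.integers(0, len(layers[-1])))]
                g.add_edge(term, parent)
                if d > 1 and rng.random() < 0.3:
                    upper = layers[int(rng.integers(1, d))]
                    extra = upper[int(rng.integers(0, len(upper)))]
                    if extra != term:
                        g.add_edge(term, extra)
                layer.append(term)
                all_terms.append(term)
            layers.append(layer)
            remaining -= width
            if remaining <= 0:
                break
    graph = OntologyGraph(graph=g, aspect=aspect, roots=roots)

    rows = []
    n_pfams = max(3, n_per_aspect // 2)
    for p in range(1, n_pfams + 1):
        acc = f"PF{p:05d}"
        k = int(rng.integers(0, 4))  # zero, one or more terms
        if k:
            terms = rng.choice(all_terms, size=min(k, len(all_terms)), replace=False)
            for t in sorted(str(x) for x in terms):
                rows.append((acc, t))
    pfam2go = pd.DataFrame(rows, columns=["pfam", "go_term"])
    return graph, pfam2go
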