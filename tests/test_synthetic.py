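"""Fixture generator: determinism, planted ground truth, recovery."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hbugkit.expression import compute_tpm, log2fc, pool_groups
from hbugkit.qc import QcConfig, TranscriptRecord, clip_polyat
from hbugkit.synthetic import (
    SimConfig,
    SimConfigError,
    gen_alignment_table,
    gen_counts,
    gen_ontology,
    gen_transcripts,
    vector_matches_from_truth,
)


def test_empty_config_yields_empty_fixtures():
    cfg = SimConfig(seed=1, n_transcripts=0)
    records, truth = gen_transcripts(cfg)
    assert records == [] and truth == {}
    counts, lengths = gen_counts(truth, cfg)
    assert counts.empty and lengths.empty


def test_probability_one_tails_all_recorded():
    cfg = SimConfig(seed=1, n_transcripts=50, polyA_prob=1.0)
    _, truth = gen_transcripts(cfg)
    assert all(t.tail_length >= 5 for t in truth.values())
    assert all(t.tail_end in ("5p", "3p") for t in truth.values())


def test_same_seed_is_byte_identical():
    cfg = SimConfig(seed=7, n_transcripts=60, polyA_prob=0.4, vector_prob=0.2,
                    zero_expr_frac=0.1, de_spec=((0, 4.0, "female:male"),))
    a_records, a_truth = gen_transcripts(cfg)
    b_records, b_truth = gen_transcripts(cfg)
    assert a_records == b_records
    assert {k: vars(v) for k, v in a_truth.items()} == {k: vars(v) for k, v in b_truth.items()}
    assert gen_counts(a_truth, cfg)[0].equals(gen_counts(b_truth, cfg)[0])
    ga, _ = gen_ontology(seed=5)
    gb, _ = gen_ontology(seed=5)
    assert set(ga.graph.edges) == set(gb.graph.edges)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(n_transcripts=-1), "n_transcripts"),
        (dict(length_range=(0, 10)), "length_range"),
        (dict(polyA_prob=1.5), "polyA_prob"),
        (dict(tier_mix=(0.5, 0.5, 0.5, 0.5)), "tier_mix"),
        (dict(n_samples=3), "n_samples"),
        (dict(de_spec=((999, 2.0, "female:male"),)), "de_spec"),
        (dict(de_spec=((0, 2.0, "left:right"),), n_transcripts=5), "de_spec"),
    ],
)
def test_invalid_config_names_the_field(kwargs, field):
    with pytest.raises(SimConfigError, match=field):
        SimConfig(seed=0, **{**dict(n_transcripts=10), **kwargs})


def test_clipping_recovers_planted_cores():
    cfg = SimConfig(seed=3, n_transcripts=80, polyA_prob=1.0)
    records, truth = gen_transcripts(cfg)
    for tid, seq in records:
        clipped = clip_polyat(TranscriptRecord(tid, seq), QcConfig())
        assert len(clipped.seq) == truth[tid].core_length
        assert len(seq) - len(clipped.seq) == truth[tid].tail_length


def test_fasta_grammar_unique_ids(tmp_path):
    from hbugkit.io import read_fasta, write_fasta

    cfg = SimConfig(seed=4, n_transcripts=30)
    records, _ = gen_transcripts(cfg)
    path = tmp_path / "t.fasta"
    write_fasta([TranscriptRecord(i, s) for i, s in records], path)
    reread = read_fasta(path)
    assert [(r.id, r.seq) for r in reread] == records
    assert len({r.id for r in reread}) == len(reread)


def test_alignment_table_round_trip_recovers_all_tiers(fixture_set):
    from hbugkit.tiering import classify_tier, tier_table

    truth = fixture_set["truth"]
    labels, counts = tier_table(fixture_set["hits"], transcript_ids=sorted(truth))
    assert all(labels[t] == truth[t].tier for t in truth)
    assert sum(counts.values()) == len(truth)


def test_vector_matches_reference_planted_intervals(fixture_set):
    truth = fixture_set["truth"]
    for m in fixture_set["matches"]:
        row = truth[m.transcript_id]
        assert row.vector_interval == (m.start, m.end)
        assert 0 <= m.start < m.end <= row.core_length


def test_planted_fold_change_recovered():
    cfg = SimConfig(seed=21, n_transcripts=100, mean_depth=500.0,
                    de_spec=((0, 4.0, "female:male"), (1, 4.0, "adults:nymphs")))
    _, truth = gen_transcripts(cfg)
    counts, lengths = gen_counts(truth, cfg)
    tpm = compute_tpm(counts, lengths)
    est = log2fc(tpm.loc["PUT00000", "female"], tpm.loc["PUT00000", "male"])
    assert abs(est - 2.0) <= 0.5
    pooled = pool_groups(counts, lengths)
    est2 = log2fc(pooled.loc["PUT00001", "adults"], pooled.loc["PUT00001", "nymphs"])
    assert abs(est2 - 2.0) <= 0.5


def test_no_zero_counts_without_planted_zeros():
    cfg = SimConfig(seed=2, n_transcripts=50, zero_expr_frac=0.0, mean_depth=100.0)
    _, truth = gen_transcripts(cfg)
    counts, _ = gen_counts(truth, cfg)
    assert (counts.to_numpy() > 0).all()


def test_planted_zero_rows_exercise_sentinels():
    cfg = SimConfig(seed=9, n_transcripts=40, zero_expr_frac=0.2)
    _, truth = gen_transcripts(cfg)
    counts, lengths = gen_counts(truth, cfg)
    tpm = compute_tpm(counts, lengths)
    zero_rows = [t for t in truth.values() if t.zero_samples]
    assert zero_rows
    for row in zero_rows:
        for s in row.zero_samples:
            assert counts.loc[row.transcript_id, s] == 0
        est = log2fc(tpm.loc[row.transcript_id, "female"],
                     tpm.loc[row.transcript_id, "male"])
        if row.zero_samples == ("female", "male"):
            assert math.isnan(est)
        else:
            assert est == -math.inf


def test_ontology_depth_one_and_acyclicity():
    graph, _ = gen_ontology(n_per_aspect=8, depth=1, seed=0)
    roots = set(graph.roots.values())
    for term in graph.aspect:
        if term not in roots:
            parents = {v for _, v in graph.graph.out_edges(term)}
            assert parents <= roots and parents
    assert nx.is_directed_acyclic_graph(graph.graph)


def test_every_term_reaches_a_root_by_enumeration():
    graph, _ = gen_ontology(n_per_aspect=15, depth=3, seed=6)  # <= 48 terms
    roots = set(graph.roots.values())
    for term in graph.aspect:
        if term in roots:
            continue
        root = graph.root_of(term)
        assert any(True for _ in nx.all_simple_paths(graph.graph, term, root))


def test_pfam_map_accessions_syntactically_valid():
    _, pfam2go = gen_ontology(n_per_aspect=12, depth=2, seed=1)
    assert pfam2go["pfam"].str.match(r"PF\d{5}$").all()
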