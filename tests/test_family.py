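"""Gene-family membership calling, ORF extraction and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from hbugkit.family import (
    FamilyThresholds,
    call_family,
    cluster_by_best_hit,
    dedup_proteins,
    longest_orf,
    summarize_loci,
)
from hbugkit.tiering import AlignmentSummary

T = FamilyThresholds()


def _summary(bit=75.0, slen=100, qlen=120, length=95, positive=80, qid="q"):
    return AlignmentSummary(qseqid=qid, qlen=qlen, sseqid="s", slen=slen,
                            length=length, positive=positive, bitscore=bit)


def test_all_boundary_pass_is_member():
    # 95/100 = 0.95, 95/120 = 0.792, 80/95 = 0.842 — all five criteria pass
    call = call_family(_summary(), T, "GST")
    assert call.member and call.failed == ()


@pytest.mark.parametrize(
    "kwargs, failed",
    [
        (dict(bit=74.9), "min_bitscore"),
        (dict(slen=99, length=95), "min_subject_aa"),
        (dict(length=89, positive=75), "min_hit_subject_ratio"),
        (dict(qlen=130), "min_hit_query_ratio"),
        (dict(positive=75), "min_positive_frac"),
    ],
)
def test_single_criterion_failures_are_named(kwargs, failed):
    call = call_family(_summary(**kwargs), T, "COE")
    assert not call.member
    assert failed in call.failed


def test_member_set_equals_brute_force_five_way_and():
    rng = np.random.default_rng(12)
    for i in range(10_000):
        qlen = int(rng.integers(50, 400))
        slen = int(rng.integers(50, 400))
        length = int(rng.integers(1, min(qlen, slen) + 1))
        positive = int(rng.integers(0, length + 1))
        bit = float(np.round(rng.uniform(40, 120), 1))
        a = AlignmentSummary(f"q{i}", qlen, "s", slen, length, positive, bit)
        expected = (
            bit >= 75.0
            and slen >= 100
            and length * 100 >= 90 * slen
            and length * 100 >= 75 * qlen
            and positive * 100 >= 80 * length
        )
        assert call_family(a, T).member == expected


def test_monotone_raising_any_threshold_never_adds_members():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(2000):
        qlen = int(rng.integers(80, 200))
        slen = int(rng.integers(80, 200))
        length = int(rng.integers(1, min(qlen, slen) + 1))
        positive = int(rng.integers(0, length + 1))
        rows.append(AlignmentSummary(f"q{i}", qlen, "s", slen, length, positive,
                                     float(rng.uniform(40, 120))))
    base_members = {a.qseqid for a in rows if call_family(a, T).member}
    stricter_variants = [
        FamilyThresholds(min_bitscore=90.0),
        FamilyThresholds(min_subject_aa=150),
        FamilyThresholds(min_hit_subject_ratio=0.95),
        FamilyThresholds(min_hit_query_ratio=0.85),
        FamilyThresholds(min_positive_frac=0.90),
    ]
    for strict in stricter_variants:
        members = {a.qseqid for a in rows if call_family(a, strict).member}
        assert members <= base_members


def test_call_family_rejects_zero_lengths():
    with pytest.raises(ValueError):
        call_family(AlignmentSummary("q", 0, "s", 100, 50, 40, 80.0), T)
    with pytest.raises(ValueError):
        call_family(AlignmentSummary("q", 100, "s", 0, 50, 40, 80.0), T)


@pytest.mark.parametrize(
    "nt, aa",
    [
        ("ATGGCC", "MA"),          # forward frame 0 wins the tie
        ("AAATAAAAA", "FLF"),      # reverse frame beats stop-split forward
        ("ATGAAATAA", "LFH"),      # reverse frame longer than 'MK'
        ("ACGTACGTACGT", "TYVR"),  # stop-free forward frame
    ],
)
def test_longest_orf_six_frames(nt, aa):
    assert longest_orf(nt) == aa


def test_longest_orf_require_start():
    assert longest_orf("ATGAAATAA", require_start=True) == "MK"
    assert longest_orf("ACGTACGTACGT", require_start=True) == ""


def test_dedup_proteins():
    unique, mapping = dedup_proteins({"t1": "MA", "t2": "MA", "t3": "MV"})
    assert unique == ["MA", "MV"]
    assert len(mapping) == 3
    # idempotent and order independent
    unique2, _ = dedup_proteins({"t3": "MV", "t1": "MA", "t2": "MA"})
    assert set(unique2) == set(unique)
    with pytest.raises(ValueError):
        dedup_proteins({"t1": ""})
    with pytest.raises(ValueError):
        dedup_proteins({})


def test_dedup_matches_brute_force_set_size():
    rng = np.random.default_rng(9)
    seqs = {f"t{i}": "".join(rng.choice(list("MAVL"), size=3)) for i in range(200)}
    unique, mapping = dedup_proteins(seqs)
    assert len(unique) == len(set(seqs.values()))
    assert len(mapping) == len(seqs)


def test_cluster_by_best_hit():
    rows = [("q1", "P1", 300), ("q2", "P1", 500), ("q3", "P1", 400)]
    groups = cluster_by_best_hit(rows)
    assert groups == {"P1": ["q2", "q3", "q1"]}  # descending query length
    assert cluster_by_best_hit([]) == {}
    with pytest.raises(ValueError, match="duplicate"):
        cluster_by_best_hit([("q1", "P1", 10), ("q1", "P2", 10)])


def test_cluster_partitions_queries():
    rng = np.random.default_rng(2)
    rows = [(f"q{i}", f"P{int(rng.integers(0, 10))}", int(rng.integers(100, 900)))
            for i in range(300)]
    groups = cluster_by_best_hit(rows)
    members = [q for g in groups.values() for q in g]
    assert sorted(members) == sorted(q for q, _, _ in rows)  # disjoint + covering
    # brute-force grouping agrees
    for s, g in groups.items():
        assert set(g) == {q for q, subj, _ in rows if subj == s}


def test_summarize_loci_worked_shape():
    # 31 aligned proteins over 19 distinct loci, plus unaligned noise rows
    rows = [(f"prot{i}", f"locus{i % 19}", True) for i in range(31)]
    rows += [(f"prot{100+i}", f"locusX{i}", False) for i in range(13)]
    df = pd.DataFrame(rows, columns=["protein_id", "locus_id", "aligned"])
    assert summarize_loci(df) == (31, 19)
    empty = pd.DataFrame(columns=["protein_id", "locus_id", "aligned"])
    assert summarize_loci(empty) == (0, 0)


def test_summarize_loci_matches_brute_force():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {
            "protein_id": [f"p{i}" for i in range(150)],
            "locus_id": [f"L{int(rng.integers(0, 40))}" for _ in range(150)],
            "aligned": rng.random(150) < 0.6,
        }
    )
    n_aligned, n_loci = summarize_loci(df)
    sub = df[df["aligned"]]
    assert n_aligned == len(sub)
    assert n_loci == len(set(sub["locus_id"]))
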