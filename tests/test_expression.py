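"""TPM normalization, pooled contrasts, log2 fold changes and sentinels."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbugkit.expression import (
    ContrastConfig,
    SexPatternConfig,
    classify_sex_pattern,
    compute_tpm,
    format_log2fc,
    log2fc,
    pool_groups,
    rank_contrast,
)
from hbugkit.published import FOLD_CHANGE_ROWS


def _frame(counts, lengths, columns=("s1",)):
    idx = [f"t{i}" for i in range(len(lengths))]
    cm = pd.DataFrame(counts, index=idx, columns=list(columns))
    return cm, pd.Series(lengths, index=idx, dtype=float)


def test_tpm_single_transcript_is_one_million():
    cm, ln = _frame([[7]], [350])
    assert compute_tpm(cm, ln).iloc[0, 0] == pytest.approx(1e6)


def test_tpm_closed_form_two_transcripts():
    cm, ln = _frame([[10], [10]], [100, 200])
    tpm = compute_tpm(cm, ln)["s1"]
    assert tpm.tolist() == pytest.approx([666666.6667, 333333.3333], abs=1e-3)


def test_tpm_columns_sum_to_one_million_and_zero_column():
    rng = np.random.default_rng(8)
    cm = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                      columns=["2nd", "4th", "female", "male"])
    cm["male"] = 0  # all-zero sample
    lengths = pd.Series(rng.integers(200, 2000, size=50).astype(float), index=cm.index)
    tpm = compute_tpm(cm, lengths)
    for col in ("2nd", "4th", "female"):
        assert tpm[col].sum() == pytest.approx(1e6, abs=1e-3)
    assert (tpm["male"] == 0).all()


def test_tpm_rejects_negative_counts_and_bad_lengths():
    cm, ln = _frame([[-1]], [100])
    with pytest.raises(ValueError):
        compute_tpm(cm, ln)
    cm, ln = _frame([[1]], [0])
    with pytest.raises(ValueError):
        compute_tpm(cm, ln)


def test_pooling_identical_members_is_identity():
    cm, ln = _frame([[10, 10], [30, 30]], [100, 300], columns=["2nd", "4th"])
    pooled = pool_groups(cm, ln, {"nymphs": ("2nd", "4th")})
    member = compute_tpm(cm, ln)
    assert pooled["nymphs"].tolist() == pytest.approx(member["2nd"].tolist())


def test_pooling_symmetric_counts():
    cm, ln = _frame([[10, 0], [0, 10]], [500, 500], columns=["female", "male"])
    pooled = pool_groups(cm, ln, {"adults": ("female", "male")})
    assert pooled["adults"].tolist() == pytest.approx([5e5, 5e5])


def test_pooled_tpm_is_not_mean_of_member_tpms():
    """Pooling sums counts before renormalizing; with unequal depths this
    differs from averaging the member TPM columns."""
    cm, ln = _frame([[10, 1000], [0, 1000]], [400, 400], columns=["a", "b"])
    pooled = pool_groups(cm, ln, {"g": ("a", "b")})["g"]
    mean_tpm = compute_tpm(cm, ln).mean(axis=1)
    assert not np.allclose(pooled, mean_tpm)
    assert pooled.sum() == pytest.approx(1e6, abs=1e-3)


def test_pool_groups_rejects_unknown_sample():
    cm, ln = _frame([[1, 2]], [100], columns=["female", "male"])
    with pytest.raises(ValueError, match="unknown sample"):
        pool_groups(cm, ln, {"adults": ("female", "males!")})


def test_log2fc_published_value_and_sentinels():
    assert round(log2fc(253.24, 7.24), 4) == 5.1284
    assert math.isnan(log2fc(0.0, 0.0))
    assert log2fc(3.0, 0.0) == math.inf
    assert log2fc(0.0, 3.0) == -math.inf
    with pytest.raises(ValueError):
        log2fc(-1.0, 2.0)


def test_format_log2fc_sentinel_spellings():
    assert format_log2fc(math.nan) == "undefined"
    assert format_log2fc(math.inf) == "+inf"
    assert format_log2fc(-math.inf) == "-inf"
    assert format_log2fc(1.23456, dp=2) == "1.23"


@given(st.floats(0.01, 1e5), st.floats(0.01, 1e5))
@settings(max_examples=200, derandomize=True)
def test_log2fc_antisymmetry(a, b):
    assert log2fc(a, b) == pytest.approx(-log2fc(b, a), abs=1e-9)


def _table3_block(contrast):
    rows = [r for r in FOLD_CHANGE_ROWS if r[0] == contrast]
    num, den = contrast.split(":")
    df = pd.DataFrame(
        {num: [r[3] for r in rows], den: [r[4] for r in rows]},
        index=[f"r{i}" for i in range(len(rows))],
    )
    return rows, df


def test_rank_contrast_reproduces_strongest_published_fold_changes():
    rows, tpm = _table3_block("2nd:4th")
    ranked = rank_contrast(tpm, ContrastConfig(contrast="2nd:4th", top_k=5))
    up = ranked[ranked["direction"] == "up"]
    down = ranked[ranked["direction"] == "down"]
    assert round(up["log2fc"].iloc[0], 4) == 5.1284
    assert round(abs(down["log2fc"].iloc[0]), 4) == 5.3563
    assert len(up) == 5 and len(down) == 5


def test_rank_contrast_floor_empties_result():
    tpm = pd.DataFrame({"female": [4.9, 1.0], "male": [2.0, 4.0]}, index=["a", "b"])
    ranked = rank_contrast(tpm, ContrastConfig())
    assert ranked.empty


def test_rank_contrast_clamp_mode():
    tpm = pd.DataFrame({"female": [40.0], "male": [1.0]}, index=["a"])
    ranked = rank_contrast(tpm, ContrastConfig(floor_mode="clamp"))
    # male clamps from 1 to the 5.0 floor: log2(40/5) = 3
    assert ranked["log2fc"].iloc[0] == pytest.approx(3.0)


def test_rank_contrast_order_invariance_and_brute_force():
    rng = np.random.default_rng(3)
    tpm = pd.DataFrame(
        {"female": rng.uniform(0, 300, 60), "male": rng.uniform(0, 300, 60)},
        index=[f"t{i}" for i in range(60)],
    )
    cfg = ContrastConfig(top_k=5)
    ranked = rank_contrast(tpm, cfg)
    shuffled = tpm.sample(frac=1, random_state=1)
    assert rank_contrast(shuffled, cfg).equals(ranked)
    # brute-force: best up transcript has the largest eligible ratio
    eligible = tpm[(tpm.min(axis=1) >= 5.0)]
    ratios = np.log2(eligible["female"] / eligible["male"])
    up = ranked[ranked["direction"] == "up"]
    if len(up):
        assert up["log2fc"].iloc[0] == pytest.approx(ratios.max())
        expected = sorted([r for r in ratios if r >= 1.0], reverse=True)[: len(up)]
        assert list(up["log2fc"]) == pytest.approx(expected)


@pytest.mark.parametrize(
    "tpm_m, tpm_f, expected",
    [
        (0.03, 18.87, "female_specific"),       # published female-specific case
        (38.09, 6.24, "male_dominant_expressed"),  # both >= 5 TPM, 2.6-fold log2
        (4.9, 4.9, "none"),
        (6.35, 0.0, "male_dominant"),
        (15.33, 7.51, "male_dominant_expressed"),
    ],
)
def test_classify_sex_pattern(tpm_m, tpm_f, expected):
    assert classify_sex_pattern(tpm_m, tpm_f) == expected


def test_sex_pattern_published_magnitudes():
    assert round(abs(log2fc(0.03, 18.87)), 4) == 9.2969
    assert round(log2fc(38.09, 6.24), 4) == 2.6098
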