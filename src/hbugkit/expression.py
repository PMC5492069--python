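"""Replicate-free expression quantification and contrasts.

The survey design has one RNA-Seq library per condition (2nd instar, 4th
instar, adult female, adult male), so no statistical differential-expression
test is possible; instead, abundances are expressed in Transcripts per
Million (TPM) and conditions are compared by binary-log TPM ratios with a
floor and sentinel rules for zeros:

    TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6

with c the read count and l the effective length (here, transcript length —
the simplified estimator applies no fragment-length correction and no EM
multi-read resolution). Every sample column sums to one million.

The nymphal/adult contrast pools *counts* (2nd + 4th; female + male) and
recomputes TPM from the pooled counts, mirroring a pooled-read analysis;
pooled TPM is generally not the mean of member TPMs when depths differ.

log2 fold changes carry sentinel values: 0/0 is ``undefined``, a positive
numerator over zero is ``+inf``, zero over positive is ``-inf``. Ranked
contrast reports exclude sentinels under the default min-both TPM floor of
5.0 (every reported row then has both TPMs at or above the floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLES",
    "GROUPS",
    "CONTRASTS",
    "ContrastConfig",
    "compute_tpm",
    "pool_groups",
    "log2fc",
    "format_log2fc",
    "rank_contrast",
    "classify_sex_pattern",
]

#: The four sequenced mRNA populations.
SAMPLES = ("2nd", "4th", "female", "male")

#: Pooled read groups for the stage contrast.
GROUPS: dict[str, tuple[str, ...]] = {
    "nymphs": ("2nd", "4th"),
    "adults": ("female", "male"),
}

#: Named contrasts as numerator:denominator column pairs.
CONTRASTS: dict[str, tuple[str, str]] = {
    "4th:2nd": ("4th", "2nd"),
    "2nd:4th": ("2nd", "4th"),
    "female:male": ("female", "male"),
    "adults:nymphs": ("adults", "nymphs"),
}


@dataclass(frozen=True)
class ContrastConfig:
    """Floor/ranking parameters for a replicate-free contrast.

    floor_mode ``filter_min_both`` keeps transcripts whose smaller TPM is at
    least ``tpm_floor`` (the reading consistent with every published row
    having both TPMs >= 5); ``clamp`` instead replaces each TPM by
    ``max(tpm, tpm_floor)`` before forming ratios.
    """

    contrast: str = "female:male"
    tpm_floor: float = 5.0
    min_fold: float = 2.0
    floor_mode: str = "filter_min_both"
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.tpm_floor < 0:
            raise ValueError("tpm_floor must be >= 0")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.floor_mode not in ("filter_min_both", "clamp"):
            raise ValueError(f"unknown floor_mode {self.floor_mode!r}")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM per sample column from raw counts and effective lengths (nt).

    An all-zero sample yields an all-zero column. Negative counts or
    non-positive lengths are rejected.
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index).astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate.div(denom.where(denom > 0), axis=1) * 1e6
    return tpm.fillna(0.0)


def pool_groups(
    counts: pd.DataFrame,
    lengths: pd.Series,
    groups: Mapping[str, Sequence[str]] = GROUPS,
) -> pd.DataFrame:
    """Pool counts within sample groups and recompute TPM.

    ``groups`` maps group label -> member sample columns; unknown members
    are an error. Returns a TPM table with one column per group.
    """
    pooled = {}
    for label, members in groups.items():
        missing = [m for m in members if m not in counts.columns]
        if missing:
            raise ValueError(f"group {label!r}: unknown sample labels {missing}")
        pooled[label] = counts[list(members)].sum(axis=1)
    return compute_tpm(pd.DataFrame(pooled), lengths)


def log2fc(tpm_num: float, tpm_den: float) -> float:
    """Binary-log TPM ratio with sentinel semantics.

    Returns ``nan`` (undefined) for 0/0, ``+inf`` for positive/0, ``-inf``
    for 0/positive. Negative inputs are rejected.
    """
    if tpm_num < 0 or tpm_den < 0:
        raise ValueError("TPM values must be nonnegative")
    if tpm_num == 0 and tpm_den == 0:
        return math.nan
    if tpm_den == 0:
        return math.inf
    if tpm_num == 0:
        return -math.inf
    return math.log2(tpm_num / tpm_den)


def format_log2fc(value: float, dp: int = 4) -> str:
    """Fixed machine-readable spelling: 'undefined', '+inf', '-inf', or a
    fixed-precision decimal."""
    if math.isnan(value):
        return "undefined"
    if math.isinf(value):
        return "+inf" if value > 0 else "-inf"
    return f"{value:.{dp}f}"


def rank_contrast(
    tpm: pd.DataFrame, cfg: ContrastConfig = ContrastConfig()
) -> pd.DataFrame:
    """Top-k up- and down-regulated transcripts for one contrast.

    ``tpm`` must contain the contrast's two columns (samples or pooled
    groups), indexed by transcript id. After applying the floor mode,
    transcripts are ranked by |log2FC| descending (ties by transcript id)
    and the top ``top_k`` per direction are returned with columns
    ``tpm_num``, ``tpm_den``, ``log2fc``, ``direction``. Sentinel ratios are
    excluded from ranking under ``filter_min_both`` (they cannot pass the
    floor anyway when ``tpm_floor > 0``). Output is independent of input
    row order.
    """
    if cfg.top_k < 1:
        raise ValueError("top_k must be >= 1")
    num_col, den_col = CONTRASTS.get(cfg.contrast, tuple(cfg.contrast.split(":")))
    for col in (num_col, den_col):
        if col not in tpm.columns:
            raise ValueError(f"contrast column {col!r} missing from TPM table")
    a = tpm[num_col].astype(float)
    b = tpm[den_col].astype(float)
    if cfg.floor_mode == "filter_min_both":
        keep = np.minimum(a, b) >= cfg.tpm_floor
        a, b = a[keep], b[keep]
    else:
        a = a.clip(lower=cfg.tpm_floor)
        b = b.clip(lower=cfg.tpm_floor)
    lfc = pd.Series([log2fc(x, y) for x, y in zip(a, b)], index=a.index, dtype=float)
    finite = lfc[np.isfinite(lfc)]
    min_lfc = math.log2(cfg.min_fold)
    frames = []
    for direction, sel in (
        ("up", finite[finite >= min_lfc]),
        ("down", finite[finite <= -min_lfc]),
    ):
        block = pd.DataFrame(
            {
                "tpm_num": a[sel.index],
                "tpm_den": b[sel.index],
                "log2fc": sel,
                "direction": direction,
            }
        )
        block = block.assign(_mag=sel.abs(), _id=block.index.astype(str))
        block = block.sort_values(["_mag", "_id"], ascending=[False, True], kind="mergesort")
        frames.append(block.drop(columns=["_mag", "_id"]).head(cfg.top_k))
    return pd.concat(frames)


@dataclass(frozen=True)
class SexPatternConfig:
    """Thresholds for the sex-expression classifier.

    The *dominant-expressed* rule mirrors the published one (both sexes at
    or above 5 TPM and at least a two-fold differential); the *specific*
    thresholds (low sex below ``tau_lo``, high sex at or above ``tau_hi``)
    are configurable design choices, as the source analysis states none.
    """

    tpm_floor: float = 5.0
    min_fold: float = 2.0
    tau_lo: float = 0.5
    tau_hi: float = 3.0


def classify_sex_pattern(
    tpm_m: float, tpm_f: float, cfg: SexPatternConfig = SexPatternConfig()
) -> str:
    """Classify a transcript's sex-expression pattern.

    Categories: ``female_specific`` / ``male_dominant`` (one sex essentially
    silent, the other clearly expressed), ``female_dominant_expressed`` /
    ``male_dominant_expressed`` (both sexes >= floor with >= min_fold
    differential), else ``none``.
    """
    if tpm_m < 0 or tpm_f < 0:
        raise ValueError("TPM values must be nonnegative")
    if tpm_m < cfg.tau_lo and tpm_f >= cfg.tau_hi:
        return "female_specific"
    if tpm_f < cfg.tau_lo and tpm_m >= cfg.tau_hi:
        return "male_dominant"
    lfc = log2fc(tpm_m, tpm_f)
    if min(tpm_m, tpm_f) >= cfg.tpm_floor and abs(lfc) >= math.log2(cfg.min_fold):
        return "male_dominant_expressed" if lfc > 0 else "female_dominant_expressed"
    return "none"
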