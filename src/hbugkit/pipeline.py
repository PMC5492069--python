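"""End-to-end orchestration: QC -> tiering -> family -> GO-Slim -> contrasts.

A single YAML config names every input file and per-stage parameter block;
the run emits each stage's tables plus a JSON manifest recording all
parameters actually used (defaults included) and the seed, so a rerun with
the same config reproduces byte-identical outputs. Per-stage record counts
entering and leaving each filter are logged.

Also hosts the raw-volume accounting: per-sample read-pair/base totals with
a consistency check that bases equal pairs x 2 x read length for a uniform
paired-end read length (PE100 by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .expression import ContrastConfig, compute_tpm, format_log2fc, pool_groups, rank_contrast
from .family import FamilyThresholds, call_family
from .goslim import OntologyGraph, count_distinct_terms, map_pfam_to_go, slim_assignments
from .qc import QcConfig, run_qc
from .tiering import TierThresholds, best_hits, read_hits_tsv, tier_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_volumes", "VOLUME_COLUMNS"]

VOLUME_COLUMNS = ("read_pairs_raw", "bases_raw", "read_pairs_norm", "bases_norm")


@dataclass
class RunConfig:
    """Validated inputs and per-stage parameters for a full run."""

    fasta: Path
    hits: Path
    counts: Path
    outdir: Path
    vector_matches: Path | None = None
    family_hits: Path | None = None
    obo: Path | None = None
    pfam2go: Path | None = None
    pfam_assignments: Path | None = None
    seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    tiers: TierThresholds = field(default_factory=TierThresholds)
    family: FamilyThresholds = field(default_factory=FamilyThresholds)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)
    family_label: str = "GST"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("fasta", "hits", "counts", "outdir", "vector_matches",
                    "family_hits", "obo", "pfam2go", "pfam_assignments"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        for key, ctor in (("qc", QcConfig), ("tiers", TierThresholds),
                          ("family", FamilyThresholds), ("contrast", ContrastConfig)):
            if key in raw:
                kwargs[key] = ctor(**raw[key])
        for key in ("seed", "family_label"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate(self) -> "RunConfig":
        required = {"fasta": self.fasta, "hits": self.hits, "counts": self.counts}
        optional = {
            "vector_matches": self.vector_matches,
            "family_hits": self.family_hits,
            "obo": self.obo,
            "pfam2go": self.pfam2go,
            "pfam_assignments": self.pfam_assignments,
        }
        for name, p in required.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: input file {p} does not exist")
        for name, p in optional.items():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: input file {p} does not exist")
        return self


def _params_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return {f.name: enc(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write outputs plus a manifest.

    Halts on the first stage failure, naming the stage. Returns the
    manifest dict (also written to ``outdir/manifest.json``).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _params_dict(cfg), "seed": cfg.seed, "outputs": {}, "stages": {}}

    def stage(name):
        log.info("stage %s: starting", name)

        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- qc
    records = stage("qc")(lambda: hio.read_fasta(cfg.fasta))
    matches = hio.read_vector_matches(cfg.vector_matches) if cfg.vector_matches else []
    cleaned, report = stage("qc")(lambda: run_qc(records, matches, cfg.qc))
    qc_fa = outdir / "transcripts.clean.fasta"
    hio.write_fasta(cleaned, qc_fa)
    manifest["stages"]["qc"] = dataclasses.asdict(report)
    manifest["outputs"]["clean_fasta"] = qc_fa.name
    log.info("stage qc: %d in, %d out", report.n_input, report.n_output)

    # --- tiering
    hits = stage("tier")(lambda: read_hits_tsv(cfg.hits))
    ids = [r.id for r in cleaned]
    labels, counts_by_tier = stage("tier")(lambda: tier_table(hits, cfg.tiers, ids))
    tier_path = outdir / "tiers.tsv"
    labels.rename_axis("transcript").to_frame().to_csv(tier_path, sep="\t")
    (outdir / "tier_counts.json").write_text(json.dumps(counts_by_tier, indent=2))
    manifest["stages"]["tier"] = counts_by_tier
    manifest["outputs"]["tiers"] = tier_path.name
    manifest["outputs"]["tier_counts"] = "tier_counts.json"

    # --- family calling (optional)
    if cfg.family_hits is not None:
        fam_hits = stage("family")(lambda: read_hits_tsv(cfg.family_hits))
        calls = [
            call_family(h, cfg.family, cfg.family_label)
            for h in best_hits(fam_hits).values()
        ]
        fam_path = outdir / "family_calls.tsv"
        pd.DataFrame(
            [
                (c.transcript_id, c.family, c.member, f"{c.bitscore:.1f}",
                 f"{c.hit_subject_ratio:.4f}", f"{c.hit_query_ratio:.4f}",
                 f"{c.positive_frac:.4f}", ";".join(c.failed))
                for c in sorted(calls, key=lambda c: c.transcript_id)
            ],
            columns=["transcript_id", "family", "member", "bitscore",
                     "hit_subject_ratio", "hit_query_ratio", "positive_frac", "failed"],
        ).to_csv(fam_path, sep="\t", index=False)
        n_members = sum(c.member for c in calls)
        manifest["stages"]["family"] = {"n_calls": len(calls), "n_members": n_members}
        manifest["outputs"]["family_calls"] = fam_path.name
        log.info("stage family: %d members of %d candidates", n_members, len(calls))

    # --- GO-Slim (optional)
    if cfg.obo is not None and cfg.pfam2go is not None and cfg.pfam_assignments is not None:
        graph = stage("goslim")(lambda: OntologyGraph.from_obo(str(cfg.obo)))
        pfam2go = hio.read_pfam2go(cfg.pfam2go)
        assignments = pd.read_csv(cfg.pfam_assignments, sep="\t", dtype=str)
        pairs = stage("goslim")(lambda: map_pfam_to_go(assignments, pfam2go))
        slim = stage("goslim")(lambda: slim_assignments(pairs, graph))
        slim_path = outdir / "goslim.tsv"
        slim.to_csv(slim_path, sep="\t", index=False)
        aspect_counts = count_distinct_terms(pairs, graph)
        (outdir / "go_counts.json").write_text(json.dumps(aspect_counts, indent=2))
        manifest["stages"]["goslim"] = aspect_counts
        manifest["outputs"]["goslim"] = slim_path.name
        manifest["outputs"]["go_counts"] = "go_counts.json"

    # --- expression
    counts, lengths = stage("contrast")(lambda: hio.read_counts(cfg.counts))
    tpm = stage("contrast")(lambda: compute_tpm(counts, lengths))
    pooled = stage("contrast")(lambda: pool_groups(counts, lengths))
    tpm_all = pd.concat([tpm, pooled], axis=1)
    tpm_path = outdir / "tpm.tsv"
    tpm_all.rename_axis("transcript").to_csv(tpm_path, sep="\t", float_format="%.4f")
    ranked = stage("contrast")(lambda: rank_contrast(tpm_all, cfg.contrast))
    ranked_out = ranked.copy()
    ranked_out["log2fc"] = [format_log2fc(v) for v in ranked_out["log2fc"]]
    contrast_path = outdir / f"contrast_{cfg.contrast.contrast.replace(':', '_vs_')}.tsv"
    ranked_out.rename_axis("transcript").to_csv(contrast_path, sep="\t", float_format="%.4f")
    manifest["stages"]["contrast"] = {"n_ranked": len(ranked)}
    manifest["outputs"]["tpm"] = tpm_path.name
    manifest["outputs"]["contrast"] = contrast_path.name

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest


def summarize_volumes(
    volumes: pd.DataFrame, read_length: int = 100
) -> tuple[pd.Series, pd.DataFrame]:
    """Column totals for a sequencing-volume table, with a consistency flag.

    ``volumes`` is indexed by sample with columns of :data:`VOLUME_COLUMNS`
    (any subset). Returns ``(totals, flags)`` where ``flags`` marks rows
    whose bases differ from read_pairs x 2 x read_length.
    """
    if (volumes.to_numpy() < 0).any():
        raise ValueError("volume entries must be nonnegative")
    totals = volumes.sum(axis=0)
    flags = pd.DataFrame(index=volumes.index)
    for pairs_col, bases_col in (("read_pairs_raw", "bases_raw"),
                                 ("read_pairs_norm", "bases_norm")):
        if pairs_col in volumes.columns and bases_col in volumes.columns:
            expected = volumes[pairs_col] * 2 * read_length
            flags[bases_col + "_consistent"] = expected == volumes[bases_col]
    return totals, flags
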