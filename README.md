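# hbugkit

Desk-scale downstream analysis for de novo insect transcriptomes, built
around the harlequin bug (*Murgantia histrionica*) whole-transcriptome
survey design (four mRNA populations — 2nd instar, 4th instar, adult female,
adult male — one library each; assembly deposited under BioProject
PRJNA302154). The heavy upstream tools (Trinity, BLAST, HMMER, RSEM) are
consumed as tables; `hbugkit` implements the bespoke downstream logic that
otherwise lives in one-off scripts and spreadsheets, as a tested, reusable
library with a CLI.

Intended users: researchers annotating a new de novo transcriptome who want
the standard post-assembly triage — and the replicate-free expression
arithmetic that goes with single-library designs — reproducible and
parameterized rather than ad hoc.

## What it computes

* **Post-assembly QC** (`hbugkit.qc`) — clip residual 3' poly-A / 5' poly-T
  tails (exact homopolymer runs ≥ 5 nt), keep transcripts ≥ 200 bp, and
  purge transcripts with Strong or Moderate vector-screen matches under the
  NCBI VecScreen score ladder (terminal Strong ≥ 24 / Moderate 19–23 / Weak
  16–18; internal 30 / 25–29 / 23–24; terminal window 25 nt).
* **Homology tiering** (`hbugkit.tiering`) — gold/silver/bronze annotation
  confidence from BLASTX-style summaries. Gold: query ≥ 300 nt, single HSP,
  subject ≥ 100 aa, positives/aligned ≥ 0.75, hit/subject ≥ 0.90. Silver:
  query ≥ 100 nt, hit spans ≥ 75% of the subject. Bronze: ≥ 30% coverage.
  Best hit per query by bitscore, deterministic tie-break.
* **Gene-family calling** (`hbugkit.family`) — GST/COE/CYP-style membership
  from the top HSP against a curated family protein: bitscore ≥ 75, subject
  ≥ 100 aa, hit/subject ≥ 0.90, hit/query ≥ 0.75 (query = longest six-frame
  ORF, aa), positives/hit ≥ 0.80. Plus ORF extraction, unique-protein
  dedup, best-hit clustering, and locus-mapping summaries.
* **GO-Slim annotation** (`hbugkit.goslim`) — pfam2go joins and resolution
  of fine-grained GO terms to their *penultimate ancestors*: every direct
  is_a child of the aspect root on some is_a path from the term to the
  root (is_a edges only; all penultimate ancestors retained).
* **Expression contrasts** (`hbugkit.expression`) — TPM
  (`TPM_i = (c_i/l_i)/Σ_j(c_j/l_j) × 10⁶`), count-level pooling into
  nymph/adult groups, and binary-log TPM ratios with a 5.0 TPM floor,
  sentinels (`undefined` for 0/0, `±inf` for one-sided zeros), ranked
  top-k per direction, and sex-pattern classification.
* **Synthetic fixtures** (`hbugkit.synthetic`) — transcripts with planted
  tails/vector decoys, tier-exact alignment tables, Poisson count matrices
  with planted fold changes and zero-expression sentinel cases, and a toy
  three-aspect ontology — all seed-deterministic with a ground-truth table.
* **Orchestration** (`hbugkit.pipeline`, `hbugkit.cli`) — a YAML-configured
  end-to-end run with a reproducible JSON manifest, plus sequencing-volume
  accounting with a PE100 bases = pairs × 200 consistency check.

## Worked example

Rank the strongest 2nd-vs-4th-instar fold changes from a TPM table (here,
the survey's published TPM pairs for that contrast, bundled in
`hbugkit.published`):

```python
import pandas as pd
from hbugkit.expression import ContrastConfig, rank_contrast, format_log2fc
from hbugkit.published import FOLD_CHANGE_ROWS

rows = [r for r in FOLD_CHANGE_ROWS if r[0] == "2nd:4th"]
tpm = pd.DataFrame({"2nd": [r[3] for r in rows], "4th": [r[4] for r in rows]},
                   index=[f"PUT{i:03d}" for i in range(len(rows))])
ranked = rank_contrast(tpm, ContrastConfig(contrast="2nd:4th", top_k=3))
ranked["log2fc"] = [format_log2fc(v) for v in ranked["log2fc"]]
print(ranked.to_string())
```

prints

```
        tpm_num  tpm_den   log2fc direction
PUT000   253.24     7.24   5.1284        up
PUT001  1055.89    42.45   4.6366        up
PUT002   366.36    28.73   3.6726        up
PUT005     8.17   334.68  -5.3563      down
PUT006     7.17   287.99  -5.3279      down
PUT007     6.33   233.59  -5.2056      down
```

i.e. the most 2nd-instar-biased transcript (a cuticular protein, plausibly
molting-related) is 2^5.1284 ≈ 35-fold higher in 2nd than 4th instars, and
the most 4th-instar-biased (a heat-shock cognate) is 2^5.3563 ≈ 41-fold
higher in 4th. Both TPMs of every reported row clear the 5.0 floor.

From the shell, the same stages run as:

```sh
hbugkit simulate --outdir fixtures --seed 3        # synthetic inputs + truth
hbugkit qc --fasta fixtures/transcripts.fasta \
           --vec-matches fixtures/vector_matches.tsv --out clean.fasta
hbugkit tier --hits fixtures/hits.tsv --out tiers.tsv
hbugkit contrast --counts fixtures/counts.tsv --contrast female:male --out fm.tsv
hbugkit run --config run.yaml                      # everything, with manifest
```

## Limitations

The TPM estimator uses transcript length as the effective length (no
fragment-length correction or multi-mapping EM), the synthetic generator
plants idealized signals (see `docs/methods.md`), and with one library per
condition the fold changes are descriptive, not statistical inferences.
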