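# Methods

## Setting and scope

`hbugkit` implements the downstream, desk-scale computations of a
single-replicate, four-condition insect transcriptome survey: cleanup of an
assembled transcript set, confidence tiering against protein homology,
detoxification gene-family calling, Pfam-derived GO-Slim annotation, and
replicate-free expression contrasts. Upstream tools (assembler, aligners,
HMMER, RSEM) are out of scope; their outputs enter as tables. The package
ships the published reference tables of the harlequin bug survey
(`hbugkit.published`) as worked-example inputs and regression anchors.

## Post-assembly cleanup

Stages run in a fixed order: tail clipping, then the length filter, then
the vector purge (vector-screen coordinates are interpreted on the clipped
sequences, matching that order).

*Tail clipping* removes one maximal exact homopolymer run per end — poly-T
at the 5' end, poly-A at the 3' end — when the run is at least
`min_tail_run` (default 5 nt). Mismatches and `N` bases never extend a run.
Exactness makes the operation idempotent: after removing the maximal run,
the new terminal base is by construction not part of a qualifying run. A
transcript that is a single homopolymer clips to the empty string, which
the ≥ 200 bp length filter then removes; this is the one place the
"sequences are non-empty" ingest invariant is deliberately relaxed.

*Vector categorization* uses the NCBI VecScreen score ladder because the
screen the pipeline emulates defines its Strong/Moderate/Weak labels that
way: a match is terminal when it starts within 25 nt of the 5' end or ends
within 25 nt of the 3' end; terminal thresholds are Strong ≥ 24, Moderate
19–23, Weak 16–18 and internal ones 30, 25–29, 23–24. All six thresholds
and the window are configurable, and the manifest records the values used.
Only Strong and Moderate matches cause removal.

## Homology tiering

Tiers encode decreasing annotation confidence. The gold rule's "positively
similar" fraction is computed as the BLAST tabular `positive` count divided
by aligned columns; subject coverage is aligned columns divided by subject
length. HSPs are not merged: coverage always reflects the best single hit,
and silver/bronze impose no single-HSP requirement. Query length is the
post-cleanup transcript length in nucleotides — the 300/100 nt floors are
stated on the transcript, so no nt→aa conversion applies. Best-hit
selection is by bitscore with ties broken toward the lexicographically
smallest subject id; determinism here is what makes round-trip tests
possible. The classifier is monotone in the evidence in the following
sense: raising the positive count, or scaling hit length and positives
together (coverage up at fixed positive fraction), never demotes a tier.
Raising hit length *alone* can demote gold (it dilutes the positive
fraction), which is why the test suite states monotonicity in terms of
positives and coverage-at-fixed-fraction.

## Gene-family calling

Membership requires all five criteria on the top HSP (bitscore ≥ 75,
subject ≥ 100 aa, hit/subject ≥ 0.90, hit/query ≥ 0.75, positives/hit
≥ 0.80), with the query length being the longest ORF of the transcript in
amino acids. The ORF scan translates all six frames under the standard
genetic code and takes the longest stop-free stretch starting at any codon;
a start codon is not required by default (configurable), since family
candidacy is about coding potential, not annotation-grade gene models.
Failed criteria are recorded per call so near-misses are auditable. The
caller is monotone: tightening any threshold can only remove members.

## GO-Slim by penultimate ancestors

The ontology is a rooted DAG per aspect with child→parent `is_a` edges
only; `part_of` and other relations are ignored — a deliberate, documented
narrowing that keeps the "reaches its aspect root" invariant checkable.
Obsolete terms are dropped at parse time. A term's slim image is the set of
direct children of its aspect root that lie on some `is_a` path from the
term to the root; all such penultimate ancestors are retained (set
semantics), so a diamond contributes both shoulders. Implementation note:
because every is_a-ancestor that is a child of the root necessarily closes
a path to the root, the resolver reduces to one reachability query plus an
edge test, and is verified against exhaustive path enumeration on small
random DAGs. Distinct-term tallies are emitted both before and after slim
resolution, per aspect. With multi-parent diamonds a *single* term can
resolve to several slim terms, so the slim distinct count is not a theorem-
level lower bound of the full count; on realistic inputs (many terms, few
slim categories) it is smaller, but the package does not enforce that.

## Expression without replicates

TPM is computed with effective length equal to transcript length; this is
a simplified estimator (no fragment-length correction, no EM multi-mapping
resolution) and is the package's documented divergence from RSEM-grade
quantification. Each nonzero sample column sums to 10⁶ within 1e-3.

Group pooling sums counts within {2nd, 4th} → nymphs and {female, male} →
adults and recomputes TPM from the pooled counts. This mirrors pooling
reads before quantifying, and differs from averaging member TPM columns
whenever depths differ — the test suite carries an explicit counterexample.
Consequently, externally published *pooled* TPM values are not reproducible
from member TPMs; only ratios of printed values are used as anchors.

Ratios are binary logs with sentinel semantics: 0/0 → `undefined`,
positive/0 → `+inf`, 0/positive → `-inf` (fixed output spellings keep TSVs
machine-readable). One published sex-pattern table prints `undefined` for a
positive-over-zero cell; the terpene table's convention (signed infinity)
is the internally consistent one and is the behavior implemented. Only
finite printed ratios are asserted in tests.

The ranked contrast applies a TPM floor of 5.0 in `filter_min_both` mode by
default — keep a transcript only if both TPMs meet the floor — because
every published top-fold-change row has both TPMs ≥ 5; a `clamp` mode
(replace each TPM by max(tpm, floor)) is retained since "floor" admits both
readings. Transcripts must also clear the two-fold differential
(|log2FC| ≥ 1) to be ranked; ties break by transcript id, making the
ranking invariant to input row order.

The sex-pattern classifier's *dominant-expressed* rule is the published one
(both sexes ≥ 5 TPM, ≥ two-fold differential). The *specific* rule — low
sex < 0.5 TPM, high sex ≥ 3.0 TPM — fills a gap where no thresholds were
published; both cut-offs are configurable and the resulting grouping is
descriptive, not an inferential claim.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions: four samples with fixed labels,
transcripts of 250–1500 nt (so most clear the 200 bp filter), a tier mix
over gold/silver/bronze/untiered, poly-A/T tails of 5–15 nt on a
configurable fraction, planted vector decoys (bundled synthetic strings,
not UniVec) with scores in the Strong/Moderate bands, and Poisson counts at
a mean depth of 500 per transcript — the depth at which the ±0.5 log2
fold-change recovery tolerance is stated. Counts are Poisson because the
design has no replication, so no overdispersion model is implied by the
data being emulated. Planted fold changes are realized on the TPM scale in
expectation up to the compositional renormalization (for 100 transcripts
and a 4-fold plant, the realized ratio is 4·N/(N−1+4) ≈ 3.88; well within
the recovery tolerance). Alignment rows are engineered to satisfy exactly
the planted tier and fail all stricter ones; family-flag fixtures plant
boundary-straddling bitscores (75.0 vs 74.9).

What passing the round trips therefore shows: the classifiers implement
their rules exactly, and the expression arithmetic recovers planted signals
at realistic depth. What it does not show: robustness to assembly
chimerism, multi-mapping, fragment-length bias, overdispersed biological
noise, or partial/frameshifted hits — none of which the generator attempts.

## Numerical and interface choices

Determinism everywhere: one integer seed drives `numpy`'s Generator;
identical configurations give byte-identical fixtures, and a pipeline rerun
reproduces byte-identical outputs and manifest (no timestamps in outputs).
Thresholds are compared with `>=` at boundaries, matching their "at least"
phrasing. The pipeline manifest records every parameter block, defaults
included, and per-stage in/out record counts are logged. Problem sizes used
in tests and the acceptance script (200–300 transcripts, ≤ 50-term
ontologies, 10,000-row classifier sweeps) were chosen as the smallest sizes
at which the properties under test are non-trivial.

## Known limitations

Single-end-of-run quantification only (no statistical DE — impossible
without replicates); is_a-only slim resolution; exact-match tail clipping
(a tail interrupted by a sequencing error survives); simplified effective
length; vector categories depend on a configurable ladder rather than a
re-implementation of the screening aligner.
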