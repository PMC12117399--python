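# Methods

## The triage problem

Genetic diagnosis of an inborn error of immunity (IEI) starts from a
whole-exome variant table — typically tens of thousands of annotated rows —
and must end with a handful of candidate genes worth experimental follow-up.
The filtering logic itself is simple Mendelian reasoning, but done by hand in
a spreadsheet it is slow and error-prone. `ieivf` encodes that reasoning as a
deterministic pipeline over a tabular read-out, with full per-record
provenance of why each variant was removed.

The input is deliberately minimal: per sample and per site the table carries
only the total read depth and the allele balance (`Var/Depth`, the fraction
of reads supporting the variant allele), optionally plus a free-text caller
label. No genotype likelihoods, no phasing, no population frequencies.
Allele-frequency filtering is explicitly out of scope and must be done
upstream; this keeps the tool's assumptions honest — it prioritizes among
the variants the user chose to load, nothing more.

## Zygosity model

Zygosity is classified per observation from the allele balance *b*:

- `hom_ref`  if *b* < 0.2
- `het`      if 0.2 ≤ *b* < 0.8
- `hom_alt`  if *b* ≥ 0.8
- `no_call`  if depth is 0 or below `min_call_depth` (default 1)

The 0.2/0.8 cut-offs are the conventional allele-balance bands for germline
short-read calls; all four numbers are user-settable (`ZygosityThresholds`).
If the configured het band ends below the hom_alt band, balances in the gap
resolve to `het`. When a row carries a recognizable caller label
(case-insensitive substrings: `ref` → hom_ref, `het` → het, `hom` →
hom_alt), the label overrides the numeric call — the upstream caller saw
read-level evidence the table no longer carries. The one exception is zero
depth, which is always `no_call`: an allele balance over zero reads is
undefined, not 0. Classification is total and monotone in *b* at fixed
depth, which the test suite checks by sweep and against an independently
written threshold-arithmetic oracle.

## Removal filters

Each filter is a pure record-wise predicate that stamps a named reason;
enabled filters are evaluated independently and reasons accumulate rather
than short-circuit, so the report explains every removal completely. Because
no predicate reads another record or a previous reason, the survivor set is
invariant under filter ordering (tested by shuffling), application is
idempotent, and the accounting identity `input = survivors + removed` holds
by construction and is asserted at run time.

| reason | removes a record when |
|---|---|
| `ref_in_patients` | no patient carries the variant (all hom_ref / no_call) |
| `hom_alt_in_control` | any control is homozygous for it — a homozygous genotype in an unaffected person cannot be the recessive cause |
| `shared_het` | every carrying patient is het AND some control is het — a simple shared heterozygote is not causal under full penetrance |
| `blacklist` | the gene (case-folded symbol, or HGNC id when the list has ids) is on the not-immunology list |
| `utr` | the consequence is exactly `5_prime_UTR_variant` or `3_prime_UTR_variant` |
| `synonymous` | the consequence is exactly `synonymous_variant` |
| `low_depth` | every patient covers the site with fewer than `min_depth` reads (default off; 10 in the worked example) |
| `trio_recessive` | the genotype pattern is NOT (patient hom_alt, both parents het) |

Design choices where the semantics were genuinely open:

- **"Present in controls" means any control**, never a frequency — there is
  no frequency parameter anywhere in the model.
- **Multi-patient semantics**: carrier-in-any-patient for presence rules and
  low-depth-in-all-patients for the quality rule, chosen so that adding
  patients can never spuriously remove a variant.
- **Consequence matching is exact and case-sensitive** on the three
  Sequence-Ontology terms above; annotation pipelines that emit other
  spellings must normalize first.
- **no_call handling is conservative in both directions**: a no-call patient
  provides no evidence of carriage (cannot rescue a record from
  `ref_in_patients`), and a no-call control can never remove one.
- `min_depth` applies to patient observations only; control depth is never a
  removal criterion.

The trio filter requires exactly one patient and two parents (checked before
any record is processed). Of the 27 (patient, mother, father) zygosity
combinations exactly one survives; the suite enumerates all 27.

## Flags (highlighting, never removal)

Flags are computed on survivors only and never change survivor membership.

**Compound heterozygotes** (pink in spreadsheet output): survivors are
grouped by gene; within a gene a record qualifies for a patient when that
patient is het with depth and allele balance inside the configured ranges
(defaults: depth ≥ 10, balance in [0.2, 0.8] — both mates must pass). If a
patient has ≥ 2 qualifying records in a gene, all of them are flagged, so
flagged counts per (gene, patient) are never exactly 1. Qualification is per
patient: two variants het in different patients do not combine. Flagging is
phase-naive by default — without parental reads both variants may sit on one
haplotype, and the flag is an invitation to check, not a phased claim. With
two parents loaded, `strict_trio_phase` additionally requires a flagged pair
to be placeable on distinct parental haplotypes (each mate het in a
different parent).

**White-list hits** (green): the gene matches a curated immune-gene panel by
case-folded symbol or HGNC id. The published panel behind this workflow is
distributed as supplementary material of its source and is not bundled here;
any one-symbol-per-line or symbol⇥id file works. `select_candidates` then
reproduces the final manual triage (e.g. homozygous ∩ white list under a
consanguinity hypothesis).

## Input/output contract

Tables are accepted as `.xlsx` or TSV with the fixed header `Gene Symbol,
Gene Id, Chr, Position, Ref, Var`, one `(sample id, Depth, Var/Depth)`
triplet per sample, then `Variant Effect, Existing Variation`. Coordinates
are 1-based; multi-allelic sites must arrive decomposed; duplicate keys
collapse to the first with a warning; `Null` and empty both mean "no dbSNP
id" and are always written back as empty. Chromosome labels are verbatim —
`6` and `chr6` are not reconciled. All tables in one analysis must share one
assembly tag (GRCh37.p13 or GRCh38.p14); mixing is a hard error. Malformed
rows raise errors carrying the file row index, and the reader guarantees
`input rows = parsed records + reported row errors`.

Output repeats the input layout plus `WHITELIST_HIT`, `COMPOUND_HET`,
`REMOVAL_REASONS` (semicolon-joined; empty for survivors). The TSV dialect
is UTF-8/LF with shortest-exact float formatting, making write→read an exact
identity and reruns byte-identical; the `.xlsx` dialect adds the green/pink
row fills (pink wins if a row earns both). The pipeline itself uses no
randomness anywhere.

## Synthetic data

Real patient exomes are private, so the fixture generator is the test bed.
It plants records of ten labelled categories — one per filter or flag — among
"clean" background records engineered so that no filter touches them
(patient het, controls hom_ref, well covered, missense, genes off both
panels). Each plant perturbs exactly the feature its filter inspects, which
makes truth-label soundness exact: with a single filter enabled, the fired
set must equal the planted set, with no cross-talk. Depths are drawn from a
right-skewed shifted negative-binomial-like distribution on [10, 120]
(low-depth plants on [1, 9]), spanning the coverage range seen in the worked
example; allele balances sit at 0/0.5/1 with Gaussian noise (σ = 0.02 het
0.05), clipped well inside their bands. Generation is a pure function of the
`FixtureSpec` (seed included).

What this emulates is the *tabular read-out* only. It does not simulate
mapping artefacts, strand bias, segmental duplications, borderline allele
balances that straddle the 0.2/0.8 cut-offs, or annotation disagreements —
so green tests demonstrate the filtering algebra is correct, not that the
upstream calls are. Gene symbols for panel tests come from two bundled
20-gene mini-panels (established IEI genes vs. large non-immune genes), so
no external download is needed.

Property and oracle checks run on 500-record planted tables with fixed
seeds, a size at which exhaustive per-record re-derivation by an independent
oracle is instant; the acceptance script uses the same size. The published
eight-variant case-study shortlist is reconstructed verbatim as
`table1_fixture()` and anchors the exact-reproduction tests (depth filter at
10 reads → the four genes MAML2, LILRB3, EZR, MAP3K4).

## Known limitations

- Only the recessive/consanguinity inheritance model is built in; dominant,
  X-linked and de-novo models are out of scope, as are allele-frequency
  filters, pathogenicity scores and gene-network prioritization.
- Compound-het flagging without trio data cannot establish phase.
- Whole-genome-scale tables are untested territory: everything is held in
  memory (fine for exomes, ~10⁵ rows).
- The consequence filter trusts the annotation strings exactly; it does not
  parse ampersand-joined multi-consequence fields.
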