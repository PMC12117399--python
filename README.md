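# ieivf

Variant prioritization for the genetic diagnosis of **inborn errors of
immunity (IEI)**. Given an annotated whole-exome variant table with
designated patient, control and (optionally) consanguineous-parent samples,
`ieivf` applies a set of Mendelian removal filters and highlighting rules
and emits a short, flagged candidate list plus a per-filter provenance
report — replacing the error-prone manual spreadsheet filtering that
clinical immunology groups otherwise do by hand.

## The model in brief

Per sample and site the table carries read depth *d* and allele balance
*b* = variant reads / *d*. Zygosity is classified as hom_ref (*b* < 0.2),
het (0.2 ≤ *b* < 0.8) or hom_alt (*b* ≥ 0.8), with caller labels such as
`P_Homo_var` taking precedence and *d* = 0 yielding no call. On top of the
calls sit record-wise filters — remove variants not carried by any patient,
homozygous in any control, het-shared between patients and controls, in
blacklisted (non-immune) genes, UTR or synonymous, under-covered in every
patient, or (trio mode) violating the recessive consanguinity pattern
*patient hom_alt ∧ both parents het* — and two flags that never remove:
compound-heterozygote pairs per (gene, patient) within user-set depth and
allele-balance ranges, and hits against an immune-gene white list. Filters
commute, reasons accumulate, and `input = survivors + removed` is asserted
on every run. See `docs/methods.md` for the full treatment.

## Worked example

The package bundles, as a programmatic fixture, the published shortlist of a
consanguineous patient (id `RP0047`) with a known homozygous *EZR*
disease-causing variant: eight homozygous variants in white-listed immune
genes, at read depths {2, 2, 2, 36, 14, 29, 21, 1}.

```python
from ieivf import FilterConfig, apply_filters, classify_records
from ieivf.annotator import flag_whitelist, select_candidates
from ieivf.fixtures import table1_fixture, table1_whitelist

records, roster = table1_fixture()
classify_records(records)

# homozygous + white-list triage recovers all eight candidates
flag_whitelist(records, table1_whitelist())
print(len(select_candidates(records, require_hom=True, require_whitelist=True)))

# the 10-read quality filter narrows them to four genes
records, report = apply_filters(records, FilterConfig(roster=roster, min_depth=10))
print([r.gene_symbol for r in records if r.surviving], report.per_filter_fired)
```

prints

```
8
['MAML2', 'LILRB3', 'EZR', 'MAP3K4'] {'low_depth': 4}
```

i.e. eight homozygous white-list candidates, of which four are covered by at
least 10 reads — *EZR* among them, matching the patient's clinical picture.

The same run from the shell, on a table in the supported layout
(`Gene Symbol, Gene Id, Chr, Position, Ref, Var`, one
`sample / Depth / Var/Depth` triplet per sample, `Variant Effect,
Existing Variation`; `.tsv` or `.xlsx`):

```bash
ieivf run --input patient.tsv --assembly GRCh37 --patient RP0047 \
      --control C1 --control C2 \
      --remove-ref-in-patients --remove-hom-alt-in-controls \
      --remove-shared-het --remove-utr --remove-synonymous --min-depth 10 \
      --whitelist immune_genes.txt --flag-whitelist --flag-compound-het \
      --out filtered.xlsx --report report.json
```

The `.xlsx` output fills white-list rows green and compound-het rows pink;
`report.json` records input/surviving counts, per-filter fired counts, flag
counts and the effective configuration. `ieivf fixtures --out DIR --seed N`
writes a synthetic table with planted truth labels for experimentation.

Note the tool does **not** filter on allele frequency — load only the
variants you want ranked.

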