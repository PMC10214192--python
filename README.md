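# splicescreen

Discovery and prioritization of alternative-splicing-derived immunotherapy
target candidates. The package screens tumor splicing profiles (percent
spliced in and splice-junction read counts) against an indexed multi-group
reference panel of normal and tumor tissue types, translates the splice
junctions of tumor-enriched isoforms into peptides using annotated reading
frames, calls HLA-I epitope candidates through a pluggable binding
predictor (median IC50 < 500 nM), maps peptides to annotated extracellular
protein regions for cell-surface candidacy, and cross-validates predicted
epitopes against MS immunopeptidomics peptide lists.

## Modules

| module | role |
| --- | --- |
| `panel_store` | read event tables (rMATS-style JC dialect: SE/A5SS/A3SS/RI) and STAR-style junction files; build, persist and query the reference panel; low-coverage PSI masking (group-mean junction-read sum < 10) |
| `screening` | tumor-association screen (two-sided t test, p < 0.01, &#124;ΔPSI&#124; > 0.05, degree-of-association ≥ 8), junction-CPM secondary screen (one-sided t), tumor-specificity screen (one-sided Fisher exact on expressing-sample counts at ≥5 tumor / ≥2 normal reads, p < 1e-6), recurrence screen |
| `junction_translation` | reading-frame resolution from GTF CDS, ≤21-aa junction-centered peptide translation, isoform-peptide comparison, microexon (≤30 nt) classification |
| `target_prediction` | junction-overlapping 9/10-mer enumeration, median-IC50 calling with a deterministic mock predictor plus an adapter contract, extracellular-interval mapping, validation shortlist (HLA-A\*02:01, FC ≥ 2, FPKM ≥ 20) |
| `proteo_integration` | RNA-seq-augmented proteome FASTA, FDR-filtered PSM cross-referencing, expression × affinity detection-rate grid |
| `synthetic_fixtures` | seeded synthetic panels/cohorts with planted tumor-associated and tumor-specific events; toy genome + GTF + protein annotation with a peptide answer key |
| `cli_reporting` | pipeline orchestration, funnel counts, violin/bar data export, `splicescreen` CLI |

## CLI

```bash
# synthetic fixtures
splicescreen simulate genome --out toy/
splicescreen simulate panel --spec spec.yaml --seed 7 --out sim/

# build a panel from event tables + junction files + a group manifest
splicescreen panel build --events SE:sim/inputs/SE.events.txt \
    --samples sim/inputs/samples.txt --manifest sim/inputs/manifest.tsv \
    --sj-dir sim/inputs/sj --out panel/
splicescreen panel inspect panel/

# screens only
splicescreen screen --panel panel/ --tumor-group TUMOR --out records.tsv

# full pipeline (screen -> translate -> predict -> shortlist)
splicescreen report --config pipeline.yaml --out out/
```

A pipeline config references the panel directory, the tumor group name,
genome FASTA + GTF, an allele list, optional extracellular annotation and
gene-expression TSVs, and any screen-threshold overrides under `screen:`.

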