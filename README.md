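# gonadspec

Gonad-specific gene expression screening for RNA-seq studies of the Pacific
oyster (*Crassostrea gigas*) and similarly designed experiments.

The Pacific oyster has a remarkably fluid sex-determination system —
protandric dioecy, sex change, occasional hermaphroditism — and a standard
way to hunt for the genes behind it is to compare gonadal and somatic
transcriptomes: quantify expression, keep the expressed genes, call the
genes expressed only in ovary or only in testis, characterise those gene
sets by annotation-term enrichment, and finally check whether homologs of
known sex-determining pathway genes (*Dmrt1*/*dsx*, *Sry*/*Sox*, *FoxL2*,
…) are among them. `gonadspec` implements that pipeline as a tested,
reusable library and CLI, together with a synthetic count-data generator
with planted ground truth so every stage's error rates can be measured.

## The method

Expression is measured in RPKM (reads per kilobase of transcript per
million mapped reads): for a gene with `C` mapped reads, exonic length `L`
bp, in a library of `N` mapped reads,

```
RPKM = C · 10⁹ / (N · L)
```

The design is 3 ovary + 3 testis + 7 somatic libraries (the 13-sample
core set; developmental-stage libraries may be added for profiling). A
gene is *expressed* if its RPKM exceeds 3 in at least one core library.
An expressed gene is called **ovary-specific** (symmetrically
testis-specific) when

1. every one of the 3 ovary replicates has a strictly greater RPKM than
   every one of the other 10 samples, and
2. the ovary mean RPKM is at least 5× the mean of the other 10 samples.

The two calls are mutually exclusive by construction. Each specific-gene
set is then tested per annotation term (GO or KEGG) against the
hypergeometric upper tail — for a set of `n` genes from a universe of `N`
with `K` term-annotated genes, `P(X ≥ k)` with expected count `nK/N` —
with Benjamini–Hochberg FDR adjustment across terms. A candidate screen
renders, for each named pathway gene, presence and sex-specific expression
in the two-sign convention (`+/+`, `+/−`, `−/−`) and reports per-gene fold
changes and per-organ expression profiles.

## Worked example

Simulate a dataset at the study layout with 50 + 50 planted
tissue-specific genes (10-fold effect, negative-binomial counts), then run
every stage:

```sh
gonadspec run-all --synthetic --n-genes 2000 --n-ovary 50 --n-testis 50 \
    --effect-fold 10 --seed 1 --out demo_out
```

which logs

```
INFO loaded 2000 genes x 13 samples
INFO 2000 of 2000 genes pass the RPKM > 3 prefilter
INFO 50 ovary-specific, 50 testis-specific genes
expressed=2000 ovary_specific=50 testis_specific=50
```

i.e. at these settings the classifier recovers all 100 planted genes
(`demo_out/summary.json` reports `sensitivity: 1.0`,
`false_positive_rate: 0.0` against the planted truth). The GO enrichment
table for the ovary set, `demo_out/enrichment_go_ovary.tsv`, begins

```
term_id      genes  expected  p_value      p_adjusted
GO:SIM0001   43     4.74      3.40324e-39  1.70162e-37
GO:SIM0045   8      2.87      0.00643734   0.160933
```

`GO:SIM0001` is the designated planted term: 43 of the 50 ovary-specific
genes carry it against a null expectation of 4.74, hence the vanishing
adjusted p; the next term is background noise. The same stages are
available individually (`simulate`, `rpkm`, `classify`, `enrich`,
`screen`) and as library functions:

```python
from gonadspec import classify_gene, fold_change, render_fold

call = classify_gene([55.7, 55.7, 55.7], [0.9] * 10, target_class="testis")
call.verdict            # True  — testis-exclusive expression profile
render_fold(fold_change(15.8, 3.0))   # '5.3'
```

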