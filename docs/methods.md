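# Methods

## Pipeline model

`gonadspec` operates on a gene-level read-count matrix over a fixed sample
design: 3 ovary, 3 testis and 7 somatic libraries (the 13-sample core
set), optionally extended by developmental-stage libraries that are
profiled but never enter filtering or classification. Stages:

1. **Quantification.** RPKM = C·10⁹/(N·L). N defaults to the per-sample
   column sum of the count matrix; an explicit per-sample mapped-read
   total can override it when the genome-wide total is known (the two
   differ by reads mapped outside annotated genes — both conventions are
   in use, and the package supports either). L is a single union-exon
   length per gene; no isoform resolution. A helper computes L from a
   GFF3 by merging overlapping exon intervals per gene (1-based closed
   coordinates).
2. **Prefilter.** A gene is expressed when its RPKM is strictly greater
   than the threshold (default 3) in at least one core library. "Strictly"
   is a deliberate reading of "larger than"; the threshold is
   configurable.
3. **Specificity.** Deterministic dual criterion per direction: (1) the
   minimum of the 3 target replicates strictly exceeds the maximum of the
   other 10 samples — ties fail; (2) the target mean is at least
   `fold_threshold` (default 5, inclusive) times the arithmetic mean of
   the other 10. The reference statistic for criterion 2 is the mean of
   the other 10 samples (the parallel reading of "mean … of that in the
   other 10"); `other_stat="max"` is available as a stricter sensitivity
   option. Zero-denominator convention: other-mean 0 with a positive
   target mean passes criterion 2 with fold reported as `inf`; an all-zero
   gene fails both criteria with fold 0. Criterion 1 makes the ovary and
   testis calls mutually exclusive on any input. Only prefiltered genes
   are classified; the 3/3/7 layout is enforced unless explicitly relaxed.
4. **Enrichment.** Each term is tested independently ("classic" style —
   no term-hierarchy propagation; if a caller supplies an
   ancestor-propagated map, that is their choice) with the hypergeometric
   upper tail, i.e. the one-sided Fisher's exact test for
   over-representation. The universe is the expressed genes carrying at
   least one annotation in the tested namespace; unannotated genes drop
   out of N, n and K, matching common GO-tool convention. Expected count
   is n·K/N at full precision (rendered at 2 decimals in tables). GO and
   KEGG share the engine and differ only in the supplied gene→term map.
   Raw p-values are BH-adjusted; default significance is adjusted p <
   0.05, and both columns are always reported since published tables are
   often ambiguous about which they print. Output sorts by raw p with
   lexicographic term-ID tie-breaks for determinism.
5. **Candidate screen.** Homology search is out of scope; the screen
   takes a table mapping named pathway genes to homolog IDs. Presence =
   non-empty homolog list; sex-specific = any homolog carries a
   specificity verdict (the two-sign rendering `+/+`, `+/−`, `−/−` is a
   pure function of those two bits). For multi-homolog families the
   record-level testis/ovary fold uses the representative homolog with
   the greatest combined gonadal mean, with every homolog's verdict and
   fold in the notes. Profiles report per-group mean and n−1 standard
   deviation (0 for singleton groups); prose-style folds are rounded
   half-up to 1 decimal.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes: 13
overdispersed RNA-seq libraries with a configurable number of planted
ovary- and testis-specific genes and one designated enriched annotation
term. It does **not** emulate read-level artifacts (mapping ambiguity, GC
or length bias beyond proportional scaling), isoforms, batch effects, or
correlated biological replicates — so passing recovery tests demonstrates
the classifier's statistical behaviour under its own model, not
performance on real libraries.

- **Counts** are independent negative binomials with mean m and size r
  (variance m + m²/r), the standard overdispersed RNA-seq count model.
  Default r = 10 (CV² ≈ 0.1 at high counts), a moderate between-sample
  dispersion for genetically distinct individuals.
- **Means** are m = b·(L/1000)·(N/10⁶)·f, with baseline b = 20 (a typical
  moderately expressed gene, comfortably above the prefilter on the RPKM
  scale, which b approximates by construction), gene length L uniform on
  [500, 3000] bp, nominal library size N = 5·10⁶ reads per library (short
  single-end libraries of the study's era; depth is configurable and no
  fidelity to the original libraries is claimed), and f = `effect_fold`
  in a planted gene's target tissue, 1 elsewhere. Because means scale
  with L and N, the planted fold is exact on the RPKM scale; the ratio of
  target to non-target means equals `effect_fold` exactly in the mean
  matrix. Stage samples always receive background means.
- **Annotations.** The designated term covers `planted_term_fraction`
  (default 0.8) of planted genes and `background_term_rate` (default
  0.05) of the rest; all other GO terms and KEGG pathways annotate genes
  independently at the background rate.
- **Determinism.** One integer seed fixes models, truth and counts;
  identical configurations write byte-identical datasets. Realised
  library sizes (column sums) are what flows into RPKM downstream,
  matching the quantification default.

## Numerical and design notes

- The hypergeometric tail is computed with scipy's survival function and
  is cross-checked in the test suite against exact integer-combinatorics
  enumeration for every parameter combination with N ≤ 30 (max abs
  difference < 10⁻¹²). BH adjustment is statsmodels' step-up
  implementation, cross-checked against hand-computed examples and a
  from-definition re-implementation on random vectors.
- The classifier is cross-checked element-for-element against a literal
  brute-force transcription of the two rules on hundreds of random
  matrices, including matrices with exact ties and zeros.
- Null calibration of the enrichment engine uses randomly drawn gene sets
  under uniform annotation (an end-to-end run with no planted effect
  yields empty specific sets and vacuous p ≡ 1, which is separately
  tested); the discrete test is conservative, so the observed fraction of
  raw p < α sits below α.
- Degenerate inputs: empty gene sets propagate to empty outputs; an
  all-zero count column is rejected at quantification (zero library
  size); genes with missing lengths, samples without metadata, duplicate
  IDs and malformed TSVs raise input errors naming the file line where
  possible.

## Limitations

- The specific-gene counts of any real study depend on its raw libraries;
  with only printed per-gene profiles available, the package validates
  the machinery (oracle equivalence, planted recovery, calibration) and
  the study's worked per-gene numbers, not the headline set sizes.
- The dual criterion is a hard rule, sensitive to a single exceptional
  sample by design (that is what makes it strict); no variance-aware
  alternative (e.g. a count-model test) is provided here.
- Criterion 2's reference statistic in the source description is open to
  a mean-vs-max reading; the mean reading is the default and the max
  reading is exposed, with no claim about which the original authors
  used. Likewise whether their enrichment universe was all genes or
  expressed genes is not recoverable; expressed genes is the default
  here.
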