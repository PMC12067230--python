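# Methods

## The measurement model

The pipeline analyses selection experiments in which a library of peptide
variants is expressed in yeast fused to a prion nucleation domain,
selection permits growth only of cells whose peptide nucleates amyloid,
and deep sequencing of the pool before (*input*) and after (*output*)
selection measures each variant's enrichment. The per-replicate score of
variant *i* is

    ES_i = ln(F_i,output) − ln(F_i,input)

with `F` the within-sample read frequencies, and the nucleation score is
`NS_i = ES_i − ES_ref`, the enrichment relative to a reference. Two
centering conventions are supported, matching the two library types:

- **wild-type centering** (designed substitution/truncation libraries):
  the reference is the wild-type variant, subtracted per replicate, so NS
  is directly "effect relative to wild type";
- **mode centering** (random-extension libraries, where no meaningful wild
  type exists and most sequences do not nucleate): after replicate
  merging, the kernel-density mode of the score distribution is subtracted
  so the non-nucleating bulk sits at 0.

Base of the logarithm: natural log throughout. Centred scores are
invariant to the base; error estimates are not, so the choice is fixed and
documented rather than configurable.

### Errors and merging

Per-replicate variances use the Poisson delta method,
`σ² = 1/c_in + 1/c_out`, plus the reference's two terms under wild-type
centering. Counts are pseudocounted (default 0.5, configurable to 0) so
variants with a zero output count in one replicate remain finite.
Replicates are combined by the inverse-variance mean,
`NS = Σ(NS_r/σ_r²)/Σ(1/σ_r²)`, `σ = (Σ 1/σ_r²)^(−1/2)`, which is the
minimum-variance unbiased combination under independent Gaussian errors
and guarantees the merged σ never exceeds the best single replicate. A
full error-regularisation model (shrinking per-replicate variances toward
a count-dependent trend, as dedicated DMS error pipelines do) is out of
scope; the delta method is deliberately isolated behind
`per_replicate_scores` so it can be replaced wholesale.

### Mode estimation and imputation

The mode is the argmax of a Gaussian kernel density (Silverman bandwidth)
evaluated on a 512-point grid spanning the data range — robust to the
heavy right tail that nucleators put on the distribution. Sequences
present in the input but with zero output reads in *every* replicate
carry no usable enrichment signal; they are imputed at the mode (0 after
centering) and assigned the largest observed σ so that no downstream test
can ever call them significant. Sequences with output reads in at least
one replicate are scored from the replicates they appear in.

## Classification

Scores are tested with a Z-statistic `z = NS/σ` against a standard normal
reference, and Benjamini–Hochberg correction controls the FDR:

- designed libraries: two-sided test at FDR 0.1; significant positive →
  `NS_inc`, significant negative → `NS_dec`, otherwise `WT_like`. The
  two-sided choice reflects that both directions of effect are reported at
  the same FDR. After labelling, `WT_like` entries whose σ normalised by
  the interquartile range of the score distribution exceeds 0.2 are
  excluded as unreliable (significant calls already carry evidence and are
  not filtered).
- random libraries: one-sided (greater) test at FDR 0.05; rejected →
  `nucleator`, otherwise `nonnucleator`. Imputed entries are nonnucleators
  by rule and are excluded from the BH family — they are not tested
  hypotheses, and p = 1 placeholders would only distort the family size.
  The strongest decile of the library by score forms the top-10% tier,
  intersected with the nucleator set so the tier is always a subset of the
  nucleators.

Duplicate protein sequences (distinct nucleotide variants translating to
the same peptide) are merged: mean score, mean σ, modal status with ties
broken conservatively to nonnucleator. Afterwards nonnucleators that
combine an unreliable error (normalised σ > 0.2, the same reliability
notion as the designed-library filter) with a mean score above the
minimum nucleator score are discarded: these are sequences the test
lacked power to call, not confident negatives.

A *gatekeeper* position is one where more mutations significantly
increase than decrease nucleation (`n_inc > n_dec` over the designed
classification).

## The synthetic experiment

No generative model of the assay is published, so the simulator is a
stand-in with the statistical structure the pipeline assumes, not a
calibration to the deposited data:

- input abundances are log-normal (dispersion 0.5 by default — uneven but
  not pathological library representation);
- one selection round multiplies each variant's frequency by
  `exp(true NS)` and renormalises: the score definition is a single
  input→output log-ratio, so a single multiplicative round with no
  explicit growth-time parameter is the matching generative picture;
- sequencing is multinomial at the configured depth (default 2×10⁶ reads
  per sample, 3 replicates, ~1,000× coverage for a 2,000-variant
  library); dropout emerges from finite depth, with an optional hard
  dropout rate to stress the imputation path;
- true effects are a two-component mixture: nucleators (probability 0.3)
  draw positive scores from gamma(shape 2, scale 1.5); the rest sit at 0.

One property of this model deserves emphasis: `exp(S)` with gamma(2, 1.5)
scores has no finite expectation, so the post-selection pool can be
dominated by the single largest draw (scores of 13–16 occur in libraries
of a few hundred nucleators, multiplying frequencies by up to e¹⁶). On
such draws, weak nucleators and null variants are starved of output reads,
their errors grow, and the recovered nucleator fraction underestimates the
truth at fixed depth — visible in `analysis/04_score_classify.py`. The
post-merge discard of unreliable high-scoring nonnucleators recovers most
of this gap; the remainder is a power limit of the measurement, not an
estimation bias. Real assays do not show this extreme because growth
saturates; the simulator keeps the unsaturated form because the score
definition it feeds is the unsaturated log-ratio.

What passing tests on this generator do **not** show: robustness to PCR
amplification bias, replicate-specific batch effects, saturating growth
kinetics, toxicity, or prion-state dynamics — none of which are modelled.

## Read processing

Reads are fixed-length amplicons `flank5 (25 nt) + variable + flank3
(21 nt)`. Flanks are matched at fixed offsets (no indel alignment, as
appropriate for amplicon sequencing), accepting at most
`floor(0.20 · flank_len)` mismatches each. The per-base Phred ≥ 30 filter
applies to the variable region only: those are the bases that determine
variant identity, while flank errors are already bounded by the mismatch
tolerance. Designed-library mode keeps only whitelisted interiors; random
mode keeps every distinct interior of the expected length. The
minimum-input-reads filter (200 designed / 100 random) removes a variant
only when it is under threshold in **every** replicate — the literal
reading of the rule — with an `any` switch for the stricter reading.
Paired-end merging, adapter discovery and demultiplexing are out of scope;
the pipeline accepts single merged reads or count tables directly.

## Enrichment statistics

Composition comparisons use per-sequence residue percentages (so each
sequence contributes equally regardless of length), a Welch t-test per
residue, Cohen's d with the pooled SD, and the raw difference of group
means in percentage points. Position-wise tests cross group membership
with residue-class membership at each position in a 2×2 chi-square without
continuity correction (sample sizes are large; cells with expected counts
below 1 are skipped and flagged). The physicochemical grouping —
aliphatic AVLIM, aromatic FWY, polar STNQ, positive KRH, negative DE,
special CGP — is a configurable mapping, not a fixed truth; Cys and Gly
warrant separate inspection since the "special" class pools them with Pro.
Enrichment analyses default to the extension region (positions 23+ on the
22-residue base) because that is the sequence actually varying in
random-extension libraries.

Property scales (Kyte–Doolittle hydropathy; Kanehisa–Tsong beta-sheet
propensity) ship as an editable TSV with citations. Cross-peptide
comparisons aggregate mean scores by position (under N-anchored,
C-anchored, or externally supplied alignments), by wild-type residue, or
by mutant residue, and report Pearson r. Predictor evaluation uses the
rank-based (Mann–Whitney) AUC with a seeded bootstrap SD, making it
invariant to monotone transforms of the predictor.

## Numerical and design choices

- Enumeration order is position-major with mutant residues alphabetical
  and the truncation record last per position, so outputs diff stably.
- Position numbering is 1-based; "position 23" is the first extension
  residue after the 22-residue base.
- Truncation at position 1 (empty peptide) is retained as a valid record.
- The NNK set is enumerated explicitly (32 codons, one stop: TAG);
  probabilities quoted for it (stop 1/32, Ser 3/32, full-length
  (31/32)¹²) come from that enumeration, not from sampling.
- SNV reachability is computed against a *synthetic* back-translated
  coding sequence (one fixed codon per residue) shipped as a labelled
  fixture; with a real coding sequence supplied, the same function yields
  the biologically meaningful annotation.
- Centering is idempotent: wild-type centering re-subtracts an
  already-zero reference; mode centering of a mode-centred sample
  subtracts a shift of exactly 0 on the shifted grid.
- BH adjustment, t/chi-square/Pearson tests and the AUC are delegated to
  statsmodels, scipy and scikit-learn; each is cross-checked in the test
  suite against a naive reimplementation (O(m²) step-up for BH, explicit
  formulas for the rest).
- Problem sizes in the analysis drivers are scaled-down counterparts of
  the real experiments (libraries of 1,800–3,000 random extensions,
  ~1,000 reads per variant per sample) chosen to keep the full run in the
  tens of seconds while preserving the coverage regime; the package
  functions take sizes as parameters throughout.

## Known limitations

- The delta-method σ ignores overdispersion between replicates beyond
  counting noise; with few replicates the Z reference is approximate for
  low-count variants.
- The KDE mode is a global-bandwidth estimate; with <~50 entries it is
  refused rather than returned unreliably.
- The simulator draws input abundances independently per replicate;
  replicate correlation of library representation is not modelled.
- Designed-library nucleotide-level structure (which codons encode each
  protein variant) is not modelled; duplicate merging operates at the
  protein level on whatever nucleotide variants are supplied.
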