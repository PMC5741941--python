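# Methods

`qsig` implements a standardized meta-analysis workflow for deriving a
consensus transcriptional signature of cellular quiescence from a
compendium of heterogeneous two-group expression studies (quiescent, QSC,
versus activated, ASC, muscle stem cells). The design principle is
*individual analysis first, multi-set analysis second*: every dataset is
processed with identical QC, differential-expression and enrichment steps,
and only the resulting per-dataset DEG calls are combined — calls are
intersected, effect sizes are never pooled, because log-fold-change scales
differ drastically across platforms and studies.

## Per-dataset model

**Quality control.** Sample quality is screened with relative log
expression (RLE): for sample *j*, the per-gene deviations
*x<sub>gj</sub> − median<sub>j'</sub>(x<sub>gj'</sub>)* are summarized by
their median and IQR. A sample is flagged when |RLE median| > 0.15 (log2
units). No reference prescribes a cutoff; 0.15 was chosen so that clean
synthetic arrays (thousands of genes, residual SD 0.5) essentially never
flag while a global +1 log2 shift always does, and it is configurable.
Flagged samples are removed, provided each condition retains ≥ 2
replicates. An optional quantile normalization (columns mapped onto the
mean order-statistic distribution, ties averaged) is available for raw
synthetic matrices and is off by default, since public datasets arrive
normalized. When probeset-level data carry gene annotation, each gene is
represented by its most variable probeset (sample variance across **all**
samples — cross-condition variance favors informative probesets); exact
ties go to the lexicographically smallest probeset id, and the chosen
probeset is recorded.

**Differential expression.** For each gene, logFC = mean(QSC) − mean(ASC)
on the log2 scale, with pooled two-group variance *s²<sub>g</sub>* on
*d<sub>g</sub> = n₁ + n₂ − 2* degrees of freedom. An inverse-chi-square
prior with hyperparameters (*d₀*, *s₀²*) shrinks each variance to the
posterior

    s̃²ᵍ = (d₀·s₀² + d_g·s²ᵍ) / (d₀ + d_g)

and the moderated statistic *t = logFC / √(s̃²(1/n₁ + 1/n₂))* is referred
to a t distribution on *d₀ + d_g* df (normal when *d₀* is infinite; the
ordinary pooled t-test when *d₀ = 0*). Hyperparameters are fitted by
moment matching on log variances, with the trigamma relation inverted by
bisection (relative tolerance 1e−8); zero excess dispersion flags *d₀*
infinite, and exactly identical variances return the common value as
*s₀²*. Genes with zero residual variance are excluded from the fit but are
still tested (their posterior variance is pulled to the prior). Trend and
robust variants of the fit are deliberately out of scope. Multiplicity is
controlled per dataset (both directions in one family) with the
Benjamini–Hochberg step-up procedure. DEGs are called at |logFC| ≥ 1 and
FDR ≤ 0.05 for per-dataset reporting; *signature mode* drops the
fold-change threshold and keeps only the sign, because a single
fold-change cutoff is not meaningful across heterogeneous platforms.
"Up" always means higher in the quiescent state.

**Competitive gene-set enrichment.** Per-gene scores are the
probability-integral transform of the moderated t to standard-normal
z-scores. For a set of *m* genes among *G* tested,

    z_set = (mean z in − mean z out) / ( sd(z) · √( VIF/m + 1/(G−m) ) )

with VIF = max(1, 1 + (m−1)·ρ̄) and ρ̄ the mean pairwise Pearson
correlation of the member genes' group-centred residual rows (0 when no
residual matrix is supplied, with a warning). Two-sided normal p-values
are BH-corrected across the tested sets; sets smaller than 5 genes after
restriction to the measured genes are skipped. ρ̄ is computed by direct
O(m²) pairwise correlation — at desk-scale compendia the low-rank shortcut
is an optimization, not a semantic choice. The VIF floor at 1 keeps
negative average correlations from anti-inflating the variance.

**Over-representation analysis (ORA).** The consensus up- (or down-) list
is tested against each gene set with the one-sided Fisher exact test
(hypergeometric upper tail P(X ≥ k)), BH-corrected. The universe is the
intersection of genes measured in all ensemble datasets — the only genes
eligible to appear in the signature.

## Multi-set analysis

Signature-mode DEG sets per dataset feed four steps:

1. **Similarity** — pairwise Jaccard index (|A∩B|/|A∪B|; 0 for two empty
   sets, logged) per direction, with complete-linkage hierarchical
   clustering on Euclidean distances between the similarity-matrix rows
   (clustering on 1 − JI directly is available behind a flag).
2. **Intersection landscape** — for every degree *k* from 2 to the
   number of datasets *K*, all C(K, k) subsets are enumerated (capped at
   K = 20; an error beyond, never a silent heuristic) and the best subset
   maximizes the **summed** up+down overlap (per-direction objectives
   behind a flag; the summed objective is a declared convention).
   Ties break toward the lexicographically smallest dataset-id tuple.
   Each record carries the expected intersection N·∏(nᵢ/N) and an
   upper-tail p-value: exact hypergeometric for two sets; for more sets a
   binomial tail with per-element joint probability ∏(nᵢ/N). The binomial
   form is a declared approximation — elements of the background are
   exchangeable with that marginal probability but weakly negatively
   dependent, so it is accurate near the mode (validated against Monte
   Carlo at the reference configuration) and conservative deeper in the
   upper tail at small N.
3. **Significance ranking** — three independent pass/fail gates decide
   ensemble membership: total DEG count ≥ 300 (a dataset with only a few
   hundred DEGs collapses every intersection it joins); ≥ 50% of a
   configured known-marker list present among the up-DEGs; and mean
   off-diagonal Jaccard similarity (up/down averaged) at least half the
   grand-mean off-diagonal similarity — an adaptive cut separating
   datasets that agree with the bulk from stragglers. Each criterion is
   independently disableable and every number used is reported. The gates
   are declared defaults, not a reconstruction of any particular weighting.
4. **Consensus signature** — the intersection of the ensemble's up
   (respectively down) DEG sets, sorted; provenance (ensemble, thresholds)
   embedded. Signature genes matching a user-supplied suspect list
   (isolation-stress immediate-early genes such as the Fos/Jun families)
   are **flagged, never silently kept or removed** — procedural isolation
   artifacts are reproducible across studies and therefore survive
   intersection, so they must be surfaced to the analyst.

**Enrichment summary network.** Per-dataset enrichment calls are coded
into a set × dataset matrix (+1 up, −1 down at FDR ≤ 0.05, else 0). Nodes
of the overlap network are sets enriched at least once (enrichment count,
dominant direction by summed codes with ties → "Mixed", optional top-k
anchors per direction); edges connect sets whose shared-gene fraction
reaches 10%. The denominator of "fraction shared" is the **smaller set**
by default (union- and larger-set conventions behind a flag; the choice is
recorded in the output) — the wording "sharing 10% of their genes" is
ambiguous and the min-denominator reading is the most inclusive.
The binary gene × significant-set ORA membership matrix is emitted with
the count of signature genes covered by no known set.

## Synthetic compendium generator

The generator emulates the statistical structure such a meta-analysis
faces, with full ground truth:

- **Shared signature**: 200 up / 500 down genes with per-gene |log2FC|
  drawn once from a folded Normal(2.0, 0.25) and re-scaled per dataset
  (default scale factors ~U(0.9, 1.4)) — consensus genes are, by
  construction of the target, strongly differential in every study, so the
  gene-to-gene spread is modest while the per-dataset scale heterogeneity
  is large.
- **Dataset-private DEGs**: 150 per dataset, random sign, same magnitude
  distribution.
- **Contaminants**: 20 genes up-shifted in the QSC group of *every*
  dataset, mimicking isolation-induced immediate-early genes; magnitudes
  from the same effect distribution.
- **Correlation**: genes are partitioned into latent blocks (default 50
  genes); residuals are noise_sd · (√ρ·f_block + √(1−ρ)·ε) with
  independent standard-normal factors per block and sample, giving exact
  within-block correlation ρ (default 0.1) — the simplest mechanism
  matching the competitive test's assumptions.
- **Replication and noise**: 3–6 replicates per group per dataset,
  additive Gaussian noise (SD 0.5) on the log2 scale, per-dataset
  baselines ~U(6, 12).
- **Markers**: six designated quiescence markers planted among the shared
  up genes, with the reserved identifier prefix `MKR` so tests are
  self-describing.

The benchmark scenario (`benchmark_spec`) uses eight datasets, two of
which get effect scale 0.12 — too small for any DEG or marker to be
called — planting exactly the exclusion decision the significance ranking
must make. What the generator does **not** model: probe-level effects and
raw-array normalization artifacts, batch effects beyond per-dataset scale,
heavy-tailed or intensity-dependent noise, and missing genes per platform
(all datasets share one namespace). Passing tests therefore demonstrate
correctness of the statistical machinery and the selection logic under a
clean Gaussian compendium, not robustness to every pathology of real
arrays.

## Numerical choices and degenerate inputs

- Zero-variance genes: t = 0 and p = 1 when logFC is also 0 (never NaN);
  ±∞ with p = 0 only in the unshrunken d₀ = 0 corner.
- z-score transform computed tail-first on the observed sign so extreme
  statistics map to finite large z rather than saturating the CDF; tails
  clipped at 1e−300.
- Quantile-normalization ties: tied values receive the mean of their
  target order statistics; the transform is idempotent.
- Empty-set Jaccard = 0 by convention (logged). Degenerate ORA tables
  (set = query = universe) give p = 1.
- All writers use fixed column order and `%.10g` float formatting;
  identical config + seed reproduces every output byte-identically, and
  manifests record a SHA-256 per output file.

## Calibration findings and known limitations

- The moderated t holds its nominal level on a null compendium (type-I
  error ≈ 0.05 at α = 0.05; p-values uniform by KS).
- The VIF-corrected competitive test is validated on null compendia with
  ρ = 0.1, sets of 10 genes aligned to correlation blocks and 8v8
  replicates: level ≈ 0.065 at α = 0.05 versus ≈ 0.15–0.35 uncorrected.
  The plug-in VIF is estimated per set from few residual degrees of
  freedom, and its sampling noise enters the denominator, so the test is
  measurably anti-conservative for larger sets and smaller samples
  (~0.07 at m = 20, ~0.074 at m = 50 with 8v8; worse at 3v3). This is a
  property of estimated inter-gene correlation in competitive tests, not
  of this implementation; it is one reason the workflow treats
  per-dataset enrichment as descriptive and bases the signature on
  cross-dataset intersection of gene-level calls.
- The multi-set intersection p-value for ≥ 3 sets is the exchangeable
  binomial approximation: accurate near the expected overlap, increasingly
  conservative deep in the upper tail for small backgrounds. For two sets
  it is exact.
- The intersection landscape is exhaustive; with the default objective the
  best combination maximizes up+down jointly, which can differ from
  per-direction optima (both are computed on request).
- Problem sizes used in the shipped studies (6000-gene, 8-dataset
  benchmark; 2000-gene null compendia) were chosen as the smallest sizes
  at which the planted structure and the calibration targets are measured
  with comfortable precision.
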