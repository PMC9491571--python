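# Methods

## The selection statistic

For a cohort with case set $C$ (fusion-positive tumors, $|C| = 7$ by default)
and control pool $P$ (tumors with reference-gene expression strictly below the
median of the non-case tumors), the screen draws $B = 100$ control sets
$S_1, \dots, S_B$ of size 50 uniformly without replacement from $P$ and
computes, for every gene $g$,

$$ T(g) \;=\; \operatorname{median}_{b=1..B}\, \bigl| r\bigl(x_g[C \cup S_b],\; x_{\mathrm{ref}}[C \cup S_b]\bigr) \bigr| $$

where $r$ is the sample Pearson correlation on $n = 57$ observations. Genes
with $T(g) > 0.2$ (strict) are selected; records are ranked by decreasing
$T$ with a lexicographic gene-ID tie-break. Medians over an even number of
values are the mean of the two central order statistics. A zero-variance
vector in any resample contributes $R = 0$ with a degenerate flag rather than
being dropped, so every gene's $R$-vector keeps length $B$. Correlation is
computed on the expression values as given ("none" transform, the default);
$\log_2(x+1)$ is available as an option.

## Permutation calibration

The $R$ cutoff is calibrated by $10^5$ permutation tests. Each test draws a
gene uniformly with replacement, randomly reorders its values across the
cohort samples ($C \cup P$), and recomputes a null selection statistic:

- **single** mode: one $|r|$ on one randomly chosen case+control set — the
  literal single-test reading. On iid Gaussian data this reproduces the
  closed-form Pearson null tail
  $2\,(1 - F_t(0.2\sqrt{55}/\sqrt{1-0.04};\,\mathrm{df}=55)) = 13.6\%$
  at cutoff 0.2 (verified in the acceptance tests to Monte-Carlo precision).
- **full** mode (default): the complete statistic $T$ over the same $B$
  resample sets the real screen uses, so calibration mirrors selection
  exactly.

Reported per cutoff is the fraction of null statistics strictly exceeding it.

### Why the full-mode rate does not reach sub-percent levels

One might expect the median over 100 resamples to concentrate the null
statistic far below the single-test rate. It does — but only when the
reference gene carries no leverage structure. In this design the reference is
*guaranteed* leveraged: the 7 cases are elevated (that is what defines them)
and the 50 controls come from the below-median pool, so within every
57-sample set most of the reference's variance sits on the case samples. For
a two-group-like reference the case slots carry $\approx 88\%$ of
$\mathrm{Var}(R)$. Since the cases are included in *every* resample, the
permuted gene's values at those 7 slots form a common component that the
median cannot average away: the full-mode rate stays within a factor of ~2 of
the single-mode rate. Empirically (default generator, $10^5$ permutations)
the full-mode false-selection rate at $R > 0.2$ is $\approx 6\%$; with a
leverage-free Gaussian reference the same machinery yields $\approx 2\%$,
matching the exchangeable-overlap calculation. The calibration TSV exposes
both modes so the discrepancy is a visible output, not a hidden assumption.
The same mechanism inflates the sampling-null selection rate of truly
uncorrelated genes in the screen itself, which is why the cutoff should be
read as a ranking device rather than a guarantee of sub-percent false
selection.

## Synthetic cohorts

`synthetic_data.generate_cohort` emulates a TCGA-style RSEM matrix:

- **Marginals** are log-normal: $x_{gs} = \exp(\mu_g + \sigma z_{gs})$ with
  $\sigma = 1.25$ (heavy right tail, non-negative values) and per-gene
  baselines $\mu_g \sim \mathcal N(6.0, 1.5^2)$, giving a median around 400
  normalized counts spanning several orders of magnitude across genes.
- **Case elevation**: the reference gene gains $\delta = 4.0$ natural-log
  units ($\approx 55$-fold) in the fusion cases — the order of magnitude a
  promoter-swap fusion produces — so all 7 planted cases pass the
  above-median elevation cross-check with $\approx 99.5\%$ probability.
- **Planted modules**: module gene $g$ with target correlation $\rho$ is
  generated on the latent log scale as
  $L_g = \rho L_{\mathrm{ref}} + \sqrt{1-\rho^2}\,\varepsilon$, where
  $L_{\mathrm{ref}}$ *includes* the case shift. Downstream genes thus respond
  to the realized reference level, as they would if the fusion drives the
  reference transcript which in turn drives its targets; module genes are
  co-elevated in cases by $\rho\delta$. The truth table records the latent
  $\rho$; the raw-scale Pearson R the screen sees is attenuated by the
  exponential marginal (for equal $\sigma$,
  $r = (e^{\rho\sigma^2}-1)/(e^{\sigma^2}-1)$), which is exactly the
  situation faced on real RSEM values.
- **Degenerate rows**: a configurable fraction (default 2%) of background
  genes is all-zero, exercising the degenerate-variance path downstream.
- **Clinical covariates** are drawn from the control-group composition of a
  fusion-negative colorectal cohort (sex, vital status, stage, MSI status,
  histology, five mutation flags), with per-variable missingness so that the
  per-variable denominators of the clinical comparison are exercised. Where
  the source table's printed percentages and counts disagreed (two cells
  appear swapped), the counts were taken as authoritative.

What the generator does *not* emulate: read-count noise, library-size or
batch effects, gene–gene correlation beyond the planted modules, per-gene
variance heterogeneity, and the zero-inflation of lowly expressed
transcripts. Passing tests therefore demonstrate the correctness of the
machinery and the qualitative behavior of the statistics — not that real
TCGA data would reproduce any specific gene list or rate.

## Exact clinical tests

Categorical Table-1-style variables are compared between cases and controls
with a two-sided Fisher exact test. For $2\times k$ tables the p-value is
computed by probability-ordered exact enumeration: all tables with the
observed margins are enumerated by recursing over the smaller row margin
(the 7-sample case group keeps this cheap), and the probabilities of tables
no more probable than the observed one are summed (tolerance $10^{-9}$ on
the log scale for ties). Age uses the Wilcoxon rank-sum test. Missing values
are dropped per variable and the per-variable denominators reported.

## Enrichment conventions

ORA uses the upper-tail hypergeometric probability $P(X \ge k)$ with the
pathway intersected with the universe first; the default universe is the
measured genes annotated to at least one pathway (annotated-background
convention of ORA web services), switchable to all measured genes.
Benjamini–Hochberg q-values are computed with the step-up rule; pathways
with $q < 0.05$ (strict) are significant, with $q < 0.2$ retained as a
documented alternative profile. The collapse of source pathways into named
cancer meta-pathways is consumed as an explicit two-column mapping — it is a
curation artifact, not reconstructible algorithmically — and a pairwise
Jaccard-overlap report is provided to assist such curation. Key genes
require the conjunction: census member, median $|R| > 0.3$ (strict), and
membership in $\ge 2$ meta-pathways.

## Drug-network conventions

Evidence tiers are never unified across sources (CIViC A–E and OncoKB 1–4
are ordered within source only). Gene roles resolve census-first; a
knowledgebase role is a fallback and conflicts are logged. Genes with
evidence that fails the prioritization scenario (for example an inhibitor of
an under-expressed oncogene) are kept as ordinary unprioritized edges, since
such "substitute" relations are still informative. The network build is a
pure function of its inputs with lexicographic node ordering, so exports are
byte-stable.

## Numerical and reproducibility choices

- Pearson correlations are clipped to $[-1, 1]$ against floating-point
  overshoot; vectorized screen and calibration paths are verified against
  naive `scipy.stats.pearsonr` loops in the tests.
- Z-score export uses the sample-SD convention (ddof = 1), mapping
  $[1,2,3] \mapsto [-1,0,1]$; constant rows map to zeros.
- One master seed derives per-stage seeds through `numpy` `SeedSequence`
  spawning; two runs with the same config are byte-identical, and every
  output file is checksummed in the run manifest.
- Default problem sizes follow the emulated study throughout (20,531 genes,
  433 samples, 7 cases, 100 × 50 resamples, $10^5$ permutations); the whole
  default chain runs in well under a minute, so no stage is scaled down.

## Known limitations

- The permutation-calibrated false-selection rate is leverage-dominated (see
  above): with an elevated-case reference the nominal sub-percent rates that
  a leverage-free analysis would suggest are not attainable, in either
  calibration mode. This is a property of the procedure, not of the
  implementation.
- Pearson R on raw RSEM values is outlier-driven under heavy-tailed
  marginals; rank-based alternatives are deliberately out of scope.
- The meta-pathway mapping is user-supplied; results downstream of the
  collapse inherit whatever curation it encodes.
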