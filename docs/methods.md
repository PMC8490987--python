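# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Study design

All stages assume a 2 × 2 factorial: compartment (somata, processes) ×
treatment (mock, PTX), with `n_replicates_rna = 2` RNA samples and
`n_replicates_protein = 4` protein samples per condition — the replication
structure of the compartmentalized-culture experiments the package
emulates.  The design matrix uses treatment-within-compartment columns
(intercept, processes, ptx:somata, ptx:processes).  This is an equivalent
reparameterization of intercept/compartment/treatment/interaction chosen
so that each contrast of interest — the PTX effect in somata, the PTX
effect in processes, the compartment effect under mock — is a single
coefficient, making every likelihood-ratio test a plain column drop.

## RNA differential expression

**Filtering.** A gene is expressed if its count is strictly greater than
`min_count = 20` in at least `min_samples = 2` samples; "more than" is read
literally, so a row of exact 20s is removed.  Compartment-specific
backgrounds for the enrichment stages apply the same rule within one
compartment's samples.  (The background could alternatively be read as
"two *conditions*"; with two replicates per condition the readings nearly
coincide, and the samples-based rule is well defined — the pipeline log
records this choice on every run.)

**TMM.** The reference sample is the column whose 75th CPM percentile is
closest to the mean 75th percentile (ties: lowest index).  Per sample,
M- and A-values over genes positive in both columns are doubly trimmed
(30% from each M tail, 5% from each A tail, rank-based) and the factor is
2^(weighted mean M) with inverse asymptotic binomial variances as weights,
rescaled to geometric mean 1.  Factors are invariant to depth rescaling of
a sample up to the (depth-dependent) weights, which tests treat as an
approximate invariance.

**Dispersion.** The NB dispersion phi is estimated by Cox–Reid adjusted
profile likelihood: APL_g(phi) = l_g(beta-hat; phi) − ½ log det(X'WX).
The common value maximizes the summed APL by golden-section search on
log10 phi in [−6, 1].  Gene-wise values maximize
APL_g(phi) + (prior_df / d_g) · mean-APL(phi) on a 25-point log grid —
a weighted-likelihood shrinkage toward the common curve with
`prior_df = 10` extra degrees of freedom.  No abundance trend is fitted;
at this design size (8 samples) a trended estimator would be
under-determined, and the simulator's dispersion is abundance-free.

**GLM and LRT.** Per-gene IRLS with log link, offsets log(lib · f),
weights mu/(1 + phi·mu), convergence at max |Δbeta| < 1e−8 or 50
iterations (non-convergence is flagged, coefficients still reported; the
linear predictor is clipped at ±30 and the normal equations carry a 1e−10
ridge for degenerate groups).  The LRT refits without the contrast column;
stat = max(0, 2Δl) against chi-square(1).  logFC is reported in log2
(the GLM is fit in natural log).  Genes with an all-zero group in the
contrasted pair get their *displayed* logFC from mean CPM with a
0.125-count prior; the test statistic is untouched.  logCPM is
log2(mean TMM-CPM + 0.5).

**Calls.** DE calls use q < 0.05 only; compartment-*enrichment* calls
additionally require |logFC| > 1.  The two rules follow the respective
figure conventions and are both configurable — differential expression
and robust enrichment are distinct claims.

## Proteomics

**VST.** Observed intensities x in sample j are transformed as
asinh(x / (1e−3 · median_j)): log-like over the bulk of the range,
linear near zero (the glog property that stabilizes low-intensity
variance), then columns are aligned to a common median and MAD.  This
replaces a full robust-ML affine calibration, whose estimator is out of
proportion to what the downstream inference needs; the per-sample median
scaling makes columns that differ by a pure dilution factor map to
identical values exactly.  A zero-MAD (constant) sample is an error.

**MinProb imputation.** Missing cells in sample j are drawn from
Normal(q-quantile of observed, width · SD of observed) with q = 0.01 and
width = 0.3 — the spirit of the standard MinProb default; width is
exposed because it is not dictated by anything.  Observed cells are never
altered; the draw is seeded.  A sample with fewer than 10 observed values
cannot support the quantile and errors out.

**Moderated statistics.** Per-protein OLS; the prior (d0, s0²) is
moment-matched on the log-variance scale (digamma/trigamma), with
d0 = ∞ when the spread of log s² does not exceed the trigamma floor;
posterior variances are the convex combination (d0 s0² + d s²)/(d0 + d);
t uses d0 + d degrees of freedom (normal when d0 = ∞; d0 = 0 reduces to
the ordinary t exactly).  Significance defaults to FDR < 0.5 — the
permissive convention of the emulated study, kept as-is for fidelity —
with 0.05 available by flag, and the recovery tests use 0.05.

## Integration

Spearman rho on midranks with the t approximation
t = rho·sqrt((n−2)/(1−rho²)), and Pearson r with the analogous t test;
constant vectors are errors, not NaNs.  Protein ids are mapped to genes
(identity by default), tables inner-joined, and significance paired at
the stage thresholds (RNA 0.05, protein 0.5).  The "synaptic genes"
subset is an input gene list; the synthetic fixture ships the planted
downregulated genes under that name.

## 3'UTRs and motifs

Per gene the transcript with the longest 3'UTR is kept (ties: smallest
transcript id) and records of length ≤ 20 nt are dropped.  Length
distributions are compared with the two-sample KS test (asymptotic p,
effective n = n_a n_b/(n_a + n_b)).

Motif enrichment is AME-style with a documented, reproducible threshold
rule instead of AME's internal partition maximization: sequences are
scored by the average odds score (N bases contribute odds 1; U maps to T;
sense strand only, since mRNA is single-stranded), candidate thresholds
are the 50–90% deciles of the background score distribution plus the
positive-set median, Fisher's exact (one-sided, positives vs background
excluding positives) is evaluated at each, the minimum p is Bonferroni
corrected by the number of thresholds, and BH runs across motifs.  Motif
files are MEME minimal format; the reader/writer round-trips matrices at
full precision and falls back to a uniform background if the file has
none.

## miRNA-binding sites

Families are restricted to those with a member miRNA expressed strictly
above the median of all detected miRNAs.  The enrichment universe is
site-level: x/n (family/all sites over the set) vs K/N (over the
compartment background), upper-tail hypergeometric, log2FE with a 0.5
pseudocount.  The site-token model treats sites as exchangeable draws
without replacement; counts generated independently per gene make the
test mildly anticonservative in principle, but the joint call rule
(p < 0.05 AND log2FE > 0.5) keeps null flag rates well below 5% (measured
by the null-calibration test).  A gene-level variant (genes with ≥ 1
site) can be built from the same table if needed.

The Fig-style up/down comparison uses per-gene-normalized site densities,
log2((sites_down + 0.5)/|down| ÷ (sites_up + 0.5)/|up|), oriented so
positive = more sites in downregulated transcripts; normalizing by set
size makes ratios comparable when the up and down sets differ in size.
Families with fewer than `min_total_sites = 10` sites across both sets
are excluded — a minimum-evidence floor standing in for an unstated
selection rule.  Compartment ratio distributions are compared with the
two-sided Mann–Whitney U (exact for small tie-free samples, midrank
normal approximation otherwise).

## GO

is_a edges only; annotations are closed over ancestors (idempotent;
cycles are errors) and tested per term with the classic one-sided
hypergeometric against the compartment background.  Terms annotating more
than `max_annotated` background genes are removed *before* testing
(defaults 1000 for CC and 300 for BP in the compartment analysis, 500 for
proteomics); BH runs per namespace on the surviving terms, and the top-k
(default 5) records are reported sorted by fold enrichment —
"enrichment" is taken to mean observed/expected.  The elim/weight
decorrelation heuristics of topGO-style tools are deliberately not
implemented: on synthetic DAGs the classic test already ranks the planted
term first, and those heuristics would dominate the engineering cost.
This is a declared limitation for real, deep GO graphs.

## The synthetic generator

What it emulates: the 2 × 2 design with the replication above; NB counts
whose per-sample gene fractions renormalize the planted log2 abundances
(so planted effects also induce composition shifts that TMM must absorb);
log-normal protein intensities with planted effects coupled to the RNA
effects at correlation rho (protein effect = rho · RNA effect +
sqrt(1−rho²) · noise) plus MNAR missingness concentrated in the lowest
intensities; mutually exclusive treatment categories (down/up in exactly
one compartment) so "exclusively regulated" sets exist by construction;
log-normal 3'UTR lengths with i.i.d. background sequences and one exact
consensus insertion per motif-positive gene; Poisson site counts per
(gene, family) with the active families' rate multiplied in process-down
genes; a three-namespace toy GO DAG with one planted BP leaf.

Key defaults and their grounds: baseline log2 CPM uniform on (2.5, 9.5)
and library sizes 1.5–2.5 M (a filtered bulk matrix of moderately
expressed genes); dispersion 0.05 (BCV ≈ 0.22, typical of primary-culture
replicates); treatment |log2FC| 1.5 and compartment |log2FC| 2 (clear but
not extreme effects); protein replicate SD 0.3 on log2 (typical label-free
precision); `missing_intensity_scale = 0.05` with the MNAR centre at the
5th intensity percentile, yielding ~95% complete proteins — matching the
structure of the deep label-free dataset the generator emulates; 30 miRNA
families at 0.3 sites/(gene·family) and a 4× active-family multiplier;
RNA–protein effect correlation 0.8.  Site counts are simulated directly
as Poisson draws rather than by scanning sequences, because the
enrichment stage consumes counts, not positions.  One global seed; every
stage derives a child generator from (seed, stage-name CRC), so universes,
counts, intensities and sequences are individually reproducible.

What it does *not* emulate — and what passing tests therefore do not
show: genomic sequence composition and real 3'UTR isoform structure,
abundance-dependent dispersion trends, correlated gene programs,
peptide-level roll-up noise, batch effects, or annotation-version
ambiguity.  Recovery on this generator demonstrates that the statistical
machinery is correct and calibrated, not that the biological conclusions
of any particular dataset would reproduce.

Problem sizes in the tests and acceptance script (2,000 genes for null
calibration, 1,000 genes × 10 seeds for recovery at 4 replicates/group,
4,000 genes × 10 families for the binding-site recovery, 700 genes × 21
motifs for motif recovery) are the package's chosen working sizes: large
enough that binomial error on the measured rates is small against the
acceptance margins, small enough to iterate on quickly.  Recovery tests
that raise the replicate number beyond the study design document their
own n.

## Known limitations

- The dispersion estimator is untrended; data with a strong
  mean-dispersion relationship would be better served by a trended fit.
- The VST is a calibrated glog, not a full affine-ML fit; columns with
  radically different dynamic ranges are aligned only up to median/MAD.
- MinProb imputation biases effect estimates for proteins whose
  missingness is informative; at the default (sparse, low-intensity)
  missingness this is negligible, at high missingness it is not.
- Classic GO testing inherits the DAG's statistical dependence between
  ancestors and descendants; parent terms of a truly enriched leaf will
  co-rank.
- The AME threshold grid is coarser than AME's exact optimization; p-values
  are conservative by construction (per-motif Bonferroni over the grid).
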