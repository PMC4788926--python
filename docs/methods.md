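# Methods

## Comparative-CT preprocessing

Raw data are cycle-threshold (CT) values from qRT-PCR array cards, one per
(gene, sample); higher CT means fewer transcripts. Samples carry a
perturbation label (a silenced gene, or the calibrator-siRNA control), a time
point, a phase and a biological-replicate index. The phase is a deterministic
function of time under the configured schedule — by default samples taken
after 8 h belong to the wash-out phase (the stimulus is applied at 0 h and
removed at 8 h, so 0/2/8 h are stimulation and 12 h is wash-out) — and the
constructor enforces the consistency. CT values must lie in [0, ct_max]
(default 40 cycles, the usual instrument ceiling); non-numeric entries such
as the instrument's "Undetermined" become MISSING.

The normalisation reference is chosen among the housekeeping candidates as
the gene with the smallest pooled standard deviation of raw CT across all
samples (every condition, time point and replicate together), ties broken by
candidate order. This operationalises "most stable across conditions" with
the simplest defensible statistic; the score table is returned so users can
substitute a different criterion.

ΔCT = CT_gene − CT_reference within a sample. ΔΔCT subtracts the control:
by default knockdown replicate i is paired with control replicate i at the
same time point, preserving K independent ΔΔCT values per cell for the
variance model; a `mean_control` policy (subtract the control-stratum mean
ΔCT) is available behind a switch for designs without a meaningful replicate
pairing. Any MISSING CT in a required term removes that replicate's ΔΔCT and
reduces K — no imputation. Cells with K = 0 are dropped and counted.
Summaries carry the replicate mean, the sample variance (K − 1 denominator,
undefined when K < 2), K, and the fold change 2^(−mean ΔΔCT).

The 0 h (pre-stimulus) time point is retained in the tables but excluded
from significance testing by default: before the stimulus is applied there
is no response for a modulator to modulate.

## Measurement-error model

The biological replicate variance of ΔΔCT is modelled as a function of the
signal magnitude,

    σ̂²(x) = α + β·|x|^γ,    α, β ≥ 0,  γ ∈ [0, 4],

which spans constant variance, variance growing linearly with |ΔΔCT|, and
saturating or accelerating power laws. The parameter bounds keep the
variance surface non-negative and non-decreasing in |x|; the γ ceiling of 4
merely prevents the optimiser wandering into absurd exponents and is
configurable.

Per-cell records (|mean ΔΔCT|, sample variance) from all silencing
experiments are pooled (per-experiment fitting is available), sorted by
|ΔΔCT| and averaged in equal-count bins (default 10 bins, at least 3 records
each; the division remainder goes to the leftmost bins). Fitting on binned
means rather than raw per-cell variances tames the enormous sampling noise
of a K = 2 sample variance; a raw mode exists for sensitivity analysis.
Because mean and sample variance of normal replicates are independent, bin
averaging introduces no bias under the null.

Weighted least squares uses the bin counts as weights — the natural choice
for points that are averages of different numbers of records; the weight
vector is swappable. Four nested variants are fitted:

| variant  | free parameters | constraint |
|----------|-----------------|------------|
| constant | α               | β = 0      |
| linear   | α, β            | γ = 1      |
| power    | β, γ            | α = 0      |
| full     | α, β, γ         | —          |

The constant fit is closed-form (the count-weighted mean of bin variances);
the rest use bounded trust-region nonlinear least squares (`scipy`'s
`least_squares`, tolerances 1e-14) with asymptotic standard errors from the
weighted Jacobian. Model choice: among converged fits whose every free
parameter has coefficient of variation ≤ 0.5, the smallest weighted residual
sum of squares wins, with fewer parameters breaking ties; if no fit passes
the precision screen the most parsimonious converged fit is returned flagged
`degraded`. One extra screen matters in practice: the selected model feeds a
null-hypothesis test evaluated at ΔΔCT = 0, so a fit that predicts zero
variance there (the zero-offset power law with γ > 0) is compared and
reported but never selected as the testing model.

## Two-stage selection

Within each silencing experiment:

1. **Variance filter.** Cells whose replicate sample variance strictly
   exceeds the 95th percentile of the experiment's variance distribution are
   removed as unstable measurements. The percentile is nearest-rank (the
   value at ascending rank ⌈q/100·n⌉), so the filter is exact and
   platform-independent: with n a multiple of 20 and distinct values,
   exactly 5% of cells are filtered. Ties at the threshold are retained.
   With fewer than 20 defined variances the percentile is meaningless; the
   filter is skipped with a warning. Cells with undefined variance (K < 2)
   cannot be filtered and proceed to testing.
2. **Model-based z-test.** For each remaining (gene, time point), under
   H0: ΔΔCT = 0 the replicate-averaged ΔΔCT is N(0, σ̂²/K) with σ̂² the
   *model-predicted* variance at the observed mean — never the cell's own
   sample variance, whose two-replicate estimate is far too unstable to
   standardise a test statistic. This exchange of per-cell variance for a
   smooth fitted variance is the procedure's central idea. p-values are
   two-sided (both down- and up-regulations are of interest).
3. **Bonferroni correction.** p_adj = min(1, m·p) with m the number of
   tests actually performed in that experiment (post-filter; a pre-filter m
   is available). Significance at p_adj ≤ 0.05. Bonferroni controls the
   family-wise error rate, appropriate when each call may trigger wet-lab
   validation.

The silenced gene's own cells trivially reflect the knockdown and are
excluded from target calls; they are reported separately as a
knockdown-efficiency diagnostic. Directions: significant with mean ΔΔCT > 0
is a down-regulation under silencing, < 0 an up-regulation.

Per-modulator summaries report strength (distinct significantly regulated
genes), sign (positive when more than half the regulated genes go down upon
silencing — the modulator was activating them — negative below half, mixed
at exactly half; wash-out-only genes carry no sign and never count as
down-regulations) and timing (significant calls per time point and phase).

## FFL inference

From the calls of ≥ 2 silencing experiments:

1. select ordered pairs (P1, P2) where silencing P1 significantly changes
   P2 (mutual regulation emits both orientations, flagged as a
   near-feedback situation);
2. intersect their significant target lists (panel order, excluding the
   regulators themselves);
3. each shared target closes one FFL P1→P2, P1→Z, P2→Z; edge signs follow
   the down⇒activation / up⇒repression rule;
4. merge the component FFLs of a pair into one multi-output module
   (1 + 2·n edges over 2 + n nodes).

Phase annotation: an edge backed by any stimulation-phase call is a
stimulation edge and its sign comes from the earliest significant
stimulation time point (a direction conflict across stimulation time points
is flagged on the edge); edges seen only in the wash-out phase keep an
unspecified sign, since after stimulus withdrawal the direction of the
residual regulation is not interpretable. A pair with no shared target
yields no module — an isolated P1→P2 edge is not an FFL — but is listed in
the inference report. Exports: SIF, GraphML (sign/phase/p_adj/fold-change
edge attributes) and DOT (solid = stimulation, dashed = wash-out), all
byte-deterministic for identical inputs.

## Synthetic screens

The generator emulates the target study design: 96 genes of which 3 are
housekeeping candidates, knockdown and calibrator-control conditions for
each silenced gene, time points 0/2/8/12 h (wash-out after 8 h), K = 2
biological replicates, and constant ΔΔCT replicate variance 0.3975 cycles²
as the default noise model. Baseline CTs are uniform in 18–30 cycles.
Planted regulations are ΔΔCT shifts of a target under a knockdown at chosen
time points (default 2 and 8 h, magnitude 3 cycles); `plant_ffl` assembles
the shifts that encode a whole signed module. Each knockdown also shifts its
own transcript by 4 cycles so the knockdown-efficiency diagnostic has
something to see.

Noise placement: the variance model lives at the ΔΔCT level, but noise must
be injected on CT values. Since the reference and housekeeping terms are
kept near-noiseless (they model stably expressed genes), the gene-CT noise
variance is v(0)/2 in control samples and v(shift) − v(0)/2 in knockdown
samples, which sums across the two gene terms to exactly
Var(ΔΔCT) = α + β·|shift|^γ for every monotone member of the family. An
equal four-way split across the CT terms would be incompatible with
noiseless housekeeping genes, which is why this asymmetric split is used.

What the generator does *not* emulate: amplification-efficiency differences
between assays, correlated plate effects, missing-value mechanisms tied to
low expression (MISSING cells must be introduced explicitly), or genuine
transcription dynamics (planted effects are constant within their active
time points; no kinetic simulation). Passing tests therefore demonstrate the
statistical machinery under the stated error model, not robustness to every
real-world artefact of qRT-PCR data.

## Numerical choices and edge cases

- Percentile definition pinned to nearest-rank; "strictly exceeds" taken
  literally, so degenerate all-equal variance distributions filter nothing.
- Reference-gene ties broken by candidate order; all tie-breaks in module
  and target ordering follow the input gene panel, making exports
  byte-reproducible.
- The z-test returns z = 0, p = 1 at mean ΔΔCT = 0; predicted variance ≤ 0
  raises a model error rather than silently producing infinite statistics.
- Optimiser non-convergence raises a fit error carrying the best iterate;
  the multi-variant fitter skips such variants rather than selecting them.
- Problem sizes in the test suite (1000-screen null studies, 200-run
  recovery studies, 500 random matrices for the brute-force equivalence
  check) were chosen to give stable Monte-Carlo estimates at interactive
  runtimes.

## Known limitations

- No amplification-efficiency correction or standard-curve quantification:
  the comparative-CT method assumes near-100% efficiency for all assays.
- Only the multi-output FFL motif is reconstructed — no bi-fans, cascades
  or motif-frequency enrichment statistics.
- Inferred edges are influence relations; with a ~100-gene panel a
  regulation may be mediated by unmonitored genes, so edges are putative
  direct-or-indirect regulations pending validation.
- Bonferroni within each silencing experiment is conservative; no FDR
  alternative is wired into the default path.
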