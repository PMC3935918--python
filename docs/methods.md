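# Methods

## Steady-state lifecycle model

The model treats a gene as N+1 exons separated by N introns, transcribed
continuously at a uniform rate `1/Tα` (default 60 bp/s; `Tα = 1/60` s/bp).
Transcription initiates at a constant rate, each intron is spliced
independently in two steps — 5′-splice-site cleavage (lariat formation,
`T5` seconds after the intron is fully transcribed) and 3′-splice-site
cleavage with exon ligation (`T3` after that) — the excised intron survives
a further `Tγ`, and the mature mRNA, whose clock starts when the last exon
pair is ligated, survives `Tμ`. At steady state a feature's normalized read
density equals `c0S` times its mean total lifetime, where `c0S` fuses the
initiation rate with the sample's density-per-transcript constant (only the
product is identifiable).

Mean lifetimes decompose into the shared processing times plus a
transcription waiting time fixed by gene geometry. Waiting times are
averaged per base and then length-weighted across features of a class
(total read-bases over total bases), which makes squared lengths appear:
`T_t,INT = Tα·ΣL_i²/(2·ΣL_i)`. The last exon carries a negative lag of half
its own length because its bases are born after the mature-mRNA clock
starts; junction features use equal effective lengths `σ = r−1` (read
length r), so their class averages are simple means. Assumptions worth
stating: no locus-specific pausing (uniform elongation), steady state (no
induction transients), splicing strictly intron-autonomous, and lariat
degradation that does not reshape the intron profile (the supplementary
lariat-degradation variants I/IIa/IIb/IIc/III quantify how 3′→5′ or 5′→3′
exonucleolysis at various speeds would change the intron-end density
difference while leaving splice-site differences untouched).

## Slope estimation and filtering

Each intron is divided into 100 equal bins; ordinary least squares on the
nonzero bins gives the slope (expected `−c0S·Tα` in transcription
direction), its standard error, and a goodness-of-fit summary
`TDR = 1 − Φ(slope/SE)`. Introns qualify with ≥ 20 nonzero bins, length
≥ 5 kb, and (separately switchable) a start more than 5 kb from the TSS,
where promoter-proximal pausing would bend the profile. A bin more than
10× the median nonzero density is treated as a spike (embedded ncRNA) and
dropped; an intron with more than 5 spike bins is discarded. Gene-level
slopes are the arithmetic mean of qualifying intron slopes with a
quadrature error weighted by `L_i·TDR_i²`; genes enter the solver cohort
with `TDR_g ≥ 0.90`, mean intron density ≤ 1.00, mean exon density ≤ 50,
coding only.

## Monte Carlo inversion

Samples of 5 eligible genes are drawn without replacement; each gene's
slope is perturbed by a Gaussian with its fitted SE (a perturbed slope ≥ 0
is redrawn up to 100 times, then the sample is discarded); `c0S` is the
geometric mean of |slope|/Tα; feature densities are aggregated by geometric
mean over nonzero values (a feature class with all zeros discards the
sample). The 4×4 linear system is then solved in closed form and solutions
with any negative time are rejected; drawing continues until 2,000 valid
solutions or 200,000 samples. Summaries report geometric means, medians and
percentile intervals, since accepted distributions are close to log-normal.

**Waiting-time aggregation.** A sample's genes share `T` but not geometry,
so the geometric density aggregation measures `geomean_g(T_t,g + o_f)`,
where `o_f` is the gene-shared combination of processing times entering
feature f. Subtracting `geomean_g(T_t,g)` — the obvious symmetric choice —
systematically inflates every solved time on heterogeneous cohorts (the
geometric mean is superadditive under a shared shift; we observed ~1.9×
inflation of T5 and Tγ). The default "matched" aggregation instead
Newton-solves `geomean_g(T_t,g + o_f) = D_f/c0S` for `o_f` per feature —
a strictly monotone 1-D root — which is exact on noiseless cohorts of any
geometry and identical to the plain rule when geometry is homogeneous.
Plain `geometric` and `arithmetic` aggregation remain available in
`MonteCarloConfig`.

## Synthetic cohorts

The generator is the package's test bed: it draws gene structures, places
them on linear chromosomes, evaluates the closed-form densities, and adds
counting noise. Defaults (changeable per experiment):

| parameter | default | rationale |
|---|---|---|
| introns per gene | Poisson(10), min 1 | the slope-informative cohort is long multi-intron genes; meta-intron analyses require ≥ 10 introns |
| intron length | log-normal, median 15 kb, σ=0.8 (ln) | usable introns must exceed 5 kb; long introns dominate slope information (SE ∝ L^−3/2) |
| internal exons | log-normal, median 150 bp | typical vertebrate exon |
| last exon | log-normal, median 1 kb | long 3′UTRs |
| c0S | log-normal, median 0.1 min⁻¹, σ=0.5 decades | a typical simulated gene is a well-expressed (~30 RPKM exonic) gene at the 10M×35 bp standard depth — the regime the method targets |
| processing times | T5=90, T3=45, Tγ=25, Tμ=7200 s | reference truth used throughout the tests |
| depth | 10M reads × 35 bp | the standard library the densities are normalized to |

Counting noise is Poisson on **read-bases per bin** (density × bin bp ×
depth scale), applied independently to every exon, intron bin, junction
window and 3′-intron window; noiseless mode returns exact expectations, and
an optional read-level emitter produces alignment tables for end-to-end
I/O tests. The generator can plant structure: a bimodal (or off/low/high)
synthesis-rate mixture, enrichment of low-mode genes adjacent to high-mode
genes, retained introns (intron and splice sites emitted with the mRNA
lifetime), and non-consecutive splice events at a configurable rate.

What the simulator does **not** model: sequence-composition library bias,
mappability holes, fragment-level correlations (read-base Poisson
understates the variance a read-granular process would have),
alternative isoforms beyond the two toggles above, and pausing. Passing
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions plus counting noise — not robustness to the
library-preparation biases that dominate real data.

## Meta-intron profiles

Introns longer than 50 kb from genes with ≥ 10 introns are aligned at
their 3′ ends and aggregated positionwise (mean by default, median by
flag) on a fixed 100-bp position grid; each intron's 100-bin profile is
resampled onto the grid by linear interpolation with linear extrapolation
at the window edges, which is exact for the model's linear profiles. An
OLS line through the aggregate gives the base (intercept at the 3′
terminus, `c0S·Tp`) and blade (drop across the window, `c0S·Tα·W`).
Condition comparisons report per-feature-class read-fraction fold changes
(library size cancels) and paired t-tests of base/blade across intron
ordinals 2–10.

## Bimodality and neighborhoods

Genes below a detection floor (default: the density of one 35-bp read over
a 10-kb window at the standard library, ~3.5×10⁻³) are "off"; the rest are
split low/high by a two-component Gaussian mixture on log10 density with
the posterior-0.5 boundary. Bimodality is diagnosed by the dip of the
kernel-smoothed log-density between the component means (ratio < 0.95 of
the smaller peak, both weights ≥ 5%); absent a dip the cohort is reported
unimodal and not split — the boundary defines low/high because an absolute
mRNA-per-cell cut is not computable without `c0`. Distances are
TSS-to-TSS within chromosomes; the neighbor permutation test permutes mode
labels over genes (adjacency fixed) and reports
`p = (1+#null ≥ obs)/(1+iterations)`, stratified by gene-pair orientation
(head-to-tail = same strand, tail-to-tail = convergent, head-to-head =
divergent). The tissue-transition control keeps the low→off gene set and
randomizes which tissue counts as "before", so its expectation is
`(f_increased + f_decreased)/2`; ties (nearest high expressor unchanged)
count for neither.

## Numerical choices and problem sizes

Time is seconds internally; densities are unitless standard-library
densities (÷0.35 → RPKM). The matched-offset Newton solve runs 40 damped
iterations with the domain floor `o > −min(T_t)`; noiseless round trips are
exact to ~1e−12 relative. The counting-noise experiment uses a 3×3×3 grid
(L ∈ {1, 10, 100} kb, Tp ∈ {6, 60, 600} s, depth ∈ {10M, 100M, 1000M}
reads) with 50 replicates per cell and `c0S = 1` min⁻¹, and fits slopes
over all 100 bins (zeros included) so sparse cells still yield estimates;
error orderings in Tp are assessed where processing dominates the intron
signal (1-kb introns) and on the grid marginal, because at L = 100 kb the
transcription term `TαL/2 ≈ 833 s` swamps the Tp range and the ordering is
not resolvable at 50 replicates. Test and validation cohorts use 300–2,000
genes; the recovery experiment (2,000 genes at 10M reads) and the
inhibition experiment (2×300 long-intron genes) each run in seconds on one
CPU.

## Known limitations

Single-gene inversion remains out of reach at standard depth — the method
produces cohort-level distributions, not per-gene times. T5 estimates are
upper bounds in the presence of exon skipping; retained or shortened
introns are filtered by the splice-site-density rule rather than modeled.
The mappability index uses exact k-mer uniqueness (no mismatches), which is
stricter than a real aligner. The transition chi-square treats genes as
independent, ignoring spatial correlation along chromosomes.
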