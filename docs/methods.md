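# Methods

## Study design emulated

Two chicken lines divergently selected for residual feed intake (R+, R−)
are sampled in a feed-deprived state (FD, 16 h fast) and after re-feeding
(RF).  Sequencing: 12 plasma small-RNA libraries (2 lines × 2 conditions ×
3 birds, each bird sequenced in both conditions).  qPCR validation: a
panel of six miRNAs on 8 R+ and 7 R− birds, each measured in both
conditions, collected in two batches; a liver design uses different birds
per condition and no batch structure.  All synthetic generators default to
these sizes.

## Hairpin partitioning

Dot-bracket pairs are recovered with a stack.  The terminal loop is the
open interval strictly between the partners of the innermost base pair of
the main stem, found by following the chain of singly-nested helices from
the outermost pair; bulges and external unpaired bases therefore belong to
the arms.  A structure whose nesting branches (two or more sibling
helices) is rejected as not-a-hairpin unless `force_main_stem=True`, which
follows the branch with the most base pairs (tie: 5′-most).  Canonical
pre-miRNAs are single stems, so rejection is the safer default.

Arm labels for intervals (matures and reads) use majority base overlap.
Exact ties never go to the loop, because a loop label is destructive
(loop reads are excluded from quantification and count against the
hairpin in the 3∶1 filter); between the arms the side holding the
interval's 5′ end wins.  Matures with a loop-majority overlap are labelled
`loop_spanning`.

## Read preparation

Quality trimming precedes adapter search and uses the standard running-sum
rule at Q20 (neither the algorithm nor the cutoff is dictated by the
study design; these are the common trimmer defaults and are exposed as
parameters).  The adapter search scores every 3′ occurrence including
terminal partial overlaps, requires overlap ≥ 3 and mismatch fraction
≤ 0.1, and keeps the occurrence with the lowest mismatch rate (ties:
longer overlap, then leftmost).  Only single-end 3′-ligated libraries are
supported; there is no 5′ adapter or UMI handling.

## Quantification policies

The aligner reports all forward-strand hits at Hamming distance ≤ 1 (the
library protocol is stranded); when a read has any exact hit, its
1-mismatch hits are dropped.  The 3∶1 arm:loop filter pools collapsed-read
multiplicities across libraries by default (per-library filtering is a
flag); a hairpin exactly at 3∶1 is retained.  Reads are assigned to the
same-arm mature with the largest overlap, requiring ≥ 10 shared bases; a
read hitting several redundant precursors that carry the same mature name
counts once for that name (this prevents double counting across paralogous
precursor families).  Novel matures need a read cluster (mutually
overlapping intervals) totalling ≥ 5 reads on an unannotated arm; the
novel interval is the modal (highest-count) read interval, and the name
swaps the opposite-arm mature's `-5p`/`-3p` suffix or falls back to the
precursor id plus the arm suffix.  The 10-base and 5-read minimums are
robustness choices, both configurable.  The genome/other-ncRNA/cDNA
cascade reuses the same ≤ 1-mismatch aligner, so "first reference wins"
semantics are exact at desk scale.

## Normalization and filtering

TMM factors follow the doubly-trimmed (30% on M, 5% on A),
inverse-asymptotic-variance-weighted mean of log ratios against the
highest-depth reference sample, rescaled to geometric mean 1; the
implementation agrees with edgeR's `calcNormFactors` to machine precision
(verified in a test via `Rscript`).  The data-driven filter scales counts
by library size × TMM factor (times the mean depth, to stay on a
count-like scale), binarizes at each candidate threshold from a grid of
the distinct normalized values up to their 95th percentile (capped at 500
points, with 0 always included), and picks the threshold maximizing the
mean Jaccard similarity over within-group replicate pairs (ties: smallest
threshold); undefined (empty-union) pairs score 0.  Replicate groups
default to the four line × condition cells.  On data with a very wide
abundance range the criterion can legitimately choose a high threshold
that removes a large fraction of features — the filter is data-driven by
design, and this mirrors how aggressive such filters are on real plasma
miRNA data.

## NB-GLM differential abundance

Counts are modeled as NB(μ = exp(x′β + o), φ) with offsets
o = log(library size × TMM factor).  Dispersions: the common φ maximizes
the summed Cox–Reid adjusted profile likelihood over a log-spaced grid
(1e−8 plus 1e−4…8, 25 points) with parabolic refinement in log φ; tagwise
values maximize APL_g + 10 · mean-APL, i.e. weighted-likelihood shrinkage
with a prior weight of 10 features.  No abundance trend is fitted — a
deliberate simplification of the full trended-dispersion machinery; the
per-feature shrinkage target is the common profile.  β is fitted by IRLS
(convergence max|Δβ| < 1e−8, 100 iterations, linear predictor clipped at
±30); all-zero features take the zero-mean limit and are flagged.  The six
contrasts: Condition and Line drop one main effect from the additive
model; the four within-contrasts equate two cells of the cell-means
parameterization of the 2×2 design; the interaction test compares
cell-means vs additive.  All are 1-df LRTs against χ²; BH adjustment (via
statsmodels) controls FDR at 5% per contrast.  Reported log₂FC comes from
the fitted coefficients, except when a contrasted cell has all-zero
normalized means, where a 0.125-count prior shift is applied to the group
means for reporting only.  Log-FC profiles are clustered with Euclidean
distance and complete linkage (scipy), rows and columns.

## Poisson mixture and ICL

y_ij | k ~ Poisson(w_i s_j λ_{g(j)k}) with w_i the feature total, s_j the
library-size share, and λ tied within line × condition groups (per-sample
λ is a flag), normalized so Σ_g S_g λ_gk = 1.  Because of that
normalization the E-step reduces to group-summed counts times log λ, and
the M-step is closed-form.  Initialization is "small-EM": 20 random
Dirichlet posteriors run for 10 iterations, the best continued to
convergence (relative log-likelihood change < 1e−6, ≤ 1000 iterations);
model selection runs the best of 5 restarts per K over K = 1…12 by
default and picks K by ICL = log L − (ν/2)·log n + Σ t·log t with
ν = (K−1) + K(G−1).  EM monotonicity is asserted on every fit.  Poisson
mixtures fitted to overdispersed (NB) counts tend to add components to
absorb the extra variance; cluster counts on such data should be read as
descriptive, which is the intended use.

## qPCR models

Abundance is −ΔCt (technical replicates averaged on the Ct scale first);
the reference assay is a required input because no universal normalizer
exists for plasma — `global-mean` (per-sample mean Ct) is the fallback.
The intra-animal correlation is estimated per miRNA by REML on a
single-random-intercept model (statsmodels MixedLM, with a paired-residual
moment estimator as fallback) and combined across miRNAs as
tanh(mean(atanh ρ_g)) with estimates capped at 0.99; this consensus value
parameterizes an exchangeable within-animal correlation in a GLS fit of
the line/feeding/batch fixed effects.  Because all miRNAs share the same
birds, the consensus does not converge to the truth as the panel grows —
its seed-to-seed spread at 20 miRNAs × 15 birds is roughly ±0.1.
Variance moderation matches moments of log s² (digamma/trigamma, Newton
inversion) to get (d0, s0²), capping d0 at 200 for numerical stability
(homogeneous panels otherwise give d0 → ∞; at the cap the statistics are
effectively fully pooled); moderated t uses d0 + d_g degrees of freedom.
The implementation agrees with limma's `squeezeVar` to 6+ digits
(Rscript-verified test).  Single-level batch columns are dropped
automatically, which yields the liver mode (no batch, ρ = 0) without a
separate code path.

## Synthetic data: what it does and does not emulate

Hairpins are perfect stems (random 5′ arm, loop, reverse-complement 3′
arm) so the dot-bracket is analytic; an option injects one bulge per arm
to exercise partition edge cases.  Reads carry planted adapter positions,
length jitter in 19–24 nt, optional substitution noise and loop-origin
reads, and low-quality 3′ tails.  Counts are NB over the 2×2×3 design
with log-normal baselines, optional ±log₂FC line/condition effects and
group-profile cluster structure; qPCR Ct values carry line, feeding,
batch, animal-intercept and residual terms.  Not emulated: empirical
sequencing error profiles, isomiR end-heterogeneity beyond 3′ jitter,
hemolysis/blood-cell contamination, amplification-efficiency differences
between assays, and real secondary structures (no folding engine ships
with the package — structures are inputs).  Green tests therefore
demonstrate correctness of the statistical machinery under its stated
models, not robustness to every artifact of real plasma libraries.

## Sizes and numerical choices

Default analysis sizes (300 features, 12 libraries, 200-feature cluster
runs, 1000-feature null calibrations, 5–10 seeds) were chosen so each
driver and the whole acceptance pass complete in seconds to a few minutes
on one CPU while keeping Monte-Carlo error well inside the asserted
bands.  Key tolerances: IRLS 1e−8 on coefficients; EM 1e−6 relative
log-likelihood; LRT statistics clipped at 0 with a −1e−6 sanity floor;
mixture λ floored at 1e−300 before logs; all generators are pure
functions of (parameters, seed) and re-runs are byte-identical.

## Known limitations

No gapped alignment or cross-genome multi-mapping resolution; no NB
mixtures; no quasi-likelihood or trended-dispersion variants; no
amplification-efficiency modeling.  The packaged 41-row summary table is
transcribed exactly as printed, including two spots where the source
narrative (cluster membership counts quoted in the text) disagrees with
its own table; cross-tabulations report the table as-is.
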