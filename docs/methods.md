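# Methods

This note documents the models implemented in `connlearn`, the parameter
choices that matter, and what the synthetic experiments do and do not show.

## Synthetic cohort model

The generator emulates the *product* of a standard BOLD preprocessing
chain, not the raw signal: zero-mean, band-limited ROI series with a
modular joint distribution.

**Signal model.** Each subject/run series is a stationary multivariate
Gaussian `N(0, Σ_run)` of shape T×n, passed through an ideal (FFT
brick-wall) band-pass of 0.008–0.09 Hz at TR 2.0 s and re-centered per
column. A linear filter applied identically to every column leaves the
cross-correlation structure of a stationary Gaussian process intact, so the
band-pass shapes the spectrum without biasing the target correlations.

**Correlation structure.** `Σ_run` is block-constant: `rho_within` (default
0.4) inside modules, `rho_between` elsewhere, unit diagonal; indefinite
combinations are repaired by eigenvalue clipping followed by
re-normalisation to unit diagonal. Run 1 has 8 contiguous modules over 106
ROIs with `rho_between = 0.05`. In the deterministic (learning) condition
run 2 both merges the modules to 5 groups (label modulo 5) and raises
`rho_between` to 0.15 — integration modelled simultaneously as module
coalescence and diffuse coupling. In the null condition run 2 equals run 1
in distribution. Defaults: 15 subjects, T = 150 scans (≈5 min at TR 2 s).
No effect size for learning-induced correlation change is established in
the literature for this design; these values are calibration choices, fixed
once.

**What the generator does not model:** hemodynamic response shape, head
motion, physiological noise, subject-level random effects (runs are
independent draws within subject), spatial autocorrelation of
parcellations. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under a known truth, not effect sizes in real
BOLD data.

## Connectome estimation

Pearson correlations of centered columns; two-sided p-values from
`t = r sqrt((T−2)/(1−r²))` on T−2 degrees of freedom; Fisher z transform
with |r| clipped at 1−1e−7 so duplicated signals produce a large finite
weight; Benjamini–Hochberg over the n(n−1)/2 distinct pairs at q = 0.05;
failing pairs set exactly to 0. Negative correlations are stored signed;
metric computation zeroes them (see below). Zero-variance columns yield
zero-weight rows with a warning rather than an error.

**Degrees of freedom after band-passing.** The p-value formula takes the
sample size at face value. An ideal band-pass keeping B Fourier bins leaves
only ≈2B independent samples (≈48 of 150 at the default band), so
nominal-T p-values on band-limited data are anti-conservative and the FDR
mask admits extra noise edges. `build_connectome(..., effective_samples=k)`
with `effective_samples_bandlimited(T, TR, low, high)` implements the
dof-corrected variant — the convention widely used by fMRI connectivity
toolboxes after temporal filtering. The package default remains the
face-value T (matching the printed estimation formulas); the corrected
variant is exercised wherever calibration on band-limited null data is the
claim under test. The default was kept because, under the corrected dof,
the generator's 0.15 between-module correlation falls below the detection
threshold at T≈48 effective samples and the clustering contrast vanishes by
construction; under face-value T the extra retained noise edges instead
dilute the local-efficiency contrast. This trade-off is intrinsic to the
fixed generator conditions (see Limitations).

## Network statistics

All five statistics follow the weighted formulations with edge length
`1/w` for path metrics. Design points:

* **Negative weights** are set to 0 for metric computation (`1/w` lengths
  and cube roots are undefined for negatives); `negative_mode="abs"` is the
  alternative, isolated behind one switch. The signed matrix itself is
  preserved for edge filtering.
* **Clustering and local-efficiency denominators** use the *binary* degree
  `k_i`; with the strength there instead, `C_i` could exceed 1 on sub-unit
  weights. This matches the canonical weighted formulations.
* **Local efficiency**: neighbour distances `d_jz(N_i)` are shortest paths
  within the subgraph induced by i's neighbours, then each pair contributes
  `(w_ij w_iz / d_jz)^{1/3}`; nodes with fewer than two neighbours
  contribute 0.
* **Unreachable pairs** are excluded from L's average (isolated nodes from
  the outer mean); E handles them natively via `d^{−1} = 0`.
* Implementation uses scipy's Dijkstra on sparse length matrices; the test
  suite checks all five statistics against independent brute-force
  references (triple-loop Floyd–Warshall, explicit triangle loops) on 100
  random graphs to 1e−9.

## Compression Flow

Inputs: node betweenness (BC) and edge betweenness with length `1/w`.
Pivot `ϑ` is a percentile (default 10, range 5–20) of the BC distribution;
the periphery φ is every node with BC ≤ ϑ (inclusive, so tied minima such
as star leaves never empty the set); the centre is the maximum-BC node
(ties broken by lowest id). For each load `w = 1..k`, `w` sources are drawn
without replacement from φ, one walk per source runs until absorption at
the centre or a cap of 10n steps, and `ρ_w = w/(n − |c(Ĝ_w)|)` where
`|c(Ĝ_w)|` counts connected components (depth-first search; isolated nodes
count) of the traced edge set. CF is the mean of the defined ratios; loads
that traverse no edge are excluded with a warning.

**Walk law.** The step distribution is pluggable (`walk_bias`): the default
draws the next node with probability ∝ `w_ij · (BC_j + ε)²` — a drift up
the centrality gradient, so that input loads actually *flow* from periphery
to centre and absorb within a few steps. A pure weight-proportional walk is
provided but documented as degenerate on non-star topologies: its expected
hitting time of one designated node is of order n, each traced subgraph
then spans most of the network, every ratio collapses to ≈ w/(n−1), and CF
degenerates into a readout of the periphery size — which both destroys the
pivot-robustness the measure is supposed to have and erases its sensitivity
to integration. On fixtures with a single route to the centre (star, path)
all walk laws trace identical edge sets, so the closed forms (star CF = 1,
five-node path CF = 1/2) are walk-law invariant. Measured on the default
deterministic cohort, the mean per-connectome CF spread across pivots 5–20
(≈0.07) stays below the run-1→run-2 CF effect (≈0.08–0.21 depending on
seed), and CF across 10 walk realisations of one connectome has a
coefficient of variation below 10%.

## Modularity

Community detection is a pluggable backend; the claim exercised is the
module-count contrast, not any particular community model. Default:
deterministic greedy modularity maximisation (Clauset–Newman–Moore,
networkx) on the positive weights; optional Leiden (igraph + leidenalg)
with fixed seed. Hierarchical nested block models would slot in as another
backend but are not shipped. The "number of modules" is the partition size
at the finest level. Greedy modularity under-resolves small planted blocks
on subject-level matrices (counts ≈4.5 vs 8 planted in run 1), but the
contrast — the only tested surface — is preserved; on the grand-average
networks the planted 8 → 5 collapse is recovered exactly.

## Group statistics and edge filtering

Paired run contrasts use the two-sided Wilcoxon signed-rank test; the exact
null distribution for ≤25 untied pairs, otherwise the normal approximation
with continuity correction. Bonferroni multiplies raw p by the family size
(the five statistics form one family; CF and module counts are reported as
single hypotheses). Kruskal–Wallis with BH-FDR covers multi-group
comparisons. All-zero difference vectors return p = 1 with a degeneracy
flag.

Edge filtering runs a vectorised one-way ANOVA (run factor) per
upper-triangle edge plus a Tukey HSD p-value from the studentized-range
distribution (with two groups this equals the pooled t test — verified
against the F = t² identity). Percentile cutoffs (95th/5th) are computed
over **all** edges' mean differences by default (`scope="significant"` is
available), and selection intersects them with Tukey p < 0.05. No
multiplicity correction precedes the percentile stage; the percentile
filter is the stringency mechanism. Consequently ~2% of null edges per tail
pass both criteria, so the number of false selections grows linearly with
the edge count regardless of effect size; the planted-recovery experiment
uses a 13-ROI graph (78 edges), where the 5% tails hold about as many edges
as the 4 + 3 planted effects, mirroring the sparse-selection regime of the
motivating design. Planted effects of 1.5 within-run SD with 15 subjects
are then recovered with mean precision ≈0.9 and recall ≈1.0.

## Problem sizes and numerical choices

Default experiment: 15 subjects × 2 runs × 106 ROIs × 150 scans (runs in
~1 minute end to end). The type-I calibration study uses 50 null cohorts of
12 subjects × 40 ROIs × 120 scans. Tolerances: metric oracle agreement at
1e−9; PSD repair floor 1e−10; Fisher-z clip 1e−7; CF walk cap 10n steps.
Ties: centre node by lowest id; BH at q = 0 masks everything (the
degenerate "nothing survives" convention).

## Limitations

* Under the fixed generator defaults, the local-efficiency run contrast is
  directionally positive but tiny (≈0.32 both runs) because newly retained
  weak between-module edges enlarge neighbourhoods and the `k(k−1)`
  normalisation absorbs the added triangle weight; with the dof-corrected
  estimator the clustering contrast vanishes instead (merged blocks share
  `rho_within`, and 0.15 between-module coupling is sub-detection at ≈48
  effective samples). No estimator convention makes all five contrasts
  large under these conditions; the four robust ones (strength, global
  efficiency, clustering, path length) are Bonferroni-significant in
  essentially every cohort.
* Subject-level module counts depend on the backend's resolution; absolute
  counts are not comparable across backends, only contrasts.
* CF is a stochastic estimator; single-realisation values carry walk noise
  (CoV < 10% on default-size connectomes) and cohort averages should be
  used for contrasts.
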