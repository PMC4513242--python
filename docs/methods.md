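# Methods

This note documents the models, numerical choices and limitations behind
`conntensor`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A connectome is a symmetric, zero-diagonal, nonnegative `p x p` matrix.
Files are plain delimited text (comma or whitespace, auto-detected), with
an optional header line of region labels. Asymmetry up to `1e-8` relative
to the largest entry is treated as print noise and repaired by averaging;
anything larger raises an error naming the worst cell, because silently
symmetrizing badly asymmetric data would hide upstream bugs. Each subject's
matrix is divided by its own maximum entry before analysis, since matrices
from different subjects (and tractography runs) live on different scales;
an all-zero matrix passes through with a warning so batch runs survive
degenerate subjects.

Vectorization takes the strict upper triangle row-major (`(i, j)` with
`i < j`, `i` ascending then `j`). The ordering is arbitrary but fixed, so
extracted features are reproducible across runs and machines.

## Confound residualization

Age and sex effects are removed by ordinary least squares on the design
`[1, age, sex]` — a Gaussian identity-link GLM — applied across all
subjects pooled, separately to every edge (and to every global network
measure). Residuals are exactly orthogonal to the design columns, so group
contrasts computed afterwards cannot be driven by age or sex imbalance.
Sex is coded 0/1 (reference female); the coding cannot change residuals.
Rank-deficient designs (single-sex cohorts, constant age) fall back to the
pseudoinverse with a warning. Pooled residualization can absorb some group
signal when confounds correlate with diagnosis; this is the standard
trade-off of confound regression and is deliberately not second-guessed.

Network *metrics* are computed on the nonnegative max-normalized networks
first and residualized afterwards; *edge-wise* analyses use the
residualized (possibly negative) networks. Weighted graph measures are not
defined on negative-weight networks, which forces this order.

## Global network measures

Five weighted whole-network summaries, in the variants popularized by the
Brain Connectivity Toolbox:

| measure | definition | default knobs |
|---|---|---|
| MOD | Newman weighted modularity of the best Louvain partition | 10 seeded restarts, resolution 1 |
| MCC | mean Onnela clustering: per node, Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / k(k-1), weights scaled by the max | degree < 2 contributes 0 |
| CPL | mean Dijkstra shortest-path length, edge length = 1/weight, over ordered reachable pairs | unreachable pairs excluded |
| GLOB | mean of 1/distance over ordered pairs | unreachable pairs contribute 0 |
| SW | sigma = (C/C_null)/(L/L_null) against rewired nulls | 10 nulls, 10 swap passes per edge |

The null model for SW rewires the binarized topology by Maslov–Sneppen
double edge swaps (degree-preserving) and reassigns the original weights by
shuffling; when the input is connected, disconnected nulls are redrawn (up
to 10 times) so path lengths stay comparable. Zero swap passes yield the
identity null, a useful sanity check (sigma = 1). All stochastic steps
(Louvain restarts, rewiring) are seeded, so per-subject metric tables are
deterministic. On dense graphs few swaps are feasible; the rewiring keeps
whatever swaps were achieved rather than failing.

## HO-SVD

The mode-k unfolding orders the remaining modes cyclically
(k+1, ..., N, 1, ..., k-1); any fixed convention yields identical singular
values, and the convention only permutes core columns. Factors are the full
left singular matrices of each unfolding; the core is the tensor multiplied
by every factor transpose. Sign ambiguity of singular vectors is resolved
by flipping each column so its largest-magnitude entry is positive (ties:
first index) — required for deterministic features.

Feature extraction keeps the sample mode full (the subjects axis is never
truncated) and truncates both region modes to rank `k`, then multiplies the
truncated core back along the sample mode only: each subject gets its
`k x k` slice of the reduced tensor, stacked row-major. Default `k = 15`
(`225` features); the SVD baseline column-centers the raw feature matrix
before projecting onto the top `k` right singular directions, making it
exactly PCA. HO-SVD is computed on the uncentered tensor by default, with a
`center` flag; centering is a modeling choice, not a requirement of the
decomposition. Both decompositions are fit on the full cohort before
train/test splitting. This leaks unlabeled feature structure across the
split (labels are never used), and is retained because it matches how such
pipelines are typically run; fitting on training data alone is possible by
composing the library functions.

## Sparse logistic regression

The objective is average logistic loss plus `λ‖w‖₁`, intercept unpenalized.
The solver is FISTA with soft-thresholding and backtracking line search
(halving), started from the intercept-only optimum `c* = log(n₊/n₋)`, with
a monotone restart: if an accelerated step would increase the objective, a
plain proximal step from the current iterate is taken instead, so the
recorded objective history is non-increasing. Convergence is declared when
the relative objective change drops below `tol = 1e-7` (configurable), with
an optional additional KKT-stationarity threshold for applications needing
coefficient-level agreement — near-separable problems have flat objectives
where iterates can differ at ~1e-4 while objectives agree to 1e-12.
`λ_max = max_j |(1/n) Σᵢ yᵢ x_ij σ(-yᵢ c*)|` is the smallest penalty with
an all-zero solution (by the KKT conditions at the intercept-only optimum);
the default grid is 20 log-spaced values from `λ_max` down to `1e-3 λ_max`.
sklearn's saga solver on the identical objective is used in tests as an
independent cross-check, never as the implementation.

## Experiment protocol

Per repeat (20 by default): stratified 85/15 split; features standardized
by training mean/SD (constant columns zeroed); λ selected by 5-fold CV on
training data by mean fold accuracy, ties toward the larger (sparser) λ;
final model = 21-bag undersampling ensemble on the whole training set.
Each bag keeps all minority-class samples plus an equal-size
without-replacement draw of the majority; predicted probabilities are
averaged and thresholded at 0.5. Inside CV a single undersampled fit per
fold, warm-started along the descending λ path, stands in for the full
ensemble — bagging inside CV would multiply cost ~20x while λ selection
only needs a ranking of penalties. Splits are stratified (a plain random
15% test draw can lose an entire class at realistic group sizes); the bag
count is odd so majority voting is defined. The positive class of a
contrast is the clinically worse diagnosis (AD > MCI > NC), so sensitivity
always means disease detection. AUC is the Mann–Whitney statistic with
midranks, computed per repeat and then averaged. Every split, fold,
undersample and bag derives its seed from one master seed, so results are
bitwise reproducible.

Group statistics: edge-wise equal-variance two-sample t-tests on adjusted
networks, Bonferroni threshold `0.05 / (p(p-1)/2)` (7.9e-6 at p = 113);
metric-wise tests at `0.05/5 = 0.01`; method comparisons by paired
one-sided t-tests on per-repeat performances (all-zero differences return
p = 0.5, zero-variance nonzero differences 0 or 1 by sign); McNemar's test
uses the exact binomial below 25 discordant pairs and chi-square with
continuity correction above.

## Synthetic cohorts

Each subject's matrix is `|M + group_shift + age_slope·(age - mean age) +
sex_offset·sex + ε|` with the diagonal zeroed and the matrix
max-normalized. `M` is a shared symmetric nonnegative rank-`base_rank`
structure (outer products of folded Gaussians, scaled to max 1): low-rank
plus noise, so tensor truncation can genuinely concentrate structure. The
group shift adds `δ · noise_sd` per effect edge with ordered severity
NC (0) < MCI (0.5) < AD (1), emulating a disease gradient. Effect edges
either form a clique over a small node block (default — a low-rank,
spatially coherent contrast) or are scattered uniformly (a sparse contrast
that favors edge-wise methods). The absolute value keeps weights
nonnegative without a point mass at zero. Group sizes default to
39/112/51 (AD/MCI/NC), the shape of a typical elderly diffusion-MRI cohort;
ages are uniform on 60–85 years (optionally per-group, to construct
deliberate age confounding) and sex is Bernoulli(1/2). `noise_sd = 0.1`
relative to the unit-max mean structure gives edge-level SNR low enough
that single edges are unreliable — the regime the tensor method targets.

What the generator does **not** emulate: integer-valued streamline counts
and their heavy-tailed marginals, spatial autocorrelation of tractography
errors, scanner/site effects, and realistic sparsity patterns. Passing
tests therefore demonstrate the pipeline's statistical behavior under
controlled conditions, not performance on real diffusion MRI.

## Problem sizes in the shipped checks

The acceptance checks run at desk scale, chosen so the full suite completes
in minutes on one CPU: HO-SVD verification on 8x10x12 tensors; calibration
on p = 20 cohorts (200 null draws for the family-wise error rate); the
raw-vs-HO-SVD comparison on p = 60 cohorts, 40 subjects per group, 190
block effect edges at δ = 0.3 — calibrated once so raw-feature accuracy
lands near 0.55–0.65, leaving the tensor features headroom to demonstrate
their advantage — with 4 repeats per master seed and 20 (tests) or 16
(acceptance script) master seeds, 11 bags and a 6-point λ grid.

## Known limitations

- Louvain is a heuristic; modularity values are best-of-restarts, not
  global optima (exact only on the tiny graphs the tests enumerate).
- The HO-SVD truncation is the interlaced-SVD construction, not the
  optimal Tucker fit (no HOOI iterations); its error obeys the standard
  sum-of-discarded-singular-values bound.
- CPL on disconnected graphs averages over reachable pairs only, which can
  make a *more* fragmented network look "shorter"; GLOB is the safer
  summary in that regime.
- The FISTA solver targets dense feature matrices of desk scale
  (n x m up to ~10^6 entries); it makes no sparse-matrix provisions.
- Degenerate edges (zero variance within both groups) get p = 1 with a
  warning rather than NaN, which is conservative for discovery counts.
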