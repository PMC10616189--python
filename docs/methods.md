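# Methods

This note documents the models and numerical choices behind `xicalign`:
what is computed, under which assumptions, which parameters matter, and
what the synthetic benchmark does and does not show.

## Pairwise alignment

### Global fit

Anchors are the apex times of features passing the anchor q-value cut-off
(default 0.01) in both runs, one per precursor (the best-q feature on each
side). The linear fit is ordinary least squares; the lowess fit
(`statsmodels`, robustifying iterations on, span max(0.1, 10/n)) is
projected onto the monotone cone by isotonic regression, because every
downstream consumer requires a monotone RT mapping. The residual standard
error `RSE = sqrt(Σ r² / (n − 2))` uses two effective parameters for both
kinds; for lowess this undercounts the effective degrees of freedom
slightly, which is acceptable for a *relative* distance measure. Fits
degrade gracefully: lowess → linear → identity (the identity fallback
carries a sentinel RSE so tree builders treat the pair as distant).

### Similarity measure

Per time point, each run contributes the vector of its fragment-ion
intensities. The default measure is the **scaled dot product**
`S[i][j] = a_i · b_j / (max_i‖a_i‖ · max_j‖b_j‖)`. Two properties drove
this choice over plain cosine:

* cosine is scale-free, so a half-intensity interference peak attracts the
  alignment path exactly as strongly as the analyte; the scaled dot
  product weights candidate matches by intensity, as a chromatographer
  would;
* on strictly non-negative noisy traces the cosine of two noise vectors
  is large (≈0.8 for six fragments), so the adaptive gap penalty — a
  quantile of the off-diagonal similarity — becomes so expensive that the
  path cannot afford the gap moves needed to follow an analyte-specific
  shift. With the scaled dot product, baseline noise contributes almost
  nothing and the penalty stays small.

Plain `cosine`, a noise-masked cosine (`masked_cosine`, columns below
`mask_factor` × median column norm zeroed) and the raw `dot` product
remain selectable. Intensities enter raw by default; Savitzky–Golay
smoothing is available as an explicit option and is never applied
silently.

### Dynamic program

Standard edit-graph recursion with steps match (+1,+1), and gaps (+1,0) /
(0,+1) at a per-step penalty. Matching is allowed only in admissible
(unmasked) cells; gap moves may cross masked regions, so a feasible path
always exists. The gap penalty defaults to the 0.5 quantile of the
off-diagonal similarity values of the matrix at hand — a property of the
data, deliberately *not* of the constraint mask, so local and hybrid
alignment share one penalty and the hybrid result can never be worse than
local merely because its band contains the high-similarity ridge.
Traceback ties prefer diagonal, then vertical, then horizontal, making
paths deterministic. The hybrid band half-width is
`max(rse_factor · RSE, min_band_intervals · Δt)` with `rse_factor = 3.5`
and a floor of 3 sampling intervals, so a near-perfect fit still admits
matches. The RT mapping of a path interpolates linearly between matched
pairs, with end-slope extrapolation; it is monotone by construction.

## Multirun strategies

Run-to-run distance is the pairwise lowess-fit RSE on shared anchors;
pairs with fewer than two anchors receive a large sentinel distance. The
MST uses Kruskal with lexicographic tie-breaking. The hierarchy is UPGMA
(average linkage); with site labels, runs are clustered within each site
first and site subtrees are then joined on mean cross-site distances,
matching how multi-laboratory experiments are structured.

**Seeds.** Star and MST choose, per precursor, the run holding the lowest
q-value feature. The reference therefore varies across precursors and no
single run biases the experiment. This rule is exposed to score
confusions: if an interfering peak out-scores the analyte in every run,
the whole row inherits the wrong reference — visible in the residual error
of the benchmark.

**Progressive merging.** At each internal node the children's XICs are
hybrid-aligned (node-level fit refitted on features projected upward) and
merged. Matched time points take the leaf-count-weighted average of times
and intensities; gap points carry the present child's time and intensity
unchanged (zero-filling would bias averaged intensities downward at
boundaries); the merged grid is sorted and collapsed to strictly
increasing. The child→master time mappings are anchored on **matched pairs
only** — a gap step's raw child time is off the merged timeline by the
whole inter-run shift and would distort projections. The root reference is
the best projected feature (q ≤ `max_fdr_query`), falling back to the
summed-trace maximum with half-height boundaries; the rule that fired is
recorded. Whether node fits should instead be composed from children was
an open design point; refitting on projected anchors keeps each fit local
and was adopted.

## Peak selection and quantification

Two-tier acceptance (defaults mirror common workflow practice:
`max_fdr_query = aligned_fdr1 = aligned_fdr2 = 0.05`, final matrix filters
0.025): the lowest-p candidate whose apex lies within the window about the
aligned time is accepted up to `aligned_fdr2`; an out-of-window candidate
is accepted only up to `aligned_fdr1` when nothing inside qualifies, and
is flagged. The window defaults to the mapped reference-peak boundary
half-width, floored at 3 sampling intervals. An accumulated-RSE window
(3.5 × RSE) was evaluated and rejected as the default: for multi-hop MST
mappings it grows to ±1 minute and re-admits exactly the confident
interference peaks alignment is meant to exclude, while the DP mapping
places the boundaries to within about one sampling interval. An explicit
`window_seconds` override remains.

Signal integration is trapezoidal over the aligned boundaries, summed
across fragments, with an optional linear-baseline subtraction (off by
default); integrated features carry no p/q values, are exempt from the
final score filters, and are excluded from error-rate computations — they
add completeness, not confidence. Within a run, boundaries are transposed
from the best-scoring charge state of a peptide to scoreless sibling
charges; a zero-signal transposed window is kept as a zero-intensity,
flagged feature so the event is auditable.

The quantitation error rate is computed over annotated, scored cells
passing a q-value cutoff: correct = any positive boundary overlap with the
annotation (no overlap fraction is imposed); incorrect = selection where
the annotation says absent, or no overlap. Both the correct and the
incorrect fraction are reported, since the two conventions ("correct /
total" and "false / true") coexist in the field; the benchmark curves use
the incorrect fraction. CV is sd/mean on linear intensities per analyte;
the site-specific summary averages within-site CVs, the cross-site summary
uses all runs. Missing cells are never imputed.

## Synthetic benchmark

The generator emulates, per run: a monotone warp (linear drift `slope ~
N(1, 0.015)`, `intercept ~ N(0, 8 s)` plus a monotone PCHIP spline with
10 s knot jitter — monotone by construction, hence invertible);
analyte-specific local shifts (probability 0.5, magnitude U(5, 12) s)
applied after the warp; Gaussian peaks (σ = 5 s) of 6 fragments with a
per-precursor Dirichlet intensity pattern on a 3.4 s grid (a typical SWATH
cycle time) in a ±60 s extraction window; and white noise at a configured
apex signal-to-noise ratio. Decoy peaks (2 per precursor, 80% intensity,
offsets U(18, 45) s) and occasional interfering peaks (10% of precursors,
90% intensity) are modelled as *co-eluting analytes*: they hold a
characteristic position on the reference time scale and move with the run
warp — not as per-run random clutter, which would have no coherent
cross-run order and no counterpart in real chromatography.

The score model: true-peak q values are log-uniform 10^[−4, −1.6] (with a
10% weakly-scored fraction, q ~ U(0.01, 0.5)); interfering peaks are
confident but on average a decade weaker, q ~ 10^[−2.5, −1.0]; decoy q
values are exactly Uniform(0, 1), so threshold calibration is testable;
p values are a random fraction of q; d-scores are −log₁₀(q) plus noise.
Multisite experiments add per-(site, analyte) systematic shifts
(probability 0.4, magnitude U(5, 15) s) shared by all runs of a site — the
column-specific retention behaviour that a smooth global fit cannot
absorb, and the mechanism separating within-site from cross-site RSE.

**What passing the benchmark does not show.** The simulation has idealized
Gaussian peak shapes, uncorrelated white noise, no intensity saturation or
shouldering, no interference at the fragment m/z level inside the peak,
and score distributions chosen rather than learned; real data adds all of
these. Results on the benchmark demonstrate algorithmic correctness and
the direction and rough magnitude of the alignment gains, not
instrument-grade performance numbers.

## Problem sizes and numerical choices

Benchmarks run at desk scale: 200 precursors × 6 runs for warp recovery,
1000 precursors × 4 runs for error-rate control, 2 sites × 5 runs for the
multisite structure, 10,000 sampled matrices (≤5×5) for the DP oracle and
200 random 6-run matrices for the MST oracle — sizes at which exhaustive
oracles are feasible and simulations finish in seconds. Degenerate inputs
fail loudly: non-monotone grids, inverted boundaries, all-masked
similarity matrices, integration windows off the grid, and configs with
peaks wider than the extraction window all raise validation errors rather
than being repaired. Known limitations: sqMass (SQLite) chromatograms are
not read; upstream peak picking and classifier scoring are consumed, never
recomputed; protein rollup is a plain top-k summarizer, not an inference
model.
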