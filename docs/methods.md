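# Methods

This note documents the models behind `coopgis`, the defaults and why,
the numerical choices, and what the synthetic-data tests do and do not
establish about real data.

## Coordinate and time conventions

All geometry is 2-D planar in meters, origin at a room corner, x along the
6 m wall, y along the 4.5 m wall, y up. Perch height is deliberately
ignored: the analysis is a floor-plan GIS. Time is seconds since the study
epoch, taken as midnight of the first observation day; the sensor's nominal
8-s poll interval is a parameter, not a constant.

## Movement model (CTCRW)

Per axis, velocity v(t) is an Ornstein–Uhlenbeck process
dv = −βv dt + σ dW and position is x(t) = x(0) + ∫v. The exact Gaussian
transition over a step Δ (matrices in `coopgis.ctcrw.transition`) makes the
model a linear state-space system; fixes are observed positions with
independent N(0, τ²) noise per axis. The two axes are independent and share
(β, σ, τ), so the likelihood of an irregular, gappy track is the product of
two univariate-state Kalman filters — gaps enter only through Δ, with no
pre-interpolation.

*Fitting.* Maximum likelihood over (log β, log σ, log τ) by Nelder–Mead
with three starts (initial guess; σ ×10; σ ÷10), ties broken by higher
log-likelihood then lower β. τ is floored at 10⁻⁴ m so the observation
variance stays positive. The search is confined to a physical box
(β ≤ 2 s⁻¹, σ ≤ 10, τ ≤ 5 m) by a smooth quadratic penalty on the log
scale: at 8-s sampling, β above ~2 s⁻¹ is indistinguishable from
white-noise velocity and the likelihood has a degenerate ridge
(β, σ → ∞ at fixed σ/β) that an unconstrained simplex will run off,
especially for room-bounded tracks (below).

*Imputation.* The RTS smoother is evaluated on the union of fix and grid
times (grid nodes carry no observation) and reported at the grid times;
the grid spans first to last fix inclusive, so 48 h at 8 s gives 21 601
states. Initial state: first fix position, zero velocity, position variance
τ² + 0.25 m², velocity variance at stationarity σ²/(2β).

*Boundaries.* The likelihood ignores the walls — the free-space model is
fit to indoor data, and smoothed means are clipped to the room rectangle
afterwards. This is a deliberate, minimal correction: a reflected process
has no tractable exact likelihood. Consequences observed with the
simulator: for tracks that bounce off the walls frequently, the free-model
MLE drifts toward the white-noise-velocity boundary of the box (the
mean-reversion the data show in *position* cannot be expressed by the
model, which mean-reverts only in velocity). Imputation quality remains
good (RMSE at or below τ in the bundled example), but fitted β/σ for
heavily reflected tracks should be read as effective, not structural,
parameters.

*Identifiability at 8-s sampling.* Two regimes degrade the fit and are
worth knowing about. (1) βΔ ≫ 1: velocity decorrelates within one poll, β
and σ are only jointly identified through σ/β. (2) per-step displacement
SD ≫ τ: the measurement noise is invisible and the τ MLE is erratic,
including exact zeros at some seeds even with ~5 000 fixes. The
parameter-recovery experiment in the tests and acceptance script therefore
uses β = 0.2 s⁻¹, σ = 0.05 m s⁻³ᐟ² and τ = 0.25 m on an interior-dominated
track (simulated in a 1 km arena so no reflections occur): βΔ ≈ 1.6 and
per-step displacement ≈ 0.39 m against 0.25 m noise. Under that design all
three parameters are recovered within 15% (typically well under 12%) at
every seed tried.

## Synthetic data generator

`simulate_track` draws the exact CTCRW transition on a fine grid (default
1 s) and reflects at the walls (position folded, velocity component
negated), which preserves the free-space dynamics in the interior.
`simulate_sensor_log` samples the polls, drops each independently with
probability `dropout_prob`, and adds N(0, τ²) noise. `simulate_behavior_log`
runs a semi-Markov chain at 1-s resolution: exponential dwell times,
transition weights, and optional spatial gates — a gated state (feed near a
feeder, drink near the water line) can only be entered, and remains
occupied, while the animal is within the gate radius. Annotations are
emitted only inside the observation windows; the full ground-truth state
path is returned alongside.

Defaults (placeholders — no movement parameters for hens have been
published, so these are chosen once for plausibility, not estimated):
β = 0.2 s⁻¹ (velocity decorrelation over ~5 s), σ = 0.05 m s⁻³ᐟ²
(stationary RMS speed ≈ 0.08 m/s per axis — a slow amble, because
standing/resting dominates a hen's day), τ = 0.25 m, dropout 0.2,
48-h duration. The default room layout places two tube feeders on the open
floor, an 8×2 nest-box bank on the far wall, a 1 m × 6 m perch strip along
the near wall and a water line across the middle.

What the generator does *not* emulate: burst-like movement coupled to
behavior (a real hen parks at the feeder while feeding; the simulated one
wanders through the feeder gate independently of its behavior state),
social interaction between birds, diurnal activity rhythm, and
non-Gaussian sensor error. Passing tests therefore show the pipeline is
correct under its stated statistical assumptions, not that those
assumptions hold for real hens.

## Utilization distributions and home ranges

The bandwidth matrix is computed "along rotated axes": points are rotated
to the principal axes of their covariance, a univariate two-stage direct
plug-in selector (Gaussian kernels; ψ₈ from the normal reference, then
kernel estimates of ψ₆ and ψ₄ at their optimal pilot bandwidths, then
h = (R(K)/(μ₂²ψ₄n))^{1/5}) runs on each axis, and diag(h₁², h₂²) is rotated
back to a full SPD H. If a kernel functional comes out with the wrong sign
(possible in small samples) it falls back to its normal-reference value.
Pairwise functional sums are O(n²) and are evaluated on an evenly strided
subsample above 4 000 points.

The KDE is evaluated at the centers of a 0.05 m grid (120 × 90 cells —
below hen body size) and renormalized after truncation to the room, so the
UD mass is exactly 1 over the room. The home range at level p is the
smallest set of cells reaching mass p (density-ranked, ties in row-major
order), its area the cell count × cell area; p defaults to 0.95, the
wildlife convention, since no level is canonical indoors. Overlap measures
are plain polygon areas on these isopleth regions (not UD-weighted indices),
matching the units of the observed summaries (m², proportions).

## Hotspot maps

Annotations are matched to the nearest imputed grid state within a
tolerance (default 4 s = half the poll interval; equidistant ties go to the
earlier state; unmatched annotations are dropped and counted). Thiessen
seeds are the animal's unique synced locations snapped to 1 cm. Bounded
Voronoi cells come from mirroring the seeds across the four walls — the
perpendicular bisector between a seed and its mirror is the wall itself, so
cells clip exactly to the room and tile it (the room is convex). Each
polygon's intensity is the fraction f of its synced points carrying the
target label ("mean count" read as a within-polygon fraction — the only
reading consistent with percentage thresholds); raw counts are kept
alongside. Quantization: f > 0.75 high, 0.25 ≤ f ≤ 0.75 medium,
0 < f < 0.25 low, f = 0 or no points none. The boundary values 0.25 and
0.75 fall in the middle band, otherwise the printed bands would leave
(0.74, 0.75) undefined. A point on a shared cell boundary goes to the
lowest polygon index.

## Bout segmentation and time budgets

Behavior is scored as instantaneous 1-s samples, each covering [t, t+1).
The segmentation rule: a new state begins when the previous one stopped for
more than 5 s or a new one was performed for more than 5 s. Conventions the
rule text leaves open, fixed here: strict inequality (an interruption of
exactly 5 s does not break a bout); a run of a label opens a bout
immediately when no bout is open (recording starts at the first sample); a
different label over an open bout must be sustained for more than 5 s *as a
single run* to open its own bout, and when it does, the previous bout
closes at the end of its last own sample. Bout duration is elapsed time
including absorbed interruptions; bouts of one category never overlap, so
label seconds cannot exceed observed seconds.

Budgets divide label seconds (clipped to observation windows) by the total
scheduled window time — ten 30-min windows per day for two days, 36 000 s —
with "other" the residual to 100%. The paired t-test and Pearson
correlation are the classical closed forms (df = n−1 and n−2); correlations
run over the 18 hen-period rows. No multiple-testing correction is applied,
matching the observed analysis.

## Bundled observed dataset

`coopgis.datasets` ships the published per-hen summaries (time budgets,
home ranges/overlap, pairwise overlap areas) as plain CSV. The raw fixes
behind them were never deposited, so per-hen ranges and maps cannot be
regenerated from source data; the statistics layer recomputes every
cross-hen summary from these tables instead. Because the printed inputs are
rounded to 2 dp, recomputed summaries can differ from printed ones in the
last digit (e.g. a column mean of 17.2656 printed as 17.26).

## Problem sizes

Test and acceptance runs use deliberately modest sizes: ~5 000 fixes for
parameter recovery, 10⁵ replicates at 10⁻³ s steps for the SDE oracle,
500–5 000 points for KDE checks, exhaustive bout-path enumeration to length
9 plus randomized length-20 paths. These were chosen as the smallest sizes
at which the Monte-Carlo tolerances in the tests are comfortably resolved.

## Known limitations

* The free-space CTCRW is misspecified for bounded rooms; see above.
* Velocity states at reflection instants flip sign discontinuously, so
  imputed velocities near walls are not physical.
* The plug-in selector assumes moderately smooth underlying densities; for
  a hen camped in one spot it degenerates (guarded by the coincident-point
  check).
* Thiessen intensity fractions are undefined in cells without points
  (class `none`), which conflates "never there" with "never did it there";
  the per-cell totals are exported so users can tell these apart.
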