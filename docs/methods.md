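# Methods

This note documents the models, conventions and numerical choices behind
`instaspace`, in the order data flows through the package.

## Session model and time conventions

A session holds sorted units, behavioral trials and spike times on a
single absolute clock (64-bit seconds). Trials carry eight strictly
increasing event markers (start, instruction on/off, go, movement onset,
hold on/off, end), an object label (sphere, button, coax, perp) and a
context label (execution | observation). All analysis runs on a 1-ms grid
with half-open bins: a spike exactly on a bin edge belongs to the later
bin. HDF5 and csv-bundle serializations are lossless (csv reads use
round-trip float parsing), and `read ∘ write` is the identity.

## Preprocessing

Spike trains are binned at 1 ms, convolved with a Gaussian kernel
(σ = 50 ms, truncated at ±4σ, unit mass) and square-root transformed. The
sqrt transform approximately stabilizes Poisson variance: the standard
deviation of a smoothed, sqrt-transformed trace is ≈ ‖k‖/2 ≈ 0.038 per
trial regardless of the underlying rate, which matters for every
signal-to-noise consideration below. Edge handling renormalizes by the
convolved kernel mass, which keeps the *rate estimate* unbiased at window
edges (total mass is preserved only for interior spikes). Smoothing is
applied to the whole trial **before** snippets are cut, so concatenation
boundaries carry no edge artifacts.

Each trial is cut into four event-aligned snippets — instruction onset
±500 ms; go cue from one median delay before to half a median reaction
time after; movement onset from half a median reaction time before to
+200 ms; hold start ±200 ms — and concatenated. Medians are computed per
object (reported in `AlignmentWindows.per_object`), but the snippet
window lengths use the pooled successful trials of the context so that
all four objects share one time axis; a common axis is required for the
cross-object instantaneous PCA, whereas per-object windows would give
each object its own T. Trials shorter than their windows are excluded
with a logged warning.

## Unit classification

Spike counts in eleven 200-ms windows (before/after instruction onset and
offset, before/after the go cue, before/after movement onset, before/after
hold start, before hold end) enter a two-way fixed-effects ANOVA with
interaction (factors: object × period), separately per context. Type II
sums of squares are computed by model comparison, which handles unbalanced
trial counts; the implementation is vectorized across units (the design
matrix is shared within a context) and agrees with `statsmodels`
`anova_lm(typ=2)` to 8 digits. A unit is task-related in a context if any
of the three effects has p < α with α = 0.05/6 = 0.0083, Bonferroni over
the six tests each unit receives; MN = related in both contexts, AE =
execution only, AO = observation only, NS = neither. Units with no count
variance get undefined p-values and are classified NS with a note.

Two caveats worth knowing. First, the classical F-test is nearly exact on
Poisson counts when window counts are independent (measured union-bound
type-I ≈ 2.4% at the nominal 2.5% over 4000 null units), but windows
*overlap* when reaction or movement times are shorter than 400 ms,
correlating cells and inflating the type-I rate to ~3–4%; the type-I
validation therefore uses kinematics slow enough that the windows are
disjoint. Second, sensitivity at the default effect sizes needs on the
order of 40 trials per object; at 8 trials the planted classes are widely
missed.

## Instantaneous subspaces and principal angles

At each time step the four object-mean population vectors are centered on
their across-object mean — removing the condition-independent signal; the
paper-level description leaves the centering implicit, but without it the
first component would simply track the common time course — and the
centered 4 × N point set is decomposed by SVD. The top three right
singular vectors form the orthonormal filter `W_i` (column signs fixed by
making each column's largest-magnitude loading positive); four centered
points have rank ≤ 3, so three components capture all their variance.
Steps where the four means coincide are flagged degenerate, and consumers
either error or mark outputs missing.

Principal angles between two orthonormal N × 3 bases are
`arccos` of the clipped singular values of `W_a^T W_b`, sorted ascending.
Bootstrap variability resamples 20 trials per object with replacement,
10 folds, against anchor subspaces computed from all trials; because the
anchors use all trials, the fold mean never reaches zero even at the
anchor's own time. The chance reference draws random N × 3 bases by
orthonormalizing Gaussian matrices (rotation-invariant, so the fixed
reference is taken as the first three coordinate axes) and reports the
mean and mean − 3 SD of θ₁; by default the ambient dimension is the
smallest population under comparison.

Estimation error matters here: a subspace estimated from a single
smoothed millisecond carries Poisson noise that *inflates* small angles
and *deflates* large ones (two noisily estimated orthogonal subspaces
cannot measure 90°: with per-subspace error e, the measured θ₁ ceiling is
roughly 90° − 2e). Resolvability also requires the true rotation to be
slow relative to the 50-ms kernel — a 90° rotation completed within a
300-ms reaction time is partially averaged away. The planted-angle
recovery tests therefore run under high-rate, slow-kinematics conditions
(≈150–200 Hz baselines, strong condition-dependent amplitude, 600/800-ms
reaction/movement times) where the estimator's error is a few degrees;
these are estimator-validation conditions, not a claim about cortex.

## Trajectory segments, separation and decoding

Segments are the 100 consecutive 1-ms samples starting at an event
(inclusive), high-dimensional or projected as `L = X W`. Cumulative
separation sums the six pairwise Euclidean distances among the four
projected trajectories and divides by T = 100; it is invariant to rigid
motions and homogeneous of degree one in scale. On sessions with a
planted separation ramp, the 4 × 4 segment × subspace CS matrix grows
along the diagonal from instruction to movement and each segment
separates best in its own-time subspace (the row maximum); with strong
ramps, late segments can exceed the Instruction diagonal even inside the
Instruction subspace, so no column-wise dominance is asserted.

The decoder is a bidirectional LSTM — 3 inputs, 20 hidden units per
direction, final hidden states concatenated into a 4-class softmax —
written in numpy with exact backpropagation through time (verified
against numerical gradients) and trained full-batch with Adam
(defaults: 150 epochs, learning rate 0.01, per-feature input
standardization). A multinomial-logistic baseline on flattened segments
is provided for fast sweeps; both sit behind the same split protocol.
Splitting balances classes to the smallest per-object trial count, but
assigns distinct trial *identities* to train (40%) and test (60%) first
and only then resamples each side with replacement: balancing with
replacement before splitting could place copies of one trial on both
sides. Repeated hold-out (10 independent splits) is used rather than
k-fold. The chance band projects the same segments into random
orthonormal N × 3 bases (default 500 draws, one fit each); a reduced-cost
mode (50 draws, 5 repeats) reproduces the full band mean within 2 SD.

One selection effect deserves emphasis. The instantaneous subspace at
time t is estimated from *all* trials, so when decoded segments contain
the very samples (within the ±200-ms kernel support) that defined the
subspace, the projection is tilted toward those trials' own noise and
"chance" accuracy is inflated well above 0.25 — an excess of roughly
1/√K that is still ≈ 0.10 at K = 80 trials. Honest chance-level
measurements therefore pair segments and subspaces whose raw supports do
not overlap; the package's chance-floor quantity decodes pre-instruction
segments ([I−500, I−400) ms) projected into the subspace at instruction
onset, the nearest subspace with disjoint support.

## CCA alignment

Latent blocks stack the four object-averaged 100-ms segments (400 × 3)
after two operations: the across-object mean trajectory is subtracted per
time point (the alignment concerns condition-*dependent* geometry; the
condition-independent trajectory is common to all objects and would
otherwise dominate every correlation), and the block is projected into
its source's own all-trial subspace at the event time. Columns are
centered; thin QR of each block, SVD of `Q_A^T Q_B = U S V^T`, manifold
directions `M_A = R_A⁻¹U`, `M_B = R_B⁻¹V` by triangular solve with a
condition-number guard (> 1e10 raises, suggesting regularization), and
the sorted diagonal of S gives CC1 ≥ CC2 ≥ CC3. The implementation agrees
with the covariance-based generalized-eigenproblem solution to 1e-8 and
is invariant to any invertible 3 × 3 transform of either block.

Bootstrap distributions resample 20 trials per object with replacement
(500 iterations by default; sources require a configurable minimum of 10
trials per object). Within-group alignment draws two *independent*
samples from the same source, overlap allowed. Two consequences of this
protocol: the two samples share the finite trial pool, so within-group
CC1 has a high floor that rises as the pool shrinks toward the sample
size; and CC1 is the best-aligned of three directions, so noise shows up
far more strongly in CC2/CC3 than in CC1. Within-group comparisons across
groups (Kruskal–Wallis omnibus plus pairwise Tukey HSD on a chosen
coefficient) therefore resolve only ordering effects whose planted SNR
differences are large relative to the pooled bootstrap spread;
the validation plants a strong ordering (full-amplitude execution with
fast latent dynamics, 0.28-scaled and 3×-noisier observation,
0.2-amplitude smaller AE population, 80 available trials per object) for
that reason. Degenerate
comparisons (all groups identical constants) return an explicit
"no variance" report.

## Synthetic sessions

Per unit n on trial k (object o, context c) the rate on the 1-ms grid is

    λ(t) = max(0, b_n + g(class_n, c) · [ c_n · A_CI · f_CI(t)
                + A_CD · a_class · (U_c(t) · s_{o,k}(t))_n ])

with baseline b_n ~ U(5, 15) Hz, per-unit CI weights c_n ~ |N(1, 0.3)|, a
fixed smooth CI profile f_CI rising through the delay and peaking mid
movement, and object scores s_{o,k}(t) = ramp(t) · (d_o + η_k) where the
d_o are the four centered tetrahedron directions in R³ and η_k is
per-trial Gaussian score noise (optionally scaled up in observation). The
ramp is zero before instruction onset, steps to 0.4 at onset
(signal-related discharge), rises linearly to 1 at movement onset, then
drifts to 0.85 (execution) or 1.1 (observation) by hold start. An
optional fast-dynamics term (`score_dynamics_amp`, default 0) adds
object-specific smooth oscillations to the scores — two sinusoidal
components per latent dimension, 1.5–4 cycles per inter-anchor interval,
phased per object and anchored to trial progress so trial averaging
preserves them. It models the looping within-segment latent trajectories
of real populations; without it, 100-ms segments are nearly static and
within-group CCA consistency is dominated by smoothed noise paths rather
than signal dynamics. The gate g
is 1 where a class is active, γ (default 0.7) for mirror units during
observation, and 0 otherwise — it multiplies the CI term as well, since a
unit with ungated CI modulation would be task-related in every context
and the NS/AE/AO classes could not exist. Spikes are inhomogeneous
Poisson per 1-ms bin, uniformly placed within bins; objects are ordered
in shuffled blocks of four; epoch durations are drawn per trial (initial
hold U(0.5, 1), instruction 0.5 s, delay U(0.5, 2), reaction
N(0.3, 0.03), movement N(0.5, 0.05), hold 1 s).

The loading schedule plants anchor matrices U_I, U_G, U_M, U_H whose
consecutive-pair first principal angles equal the request *exactly*: each
step rotates all three columns by the requested angle into fresh
orthonormal directions drawn from the current frame's orthogonal
complement, so between anchors the geodesic
`U(τ) = cos(τa)·U_k + sin(τa)·V_k` stays exactly orthonormal and the
angle to the previous anchor is exactly τa (linear in time). Any nonzero
step needs N ≥ 6; angles of non-consecutive pairs follow from the chain
and are not independently controllable. By default the observation
schedule is drawn in the orthogonal complement of the execution chain's
span (requiring N ≥ span + 6) with the same object directions —
orthogonal subspaces, shared relational geometry; both choices are
switchable.

Defaults (≈60 units dominated by mirror neurons, 24 trials per object and
context, 12-Hz condition-dependent amplitude on a ~10-Hz baseline) are
realistic for premotor array recordings. What the generator does **not**
emulate: non-Poisson spiking statistics (refractoriness, bursting,
rate-dependent Fano factors), correlated noise across units, kinematic or
electromyographic covariates, eye movements, unsuccessful trials, and
electrode-level artifacts. Passing tests demonstrate that the analysis
chain recovers planted structure under its own assumptions — not that
cortical data satisfy those assumptions.

## Validation problem sizes

The test suite chooses problem sizes so the full run completes in a few
minutes of CPU: planted-angle recovery uses three 60-unit, 40-trial
sessions in the high-SNR regime above; the dissociation check one
60-unit session (100 bootstrap iterations); the consistency ordering ten
30-unit sessions (250 iterations per group); type-I control one session
with 1000 constant-rate units; the chance-floor decoding one
default-conditions session with the full 10-repeat LSTM protocol and a
16-draw permutation band. The pipeline's own defaults (500 CCA
iterations, 5000 baseline draws, 500 chance projections) remain the
paper-scale settings.
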