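# Methods

`critdiv` detects critical phase transitions in families of conditional
distributions ("codebooks") indexed by a control parameter, with discrete
rate–distortion (RD) theory as its validation ground. This note records the
model, the numerical choices, and what the synthetic studies do and do not
establish.

## The divergence rate

For a family p_t(y|x) over a finite input set with weights q, the divergence
rate over one sampled step is

    M_t = (1/Δt) · Σ_x q_x · KL( p_t(·|x) ‖ p_{t+Δt}(·|x) ),

with KL in natural log (the base rescales the series uniformly and cancels
in the normalization below). For a differentiable family with full support,
M_t → 0 linearly in Δt, so on a refining grid the smooth background
vanishes. When some conditional *loses* an output state between consecutive
samples the true KL is infinite; these are the critical points the measure
is built to find.

Numerically a loss step is detected as an entry of the earlier conditional
above a probability floor facing an entry of the later one at or below it,
and the step reports a fixed sentinel `cap` plus the finite floor-clamped
sum (the finite part orders coincident events for the peak finder's strict
comparisons). Making all loss spikes essentially equal height is what lets
a single global significance threshold separate them from background.

* `floor = 1e-6`. The floor defines "numerically zero". It must sit above
  the stall scale of the fixed-point solver — probabilities converging to
  zero linger around `tol/(1−rate)`, up to ~1e-7 with the defaults below —
  and below genuinely small probabilities of interest (entries near a
  transition are ~`slope·Δβ` ≈ 1e-3..1e-4 on the default grids).
* `cap = 1e6`. Any large finite value works; it only needs to dominate the
  smooth background after z-scoring while keeping moments finite.

The series is z-score normalized over the whole sampled range (not
windowed), each value assigned to the midpoint of its parameter step. A
constant series is returned as all-zero and flagged rather than divided by
a zero standard deviation.

### Traversal direction

The forward KL is asymmetric: a state *vanishing* along the traversal gives
a divergent spike, a state *emerging* gives only a bounded kink (the new
state's mass sits in the u ln(u/v) term with u ≈ 0). Measured on the Berger
example below, an emergence kink is ~80× smaller than a coexisting loss
spike, far below any usable global threshold. Criticality scans therefore
traverse β *downward* (equivalently w = e^{−β} upward): support shrinks as
β decreases, so every transition — including re-emergences seen from the
high-β side — is a loss with a sentinel-capped spike. The scan abscissa is
t = −ln β, on which a geometric β grid has uniform steps; geometric spacing
also matches the roughly log-uniform spread of critical β values.

## Rate–distortion solver

The Blahut–Arimoto fixed point for the output distribution is iterated in
the compact form p ← p ⊙ W(q ⊘ (Wᵀp)), W_ij = e^{−β d_ij}, rows = outputs.
The iteration preserves the simplex exactly; the codebook, average
distortion D and rate R (bits) are evaluated from the converged p.

* `tol = 1e-10` (max-abs change of p), `max_iter = 10000`,
  `support_eps = 1e-8` for the reported support set. Convergence slows
  critically near transitions (the contraction rate approaches 1); capped
  iterations there are flagged on the returned solution rather than raised.
* Grids are solved by continuation: each point warm-starts from the
  previous output distribution, floored at 1e-6/n so that states which lost
  support can re-enter (a multiplicative update can never revive an exact
  zero).
* Degenerate low β: when β·max(d) < 1e-6, W is within 1e-6 of all-ones and
  every simplex point is a fixed point to machine scale — the iterate
  cannot move at any budget. The analytic zero-rate limit (single output
  arg min_i E_q d(i,·), R = 0) is returned; its D and R err by O(β·max d).
* The inner loop is numba-compiled; the pure-numpy loop costs ~9 µs per
  iteration in interpreter overhead, which matters at ~10^7 iterations per
  scan.

Closed forms anchor the numerics: the high-β output p = W^{−T}(q ⊘ W^{−1}1)
(valid until its first entry hits zero, which defines the first critical
β*), the explicit two-state rational formulas, and the Berger three-state
critical point w* = (1 − u − √(1 − 6u + u²))/2 for u ≤ 3 − 2√2. The first
critical point is located by a geometric downward scan of the closed form's
minimum entry, bracketing the first sign change, then Brent refinement; the
generalized Descartes sign-rule bounds the root counts that make the
two-state analysis rigorous. The general three-state output vector is
computed through the matrix closed form rather than a transcribed explicit
vector.

## Peak finding

Candidate peaks are strict interior local maxima (plateaus excluded). The
noisy sweep seeds a Nesterov-momentum ascent at interior minima taken
*weakly* (plateau samples qualify): divergence series are exactly flat
between spikes, where strict minima are too scarce to seed every region.
Each recorded maximum advances the start to the next minimum beyond it;
finally, maxima with normalized height ≤ α are discarded.

The ascent runs in sample-index coordinates — the gradient is the forward
difference of the sample nearest the iterate, and η is in units of one grid
step — which makes the dynamics identical on linear, log or irregular
grids. Two stabilizers are needed on spiky signals, where slopes reach
thousands of grid steps: per-iteration displacement is clipped to 3 grid
steps (the nearest-sample gradient carries no information beyond its own
segment; momentum is reset on clipping), and the final snap goes to the
candidate nearest the *highest sample visited* rather than the last
iterate, which otherwise lands on arbitrary neighbors after bouncing around
a one-sample spike. A fixed-step momentum scheme cannot settle on a kink of
a piecewise-linear signal, so alongside the |θ−θ_prev| < ε test the ascent
terminates when it makes no net progress over 50 iterations; a 10,000
iteration cap guarantees termination regardless.

Defaults: η = 0.05, μ = 0.9, ε = 1e-6, α = 1.0 (one standard deviation of
the normalized series). Peak sets on the worked examples are unchanged
across η ∈ {0.01, 0.05, 0.1} × μ ∈ {0.5, 0.9}, which is asserted by test.
The α filter is applied after the sweep, on the normalized signal.

## Studies and their scope

**Criticality counting (random problems).** Problems draw q from normalized
uniforms and off-diagonal distortions uniform on [0, 4] (zero diagonal).
The scan window must contain essentially *all* transitions to estimate the
total count: first entries scale up as the smallest off-diagonal distortion
shrinks (observed up to β ≈ 54 at these sizes), and the collapse to a
single output finishes above β ≈ 0.01, hence the default window
geomspace(0.01, 60, 700). Counts regress the per-n mean of significant
peaks onto the fixed line n − 1 (R² computed against that line, not a
fitted one). At n = 2..10 with 10 trials per n this yields R² ≈ 0.99
(seed-dependent in the third decimal). Two caveats are inherent: states can
genuinely re-enter support and vanish again (verified by cold-started
solves), producing more than n − 1 loss events for some problems, and
transitions closer than ~2 grid steps merge into one peak — the means
balance slightly above the line at large n.

**Berger three-state family.** At u = 1/13 the downward scan over
β ∈ [0.02, 4] finds exactly two significant peaks: the re-emergence-side
critical point within a grid step of the closed form β* = −ln((6−√23)/13) ≈
2.379, and the low-β collapse at β ≈ 0.15–0.19 where the middle output
vanishes (the states 1 and 3 drop together there, one event). The (u, β)
heatmap overlays the closed-form critical curve on its domain
u ≤ 3 − 2√2.

**Clustering demo.** 18 states in 3 blocks, d_intra = 0.1,
d_inter = 4.0, uniform jitter on [0, 0.05] breaking within-block ties. The
40× intra/inter separation opens a wide annealing phase in which exactly
three outputs — one per block — carry >99% of the output mass; with a
milder separation (e.g. intra 0.5) the within-block and across-block merges
overlap and no exact one-per-block phase exists in the solvable range.
"Carries mass" is judged at the 1% level because outputs near a phase
boundary hold tiny positive masses (~1e-6) over narrow β windows.

**Image-patch coding.** 2×2 patches are mean-centered, scaled to unit
variance, and each value ternarized at ±0.5 into 2-bit ON/OFF-style codes
(below → (0,1), middle → (0,0), above → (1,0)); constant patches map to the
all-middle state. The 81-state source distribution is empirical with a
pseudo-count of 1 on unobserved states (the source must be strictly
positive); distortion is the Hamming distance between 8-bit codes, which
equals the L1 distance between ternary digit vectors (max 8). The built-in
image generator produces 1/f-amplitude, random-phase noise rescaled to
[0, 1] — it reproduces the second-order (spectral) statistics of natural
scenes but none of their phase structure (edges, occlusions), so pipeline
results on it demonstrate mechanics, not the specific critical-codebook
census of real natural images. On these synthetic images the pipeline
finds far fewer transitions than the generic n − 1 = 80.

**Weak universality.** Two problems with uniform q and i.i.d. uniform[0,1]
distortions give RD curves whose sup vertical gap (interpolated on the
common distortion range) shrinks with n, while their significant-peak
locations do not align — supporting the curve-level conjecture and speaking
against a critical-point-level strengthening.

## Known limitations

* Peak *counts* depend on the scan window by construction; the default is
  matched to the random-problem class above and must be widened for
  distortion scales outside [0, 4].
* Transitions separated by less than ~2 grid steps merge.
* The divergence series inherits BA non-convergence near criticality;
  peak locations are accurate to a few grid steps there, which the worked
  examples bound by test.
* The deterministic-map codebook helper supports the sub-normalized
  1/(n_in+1) convention for compatibility with dynamics-derived maps whose
  output set carries one extra catch-all state; KL on such columns relies
  on the floor clamp and is exercised in one-hot mode by the tests.
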