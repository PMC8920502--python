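# Methods

## Model and assumptions

A cell's state is a point **x** in a reduced feature space (morphology and
texture principal components in the motivating application), and its
recorded trajectory is assumed to follow overdamped Langevin dynamics
dx/dt = F(x) + η(x, t) with zero-mean white Gaussian noise.  All estimators
in the package are built on two reductions of this ansatz:

1. **Discrete-state reduction.**  Vector-quantizing the recorded states
   (SOM micro-clusters, or the Voronoi cells of a reaction coordinate)
   turns the ensemble into realizations of a Markov chain whose one-frame
   transition matrix is estimated by counting.  Markovianity is an
   approximation — memory enters through the unobserved degrees of freedom —
   and is checked, not assumed, via the Chapman–Kolmogorov test.
2. **One-dimensional reduction.**  Along a reaction coordinate s the ansatz
   becomes ds/dt = −dϕ/ds + η.  For a 1-D system a quasi-potential ϕ exists
   even without detailed balance; its negative gradient is the conditional
   mean drift, and the corresponding Fokker–Planck equation
   ∂ₜρ = ∇·[D(∇ − F/k_BT)ρ] closes the loop from estimated (ϕ, D) back to a
   predicted stationary distribution.

## Reactive trajectories

E and M are closed balls around empirical attractor centers; everything
else is I.  A recorded trajectory is *reactive* when its first frame lies in
E and it enters M at or before a deadline (default 48 h).  This is the
practical single-recording definition: unlike classical transition path
theory there is no infinitely long trajectory to cut into exhaustive
reactive segments, so one recorded pass counts once.  Downstream stages that
characterize the transition itself (SOM discretization, density maps) use
the *transition segments* — each reactive trajectory truncated a few frames
after its first M entry — because hours of post-transition dwell in the
product basin would otherwise dominate the state allocation.  Drift and
diffusion estimation deliberately uses **all** trajectory segments,
reactive or not: within each Voronoi cell the noise averages to zero only
under unbiased sampling of visits.

## String method

The reaction coordinate is discretized by N = 30 images with uniform arc
spacing; their Voronoi cells bin the data.  One iteration replaces each
interior image X(s_k) by

    Xbar(s_k) = (cell_mean_k + w * closest_mean_k) / (1 + w),     w = 10,

where `cell_mean_k` averages every data point assigned to cell k and
`closest_mean_k` averages, over trajectories, each trajectory's single
nearest point to X(s_k).  The first term anchors the string to the local
data density; the second penalizes the overall distance between each
individual trajectory and the path, which keeps sparsely populated cells on
course.  A smoothing cubic spline (total squared residual capped by the
smooth factor, default 1) is then fit through the averages and N images are
resampled uniformly in arc length; the endpoint anchors — the E- and
M-region data means — are interpolated exactly (large spline weights) and
restored after resampling.  Iteration stops when the data-to-cell Voronoi
assignment repeats (a cycle of period ≤ 4 is detected and flagged as
non-convergence; the last iterate is still returned, since assignment
flicker of a few points is common on noisy ensembles and does not move the
images perceptibly).  For quasi-potential work the converged string is
extrapolated linearly by 3 images at each end so that the first/last
(unbounded) Voronoi cells can be discarded.

Whether the trajectory term should average one closest point per trajectory
or one per visit is genuinely ambiguous; one-per-trajectory is the default
and `closest_per="visit"` switches to the alternative.

## Drift, diffusion, quasi-potential

With Δt one recording interval, every consecutive frame pair whose first
frame lies in interior cell i contributes a velocity sample
(s(X(t+Δt)) − sᵢ)/Δt, where s(X) is the arc coordinate of the Voronoi cell
containing X (a piecewise-constant map).  Then dϕ/ds|ᵢ = −mean,
D(sᵢ) = variance, and ϕ is the left-Riemann cumulative sum of the gradient
(the offset ϕ(s₀) is irrelevant).  Cells with fewer than `min_count` = 5
samples are masked; interior gaps are filled by linear interpolation for
the integration and leading/trailing masked cells truncate the domain.

Two discretization biases matter and set the recommended operating point:

- *Lag bias*: over a finite Δt the drift relaxes, shrinking the measured
  gradient by roughly (1 − e^{−λΔt})/(λΔt) for local stiffness λ.
- *Quantization bias*: because s(X) is cell-quantized, the within-cell
  density asymmetry inflates the measured gradient by a term that grows
  like Δs/√(DΔt).

The two act in opposite directions; the recovery fixtures therefore sample
at intervals a few times the integrator step (Δt = 0.02–0.1 in fixture time
units, cell spacing ≈ 0.1–0.15) where both are a few percent.  The real
pipeline exposes Δt and the cell count as configuration.

The reference potential of a stationary sample is ϕ₀ = −log p_ss with
p_ss estimated from per-cell counts regularized by a pseudocount of 0.5
(keeps empty cells finite while preserving ordering).

## Fokker–Planck solver

The 1-D equation is discretized in conservative finite-volume form with the
exponential-fitting face flux

    J_{i+1/2} = −D_f e^{−ψ_f} (ρ_{i+1} e^{ψ_{i+1}} − ρ_i e^{ψ_i}) / h,
    ψ = ϕ/k_BT,  ψ_f, D_f face averages,

so only ψ *differences* enter (no overflow for deep wells), probability is
conserved to round-off under implicit Euler stepping (the generator's
columns sum to zero), and the discrete stationary state is exactly the
Boltzmann density ρ ∝ e^{−ϕ/k_BT} independent of D — D only sets the
relaxation timescale, as in the continuous equation.  Time steps grow
geometrically until ‖dρ/dt‖₁ < 10⁻⁸.  The pseudo-temperature defaults to
k_BT = 1/2 and is configurable; when closing the loop against the
package's own simulations the fluctuation–dissipation value
k_BT = D_est·Δt/2 (= σ²/2) is the consistent choice, since the estimated
D = Var(Δs/Δt) ≈ σ²/Δt carries per-recording-interval units.

## Chapman–Kolmogorov test

P(τ) and P(kτ) are row-normalized lagged count matrices over all
trajectories; the reported deviation at k is the maximum row-wise L1
difference between P(kτ) and P(τ)ᵏ over states with at least `min_count`
lagged pairs at both lags.  The k = 1 deviation is identically zero.  On
discrete fixtures the test separates a genuine Markov chain (deviation at
the sampling-noise level, ~10⁻² at 10⁵ transitions) from a hidden-state
chain lumped into non-lumpable observed labels (deviation an order of
magnitude larger, growing with k).

## Synthetic-data generator

`simulate_langevin` integrates Euler–Maruyama,
x_{k+1} = x_k − ∇U(x_k)Δt + σ√Δt ξ, with the integrator step chosen well
below the stiffest curvature's relaxation time (0.002–0.0025 in fixture
units, ~1% of the fastest timescale); frames are recorded every `thin`
steps.  Trajectories exceeding a norm bound are dropped and listed, never
silently NaN.  Noise is isotropic additive by default; state-dependent σ(x)
is accepted through the same array interface but is not used by the stock
fixtures.

The two-channel landscape (`make_two_path_potential`) is a sum of Gaussian
wells and barriers plus a weak quadratic confinement: an epithelial well at
the origin, a mesenchymal basin near (20, 15), two trench paths — a
straight "concerted" diagonal and an elliptical "texture-first" arc that
rises along the texture axis before bending toward M — separated by a
ridge, with saddle bumps guarding each channel entrance.  A dose-like
control in [0, 1] flattens the E well (gone by 0.55) and lowers the two
saddles at different rates, so the concerted channel opens near control
0.45 and the texture-first channel near 0.55–0.7: sequential saddle-node
collisions.  Above control 0.5 a wide shallow well on the texture axis
biases the E exit toward the texture-first channel, making it the dominant
path at full dose.  The E well is re-centred numerically so the composite
landscape is stationary exactly at the nominal E centre at control 0.

Deliberate design choices in the fixture geometry: the two channels have
comparable arc lengths (elliptical arc ≈ 1.1 × diagonal) and comparable
transit times (the concerted trench is a chain of narrow wells that slows
passage), because the empirical study conditions the fixture emulates show
both channels carrying substantial probability — a fixture with one
much-cheaper channel would trivially collapse every shortest transition
path onto it.  The default recording covers 36 h at 0.4 h per frame with
noise σ = 1.5, so the recording window is transit-dominated (median first
M entry 11–13 h), as in a time-lapse study ended shortly after most cells
complete the transition.  Channel-resolved ground truth is generative:
each half of a labeled ensemble is integrated with the other channel's
entrance blocked by a tall bump.

What the generator does **not** emulate: cell division and death, cell–cell
interactions and secreted-ligand feedback, measurement noise with heavy
tails or frame dropouts, non-stationary imaging drift, and state-dependent
(multiplicative) noise.  Passing recovery tests on these fixtures therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to everything real imaging data can do.

## Parallel-path discovery choices

"K-means on the DTW distance matrix" is read as rows-as-features k-means
(seeded, 10 restarts).  That reading has a known pathology — one or two
outlier trajectories can be isolated as their own cluster — so a degenerate
split (smallest group below 5%) automatically falls back to seeded
k-medoids on the same distances, and k-medoids is also available directly.
Group labels are canonicalized by relative timing: group 1 is the group
whose texture axis covers half of its net change earlier relative to the
morphology axis ("texture-first" convention), so labels are stable across
runs and seeds.  DTW is the classic unconstrained algorithm with
multivariate Euclidean local cost and no normalization; subsequence
alignment treats the RC image chain as a short query free to match any
contiguous window of a trajectory, after which each frame is assigned to
the RC whose nearest image is closer (ties to RC 1) and maximal consecutive
runs feed per-path drift estimation.

The SOM is an online Kohonen map (Gaussian grid neighborhood, std 1,
truncated at radius 1, learning rate decaying linearly 0.5 → 0.01 over all
presentations, data-sampled initialization, fully seeded).  Transition
probabilities below 0.01 are reset to zero without renormalizing the rows —
renormalization is available but off by default.  The E/M neuron
communities are neurons within a configurable radius of the empirical
region means; the full pipeline widens the radius to the nearest neuron
when a community would otherwise be empty.  Equal-weight shortest-path ties
resolve to the lexicographically smallest node sequence.

Ridge counting on the reactive density map projects the map's mass in the
middle band of the E→M axis onto the transverse direction and counts modes
of that 1-D profile above 25% of its peak (merged within 3 map units) —
robust to speckle along a thin ridge, unlike raw 2-D local maxima.

## Dose-response protocol

Mirroring the low-versus-high dose comparison of the motivating study, the
two reaction coordinates are reconstructed once at full destabilization
(control 1) and held fixed; ensembles recorded at lower control values are
projected onto them and the quasi-potential is re-estimated per channel and
dose.  The E-side barrier is the climb of the reconstructed ϕ (maximum
minus preceding minimum) over the first half of the arc.  A channel none of
whose trajectories reached M cannot have its barrier measured — only
bounded below by the exploration depth — and is censored at a fixed ceiling
(12 energy units, above any measured climb), which makes the flattening
profile monotone in the measurable sense: uncrossed → crossed with residual
climb → flat.

## Known limitations

- The drift estimator's quantization bias grows with cell spacing and
  shrinks with the sampling interval; potentials reconstructed from very
  finely sampled data on coarse strings overestimate barrier heights.
- The quasi-potential is one-dimensional by construction: transverse
  structure, rotational (non-gradient) flux components, and memory kernels
  are outside the model class.
- DTW is not a metric (triangle-inequality violations are possible), so
  distance-matrix clustering has no geometric guarantee; the k-medoids
  fallback mitigates but does not remove this.
- Shortest transition paths concentrate on whichever corridor is cheapest
  in the −log p measure; when one channel is substantially more probable,
  per-pair Dijkstra paths will all use it even though a secondary channel
  exists (the density map and DTW clustering still reveal it).
- CK-test deviations on RC Voronoi cells conflate genuine memory with
  projection/quantization effects; they are a diagnostic, not a hypothesis
  test with calibrated size.
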