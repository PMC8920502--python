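# statepath

Rate-theory analysis of single-cell trajectory ensembles undergoing cell
phenotypic transitions (CPTs), such as the epithelial-to-mesenchymal
transition (EMT).

Live-cell imaging platforms can now track individual cells for days through
a reduced morphology/texture feature space (e.g. cell-shape and
vimentin-Haralick principal components).  Treating each cell as a point
moving in that space under overdamped Langevin dynamics,

    dx/dt = F(x) + eta(x, t),        <eta> = 0  (white Gaussian noise),

`statepath` provides the full chain of analyses needed to turn a recorded
trajectory ensemble into a mechanistic picture of the transition:

- **Reactive-trajectory extraction** — partition the feature space into an
  epithelial region E, a mesenchymal region M and the intermediate region I,
  and keep the recorded passes that start in E and reach M by a deadline
  (the practical, single-recording analogue of transition path theory's
  reactive trajectories).
- **Parallel-path discovery** — discretize the transition passes with a
  self-organizing map (12 x 12 by default), estimate the Markov transition
  matrix between micro-states, weight edges by −log p, and trace Dijkstra
  shortest paths between the E and M neuron communities; cluster the
  reactive trajectories by dynamic-time-warping (DTW) distance; and map the
  reactive-trajectory density ρ_R on a 200 x 200 grid.
- **Reaction-coordinate reconstruction** — a revised finite-temperature
  string method driven directly by measured trajectories: N = 30 image
  points with uniform arc spacing define Voronoi cells, and each iteration
  moves every image to the weighted average
  (cell mean + w · per-trajectory closest point mean)/(1 + w), w = 10,
  followed by a smoothing-spline reparameterization, until the Voronoi
  assignment of the data stops changing.
- **Quasi-potential and diffusion estimation** — within each interior
  Voronoi cell i, dϕ/ds|ᵢ = −⟨(s(X(t+Δt)) − sᵢ)/Δt⟩ over all recorded
  segments (reactive and non-reactive), ϕ(sᵢ) = ϕ(s₀) + Δs Σⱼ dϕ/ds|ⱼ, and
  D(sᵢ) = Var(ds/dt | sᵢ); a stationary sample gives the reference potential
  ϕ₀ ∝ −log p_ss.
- **Markovianity check** — the Chapman–Kolmogorov test, comparing P(kτ)
  against P(τ)ᵏ over the RC's Voronoi states.
- **Stationary-state prediction** — a conservative finite-volume solver for
  the 1-D Fokker–Planck equation ∂ₜρ = ∇·[D(∇ − F/k_BT)ρ] with spatially
  varying D and no-flux boundaries, whose discrete stationary state is
  exactly the Boltzmann density.

A first-class synthetic-data module generates seeded Langevin ensembles on
analytic landscapes — including a two-channel EMT-like landscape in which a
dose-like control parameter destabilizes the epithelial attractor through
two sequential saddle-node collisions — so every stage is verified by
parameter recovery against known ground truth.

## Worked example

Recover the quasi-potential of a 1-D Ornstein–Uhlenbeck process
(U = s²/2, σ = 1) from 300 simulated trajectories, then predict its
stationary distribution:

```python
import numpy as np
from statepath import (SimulationConfig, QuasiPotentialModel, quadratic_well,
                       simulate_langevin, uniform_rc_1d, stationary_stats)

cfg = SimulationConfig(n_traj=300, n_steps=2000, dt_sim=0.005,
                       noise_sigma=1.0, init=(0.0, 1.0), seed=0, thin=20)
ensemble = simulate_langevin(quadratic_well(), cfg)

rc = uniform_rc_1d(-1.8, 1.8, 25)          # 25 Voronoi cells on [-1.8, 1.8]
result = QuasiPotentialModel(ensemble, rc).fit()
print(result.summary())

ok = ~result.mask
curvature = 2 * np.polyfit(result.s_grid[ok], result.phi_cells[ok], 2)[0]
print(f"fitted curvature: {curvature:.3f}")

sol = result.solve_fokker_planck(kBT=0.5)
mean, sd = stationary_stats(sol)
print(f"predicted stationary sd: {sd:.4f}")
```

```
Quasi-potential along reaction coordinate
  interior cells:     25 (ds = 0.15)
  estimated cells:    25  (masked: 0, min_count = 5)
  samples used:       29732
  mean diffusion D:   9.256
  potential range:    1.872
fitted curvature: 1.056
predicted stationary sd: 0.6714
```

The fitted curvature recovers the true well stiffness (1.0) within a few
percent; the Fokker–Planck stationary standard deviation at k_BT = 1/2
approaches the Boltzmann value 1/√2 ≈ 0.7071 (the residual gap reflects the
finite Voronoi-cell resolution of the estimated potential).  Note the
estimated diffusion D = Var(Δs/Δt) ≈ σ²/Δt is reported in per-recording-
interval units.

The full pipeline (simulate or ingest → reactive extraction → SOM shortest
paths → DTW clustering → per-path strings → quasi-potentials → CK test →
Fokker–Planck) runs from a single YAML config:

```
statepath run --seed 1 --out my_run          # two-channel demo by default
statepath run --config my_config.yaml        # your own data
```

Each stage is also exposed as a subcommand (`simulate`, `reactive`,
`som-paths`, `cluster`, `string`, `potential`, `ck`, `fp`); see
`statepath --help`.

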