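# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the order the pipeline applies them.

## Synthetic dynamics with planted ground truth

The generators in `condyn.trajgen` exist so that every estimator in the
package can be validated against quantities that are *known by
construction*, not merely plausible.

**Discrete Markov chains.** `sample_markov_chain` draws a state sequence
from an arbitrary row-stochastic matrix via inverse-CDF sampling of each
row (PCG64 generator; every public entry point takes an explicit seed and
derives independent sub-streams through `numpy.random.SeedSequence`, so
fixed seeds reproduce output bit-identically across runs and platforms).
`chain_with_stationary(weights, r)` builds `T = (1−r)I + r·1πᵀ`, which has
the prescribed stationary vector π, is reversible, and has all non-trivial
eigenvalues equal to `1−r` — hence an analytic slowest relaxation time
`t₂ = −1/ln(1−r)` used as truth for timescale recovery.

**Overdamped Langevin dynamics.** `simulate_langevin` integrates
`x_{t+1} = x_t + D f(x_t) dt + √(2D dt) ξ_t` (Euler–Maruyama; energies in
kT so the mobility is just D). Potentials: harmonic `½kx²` (stationary
variance 1/k, an equipartition check), a double well `h(x²−1)²` with
barrier h between minima at ±1, and a triple well `h x²(x²−1)²`. The
integrator warns when `D·dt·max|U''| > 0.5`, the usual explicit-scheme
stability bound. Higher-order schemes are deliberately out of scope; the
trajectories only need a computable slowest timescale, which the
double-well run provides through its interwell exchange.

**Pseudo-receptor trajectories.** `generate_receptor_trajectory` advances
a hidden conformational state by one step of a supplied transition matrix
per frame and emits `coordinates = mean_structure[state] + fluctuation`,
where the fluctuation is drawn per Cartesian axis from a per-residue
covariance Σ (so the planted displacement correlation between residues i
and j is exactly `Σ_ij/√(Σ_ii Σ_jj)`, preserving the vector-dot-product
structure of the DCCM). Σ is factored by symmetric eigendecomposition with
negative eigenvalues clipped at zero, so exactly semidefinite inputs are
legal. Hidden-state labels are returned for truth checks.

`default_receptor_spec` is the study condition used throughout the tests
and the demo: 48 residues in four 12-residue blocks, three hidden states
with stationary weights (0.36, 0.36, 0.28) exchanged at rate 0.02 per
frame (t₂ ≈ 49.5 frames — slow enough to demand a real kinetic model at
the default lag of 60 frames, fast enough that 10⁵ frames estimate the
weights to ~0.015), per-residue fluctuation σ = 0.8 Å with intra-block
correlation 0.6, and the last block (a "TM6" analog) rigidly displaced by
6 Å per state index so the hidden states are separable along PC1.
Geometry: each block is a ring whose 2- and 3-step sequence neighbors sit
at 2.8/3.8 Å chords (within the 4.5 Å contact range), plus two pendant
residues per block that form exactly one 3.0 Å bridge per adjacent block
pair. Because contact analysis excludes i,i±1 sequence neighbors, the ring
construction keeps each block's contact graph connected under that rule.
The displaced block's bridge breaks in the displaced states (occupancy
≈ π₀ < 75 %), so the network stage reports it contact-isolated — the
analog of an activating domain disengaging — while community recovery of
the four blocks is unaffected. What the generator does *not* emulate:
bonded geometry, excluded volume, solvent or membrane, anisotropic
per-residue fluctuations, or state-dependent covariances; passing tests
demonstrate estimator correctness, not robustness to force-field-level
realism.

## Superposition, RMSD/RMSF, DCCM

Superposition is weighted least-squares Kabsch (SVD with the determinant
sign fixed to exclude reflections), batched over frames with stacked 3×3
SVDs. Degenerate references (collinear/coincident atoms) are rejected.
The RMSF/DCCM/PCA reference defaults to the once-iterated mean structure
(align to frame 0, average, re-align to the average); `reference="first"`
is available since real studies differ and the choice is not always
reported. RMSD summaries discard the first 20 % of frames as equilibration
by default (configurable).

DCCM entries are clipped to [−1, 1] and symmetrized against rounding;
zero-variance residues are flagged (`defined=False`) with zero rows rather
than propagating NaN. The conventional |C| < 0.3 display floor is a
plotting mask only — network construction always consumes raw C values,
because the edge weight −log|C| must see the actual correlation.

## PCA

Covariance with 1/(F−1) normalization, computed via SVD of the centered
(optionally √mass-weighted) coordinate matrix. Eigenvector sign is fixed
by making each column's largest-magnitude entry positive, so refits and
downstream metastate maps are reproducible. The number of components fed
to the MSM defaults to the smallest set explaining ≥ 80 % of variance,
capped at 10 (the demo pins it to 2, matching a 2-D landscape view);
whether 2 or more PCs feed the kinetic model is exposed in config because
practice varies.

## Markov state models

* **Microstates**: k-means (k-means++ seeding, seeded, max 100 iterations
  by default) on the PC scores, delegated to scikit-learn.
* **Counting**: sliding-window by default (every start frame), strided
  available; counts never cross boundaries between independent
  trajectories.
* **Estimation**: restriction to the largest strongly connected microstate
  set (dropped states are logged loudly; their frames are excluded from
  metastate populations). Non-reversible estimate = row-normalized counts.
  Reversible estimate = maximum likelihood under detailed balance via the
  standard self-consistent iteration on symmetrized variables
  `x_ij ← (c_ij+c_ji)/(c_i/x_i + c_j/x_j)`, converged at max-abs change
  < 1e-10 (cap 10⁶ sweeps). The stationary vector is taken from the
  leading left eigenvector of the result.
* **Spectra**: reversible matrices are symmetrized by √π similarity and
  diagonalized with `eigh` (real spectrum guaranteed); non-reversible
  spectra use |λ|. Implied timescales `t_i = −τ/ln λ_i`; eigenvalues ≤ 0
  yield NaN ("undefined at this lag") rather than an arbitrary number.
* **PCCA+**: inner-simplex vertex algorithm on the top-m right
  eigenvectors (first vertex = largest-norm row, then iterative
  farthest-point selection with Gram–Schmidt deflation), memberships
  `χ = X A⁻¹` clipped to ≥ 0 and row-renormalized. The crispness
  optimization of full PCCA+ is omitted: on the block-structured and
  planted-receptor problems this package validates against, hard
  assignments are already exact, and the feasibility projection is cheap
  and deterministic. Reported metastate probabilities are the stationary
  mass of each hard metastable set — the population a study quotes for a
  metastate; the membership-weighted mass χᵀπ is kept alongside
  (`macrostate_probabilities_weighted`) but is biased when sampling noise
  blurs small-eigenvalue eigenvectors, which is measurable already at 10⁵
  frames.
* **Chapman–Kolmogorov**: `T(τ)^k` vs re-estimated `T(kτ)`, both projected
  onto the PCCA+ metastable sets with stationary weighting; factors whose
  lag exceeds the data are omitted and flagged. The default pass band of
  0.05 absolute deviation comfortably contains sampling error for
  well-sampled Markovian input (measured < 0.02 at 10⁶ steps) while a
  heavy-tailed (Pareto) dwell-time alternation — a semi-Markov process —
  fails it by more than a factor of two.
* **TPT**: forward committor from the discrete boundary-value linear
  system; backward committor from the time-reversed chain (reducing to
  1−q⁺ for reversible models); gross flux `f_ij = π_i q⁻_i T_ij q⁺_j`,
  net flux its positive antisymmetric part. MFPT solves
  `(I − T_restricted)m = 1` over non-sink states and reports the
  π-weighted mean over the source, in lag units and in ns via the frame
  spacing.
* **Representatives**: all-pairs superposed RMSD within a metastate's
  frame pool; `d_scale` = standard deviation of the pooled distances; a
  frame's score is the *mean* of `exp(−d_ij/d_scale)` over partners (sum
  and max aggregation are selectable — the per-frame aggregate is a
  genuine ambiguity in how the pairwise score is used for selection).
  Ties go to the lowest frame index; an all-identical pool (d_scale = 0)
  returns frame 0 with score 1, logged. The pipeline subsamples pools to
  100 frames (evenly) to keep the O(F²) RMSD matrix cheap.

## Residue networks

Contacts default to minimum heavy-atom distance (the dynamical-network
convention) even though nodes anchor at Cα; a pure Cα mode exists. The
occupancy threshold is inclusive (≥ 0.75, "at least"), and i,i±1 sequence
neighbors are excluded by default to suppress trivial backbone edges.
Edges carry `d = −log|C|` with |C| floored at 1e-6 (the weight diverges at
C = 0; a floored edge is logged). Frame subsampling for occupancy is even
(default cap 2000 frames in the pipeline).

Shortest paths: Floyd–Warshall with predecessor reconstruction,
deterministic under ties (first improvement kept). Edge betweenness counts
optimal paths per edge with co-optimal paths splitting a pair's unit
weight equally (Brandes accumulation over the shortest-path DAG, Dijkstra
per source); an integer single-path mode uses the Floyd–Warshall
predecessors instead. Note the total betweenness over edges equals the sum
over node pairs of their (tie-weighted) path *edge counts*, not the number
of pairs — each pair increments every edge on its path.

Girvan–Newman removes the highest-betweenness edge (lexicographic
tie-break, logged), recomputes, and records the component partition at
every level; the returned partition maximizes Newman–Girvan modularity
computed with *affinity* weights `exp(−d) = |C|` (distance weights would
invert the meaning of a strong tie; for uniformly weighted planted graphs
this coincides with unweighted modularity, which the brute-force oracle
checks). Communities below 3 residues are then discarded from the reported
partition and listed separately. Inter-community connectivity sums the
full network's edge betweenness over edges crossing each community pair.
The "optimal substructure" criterion for cutting the dendrogram is a
genuine design choice; max-modularity is the default and the only
implemented rule.

## Interaction fingerprints

Strong hydrogen bond: donor–acceptor ≤ 3.5 Å with donor–H–acceptor angle
≥ 120°; weak: 3.5–4.0 Å at bonding angle, or 90–120° (exclusive at 90°)
within 3.5 Å; hydrophobic: apolar-carbon pairs ≤ 4.5 Å (apolar = no
covalent N/O within 1.75 Å, typed from first-frame geometry); persistence
≥ 0.5 by default. These criteria are package defaults following common
practice — reports always echo the criteria used, and all are
configurable. Topologies without hydrogens fall back to distance-only
hydrogen-bond detection with a logged caveat. No π-stacking, salt-bridge
or halogen-bond detectors, and no binding-energy or allosteric free-energy
estimates.

## Pipeline, determinism, problem sizes

All randomness flows from the single config seed through named
sub-streams, artifacts are written with fixed numeric formats, and the
manifest records SHA-256 checksums — so identical config + seed reproduces
every artifact byte-for-byte. The bundled demo uses 20 000 frames,
k = 50 microstates and lag 20 (the chain relaxes in ~50 frames, so this
demo is sized as a fast, self-checking example); the validation runs in
the test-suite and acceptance script use the full study conditions:
10⁶-step chains, 5×10⁵-step Langevin paths, and the 10⁵-frame receptor
with k = 100 and lag 60.

## Known limitations

* PCCA+ memberships come from the inner-simplex construction without the
  subsequent crispness optimization; fuzzy-membership *values* (as opposed
  to hard assignments and set populations) should be treated as
  qualitative.
* No Bayesian/error-bar MSM estimation, no hidden-Markov MSMs, no
  reweighting estimators.
* The PDB reader handles ATOM/HETATM/MODEL/ENDMDL with strict fixed-width
  parsing; altloc/insertion-code records and binary trajectory formats are
  out of scope (binary MD formats would enter through an adapter producing
  the in-memory `Trajectory`).
* Network construction is O(n²) per frame in residues and the community
  dendrogram recomputes betweenness per removed edge — appropriate for
  receptor-sized systems (hundreds of residues), not for whole-proteome
  graphs.
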