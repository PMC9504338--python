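"""Synthetic dynamics generators with known ground truth.

Every downstream stage of the package (fluctuation analysis, PCA, Markov
state models, residue networks) is validated against data produced here,
because each generator plants the quantity the stage is supposed to
recover: a transition matrix, a relaxation time, a pairwise displacement
correlation, stationary state weights, or a community partition.

All generators use numpy's PCG64 via explicit seeds (see ``_utils.rng_from``);
a fixed seed reproduces output bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import check_stochastic, rng_from, stationary_distribution
from .traj_io import Topology, Trajectory


# --------------------------------------------------------------------------
# Discrete Markov chains
# --------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """A discrete-time Markov chain to sample from.

    transition_matrix : row-stochastic square matrix
    n_steps           : length of the sampled state sequence
    seed              : master seed
    start_state       : initial state (default 0)
    """

    transition_matrix: np.ndarray
    n_steps: int
    seed: int
    start_state: int = 0

    def __post_init__(self):
        self.transition_matrix = check_stochastic(self.transition_matrix)
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        n = self.transition_matrix.shape[0]
        if not 0 <= self.start_state < n:
            raise ValueError(f"start_state {self.start_state} outside [0, {n})")


def sample_markov_chain(spec: ChainSpec) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` (includes the start state)."""
    T = spec.transition_matrix
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    rng = rng_from(spec.seed, 0)
    u = rng.random(spec.n_steps - 1)
    states = np.empty(spec.n_steps, dtype=np.int64)
    s = spec.start_state
    states[0] = s
    rows = [cum[i] for i in range(T.shape[0])]
    searchsorted = np.searchsorted
    for t in range(1, spec.n_steps):
        s = int(searchsorted(rows[s], u[t - 1], side="right"))
        states[t] = s
    return states


def chain_with_stationary(weights, exchange_rate: float = 0.05) -> np.ndarray:
    """Reversible transition matrix with a prescribed stationary distribution.

    T = (1 - r) I + r (1 pi^T): every non-trivial eigenvalue equals 1 - r,
    so the slowest relaxation time is analytic, t2 = -1 / ln(1 - r) steps.
    """
    pi = np.asarray(weights, dtype=float)
    if pi.ndim != 1 or abs(pi.sum() - 1.0) > 1e-10 or np.any(pi <= 0):
        raise ValueError("weights must be positive and sum to 1")
    if not 0 < exchange_rate < 1:
        raise ValueError("exchange_rate must be in (0, 1)")
    n = pi.size
    return (1.0 - exchange_rate) * np.eye(n) + exchange_rate * np.tile(pi, (n, 1))


# --------------------------------------------------------------------------
# Overdamped Langevin dynamics
# --------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Overdamped (Brownian) dynamics in a 1D model potential.

    Energies are in units of kT. Potentials:

    * ``harmonic``     : U = k x^2 / 2 with k = ``spring_constant``
    * ``double-well``  : U = h (x^2 - 1)^2, minima at +-1, barrier h = ``barrier_height``
    * ``triple-well``  : U = h x^2 (x^2 - 1)^2, minima at 0 and +-1

    diffusion_coefficient : D, length^2/time
    time_step             : integration dt
    """

    potential: str = "double-well"
    barrier_height: float = 2.0
    spring_constant: float = 1.0
    diffusion_coefficient: float = 1.0
    time_step: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    x0: float = 1.0

    def __post_init__(self):
        if self.potential not in ("harmonic", "double-well", "triple-well"):
            raise ValueError(f"unknown potential {self.potential!r}")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.barrier_height <= 0 or self.spring_constant <= 0:
            raise ValueError("barrier heights must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def force(self, x: float) -> float:
        """-dU/dx in kT per length."""
        if self.potential == "harmonic":
            return -self.spring_constant * x
        if self.potential == "double-well":
            return -4.0 * self.barrier_height * x * (x * x - 1.0)
        h = self.barrier_height
        x2 = x * x
        return -h * (6.0 * x2 * x2 * x - 8.0 * x2 * x + 2.0 * x)

    def _max_curvature(self) -> float:
        if self.potential == "harmonic":
            return self.spring_constant
        return 8.0 * self.barrier_height  # curvature at the double-well minima


def simulate_langevin(spec: LangevinSpec) -> np.ndarray:
    """Euler-Maruyama path x_{t+1} = x_t + D f(x_t) dt + sqrt(2 D dt) xi.

    f = -dU/dx in kT units (so D/kT collapses to D).  Warns when
    D * dt * max|U''| > 0.5, the documented stability bound.
    """
    if spec.diffusion_coefficient * spec.time_step * spec._max_curvature() > 0.5:
        warnings.warn("time_step too large for stable Euler-Maruyama integration "
                      f"(D*dt*U''_max = {spec.diffusion_coefficient * spec.time_step * spec._max_curvature():.3g} > 0.5)")
    rng = rng_from(spec.seed, 1)
    noise = rng.standard_normal(spec.n_steps - 1) * np.sqrt(
        2.0 * spec.diffusion_coefficient * spec.time_step)
    x = np.empty(spec.n_steps)
    x[0] = spec.x0
    xi = spec.x0
    D_dt = spec.diffusion_coefficient * spec.time_step
    force = spec.force
    for t in range(1, spec.n_steps):
        xi = xi + D_dt * force(xi) + noise[t - 1]
        x[t] = xi
    return x


# --------------------------------------------------------------------------
# Multi-state pseudo-receptor trajectories
# --------------------------------------------------------------------------

@dataclass
class ReceptorSpec:
    """A pseudo-receptor whose dynamics mix hidden-state switching with
    correlated Gaussian fluctuations.

    state_means              : (n_states, n_residues, 3) mean structures, Angstrom
    stationary_weights       : target occupation probability per hidden state
    hidden_transition_matrix : row-stochastic matrix advancing the hidden state
                               once per frame
    fluctuation_covariance   : (n_residues, n_residues) covariance of per-residue
                               displacements, Angstrom^2; expanded isotropically to
                               the three Cartesian components, so the planted
                               displacement correlation between residues i and j is
                               cov_ij / sqrt(cov_ii cov_jj)
    planted_communities      : optional partition of residue indices (ground truth
                               for community detection)
    frame_spacing            : ns per frame
    """

    state_means: np.ndarray
    stationary_weights: np.ndarray
    hidden_transition_matrix: np.ndarray
    fluctuation_covariance: np.ndarray
    planted_communities: list[list[int]] | None = None
    frame_spacing: float = 1.0
    residue_annotations: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.stationary_weights = np.asarray(self.stationary_weights, dtype=float)
        self.fluctuation_covariance = np.asarray(self.fluctuation_covariance, dtype=float)
        if self.state_means.ndim != 3 or self.state_means.shape[2] != 3:
            raise ValueError("state_means must be (n_states, n_residues, 3)")
        if abs(self.stationary_weights.sum() - 1.0) > 1e-10:
            raise ValueError("stationary weights must sum to 1")
        self.hidden_transition_matrix = check_stochastic(self.hidden_transition_matrix)
        n = self.n_residues
        C = self.fluctuation_covariance
        if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("fluctuation_covariance must be symmetric n_residues x n_residues")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError(f"fluctuation_covariance is not positive semidefinite "
                             f"(smallest eigenvalue {w.min():.3g})")
        if self.planted_communities is not None:
            flat = sorted(i for block in self.planted_communities for i in block)
            if flat != list(range(n)):
                raise ValueError("planted_communities must partition residue indices exactly")

    @property
    def n_residues(self) -> int:
        return self.state_means.shape[1]

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]


def _calpha_topology(n_residues: int, annotations: dict[str, list[int]] | None = None) -> Topology:
    top = Topology(
        names=["CA"] * n_residues,
        resids=np.arange(1, n_residues + 1),
        resnames=["ALA"] * n_residues,
        chains=["A"] * n_residues,
        masses=np.full(n_residues, 12.011),
        elements=["C"] * n_residues,
    )
    top.add_segment("receptor", 1, n_residues, chain="A")
    if annotations:
        top.annotations.update(annotations)
    return top


def generate_receptor_trajectory(spec: ReceptorSpec, n_frames: int, seed: int
                                 ) -> tuple[Trajectory, np.ndarray]:
    """Sample a receptor trajectory; returns (Trajectory, hidden-state labels).

    Per frame the hidden state advances by one step of
    ``hidden_transition_matrix``; coordinates are the state's mean structure
    plus a correlated Gaussian fluctuation drawn independently per Cartesian
    axis from ``fluctuation_covariance``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = spec.n_residues
    # initial state drawn from the stationary weights so labels are stationary
    rng0 = rng_from(seed, 2)
    start = int(rng0.choice(spec.n_states, p=spec.stationary_weights))
    labels = sample_markov_chain(ChainSpec(spec.hidden_transition_matrix, n_frames,
                                           seed=seed * 2 + 1, start_state=start))
    # factor the covariance once (eigen route tolerates semidefinite input)
    w, V = np.linalg.eigh(spec.fluctuation_covariance)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = rng_from(seed, 3)
    z = rng.standard_normal((n_frames, 3, n))
    fluct = z @ L.T                       # (frames, 3, n), covariance per axis = C
    coords = spec.state_means[labels] + np.transpose(fluct, (0, 2, 1))
    top = _calpha_topology(n, spec.residue_annotations)
    return Trajectory(top, coords, spec.frame_spacing), labels


def default_receptor_spec(n_residues: int = 48,
                          weights=(0.36, 0.36, 0.28),
                          exchange_rate: float = 0.02,
                          block_size: int = 12,
                          displacement: float = 6.0,
                          fluct_sigma: float = 0.8,
                          intra_corr: float = 0.6,
                          planted_pair_corr: float | None = None,
                          ) -> ReceptorSpec:
    """A three-state pseudo-receptor emulating an activating GPCR.

    Residues are laid out in ``n_residues // block_size`` spatial blocks
    (the planted communities).  Within a block, residues 2..B-1 sit on a
    ring whose 2- and 3-step sequence neighbors fall at 2.8/3.8 A chords —
    inside contact range — while 1-step sequence neighbors are irrelevant
    (contact analysis excludes them anyway), so the block's contact graph
    stays connected under the i,i+-1 exclusion rule.  Residues 0 and 1 of
    each block are pendant bridge residues below/above the ring; the
    outgoing pendant of block b and the incoming pendant of block b+1 meet
    at 3.0 A in the inter-block gap, giving exactly one planted bridge per
    adjacent block pair.  One contiguous block — the "TM6" analog, the last
    one — is rigidly displaced along +x by ``displacement`` * state_index
    Angstrom, so the slowest collective motion (PC1) has a known direction
    and the hidden states are separable in PC space (its bridge breaks in
    the displaced states, which the network stage simply reports).

    Fluctuations: per-residue variance ``fluct_sigma``^2 with correlation
    ``intra_corr`` inside each block and 0 between blocks.  Optionally a
    single planted correlation between residues 0 and 1 overrides the block
    value (used to validate DCCM recovery).
    """
    if n_residues % block_size:
        raise ValueError("n_residues must be a multiple of block_size")
    if block_size < 6:
        raise ValueError("block_size must be >= 6 (ring plus two bridge pendants)")
    n_blocks = n_residues // block_size
    ring = block_size - 2
    r = 2.35                      # chord-3 = 2 r sin(3 pi / 10) ~ 3.8 A for B=12
    spacing_y = 2 * r + 9.0       # puts facing pendant tips 3.0 A apart
    base = np.zeros((n_residues, 3))
    for b in range(n_blocks):
        oy = spacing_y * b
        base[b * block_size + 0] = [0.0, oy - (r + 3.0), 0.0]   # incoming pendant
        base[b * block_size + 1] = [0.0, oy + (r + 3.0), 0.0]   # outgoing pendant
        for j in range(2, block_size):
            k = (j - 5) % ring    # sequence shifted 3 slots from the pendant anchors
            phi = np.pi / 2 + 2.0 * np.pi * k / ring
            base[b * block_size + j] = [r * np.cos(phi), oy + r * np.sin(phi), 0.0]

    weights = np.asarray(weights, dtype=float)
    n_states = weights.size
    means = np.tile(base, (n_states, 1, 1))
    tm6 = np.arange(n_residues - block_size, n_residues)
    for s in range(n_states):
        means[s, tm6, 0] += displacement * s

    corr = np.eye(n_residues)
    for b in range(n_blocks):
        blk = slice(b * block_size, (b + 1) * block_size)
        corr[blk, blk] = intra_corr
    np.fill_diagonal(corr, 1.0)
    if planted_pair_corr is not None:
        corr[0, 1] = corr[1, 0] = planted_pair_corr
    cov = fluct_sigma ** 2 * corr
    # lift tiny negative eigenvalues from the uniform-block construction
    w = np.linalg.eigvalsh(cov)
    if w.min() < 0:
        cov = cov + (abs(w.min()) + 1e-10) * np.eye(n_residues)

    T = chain_with_stationary(weights, exchange_rate)
    communities = [list(range(b * block_size, (b + 1) * block_size)) for b in range(n_blocks)]
    return ReceptorSpec(
        state_means=means,
        stationary_weights=weights,
        hidden_transition_matrix=T,
        fluctuation_covariance=cov,
        planted_communities=communities,
        residue_annotations={"TM6": [int(i) + 1 for i in tm6]},
    )


def analytic_slowest_timescale(spec: ReceptorSpec, lag: int = 1) -> float:
    """-lag / ln lambda_2 of the hidden transition matrix, in frames."""
    vals = np.sort(np.abs(np.linalg.eigvals(spec.hidden_transition_matrix)))[::-1]
    lam2 = float(vals[1])
    return -lag / np.log(lam2)


def hidden_stationary(spec: ReceptorSpec) -> np.ndarray:
    return stationary_distribution(spec.hidden_transition_matrix)


# --------------------------------------------------------------------------
# Planted community graphs
# --------------------------------------------------------------------------

def generate_planted_graph(community_sizes, intra_weight: float = 0.2,
                           inter_edges=None, inter_weight: float = 1.0,
                           seed: int = 0):
    """Weighted graph of dense intra-community cliques plus explicit bridges.

    Returns ``(nodes, edges)`` with ``edges`` a dict mapping sorted node
    pairs to edge weight (a distance: smaller = stronger coupling).  Every
    community is a complete clique at weight ``intra_weight``; the only
    inter-community edges are those listed in ``inter_edges`` at
    ``inter_weight``.  Each community must have >= 3 nodes so none would be
    discarded by the downstream minimum-size rule.
    """
    sizes = [int(s) for s in community_sizes]
    if any(s < 3 for s in sizes):
        raise ValueError("community sizes must each be >= 3")
    n = sum(sizes)
    nodes = list(range(n))
    edges: dict[tuple[int, int], float] = {}
    start = 0
    blocks = []
    for s in sizes:
        block = list(range(start, start + s))
        blocks.append(block)
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                edges[(block[a], block[b])] = float(intra_weight)
        start += s
    for u, v in (inter_edges or []):
        if not (0 <= u < n and 0 <= v < n):
            raise ValueError(f"bridge ({u}, {v}) references nonexistent node (n={n})")
        if u == v:
            raise ValueError("bridge endpoints must differ")
        edges[(min(u, v), max(u, v))] = float(inter_weight)
    return nodes, edges, blocks
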