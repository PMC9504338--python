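"""Markov state models on discretized conformational coordinates.

Workflow: k-means microstate clustering of PC projections -> transition
counting at a lag time -> (reversible) maximum-likelihood transition matrix
on the largest strongly connected state set -> implied timescales and the
Chapman-Kolmogorov test for Markovianity -> PCCA+ metastable decomposition
-> transition path theory (committors, reactive flux, mean first-passage
times) -> exponential-similarity representative conformations, scored as

    S_i = <exp(-d_ij / d_scale)>_j

with d_ij the pairwise superposed RMSD inside a metastate's frame pool and
d_scale the standard deviation of the pooled d values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from ._utils import stationary_distribution
from .fluct import kabsch_superpose

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Microstate clustering
# --------------------------------------------------------------------------

@dataclass
class MicrostateAssignment:
    labels: np.ndarray | list[np.ndarray]   # per-frame microstate index
    centers: np.ndarray                     # (k, d) cluster centers in PC space
    k: int
    inertia: float


def cluster_microstates(scores, k: int = 100, max_iter: int = 100,
                        seed: int = 0) -> MicrostateAssignment:
    """k-means (k-means++ seeding) on per-frame PC scores.

    ``scores`` may be one (frames, d) array or a list of them (independent
    trajectories); labels are returned in the same structure.  Deterministic
    for a fixed seed.
    """
    multi = isinstance(scores, (list, tuple))
    parts = [np.asarray(s, dtype=float) for s in (scores if multi else [scores])]
    X = np.vstack(parts)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of frames ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=int(seed) % (2 ** 31)).fit(X)
    labels = km.labels_.astype(np.int64)
    if multi:
        out, at = [], 0
        for p in parts:
            out.append(labels[at:at + p.shape[0]])
            at += p.shape[0]
        labels = out
    return MicrostateAssignment(labels=labels, centers=km.cluster_centers_,
                                k=k, inertia=float(km.inertia_))


# --------------------------------------------------------------------------
# Transition counting and estimation
# --------------------------------------------------------------------------

def _as_dtraj_list(labels) -> list[np.ndarray]:
    if isinstance(labels, (list, tuple)):
        return [np.asarray(d, dtype=np.int64) for d in labels]
    return [np.asarray(labels, dtype=np.int64)]


def count_transitions(labels, lag: int, n_states: int | None = None,
                      sliding: bool = True) -> np.ndarray:
    """Transition count matrix at the given lag (in frames).

    Sliding mode counts (s_t, s_{t+lag}) for every start frame t; strided
    mode advances t by ``lag`` between counts.  Counts never cross the
    boundary between independent trajectories.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dtrajs = _as_dtraj_list(labels)
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    counted_any = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        counted_any = True
        if sliding:
            i, j = d[:-lag], d[lag:]
        else:
            i, j = d[:-lag:lag], d[lag::lag]
        np.add.at(C, (i, j), 1)
    if not counted_any:
        raise ValueError(f"lag {lag} is not shorter than any trajectory")
    return C


@dataclass
class MSModel:
    lag: int                           # frames
    count_matrix: np.ndarray           # restricted to active_set
    transition_matrix: np.ndarray      # row-stochastic on active_set
    stationary_distribution: np.ndarray
    active_set: np.ndarray             # original microstate indices retained
    reversible: bool
    frame_spacing: float = 1.0         # ns per frame

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_spacing

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real spectrum for reversible models; |eigenvalue| otherwise. Descending."""
        if self.reversible:
            vals = _reversible_spectrum(self.transition_matrix,
                                        self.stationary_distribution)[0]
        else:
            vals = np.sort(np.abs(np.linalg.eigvals(self.transition_matrix)))[::-1]
        return vals[:k] if k else vals


def _largest_scc(C: np.ndarray) -> np.ndarray:
    adj = (C > 0).astype(np.int8)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(comp, minlength=n_comp)
    return np.where(comp == int(np.argmax(sizes)))[0]


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_sweeps: int = 1_000_000
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Detailed-balance maximum likelihood via the self-consistent fixed point
    on symmetrized variables x_ij = x_ji: x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)."""
    Csym = C + C.T
    c_i = C.sum(axis=1).astype(float)
    x = Csym.astype(float)
    T_prev = x / x.sum(axis=1, keepdims=True)
    for _ in range(max_sweeps):
        x_i = x.sum(axis=1)
        q = c_i / x_i
        x = Csym / (q[:, None] + q[None, :])
        T = x / x.sum(axis=1, keepdims=True)
        if np.max(np.abs(T - T_prev)) < tol:
            break
        T_prev = T
    else:
        warnings.warn("reversible MLE did not converge to 1e-10; returning last iterate")
    x_i = x.sum(axis=1)
    pi = x_i / x_i.sum()
    return x / x_i[:, None], pi


def estimate_transition_matrix(counts: np.ndarray, reversible: bool = True,
                               lag: int = 1, frame_spacing: float = 1.0) -> MSModel:
    """Transition matrix on the largest strongly connected microstate set.

    Non-reversible: row-normalized counts.  Reversible: maximum likelihood
    under detailed balance (fixed-point iteration, converged at max-abs
    change < 1e-10).  The stationary distribution is taken from the leading
    left eigenvector of the result.
    """
    C = np.asarray(counts)
    if np.any(C < 0):
        raise ValueError("count matrix must be nonnegative")
    keep = _largest_scc(C)
    if keep.size == 0:
        raise ValueError("count matrix has no connected states")
    if keep.size < C.shape[0]:
        log.warning("dropping %d of %d microstates outside the largest strongly "
                    "connected set", C.shape[0] - keep.size, C.shape[0])
    Cr = C[np.ix_(keep, keep)].astype(float)
    if np.any(Cr.sum(axis=1) == 0):
        raise ValueError("a retained state has no outgoing counts")
    if reversible:
        T, _ = _reversible_mle(Cr)
    else:
        T = Cr / Cr.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    return MSModel(lag=lag, count_matrix=Cr.astype(np.int64), transition_matrix=T,
                   stationary_distribution=pi, active_set=keep,
                   reversible=reversible, frame_spacing=frame_spacing)


def _reversible_spectrum(T: np.ndarray, pi: np.ndarray):
    """Eigenvalues (descending, real) and right eigenvectors of a reversible T."""
    s = np.sqrt(pi)
    S = (T * s[:, None]) / s[None, :]
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    psi = vecs[:, order] / s[:, None]     # right eigenvectors of T
    return vals, psi


# --------------------------------------------------------------------------
# Implied timescales and Chapman-Kolmogorov
# --------------------------------------------------------------------------

@dataclass
class ImpliedTimescales:
    lags: np.ndarray                  # frames
    timescales: np.ndarray            # (n_lags, n_its) in frames; NaN = undefined
    frame_spacing: float = 1.0

    @property
    def timescales_ns(self) -> np.ndarray:
        return self.timescales * self.frame_spacing


def implied_timescales(labels, lags, n_timescales: int = 5,
                       reversible: bool = True, sliding: bool = True,
                       frame_spacing: float = 1.0) -> ImpliedTimescales:
    """t_i(tau) = -tau / ln lambda_i(tau) below the unit eigenvalue.

    Eigenvalues <= 0 (possible for noisy estimates) yield NaN at that lag;
    non-reversible models use |lambda|.
    """
    lags = np.asarray(sorted(int(l) for l in lags))
    out = np.full((lags.size, n_timescales), np.nan)
    for li, lag in enumerate(lags):
        C = count_transitions(labels, lag, sliding=sliding)
        model = estimate_transition_matrix(C, reversible=reversible, lag=lag,
                                           frame_spacing=frame_spacing)
        vals = model.eigenvalues()[1:n_timescales + 1]
        for k, lam in enumerate(vals):
            if 0 < lam < 1:
                out[li, k] = -lag / np.log(lam)
    return ImpliedTimescales(lags=lags, timescales=out, frame_spacing=frame_spacing)


def timescales_from_matrix(T: np.ndarray, lag: int = 1, n_timescales: int = 5) -> np.ndarray:
    """Implied timescales of an exact transition matrix (frames)."""
    vals = np.sort(np.abs(np.linalg.eigvals(T)))[::-1][1:n_timescales + 1]
    return np.array([-lag / np.log(v) if 0 < v < 1 else np.nan for v in vals])


# --------------------------------------------------------------------------
# PCCA+ metastable decomposition
# --------------------------------------------------------------------------

@dataclass
class MetastableDecomposition:
    memberships: np.ndarray             # (n_microstates, m), rows sum to 1
    macrostate_of: np.ndarray           # hard argmax assignment
    macrostate_probabilities: np.ndarray           # stationary mass of each hard set
    macrostate_probabilities_weighted: np.ndarray  # membership-weighted mass chi^T pi
    n_macrostates: int


def _inner_simplex_vertices(X: np.ndarray) -> list[int]:
    """Vertex rows of the (m-1)-simplex spanned by eigenvector rows."""
    n, m = X.shape
    verts = [int(np.argmax(np.linalg.norm(X, axis=1)))]
    Y = X - X[verts[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(Y, axis=1)
        v = int(np.argmax(norms))
        verts.append(v)
        d = Y[v] / max(norms[v], 1e-300)
        Y = Y - np.outer(Y @ d, d)
    return verts


def pcca_plus(model: MSModel, m: int) -> MetastableDecomposition:
    """Fuzzy metastable memberships from the top-m eigenvectors (PCCA+,
    inner-simplex vertex algorithm with feasibility projection).

    Requires a reversible model (real spectrum / simplex structure).  Hard
    assignment is the membership argmax, ties resolved to the lower
    macrostate index.  The reported macrostate probability is the stationary
    mass of each hard metastable set (the population one would quote for a
    metastate); the membership-weighted mass chi^T pi is kept alongside —
    finite-sampling noise in small eigenvectors blurs chi, which biases the
    weighted variant even when the hard partition is clean.
    """
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible model; re-estimate with reversible=True")
    n = model.n_states
    if not 2 <= m <= n:
        raise ValueError(f"m must be in [2, {n}]")
    vals, psi = _reversible_spectrum(model.transition_matrix,
                                     model.stationary_distribution)
    X = psi[:, :m].copy()
    X[:, 0] = 1.0                        # exact constant first eigenvector
    verts = _inner_simplex_vertices(X)
    A = X[verts]
    chi = X @ np.linalg.inv(A)
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    hard = np.argmax(chi, axis=1)        # argmax takes the first maximum: low index wins
    pi = model.stationary_distribution
    hard_mass = np.array([pi[hard == a].sum() for a in range(m)])
    return MetastableDecomposition(memberships=chi, macrostate_of=hard,
                                   macrostate_probabilities=hard_mass,
                                   macrostate_probabilities_weighted=chi.T @ pi,
                                   n_macrostates=m)


@dataclass
class CKResult:
    factors: np.ndarray
    predicted: np.ndarray       # (n_factors, m) macrostate self-transition, T(tau)^k
    estimated: np.ndarray       # (n_factors, m), re-estimated at lag k*tau
    valid: np.ndarray           # bool per factor (enough data at k*tau)
    max_deviation: float
    tolerance: float
    passed: bool


def _set_transition(T: np.ndarray, pi: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    """Stationary-weighted set-to-set transition probabilities."""
    m = len(sets)
    P = np.zeros((m, m))
    flux = pi[:, None] * T
    for a, A in enumerate(sets):
        wA = pi[A].sum()
        for b, B in enumerate(sets):
            P[a, b] = flux[np.ix_(A, B)].sum() / wA
    return P


def ck_test(labels, lag: int, m: int, factors=(1, 2, 3, 4, 5),
            reversible: bool = True, tolerance: float = 0.05,
            sliding: bool = True) -> CKResult:
    """Chapman-Kolmogorov test: T(tau)^k vs T(k tau), projected onto the m
    PCCA+ macrostates of the base model.

    Factors whose lag k*tau no trajectory can support are omitted and
    flagged invalid.  Passes when the max absolute deviation over valid
    points stays within ``tolerance``.
    """
    base = estimate_transition_matrix(count_transitions(labels, lag, sliding=sliding),
                                      reversible=reversible, lag=lag)
    decomp = pcca_plus(base, m) if reversible else None
    if decomp is None:
        raise ValueError("CK test requires a reversible base model")
    sets = [np.where(decomp.macrostate_of == a)[0] for a in range(m)]
    sets = [s for s in sets if s.size]
    m_eff = len(sets)
    factors = np.asarray(sorted(int(k) for k in factors))
    pred = np.full((factors.size, m_eff), np.nan)
    est = np.full((factors.size, m_eff), np.nan)
    valid = np.zeros(factors.size, dtype=bool)
    pi = base.stationary_distribution
    max_len = max(len(d) for d in _as_dtraj_list(labels))
    Tk = np.eye(base.n_states)
    for fi, k in enumerate(factors):
        Tk = np.linalg.matrix_power(base.transition_matrix, int(k))
        pred[fi] = np.diag(_set_transition(Tk, pi, sets))
        if k * lag >= max_len:
            log.warning("CK factor %d omitted: lag %d exceeds trajectory length", k, k * lag)
            continue
        try:
            mod_k = estimate_transition_matrix(
                count_transitions(labels, k * lag, sliding=sliding),
                reversible=reversible, lag=k * lag)
        except ValueError:
            continue
        if not np.array_equal(mod_k.active_set, base.active_set):
            # compare on the common state set only
            common = np.intersect1d(mod_k.active_set, base.active_set)
            pos_base = np.searchsorted(base.active_set, common)
            pos_k = np.searchsorted(mod_k.active_set, common)
            Tk_est = mod_k.transition_matrix[np.ix_(pos_k, pos_k)]
            Tk_est /= Tk_est.sum(axis=1, keepdims=True)
            sets_c = [np.searchsorted(pos_base, np.intersect1d(s, pos_base)) for s in sets]
            est[fi] = np.diag(_set_transition(Tk_est, pi[pos_base] / pi[pos_base].sum(),
                                              [s for s in sets_c if s.size]))
        else:
            est[fi] = np.diag(_set_transition(mod_k.transition_matrix, pi, sets))
        valid[fi] = True
    dev = np.abs(pred[valid] - est[valid])
    max_dev = float(dev.max()) if dev.size else float("nan")
    return CKResult(factors=factors, predicted=pred, estimated=est, valid=valid,
                    max_deviation=max_dev, tolerance=tolerance,
                    passed=bool(dev.size) and max_dev <= tolerance)


# --------------------------------------------------------------------------
# Transition path theory
# --------------------------------------------------------------------------

@dataclass
class TPTResult:
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    net_flux: np.ndarray              # antisymmetric part, nonnegative support
    gross_flux: np.ndarray
    mfpt: float                       # in lag units
    mfpt_ns: float
    mfpt_per_state: np.ndarray        # from each non-sink state, lag units


def tpt_analysis(model: MSModel, source, sink,
                 decomposition: MetastableDecomposition | None = None) -> TPTResult:
    """Committors, reactive flux and MFPT between two state sets.

    ``source``/``sink`` are either iterables of microstate indices (positions
    within the model's active set) or, when ``decomposition`` is given,
    macrostate indices whose member microstates form the sets.
    """
    n = model.n_states
    if decomposition is not None:
        A = np.where(decomposition.macrostate_of == int(source))[0]
        B = np.where(decomposition.macrostate_of == int(sink))[0]
    else:
        A = np.asarray(list(source), dtype=int)
        B = np.asarray(list(sink), dtype=int)
    if A.size == 0 or B.size == 0:
        raise ValueError("source and sink must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink must be disjoint")
    T = model.transition_matrix
    pi = model.stationary_distribution
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))

    qp = np.zeros(n)
    qp[B] = 1.0
    if inter.size:
        M = np.eye(inter.size) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        try:
            qp[inter] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            raise ValueError("sink unreachable from intermediate states (singular system)")
    # backward committor via the time-reversed chain
    Trev = (pi[None, :] * T.T) / pi[:, None]
    qm = np.zeros(n)
    qm[A] = 1.0
    if inter.size:
        M = np.eye(inter.size) - Trev[np.ix_(inter, inter)]
        rhs = Trev[np.ix_(inter, A)].sum(axis=1)
        qm[inter] = np.linalg.solve(M, rhs)

    F = pi[:, None] * qm[:, None] * T * qp[None, :]
    np.fill_diagonal(F, 0.0)
    net = np.clip(F - F.T, 0.0, None)

    notB = np.setdiff1d(np.arange(n), B)
    M = np.eye(notB.size) - T[np.ix_(notB, notB)]
    try:
        m_vec = np.linalg.solve(M, np.ones(notB.size))
    except np.linalg.LinAlgError:
        raise ValueError("sink unreachable (singular first-passage system)")
    mfpt_state = np.zeros(n)
    mfpt_state[notB] = m_vec
    wA = pi[A] / pi[A].sum()
    mfpt = float(wA @ mfpt_state[A])
    return TPTResult(forward_committor=qp, backward_committor=qm, net_flux=net,
                     gross_flux=F, mfpt=mfpt,
                     mfpt_ns=mfpt * model.lag * model.frame_spacing,
                     mfpt_per_state=mfpt_state)


# --------------------------------------------------------------------------
# Representative conformations
# --------------------------------------------------------------------------

@dataclass
class RepresentativeFrame:
    frame_index: int        # position within the supplied pool
    score: float            # in (0, 1]
    d_scale: float          # Angstrom
    scores: np.ndarray = field(repr=False, default=None)


def select_representative(coords: np.ndarray, mode: str = "mean") -> RepresentativeFrame:
    """Most representative frame of a pool by exponential pairwise similarity.

    All-pairs superposed RMSD d_ij is converted to similarities
    exp(-d_ij / d_scale) with d_scale the standard deviation of the pooled
    d values; a frame's score aggregates over its partners (``mode`` one of
    ``mean``/``sum``/``max``; sum-mode scores are normalized by the pool
    size so scores stay in (0, 1]).  Returns the argmax frame, ties to the
    lowest index.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("pool must contain at least 2 frames of (atoms, 3) coordinates")
    F = X.shape[0]
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            D[i, j] = D[j, i] = kabsch_superpose(X[i], X[j]).rmsd
    pooled = D[np.triu_indices(F, k=1)]
    d_scale = float(pooled.std(ddof=0))
    if d_scale == 0.0:
        log.info("all pool frames identical (d_scale = 0); returning frame 0")
        return RepresentativeFrame(0, 1.0, 0.0, np.ones(F))
    S = np.exp(-D / d_scale)
    np.fill_diagonal(S, 0.0)
    if mode == "mean":
        scores = S.sum(axis=1) / (F - 1)
    elif mode == "sum":
        scores = S.sum(axis=1)   # same argmax as mean; score may exceed 1
    elif mode == "max":
        scores = S.max(axis=1)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    best = int(np.argmax(scores))
    return RepresentativeFrame(best, float(scores[best]), d_scale, scores)
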