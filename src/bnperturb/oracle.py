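"""Brute-force ground truth on small networks.

Everything here enumerates the full state space (2**N states, or 4**N joint
pair states for the stochastic asynchronous analysis) and is therefore capped
at small N.  It exists to validate the sampling-based estimators exactly:
state-transition graphs, attractors (terminal SCCs), basins/absorption
probabilities, quasiattractor signatures, and exact values of the Derrida
coefficient, final Hamming distance, fragility and quasicoherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .network import BooleanNetwork, classify_nodes

__all__ = [
    "StateTransitionGraph",
    "AttractorSet",
    "QuasiattractorReport",
    "build_stg",
    "find_attractors",
    "quasiattractors",
    "signature_of_states",
    "exact_measures_sync",
    "exact_measures_async",
    "exact_mean_node_values",
    "steady_states",
    "STG_CAP",
    "ASYNC_PAIR_CAP",
]

SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"

STG_CAP = 16  # 2**16 states
ASYNC_PAIR_CAP = 6  # 4**6 joint pair states


def _check_scheme(scheme: str) -> str:
    aliases = {
        "s": SYNCHRONOUS,
        "sync": SYNCHRONOUS,
        SYNCHRONOUS: SYNCHRONOUS,
        "a": ASYNCHRONOUS,
        "async": ASYNCHRONOUS,
        ASYNCHRONOUS: ASYNCHRONOUS,
    }
    try:
        return aliases[scheme]
    except KeyError:
        raise ValueError(f"unknown update scheme {scheme!r}") from None


def _node_images(net: BooleanNetwork) -> np.ndarray:
    """(2**N, N) array: image of every state under a single-node update."""
    N = net.N
    states = np.arange(1 << N, dtype=np.int64)
    bits = ((states[:, None] >> np.arange(N)) & 1).astype(np.int64)
    images = np.empty((1 << N, N), dtype=np.int64)
    for j, comp in enumerate(net.compiled):
        if comp.inputs:
            idx = np.zeros(1 << N, dtype=np.int64)
            for b, k in enumerate(comp.inputs):
                idx |= bits[:, k] << b
            newbit = comp.table[idx].astype(np.int64)
        else:
            newbit = np.full(1 << N, int(comp.table[0]), dtype=np.int64)
        images[:, j] = (states & ~(1 << j)) | (newbit << j)
    return images


def _sync_successor(net: BooleanNetwork) -> np.ndarray:
    """(2**N,) array: synchronous successor of every state."""
    N = net.N
    states = np.arange(1 << N, dtype=np.int64)
    bits = ((states[:, None] >> np.arange(N)) & 1).astype(np.int64)
    succ = np.zeros(1 << N, dtype=np.int64)
    for j, comp in enumerate(net.compiled):
        if comp.inputs:
            idx = np.zeros(1 << N, dtype=np.int64)
            for b, k in enumerate(comp.inputs):
                idx |= bits[:, k] << b
            newbit = comp.table[idx].astype(np.int64)
        else:
            newbit = np.full(1 << N, int(comp.table[0]), dtype=np.int64)
        succ |= newbit << j
    return succ


@dataclass(frozen=True)
class StateTransitionGraph:
    """Complete transition structure over all 2**N states."""

    n_nodes: int
    scheme: str
    #: synchronous: shape (2**N,); asynchronous: shape (2**N, N), column i
    #: holding the image under an update of node i (repeats possible).
    images: np.ndarray

    def successors(self, state: int) -> tuple[int, ...]:
        if self.scheme == SYNCHRONOUS:
            return (int(self.images[state]),)
        return tuple(sorted(set(int(s) for s in self.images[state])))

    @property
    def n_states(self) -> int:
        return 1 << self.n_nodes


def build_stg(
    net: BooleanNetwork, scheme: str, cap: int = STG_CAP
) -> StateTransitionGraph:
    """Exact state-transition graph of a small network."""
    scheme = _check_scheme(scheme)
    if net.N > cap:
        raise ValueError(
            f"N={net.N} exceeds the exact-enumeration cap of {cap}; "
            "use the walker-simulation path instead"
        )
    if scheme == SYNCHRONOUS:
        return StateTransitionGraph(net.N, scheme, _sync_successor(net))
    return StateTransitionGraph(net.N, scheme, _node_images(net))


@dataclass(frozen=True)
class AttractorSet:
    """Attractors (terminal SCCs) plus basin data."""

    scheme: str
    n_nodes: int
    attractors: tuple[tuple[int, ...], ...]
    #: synchronous: attractor index per state.
    basin_index: np.ndarray | None
    #: asynchronous: (2**N, n_attractors) absorption probabilities under
    #: uniform node choice.
    absorption: np.ndarray | None

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def basin_fractions(self) -> np.ndarray:
        """Probability of reaching each attractor from a uniform initial state."""
        n_states = 1 << self.n_nodes
        if self.scheme == SYNCHRONOUS:
            return np.bincount(
                self.basin_index, minlength=self.n_attractors
            ) / n_states
        return self.absorption.mean(axis=0)


def _adjacency(stg: StateTransitionGraph) -> sp.csr_matrix:
    n = stg.n_states
    if stg.scheme == SYNCHRONOUS:
        rows = np.arange(n)
        cols = stg.images
        data = np.ones(n)
    else:
        rows = np.repeat(np.arange(n), stg.n_nodes)
        cols = stg.images.reshape(-1)
        data = np.ones(rows.size)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _terminal_components(adj: sp.csr_matrix) -> tuple[int, np.ndarray, list[int]]:
    n_comp, labels = connected_components(adj, connection="strong")
    coo = adj.tocoo()
    has_exit = np.zeros(n_comp, dtype=bool)
    cross = labels[coo.row] != labels[coo.col]
    has_exit[labels[coo.row[cross]]] = True
    terminal = [c for c in range(n_comp) if not has_exit[c]]
    return n_comp, labels, terminal


def find_attractors(stg: StateTransitionGraph) -> AttractorSet:
    """Attractors as terminal SCCs, with exact basin data.

    Synchronous: each state's unique attractor.  Asynchronous: absorption
    probabilities into each attractor under uniformly-random node choice.
    """
    n = stg.n_states
    adj = _adjacency(stg)
    _, labels, terminal = _terminal_components(adj)
    # deterministic attractor order: by smallest member state
    comp_states = {c: np.flatnonzero(labels == c) for c in terminal}
    order = sorted(terminal, key=lambda c: int(comp_states[c].min()))
    attractors = tuple(tuple(int(s) for s in comp_states[c]) for c in order)
    attr_of_comp = {c: k for k, c in enumerate(order)}

    if stg.scheme == SYNCHRONOUS:
        basin = np.full(n, -1, dtype=np.int64)
        for c in order:
            basin[comp_states[c]] = attr_of_comp[c]
        succ = stg.images
        # follow the functional graph with path memoization
        for s in range(n):
            if basin[s] >= 0:
                continue
            path = []
            cur = s
            while basin[cur] < 0:
                path.append(cur)
                cur = int(succ[cur])
            basin[np.array(path)] = basin[cur]
        return AttractorSet(stg.scheme, stg.n_nodes, attractors, basin, None)

    # asynchronous: uniform-choice transition matrix, absorption solve
    P = _uniform_transition_matrix(stg)
    K = len(attractors)
    in_attr = np.full(n, -1, dtype=np.int64)
    for k, states in enumerate(attractors):
        in_attr[list(states)] = k
    absorption = np.zeros((n, K))
    closed_mask = in_attr >= 0
    absorption[closed_mask] = np.eye(K)[in_attr[closed_mask]]
    transient = np.flatnonzero(~closed_mask)
    if transient.size:
        Ptt = P[transient][:, transient]
        rhs = P[transient].dot(absorption)
        sol = spsolve(
            (sp.identity(transient.size, format="csc") - Ptt).tocsc(),
            rhs,
        )
        absorption[transient] = np.atleast_2d(sol).reshape(transient.size, K)
    return AttractorSet(stg.scheme, stg.n_nodes, attractors, None, absorption)


def _uniform_transition_matrix(stg: StateTransitionGraph) -> sp.csr_matrix:
    n, N = stg.n_states, stg.n_nodes
    rows = np.repeat(np.arange(n), N)
    cols = stg.images.reshape(-1)
    data = np.full(rows.size, 1.0 / N)
    P = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    P.sum_duplicates()
    return P


# ---------------------------------------------------------------------------
# Quasiattractors
# ---------------------------------------------------------------------------

def signature_of_states(states, n_nodes: int) -> str:
    """Quasiattractor signature over {0,1,*}: per node, the constant value
    across the given states, or '*' if the node takes both values."""
    arr = np.asarray(list(states), dtype=np.int64)
    chars = []
    for j in range(n_nodes):
        bits = (arr >> j) & 1
        if (bits == 0).all():
            chars.append("0")
        elif (bits == 1).all():
            chars.append("1")
        else:
            chars.append("*")
    return "".join(chars)


@dataclass(frozen=True)
class QuasiattractorReport:
    signatures: tuple[str, ...]  # unique, first-occurrence order
    attractor_signature: tuple[int, ...]  # attractor -> signature index

    @property
    def n_quasiattractors(self) -> int:
        return len(self.signatures)


def quasiattractors(attrs: AttractorSet) -> QuasiattractorReport:
    """Merge attractors sharing fixed-0 / fixed-1 / oscillating node sets."""
    sigs: list[str] = []
    mapping: list[int] = []
    for states in attrs.attractors:
        sig = signature_of_states(states, attrs.n_nodes)
        if sig not in sigs:
            sigs.append(sig)
        mapping.append(sigs.index(sig))
    return QuasiattractorReport(tuple(sigs), tuple(mapping))


# ---------------------------------------------------------------------------
# Exact perturbation measures
# ---------------------------------------------------------------------------

def _perturbable_indices(net: BooleanNetwork, source_mode: str) -> list[int]:
    if source_mode not in ("p", "f"):
        raise ValueError(f"source_mode must be 'p' or 'f', got {source_mode!r}")
    if source_mode == "p":
        return list(range(net.N))
    cls = classify_nodes(net)
    targets = [i for i in range(net.N) if cls.labels[i] != "source"]
    if not targets:
        raise ValueError(
            "fixed-source mode is undefined: every node is a source node"
        )
    return targets


def _popcount(x: np.ndarray | int) -> np.ndarray | int:
    if isinstance(x, (int, np.integer)):
        return int(x).bit_count()
    return np.array([int(v).bit_count() for v in np.atleast_1d(x)])


def exact_measures_sync(
    net: BooleanNetwork, source_mode: str = "p", cap: int = STG_CAP
) -> dict[str, float]:
    """Exact delta, h_inf, phi, q under synchronous update by exhaustion.

    Every (initial state, perturbable target) pair is iterated as a joint
    deterministic trajectory until the joint state repeats; time averages are
    taken over exactly the detected cycle.
    """
    if net.N > cap:
        raise ValueError(f"N={net.N} exceeds the exact-enumeration cap of {cap}")
    N = net.N
    targets = _perturbable_indices(net, source_mode)
    succ = _sync_successor(net)
    bits = ((np.arange(1 << N)[:, None] >> np.arange(N)) & 1).astype(np.float64)

    delta_sum = 0.0
    h_sum = 0.0
    phi_sum = 0.0
    q_sum = 0.0
    n_pairs = 0
    for s in range(1 << N):
        for i in targets:
            y0 = s ^ (1 << i)
            delta_sum += int(succ[s] ^ succ[y0]).bit_count()
            # joint cycle detection
            seen: dict[tuple[int, int], int] = {}
            traj: list[tuple[int, int]] = []
            x, y = s, y0
            while (x, y) not in seen:
                seen[(x, y)] = len(traj)
                traj.append((x, y))
                x, y = int(succ[x]), int(succ[y])
            cycle = traj[seen[(x, y)] :]
            xs = np.array([p[0] for p in cycle])
            ys = np.array([p[1] for p in cycle])
            h_sum += float(np.mean([int(a ^ b).bit_count() for a, b in cycle]))
            mx = bits[xs].mean(axis=0)
            my = bits[ys].mean(axis=0)
            phi_sum += float(np.abs(mx - my).sum())
            sig_x = signature_of_states(xs, N)
            sig_y = signature_of_states(ys, N)
            q_sum += 1.0 if sig_x == sig_y else 0.0
            n_pairs += 1
    return {
        "derrida": delta_sum / n_pairs,
        "final_hamming": h_sum / n_pairs,
        "fragility": phi_sum / n_pairs,
        "quasicoherence": q_sum / n_pairs,
    }


def _pair_chain(net: BooleanNetwork) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Coupled Markov chain on (X, Y) pairs sharing the uniform node choice.

    Returns (P, bits_x, bits_y) where the joint state is x | (y << N).
    """
    N = net.N
    n = 1 << N
    M = n * n
    upd = _node_images(net)
    z = np.arange(M, dtype=np.int64)
    xs = z & (n - 1)
    ys = z >> N
    rows = []
    cols = []
    for i in range(N):
        rows.append(z)
        cols.append(upd[xs, i] | (upd[ys, i] << N))
    P = sp.csr_matrix(
        (
            np.full(M * N, 1.0 / N),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(M, M),
    )
    P.sum_duplicates()
    bits = ((np.arange(n)[:, None] >> np.arange(N)) & 1).astype(np.float64)
    return P, bits[xs], bits[ys]


def _stationary(P_sub: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible finite chain (dense)."""
    m = P_sub.shape[0]
    if m == 1:
        return np.ones(1)
    A = np.vstack([P_sub.T - np.eye(m), np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def exact_measures_async(
    net: BooleanNetwork, source_mode: str = "p", cap: int = ASYNC_PAIR_CAP
) -> dict[str, float]:
    """Exact delta, h_inf, phi, q under uniformly-random asynchronous update.

    Built on the coupled chain over (X, Y) joint states: Cesaro (long-run
    time-average) expectations come from stationary distributions of the
    closed communicating classes plus transient absorption solves; delta uses
    the N-step power of the one-step pair chain (N node updates).
    """
    if net.N > cap:
        raise ValueError(
            f"N={net.N} exceeds the asynchronous pair-chain cap of {cap}; "
            "use the stochastic estimator instead"
        )
    N = net.N
    n = 1 << N
    M = n * n
    targets = _perturbable_indices(net, source_mode)
    P, bits_x, bits_y = _pair_chain(net)
    z = np.arange(M, dtype=np.int64)
    hamming = np.array(
        [int(v).bit_count() for v in (z & (n - 1)) ^ (z >> N)], dtype=np.float64
    )

    # --- closed communicating classes and their Cesaro values -------------
    n_comp, labels, terminal = _terminal_components(P)
    u_h = np.zeros(M)
    u_phi = np.zeros(M)
    u_q = np.zeros(M)
    closed_mask = np.zeros(M, dtype=bool)
    for c in terminal:
        idx = np.flatnonzero(labels == c)
        closed_mask[idx] = True
        pi = _stationary(P[idx][:, idx].toarray())
        u_h[idx] = float(pi @ hamming[idx])
        mx = pi @ bits_x[idx]
        my = pi @ bits_y[idx]
        u_phi[idx] = float(np.abs(mx - my).sum())
        # node fixed within the class iff constant across all class states
        sig_x = _member_signature(bits_x[idx])
        sig_y = _member_signature(bits_y[idx])
        u_q[idx] = 1.0 if sig_x == sig_y else 0.0

    transient = np.flatnonzero(~closed_mask)
    if transient.size:
        rhs = np.column_stack([u_h, u_phi, u_q])
        A = (sp.identity(transient.size, format="csc") - P[transient][:, transient]).tocsc()
        b = P[transient].dot(rhs)
        sol = spsolve(A, b)
        sol = np.atleast_2d(sol).reshape(transient.size, 3)
        u_h[transient], u_phi[transient], u_q[transient] = sol.T
        # linear-solve round-off: expectations of bounded quantities
        np.clip(u_h, 0.0, None, out=u_h)
        np.clip(u_phi, 0.0, None, out=u_phi)
        np.clip(u_q, 0.0, 1.0, out=u_q)

    # --- delta: expected Hamming distance after N shared updates ----------
    v = hamming.copy()
    for _ in range(N):
        v = P.dot(v)

    delta_sum = h_sum = phi_sum = q_sum = 0.0
    n_pairs = 0
    for s in range(n):
        for i in targets:
            z0 = s | ((s ^ (1 << i)) << N)
            delta_sum += v[z0]
            h_sum += u_h[z0]
            phi_sum += u_phi[z0]
            q_sum += u_q[z0]
            n_pairs += 1
    return {
        "derrida": delta_sum / n_pairs,
        "final_hamming": h_sum / n_pairs,
        "fragility": phi_sum / n_pairs,
        "quasicoherence": q_sum / n_pairs,
    }


def _member_signature(bits: np.ndarray) -> str:
    chars = []
    for j in range(bits.shape[1]):
        col = bits[:, j]
        if (col == 0).all():
            chars.append("0")
        elif (col == 1).all():
            chars.append("1")
        else:
            chars.append("*")
    return "".join(chars)


# ---------------------------------------------------------------------------
# Cesaro mean node values (for the RMS update-scheme difference)
# ---------------------------------------------------------------------------

def exact_mean_node_values(
    net: BooleanNetwork, scheme: str, cap: int = STG_CAP
) -> np.ndarray:
    """Long-run time-averaged node values, averaged over uniform initial states."""
    scheme = _check_scheme(scheme)
    N = net.N
    if scheme == ASYNCHRONOUS and N > ASYNC_PAIR_CAP * 2:
        raise ValueError(f"N={N} exceeds the dense-chain cap")
    if N > cap:
        raise ValueError(f"N={N} exceeds the exact-enumeration cap of {cap}")
    n = 1 << N
    bits = ((np.arange(n)[:, None] >> np.arange(N)) & 1).astype(np.float64)
    if scheme == SYNCHRONOUS:
        succ = _sync_successor(net)
        total = np.zeros(N)
        for s in range(n):
            seen: dict[int, int] = {}
            traj: list[int] = []
            cur = s
            while cur not in seen:
                seen[cur] = len(traj)
                traj.append(cur)
                cur = int(succ[cur])
            cycle = traj[seen[cur] :]
            total += bits[cycle].mean(axis=0)
        return total / n
    # asynchronous: single chain on 2**N states
    stg = build_stg(net, ASYNCHRONOUS, cap=cap)
    P = _uniform_transition_matrix(stg)
    n_comp, labels, terminal = _terminal_components(P)
    u = np.zeros((n, N))
    closed_mask = np.zeros(n, dtype=bool)
    for c in terminal:
        idx = np.flatnonzero(labels == c)
        closed_mask[idx] = True
        pi = _stationary(P[idx][:, idx].toarray())
        u[idx] = pi @ bits[idx]
    transient = np.flatnonzero(~closed_mask)
    if transient.size:
        A = (sp.identity(transient.size, format="csc") - P[transient][:, transient]).tocsc()
        sol = spsolve(A, P[transient].dot(u))
        u[transient] = np.atleast_2d(sol).reshape(transient.size, N)
    return np.clip(u, 0.0, 1.0).mean(axis=0)


def steady_states(net: BooleanNetwork) -> list[int]:
    """Fixed points f(s) = s (identical under both update schemes)."""
    succ = _sync_successor(net)
    return [int(s) for s in np.flatnonzero(succ == np.arange(succ.size))]
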