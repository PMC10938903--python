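"""Walker-ensemble evolution under synchronous and asynchronous update.

An ensemble is a W x N binary matrix of independent network instances
("walkers").  Synchronous update recomputes every node of every walker from
the pre-step state; asynchronous update recomputes exactly one uniformly
chosen node per walker per step.  Asynchronous schedules are counter-based
(Philox): the node chosen for walker w at step t depends only on (seed, t, w),
so replay is exact regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import BooleanNetwork

__all__ = [
    "SYNCHRONOUS",
    "ASYNCHRONOUS",
    "WalkerEnsemble",
    "UpdateSchedule",
    "PairedExperiment",
    "WindowAverage",
    "ConvergenceReport",
    "sample_initial_states",
    "step",
    "evolve",
    "run_with_window",
    "convergence_check",
    "default_window",
]

SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"

_SCHEME_ALIASES = {
    "s": SYNCHRONOUS,
    "sync": SYNCHRONOUS,
    SYNCHRONOUS: SYNCHRONOUS,
    "a": ASYNCHRONOUS,
    "async": ASYNCHRONOUS,
    ASYNCHRONOUS: ASYNCHRONOUS,
}


def normalize_scheme(scheme: str) -> str:
    try:
        return _SCHEME_ALIASES[scheme]
    except KeyError:
        raise ValueError(f"unknown update scheme {scheme!r}") from None


def default_window(N: int, total: int | None = None) -> tuple[int, int]:
    """Default (burn-in, window) split of the 55N + 6000 step budget.

    The window is the largest multiple of 4 not exceeding half the total;
    the remainder is burn-in.
    """
    if total is None:
        total = 55 * N + 6000
    T_w = (total // 2) // 4 * 4
    return total - T_w, T_w


@dataclass
class WalkerEnsemble:
    """W x N binary state matrix plus a step counter."""

    states: np.ndarray  # uint8, shape (W, N)
    t: int = 0

    def __post_init__(self):
        self.states = np.ascontiguousarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("states must be a W x N matrix with W >= 1")
        if self.states.size and int(self.states.max()) > 1:
            raise ValueError("ensemble entries must be 0 or 1")

    @property
    def W(self) -> int:
        return self.states.shape[0]

    @property
    def N(self) -> int:
        return self.states.shape[1]

    def copy(self) -> "WalkerEnsemble":
        return WalkerEnsemble(self.states.copy(), self.t)


def sample_initial_states(N: int, W: int, seed) -> WalkerEnsemble:
    """IID uniform binary initial states, reproducible under the seed."""
    if W < 1:
        raise ValueError("W must be >= 1")
    rng = np.random.default_rng(seed)
    return WalkerEnsemble(rng.integers(0, 2, size=(W, N), dtype=np.uint8), 0)


# 64-bit draws reserved per asynchronous step; generous so that bounded-int
# rejection sampling can never spill into the next step's block.
def _stride(W: int) -> int:
    return 4 * W + 64


@dataclass(frozen=True)
class UpdateSchedule:
    """Update scheme plus the seed driving asynchronous node selection.

    Replaying a schedule with the same seed reproduces the identical node
    sequence.  Synchronous schedules carry no randomness (all nodes, every
    step).
    """

    scheme: str
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "scheme", normalize_scheme(self.scheme))
        if self.scheme == ASYNCHRONOUS and self.seed is None:
            raise ValueError("asynchronous schedules require an explicit seed")

    def node_choices(self, t: int, W: int, n_nodes: int) -> np.ndarray:
        """Uniform node index per walker for step ``t`` (asynchronous only)."""
        if self.scheme != ASYNCHRONOUS:
            raise ValueError("synchronous schedules have no node choices")
        bitgen = np.random.Philox(key=self.seed)
        bitgen = bitgen.advance(t * _stride(W))
        rng = np.random.Generator(bitgen)
        return rng.integers(0, n_nodes, size=W, dtype=np.int64)


def _sync_step(states: np.ndarray, net: BooleanNetwork) -> np.ndarray:
    W = states.shape[0]
    new = np.empty_like(states)
    for j, comp in enumerate(net.compiled):
        if not comp.inputs:
            new[:, j] = comp.table[0]
            continue
        idx = np.zeros(W, dtype=np.intp)
        for b, k in enumerate(comp.inputs):
            idx |= states[:, k].astype(np.intp) << b
        new[:, j] = comp.table[idx]
    return new


def _async_step(
    states: np.ndarray, net: BooleanNetwork, choices: np.ndarray
) -> np.ndarray:
    new = states.copy()
    for j in np.unique(choices):
        mask = choices == j
        comp = net.compiled[j]
        if not comp.inputs:
            new[mask, j] = comp.table[0]
            continue
        idx = np.zeros(int(mask.sum()), dtype=np.intp)
        sub = states[mask]
        for b, k in enumerate(comp.inputs):
            idx |= sub[:, k].astype(np.intp) << b
        new[mask, j] = comp.table[idx]
    return new


def step(
    ensemble: WalkerEnsemble, net: BooleanNetwork, schedule: UpdateSchedule
) -> WalkerEnsemble:
    """Advance every walker by one step under the schedule."""
    if ensemble.N != net.N:
        raise ValueError(
            f"ensemble has {ensemble.N} columns but the network has {net.N} nodes"
        )
    if schedule.scheme == SYNCHRONOUS:
        new = _sync_step(ensemble.states, net)
    else:
        choices = schedule.node_choices(ensemble.t, ensemble.W, net.N)
        new = _async_step(ensemble.states, net, choices)
    return WalkerEnsemble(new, ensemble.t + 1)


def evolve(
    net: BooleanNetwork,
    ensemble: WalkerEnsemble,
    schedule: UpdateSchedule,
    steps: int,
) -> WalkerEnsemble:
    """Advance the ensemble by ``steps`` steps."""
    states, t = ensemble.states, ensemble.t
    for _ in range(steps):
        if schedule.scheme == SYNCHRONOUS:
            states = _sync_step(states, net)
        else:
            states = _async_step(states, net, schedule.node_choices(t, states.shape[0], net.N))
        t += 1
    return WalkerEnsemble(states, t)


@dataclass(frozen=True)
class WindowAverage:
    """Time averages over the last T_w steps of a run.

    ``means`` is per-walker (W x N) unless the run was aggregated (N,);
    ``quarter_means`` holds ensemble-aggregated per-node means over the four
    equal quarters of the window (4 x N), used for convergence checking.
    """

    means: np.ndarray
    quarter_means: np.ndarray
    T_b: int
    T_w: int
    n_walkers: int


def run_with_window(
    net: BooleanNetwork,
    ensemble: WalkerEnsemble,
    schedule: UpdateSchedule,
    T_b: int,
    T_w: int,
    aggregate: bool = False,
) -> WindowAverage:
    """Evolve T_b + T_w steps and average states over the last T_w steps."""
    if T_w < 4:
        raise ValueError("T_w must be at least 4")
    if T_w % 4 != 0:
        raise ValueError("T_w must be divisible by 4 (quarter-mean convergence check)")
    if T_b < 0:
        raise ValueError("T_b must be nonnegative")
    ens = evolve(net, ensemble, schedule, T_b)
    W, N = ens.W, ens.N
    sums = np.zeros((W, N), dtype=np.int64)
    qsums = np.zeros((4, N), dtype=np.int64)
    quarter = T_w // 4
    states, t = ens.states, ens.t
    for k in range(T_w):
        if schedule.scheme == SYNCHRONOUS:
            states = _sync_step(states, net)
        else:
            states = _async_step(states, net, schedule.node_choices(t, W, net.N))
        t += 1
        sums += states
        qsums[k // quarter] += states.sum(axis=0, dtype=np.int64)
    means = sums / T_w
    if aggregate:
        means = means.mean(axis=0)
    quarter_means = qsums / (quarter * W)
    return WindowAverage(means, quarter_means, T_b, T_w, W)


@dataclass(frozen=True)
class ConvergenceReport:
    passed: bool
    max_disagreement: float
    per_node: np.ndarray

    def __bool__(self) -> bool:
        return self.passed


def convergence_check(avg: WindowAverage, tol: float = 0.0066) -> ConvergenceReport:
    """Largest per-node spread across the four quarter-means vs a tolerance."""
    per_node = avg.quarter_means.max(axis=0) - avg.quarter_means.min(axis=0)
    worst = float(per_node.max()) if per_node.size else 0.0
    return ConvergenceReport(worst <= tol, worst, per_node)


@dataclass
class PairedExperiment:
    """Matched unperturbed/perturbed ensembles sharing one update schedule.

    At t=0, pair w differs from its partner only in node ``targets[w]``; at
    every subsequent step both members update the same node set.
    """

    unperturbed: WalkerEnsemble
    perturbed: WalkerEnsemble
    targets: np.ndarray  # flipped node index per pair
    schedule: UpdateSchedule

    @classmethod
    def create(
        cls,
        ensemble: WalkerEnsemble,
        targets: np.ndarray,
        schedule: UpdateSchedule,
    ) -> "PairedExperiment":
        targets = np.asarray(targets, dtype=np.int64)
        if targets.shape != (ensemble.W,):
            raise ValueError("need exactly one flip target per walker")
        flipped = ensemble.states.copy()
        flipped[np.arange(ensemble.W), targets] ^= 1
        return cls(
            ensemble.copy(),
            WalkerEnsemble(flipped, ensemble.t),
            targets,
            schedule,
        )

    def step_pair(self, net: BooleanNetwork) -> None:
        """Advance both members one step with a shared node selection."""
        x, y = self.unperturbed, self.perturbed
        if self.schedule.scheme == SYNCHRONOUS:
            xs = _sync_step(x.states, net)
            ys = _sync_step(y.states, net)
        else:
            choices = self.schedule.node_choices(x.t, x.W, net.N)
            xs = _async_step(x.states, net, choices)
            ys = _async_step(y.states, net, choices)
        self.unperturbed = WalkerEnsemble(xs, x.t + 1)
        self.perturbed = WalkerEnsemble(ys, y.t + 1)

    def hamming(self) -> np.ndarray:
        """Current per-pair Hamming distance."""
        diff = self.unperturbed.states != self.perturbed.states
        return diff.sum(axis=1).astype(np.int64)
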