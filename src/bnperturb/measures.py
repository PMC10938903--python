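"""Perturbation-response measures: Derrida coefficient, final Hamming
distance, fragility, quasicoherence, and the RMS update-scheme difference.

Each of the four single-node-perturbation measures comes in four variants:
update scheme (subscript ``s``/``a``) crossed with source-node handling
(``p`` = source nodes perturbable, ``f`` = sources fixed).  In mode ``f``,
source nodes are excluded from the flip-target set and from the averaging
prefactor, but they are still sampled uniformly at t=0, still update as
identities, and still count in the Hamming norm (where they contribute zero
by construction).  Constant nodes remain perturbable in both modes.

The three long-term measures share one paired-trajectory simulation pass so
that the per-sample inequality fragility <= final Hamming distance holds by
construction, not only in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    ASYNCHRONOUS,
    SYNCHRONOUS,
    PairedExperiment,
    UpdateSchedule,
    WalkerEnsemble,
    _async_step,
    _sync_step,
    default_window,
    normalize_scheme,
)
from .network import BooleanNetwork, classify_nodes

__all__ = [
    "MeasureResult",
    "QuasiattractorSignature",
    "LongTermMeasures",
    "derrida",
    "final_hamming",
    "fragility",
    "quasicoherence",
    "long_term_measures",
    "rms_update_difference",
    "signature_from_means",
    "perturbable_targets",
    "DEFAULT_EPS",
    "DEFAULT_WALKERS_PER_TARGET",
    "DEFAULT_DERRIDA_PAIRS",
]

DEFAULT_EPS = 1e-9
DEFAULT_WALKERS_PER_TARGET = 2500
DEFAULT_DERRIDA_PAIRS = 100_000

_SCHEME_CODE = {SYNCHRONOUS: "s", ASYNCHRONOUS: "a"}


@dataclass(frozen=True)
class MeasureResult:
    """One measure value with its sampling metadata."""

    measure: str
    scheme: str  # "s", "a", or "sa" for the cross-scheme RMS difference
    source_mode: str | None
    value: float
    stderr: float
    n_pairs: int
    W: int
    T_b: int | None
    T_w: int | None
    seed: int | None

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("measure values are nonnegative")
        if self.stderr < 0:
            raise ValueError("stderr is nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class QuasiattractorSignature:
    """Per-node trit pattern derived from window time-averages."""

    pattern: str  # over {0, 1, *}

    def __str__(self) -> str:
        return self.pattern


def signature_from_means(means: np.ndarray, eps: float) -> QuasiattractorSignature:
    """fixed-0 iff mean <= eps, fixed-1 iff mean >= 1 - eps, else oscillating."""
    chars = np.where(means <= eps, "0", np.where(means >= 1.0 - eps, "1", "*"))
    return QuasiattractorSignature("".join(chars.tolist()))


def perturbable_targets(net: BooleanNetwork, source_mode: str) -> np.ndarray:
    """Flip-target node indices for a source mode ('p' = all nodes,
    'f' = non-source nodes only)."""
    if source_mode not in ("p", "f"):
        raise ValueError(f"source_mode must be 'p' or 'f', got {source_mode!r}")
    if source_mode == "p":
        return np.arange(net.N, dtype=np.int64)
    labels = classify_nodes(net).labels
    targets = np.array(
        [i for i in range(net.N) if labels[i] != "source"], dtype=np.int64
    )
    if targets.size == 0:
        raise ValueError(
            "fixed-source mode is undefined: every node is a source node"
        )
    return targets


def _stderr(contrib: np.ndarray) -> float:
    if contrib.size < 2:
        return 0.0
    return float(np.std(contrib, ddof=1) / np.sqrt(contrib.size))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Derrida coefficient
# ---------------------------------------------------------------------------

def derrida(
    net: BooleanNetwork,
    scheme: str = SYNCHRONOUS,
    source_mode: str = "p",
    n_pairs: int = DEFAULT_DERRIDA_PAIRS,
    seed: int = 0,
) -> MeasureResult:
    """Mean Hamming distance between a trajectory and its single-node-flipped
    copy after one network update (one synchronous step, or N asynchronous
    steps on a shared schedule)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    scheme = normalize_scheme(scheme)
    targets_pool = perturbable_targets(net, source_mode)
    seed_init, seed_targets, seed_sched = _spawn_seeds(seed, 3)
    rng = np.random.default_rng(seed_init)
    X0 = rng.integers(0, 2, size=(n_pairs, net.N), dtype=np.uint8)
    targets = np.random.default_rng(seed_targets).choice(targets_pool, size=n_pairs)
    schedule = UpdateSchedule(scheme, seed_sched if scheme == ASYNCHRONOUS else None)
    pair = PairedExperiment.create(WalkerEnsemble(X0, 0), targets, schedule)
    t_f = 1 if scheme == SYNCHRONOUS else net.N
    for _ in range(t_f):
        pair.step_pair(net)
    contrib = pair.hamming().astype(np.float64)
    return MeasureResult(
        measure="derrida",
        scheme=_SCHEME_CODE[scheme],
        source_mode=source_mode,
        value=float(contrib.mean()),
        stderr=_stderr(contrib),
        n_pairs=n_pairs,
        W=n_pairs,
        T_b=None,
        T_w=None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Long-term measures (shared simulation pass)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongTermMeasures:
    """Final Hamming distance, fragility and quasicoherence from one pass."""

    final_hamming: MeasureResult
    fragility: MeasureResult
    quasicoherence: MeasureResult
    #: ensemble-aggregated per-node quarter means of the unperturbed member
    quarter_means: np.ndarray
    #: per-pair contributions (h, phi, q), kept for diagnostics/tests
    per_pair: dict[str, np.ndarray]


def long_term_measures(
    net: BooleanNetwork,
    scheme: str = SYNCHRONOUS,
    source_mode: str = "p",
    W_per_target: int = DEFAULT_WALKERS_PER_TARGET,
    T_b: int | None = None,
    T_w: int | None = None,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
) -> LongTermMeasures:
    """Evolve matched trajectory pairs and window-average them.

    For every perturbable target, ``W_per_target`` uniform initial states are
    sampled; each pair shares its update schedule.  Per pair, the window
    yields the time-averaged Hamming distance (h), the L1 distance of the two
    window-mean vectors (phi), and the indicator that both quasiattractor
    signatures match (q).  Values are pooled over all pairs, which realizes
    the uniform average over targets with the 1/N (mode p) or 1/#non-source
    (mode f) prefactor.
    """
    scheme = normalize_scheme(scheme)
    if W_per_target < 1:
        raise ValueError("W_per_target must be >= 1")
    if not (0.0 <= eps < 0.5):
        raise ValueError("eps must lie in [0, 0.5)")
    if T_b is None or T_w is None:
        d_b, d_w = default_window(net.N)
        T_b = d_b if T_b is None else T_b
        T_w = d_w if T_w is None else T_w
    if T_w < 4 or T_w % 4 != 0:
        raise ValueError("T_w must be a multiple of 4 and at least 4")
    targets_pool = perturbable_targets(net, source_mode)
    n_pairs = W_per_target * targets_pool.size
    seed_init, seed_sched = _spawn_seeds(seed, 2)

    rng = np.random.default_rng(seed_init)
    X0 = rng.integers(0, 2, size=(n_pairs, net.N), dtype=np.uint8)
    targets = np.repeat(targets_pool, W_per_target)
    schedule = UpdateSchedule(scheme, seed_sched if scheme == ASYNCHRONOUS else None)

    X = X0.copy()
    Y = X0.copy()
    Y[np.arange(n_pairs), targets] ^= 1

    t = 0
    for _ in range(T_b):
        X, Y, t = _shared_step(net, X, Y, schedule, t)

    ham_sum = np.zeros(n_pairs, dtype=np.int64)
    x_sum = np.zeros((n_pairs, net.N), dtype=np.int64)
    y_sum = np.zeros((n_pairs, net.N), dtype=np.int64)
    q_sums = np.zeros((4, net.N), dtype=np.int64)
    quarter = T_w // 4
    for k in range(T_w):
        X, Y, t = _shared_step(net, X, Y, schedule, t)
        diff = X != Y
        ham_sum += diff.sum(axis=1, dtype=np.int64)
        x_sum += X
        y_sum += Y
        q_sums[k // quarter] += X.sum(axis=0, dtype=np.int64)

    h = ham_sum / T_w
    mx = x_sum / T_w
    my = y_sum / T_w
    phi = np.abs(mx - my).sum(axis=1)
    fixed0_x, fixed1_x = mx <= eps, mx >= 1.0 - eps
    fixed0_y, fixed1_y = my <= eps, my >= 1.0 - eps
    q = ((fixed0_x == fixed0_y) & (fixed1_x == fixed1_y)).all(axis=1).astype(np.float64)
    quarter_means = q_sums / (quarter * n_pairs)

    meta = dict(
        scheme=_SCHEME_CODE[scheme],
        source_mode=source_mode,
        n_pairs=n_pairs,
        W=W_per_target,
        T_b=T_b,
        T_w=T_w,
        seed=seed,
    )
    return LongTermMeasures(
        final_hamming=MeasureResult(
            measure="final_hamming", value=float(h.mean()), stderr=_stderr(h), **meta
        ),
        fragility=MeasureResult(
            measure="fragility", value=float(phi.mean()), stderr=_stderr(phi), **meta
        ),
        quasicoherence=MeasureResult(
            measure="quasicoherence", value=float(q.mean()), stderr=_stderr(q), **meta
        ),
        quarter_means=quarter_means,
        per_pair={"final_hamming": h, "fragility": phi, "quasicoherence": q},
    )


def _shared_step(net, X, Y, schedule, t):
    if schedule.scheme == SYNCHRONOUS:
        return _sync_step(X, net), _sync_step(Y, net), t + 1
    choices = schedule.node_choices(t, X.shape[0], net.N)
    return (
        _async_step(X, net, choices),
        _async_step(Y, net, choices),
        t + 1,
    )


def final_hamming(net, scheme=SYNCHRONOUS, source_mode="p",
                  W_per_target=DEFAULT_WALKERS_PER_TARGET,
                  T_b=None, T_w=None, seed=0) -> MeasureResult:
    """Asymptotic time-averaged Hamming separation of flipped pairs."""
    return long_term_measures(
        net, scheme, source_mode, W_per_target, T_b, T_w, seed=seed
    ).final_hamming


def fragility(net, scheme=SYNCHRONOUS, source_mode="p",
              W_per_target=DEFAULT_WALKERS_PER_TARGET,
              T_b=None, T_w=None, seed=0) -> MeasureResult:
    """L1 separation of window-mean vectors of flipped pairs."""
    return long_term_measures(
        net, scheme, source_mode, W_per_target, T_b, T_w, seed=seed
    ).fragility


def quasicoherence(net, scheme=SYNCHRONOUS, source_mode="p",
                   W_per_target=DEFAULT_WALKERS_PER_TARGET,
                   T_b=None, T_w=None, eps=DEFAULT_EPS, seed=0) -> MeasureResult:
    """Fraction of flipped pairs converging to the same quasiattractor."""
    return long_term_measures(
        net, scheme, source_mode, W_per_target, T_b, T_w, eps=eps, seed=seed
    ).quasicoherence


# ---------------------------------------------------------------------------
# RMS update-scheme difference
# ---------------------------------------------------------------------------

def rms_update_difference(
    net: BooleanNetwork,
    W: int = DEFAULT_WALKERS_PER_TARGET,
    T_b: int | None = None,
    T_w: int | None = None,
    seed: int = 0,
) -> MeasureResult:
    """Root-mean-squared difference across nodes between the converged
    ensemble-mean node values under synchronous vs asynchronous update."""
    from .dynamics import run_with_window, sample_initial_states

    if T_b is None or T_w is None:
        d_b, d_w = default_window(net.N)
        T_b = d_b if T_b is None else T_b
        T_w = d_w if T_w is None else T_w
    seed_init, seed_sched = _spawn_seeds(seed, 2)
    means = {}
    for scheme in (SYNCHRONOUS, ASYNCHRONOUS):
        ens = sample_initial_states(net.N, W, seed_init)
        schedule = UpdateSchedule(
            scheme, seed_sched if scheme == ASYNCHRONOUS else None
        )
        avg = run_with_window(net, ens, schedule, T_b, T_w, aggregate=True)
        means[scheme] = avg.means
    diff = means[SYNCHRONOUS] - means[ASYNCHRONOUS]
    value = float(np.sqrt(np.mean(diff**2)))
    return MeasureResult(
        measure="rms_update_difference",
        scheme="sa",
        source_mode=None,
        value=value,
        stderr=0.0,
        n_pairs=0,
        W=W,
        T_b=T_b,
        T_w=T_w,
        seed=seed,
    )
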