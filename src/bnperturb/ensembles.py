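"""NK random Boolean network ensembles and built-in fixture networks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .network import BooleanNetwork, classify_nodes, parse_network

__all__ = [
    "RBNSpec",
    "RBNSourceStats",
    "generate_rbn",
    "source_free_fraction",
    "fixture",
    "FIXTURE_RULES",
]

# Worked-example fixture networks.
FIXTURE_RULES = {
    "oscillator": "A, !A",
    "oscillator_plus_source": "A, !A\nB, B",
    "mutual_inhibition": "A, !B\nB, !A",
    "three_cycle": "A, B\nB, C\nC, A",
    "all_constant": "A, 0\nB, 1",
}


def fixture(name: str) -> BooleanNetwork:
    """Return one of the built-in worked-example networks by name."""
    try:
        rules = FIXTURE_RULES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_RULES)}"
        ) from None
    return parse_network(rules)


@dataclass(frozen=True)
class RBNSpec:
    """Classic Kauffman NK ensemble: each node gets K distinct regulators
    sampled uniformly (self allowed) and a truth table sampled uniformly from
    all 2**(2**K) Boolean functions."""

    N: int
    K: int

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (1 <= self.K <= self.N):
            raise ValueError("K must satisfy 1 <= K <= N")
        if self.K > 16:
            raise ValueError("K above 16 is not supported (truth-table blowup)")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_rbn(spec: RBNSpec, seed) -> BooleanNetwork:
    """Sample one NK network; reproducible under the seed.

    ``seed`` may be an int or a ``numpy.random.Generator`` (the latter lets a
    caller draw many networks from one stream).
    """
    rng = _as_rng(seed)
    names = [f"n{i}" for i in range(spec.N)]
    inputs = []
    tables = []
    for _ in range(spec.N):
        inputs.append(sorted(int(v) for v in rng.choice(spec.N, size=spec.K, replace=False)))
        tables.append(rng.integers(0, 2, size=1 << spec.K, dtype=np.uint8))
    return BooleanNetwork.from_truth_tables(names, inputs, tables)


@dataclass(frozen=True)
class RBNSourceStats:
    """Source-node prevalence over a sampled ensemble."""

    fraction_source_free: float
    ci_low: float
    ci_high: float
    n_networks: int
    n_source_free: int
    source_counts: np.ndarray  # per-network number of source nodes
    constant_counts: np.ndarray  # per-network number of constant nodes


def source_free_fraction(
    spec: RBNSpec, n_networks: int, seed, confidence: float = 0.95
) -> RBNSourceStats:
    """Fraction of sampled NK networks with zero semantically-classified
    source nodes, with an exact (Clopper-Pearson) binomial CI."""
    if n_networks < 100:
        raise ValueError("n_networks must be >= 100 for a meaningful estimate")
    rng = _as_rng(seed)
    source_counts = np.empty(n_networks, dtype=np.int64)
    constant_counts = np.empty(n_networks, dtype=np.int64)
    for m in range(n_networks):
        net = generate_rbn(spec, rng)
        cls = classify_nodes(net)
        source_counts[m] = len(cls.sources)
        constant_counts[m] = len(cls.constants)
    k = int((source_counts == 0).sum())
    ci = binomtest(k, n_networks).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return RBNSourceStats(
        fraction_source_free=k / n_networks,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_networks=n_networks,
        n_source_free=k,
        source_counts=source_counts,
        constant_counts=constant_counts,
    )
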