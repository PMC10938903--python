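# bnperturb

Perturbation-response analysis of Boolean networks.

`bnperturb` simulates ensembles of Boolean-network instances ("walkers")
under synchronous and uniformly-random asynchronous update, and computes
four single-node perturbation-response measures:

* **Derrida coefficient (δ)** — mean Hamming separation of a trajectory and
  its single-node-flipped copy after one network update (one synchronous
  step, or N asynchronous steps on a shared schedule);
* **final Hamming distance (h∞)** — long-run time-averaged Hamming
  separation of flipped trajectory pairs (phase-shift sensitive);
* **fragility (φ)** — L1 distance between the long-run mean state vectors of
  flipped pairs (phase-shift insensitive);
* **quasicoherence (q)** — fraction of flipped pairs converging to the same
  quasiattractor (pattern of fixed-0 / fixed-1 / oscillating nodes).

Each measure comes in four variants: update scheme (subscript `s`/`a`)
crossed with source-node handling (`p` = sources perturbable, `f` = sources
excluded from the flip targets and the averaging prefactor). A cross-scheme
RMS difference of converged mean node values quantifies timing robustness.

The package also provides:

* a BNet-style rule-file parser (`target, expression` with `&`/`|`/`!` or
  `AND`/`OR`/`NOT`), semantic node classification (constant / source /
  internal by truth-table equivalence), and network reduction (source-value
  percolation, self-edge-free node elimination);
* an **exact oracle** for small networks: state-transition graphs,
  attractors as terminal SCCs, basins and absorption probabilities,
  quasiattractors, and exact values of all four measures (synchronous by
  joint-cycle enumeration; asynchronous via the coupled pair Markov chain);
* **NK random Boolean network** generation and source-node prevalence
  statistics.

## CLI

```sh
# all 16 scheme x mode variants of the four measures on a built-in fixture
bnperturb measure --fixture oscillator --all --seed 1

# selected measures on a rule file
bnperturb measure --model my_model.bnet --measure fragility --measure rms \
    --scheme both --source-mode p --walkers 2500 --seed 7 --out results.json

# exact attractor / quasiattractor report (small networks)
bnperturb attractors --fixture mutual_inhibition --scheme both

# source-node prevalence in the uniform NK ensemble
bnperturb rbn-stats -n 20 -k 2 --samples 10000 --seed 3
```

JSON output is canonical and byte-reproducible from the seed; `--format csv`
flattens the measure records. `measure` exits nonzero if the quarter-mean
convergence check fails (`--tol`, default 0.0066) unless
`--no-strict-convergence` is given.

Simulation defaults: 2500 walkers per perturbation target, 100 000 Derrida
pairs, a total step budget of 55N + 6000 split into burn-in and an averaging
window (largest multiple of 4 ≤ half the budget).

## Library sketch

```python
import bnperturb as bp

net = bp.parse_network("A, !B\nB, !A")
bp.classify_nodes(net).labels           # ('internal', 'internal')

attrs = bp.find_attractors(bp.build_stg(net, "sync"))
attrs.n_attractors, attrs.basin_fractions()

res = bp.long_term_measures(net, "async", "p", W_per_target=2500, seed=0)
res.final_hamming.value, res.fragility.value, res.quasicoherence.value

bp.exact_measures_async(net, "p")       # exact small-N ground truth
```
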