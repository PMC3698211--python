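# bistacert

Certification toolkit for bistable mass-action reaction networks:

* **network_model** — declarative mass-action model definitions
  (YAML: species, reactions, rate constants, constant inputs), exact
  quadratic dynamics, analytic Jacobians, stiff simulation, and seeded
  multistart equilibrium search with stability classification.  Ships a
  9-species / 23-reaction model of the yeast galactose (GAL) regulatory
  switch as the flagship fixture, plus toy networks with closed-form
  oracles.
* **domain_of_attraction** — certifies axis-aligned boxes as subsets of
  the domain of attraction of an equilibrium by solving a linear-matrix-
  inequality feasibility problem per `gamma` (a quadratic Lyapunov
  certificate checked at the box faces and all 2^n vertices), grows
  maximal certified boxes by round-robin face stretching, and
  cross-validates certificates by dense trajectory sampling.
* **local_sensitivity** — forward sensitivity ODEs coupled to the state
  equations, normalized coefficients, and a deterministic influence
  ranking of all rate constants.
* **bifurcation** — pseudo-arclength equilibrium continuation with fold
  detection (Moore–Spence refinement) and two-parameter fold-curve
  continuation with cusp detection.
* **global_robustness** — steady-state exclusion certificates for
  (state box × parameter box) pairs via an LP relaxation of the bilinear
  equilibrium system (McCormick envelopes, with a lifted moment-matrix
  cutting-plane tier), a sound box-shrinkage procedure, and the two-box
  workflow that certifies persistence of bistability under simultaneous
  multi-parameter uncertainty.
* **cli_io** — `bistacert` command line, YAML run configurations, seeded
  determinism, JSON/CSV artifact round-trip.

No external SDP solver is required: all semidefinite feasibility problems
are solved by a cutting-plane outer approximation over `scipy`'s HiGHS LP
(infeasibility verdicts are genuine LP certificates; feasibility verdicts
are re-verified by independent eigenvalue checks).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` implements the acceptance criteria end to end.
Three asserts in it are deliberately red on this implementation — the
docstrings there explain why (published fold/threshold/box values that
are not reproducible from the published inputs, or that this toolkit's
tighter-but-sound relaxation supersedes).

## CLI

```sh
bistacert equilibria --model gal               # multistart steady states
bistacert da grow --equilibrium low            # grow a certified DA box
bistacert sens run --horizon 20                # sensitivity ranking
bistacert bif one --param k5 --range 1:50      # folds / bistable interval
bistacert bif two --params k7,k5               # fold curve + cusps
bistacert robust run --deltas 2,5,10,20,30,50  # robust two-box workflow
bistacert all --config run.yaml                # full three-phase workflow
```

Model files are plain YAML:

```yaml
species: [X, Y]
constants: {S: 10.0}
parameters: {k1: 2.0, mu: 1.0}
reactions:
  - "S + X -> X + X @ k1"
  - "X -> 0 @ mu"
```

Rates are strict mass action (`k` times the product of the reactant
concentrations, molecularity at most two), so the dynamics are exactly
quadratic — the property the certification machinery relies on.
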