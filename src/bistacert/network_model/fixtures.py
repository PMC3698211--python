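"""Packaged model fixtures.

The flagship fixture is a 9-species, 23-reaction mass-action model of the
yeast galactose (GAL) regulatory switch with a published bistable
parameter set; its two stable steady states and the published
domain-of-attraction box estimates used throughout the test-suite are
recorded here as well.  A small catalog of toy networks with closed-form oracles
supports unit testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reactions import ReactionNetwork, parse_model

__all__ = [
    "GAL_MODEL_TEXT",
    "GAL_SPECIES",
    "GAL_EQUILIBRIUM_LOW",
    "GAL_EQUILIBRIUM_HIGH",
    "GAL_DA_BOX_LOW",
    "GAL_DA_BOX_HIGH",
    "GAL_HIGH_SENSITIVITY_SET",
    "gal_model",
    "gal_da_boxes",
    "ToyModel",
    "toy_models",
]

# State ordering: (G3, Gint, G3a, G4, G80, G4_80, G80_3a, G2, G1);
# Gex is a constant input at 1000 uM (1 mM external galactose).
GAL_MODEL_TEXT = """\
name: gal_switch
species: [G3, Gint, G3a, G4, G80, G4_80, G80_3a, G2, G1]
constants:
  Gex: 1000.0
parameters:
  k1: 0.1814
  k2: 8.4586e-4
  kr2: 16.6691
  mu3: 1.0
  k4: 3.0749
  kr4: 0.1317
  k5: 22.0604
  mu6: 1.0
  k7: 29.6549
  k8: 181.4157
  k9: 1.0
  k10: 1.0
  k11: 85.8185
  kr11: 4.7482e-2
  mu12: 1.0
  mu13: 1.0
  mu14: 1.0
  mu15: 1.0
  mu16: 1.0
  mu17: 1.0
  mu18: 1.0
  k19: 36.6342
  kr19: 222.0536
reactions:
  - "Gex + G2 -> Gint + G2 @ k1"
  - "G3 + Gint -> G3a @ k2"
  - "G3a -> G3 + Gint @ kr2"
  - "G3a -> 0 @ mu3"
  - "G4_80 + G3a -> G80_3a + G4 @ k4"
  - "G80_3a + G4 -> G4_80 + G3a @ kr4"
  - "0 -> G4 @ k5"
  - "G4 -> 0 @ mu6"
  - "G4 -> G4 + G80 @ k7"
  - "G4 -> G4 + G3 @ k8"
  - "G4 -> G4 + G2 @ k9"
  - "G4 -> G4 + G1 @ k10"
  - "G4 + G80 -> G4_80 @ k11"
  - "G4_80 -> G4 + G80 @ kr11"
  - "G4_80 -> 0 @ mu12"
  - "G3 -> 0 @ mu13"
  - "G80 -> 0 @ mu14"
  - "G80_3a -> 0 @ mu15"
  - "Gint -> 0 @ mu16"
  - "G2 -> 0 @ mu17"
  - "G1 -> 0 @ mu18"
  - "G80_3a -> G80 + G3a @ k19"
  - "G80 + G3a -> G80_3a @ kr19"
"""

GAL_SPECIES = ("G3", "Gint", "G3a", "G4", "G80", "G4_80", "G80_3a", "G2", "G1")

#: published steady states (uM), low- and high-expression regimes
GAL_EQUILIBRIUM_LOW = np.array(
    [172.8212, 172.8208, 1.0, 1.0, 1.0, 21.0604, 7.5945, 1.0, 1.0]
)
GAL_EQUILIBRIUM_HIGH = np.array(
    [2711.1839, 2711.2003, 318.5443, 19.9479, 0.3061, 2.1126, 589.1342, 19.9479, 19.9479]
)

#: published domain-of-attraction box estimates (lower row, upper row)
GAL_DA_BOX_LOW = np.array(
    [
        [100.82, 100.82, 0.0, 0.0, 0.7, 18.06, 2.59, 0.0, 0.0],
        [312.82, 332.82, 4.0, 4.0, 3.0, 24.06, 27.59, 3.0, 3.0],
    ]
)
GAL_DA_BOX_HIGH = np.array(
    [
        [211.18, 209.20, 18.54, 8.95, 0.0, 1.11, 89.13, 6.9479, 7.95],
        [5213.2, 5622.0, 675.5, 30.9, 0.7, 3.2, 1528.1, 58.9, 320.9],
    ]
)

#: parameters reported to dominate the local sensitivity ranking
GAL_HIGH_SENSITIVITY_SET = frozenset(
    {"k1", "k2", "k5", "k7", "k8", "k9", "mu13", "mu16", "mu17"}
)


def gal_model() -> tuple[ReactionNetwork, np.ndarray]:
    """Fresh copy of the GAL switch network and its nominal parameters.

    Each call re-parses the packaged definition, so callers may mutate
    their copy freely.
    """
    network = parse_model(GAL_MODEL_TEXT)
    return network, network.nominal_parameters()


def gal_da_boxes():
    """The two published DA boxes as absolute-frame :class:`AxisBox` objects."""
    from ..domain_of_attraction.boxes import AxisBox

    return (
        AxisBox(GAL_DA_BOX_LOW[0], GAL_DA_BOX_LOW[1], frame="absolute"),
        AxisBox(GAL_DA_BOX_HIGH[0], GAL_DA_BOX_HIGH[1], frame="absolute"),
    )


@dataclass
class ToyModel:
    """A small fixture network with closed-form reference data."""

    name: str
    network: ReactionNetwork
    equilibria: list = field(default_factory=list)  # (state, stable) pairs
    notes: str = ""


def toy_models() -> dict[str, ToyModel]:
    """Catalog of toy fixtures with analytically known equilibria."""
    cat: dict[str, ToyModel] = {}

    # xdot = -x + x^2: equilibria 0 (stable) and 1 (unstable); the domain
    # of attraction of 0 is exactly (-inf, 1).
    net = parse_model(
        """
name: bistable_1d
species: [X]
parameters: {mu: 1.0, k: 1.0}
reactions:
  - "X -> 0 @ mu"
  - "X + X -> X + X + X @ k"
"""
    )
    cat["bistable_1d"] = ToyModel(
        "bistable_1d",
        net,
        equilibria=[(np.array([0.0]), True), (np.array([1.0]), False)],
        notes="DA of 0 is x < 1",
    )

    # xdot = k - mu x: unique stable equilibrium k/mu.
    net = parse_model(
        """
name: birth_death
species: [X]
parameters: {k: 1.5, mu: 1.5}
reactions:
  - "0 -> X @ k"
  - "X -> 0 @ mu"
"""
    )
    cat["birth_death"] = ToyModel(
        "birth_death",
        net,
        equilibria=[(np.array([1.0]), True)],
        notes="equilibrium k/mu; over k,mu in [kmin,kmax]x[mumin,mumax] the "
        "steady-state set is [kmin/mumax, kmax/mumin]",
    )

    # Autocatalytic X with quadratic Y feedback:
    #   xdot = a + b x^2 - c x - d x y,  ydot = e x^2 - f y.
    # Steady states solve a cubic with roots x = 1, 2, 4 (y = x^2/4):
    # stable / saddle / stable.
    net = parse_model(
        """
name: bistable_2d
species: [X, Y]
parameters: {a: 2.0, b: 1.75, c: 3.5, d: 1.0, e: 5.0, f: 20.0}
reactions:
  - "0 -> X @ a"
  - "X + X -> X + X + X @ b"
  - "X -> 0 @ c"
  - "X + Y -> Y @ d"
  - "X + X -> X + X + Y @ e"
  - "Y -> 0 @ f"
"""
    )
    cat["bistable_2d"] = ToyModel(
        "bistable_2d",
        net,
        equilibria=[
            (np.array([1.0, 0.25]), True),
            (np.array([2.0, 1.0]), False),
            (np.array([4.0, 4.0]), True),
        ],
        notes="cubic steady-state equation with roots 1, 2, 4",
    )

    # Linear cascade: udot = 0.5 v - u, vdot = -2 v; globally stable origin.
    net = parse_model(
        """
name: linear_2d
species: [U, V]
parameters: {kc: 0.5, ku: 1.0, kv: 2.0}
reactions:
  - "V -> V + U @ kc"
  - "U -> 0 @ ku"
  - "V -> 0 @ kv"
"""
    )
    cat["linear_2d"] = ToyModel(
        "linear_2d",
        net,
        equilibria=[(np.array([0.0, 0.0]), True)],
        notes="purely first-order; unique equilibrium at the origin",
    )
    return cat
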