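"""Mass-action reaction networks.

A :class:`ReactionNetwork` is a list of elementary mass-action reactions
over named species plus a set of constant inputs (species whose
concentration is held fixed and therefore contributes to rates but not to
the stoichiometry).  Rate laws are strictly mass-action: each reaction
fires at ``k * prod(reactant concentrations)`` with molecularity at most
two, so the resulting ODE right-hand side is at most quadratic in the
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ModelError",
    "parse_model",
    "parse_reaction",
    "network_to_text",
]


class ModelError(ValueError):
    """Raised for invalid model definitions."""


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` and ``products`` are multisets represented as tuples of
    identifiers (species or constant inputs); the empty tuple denotes the
    empty complex.  The rate is ``rate_constant_value`` times the product
    of the reactant concentrations.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant_name: str
    rate_constant_value: float

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ModelError(
                f"reaction '{self.rate_constant_name}': molecularity "
                f"{len(self.reactants)} > 2 is not supported"
            )
        if not np.isfinite(self.rate_constant_value) or self.rate_constant_value <= 0:
            raise ModelError(
                f"rate constant {self.rate_constant_name} = "
                f"{self.rate_constant_value} must be strictly positive"
            )

    def format(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"{lhs} -> {rhs} @ {self.rate_constant_name}"


def parse_reaction(text: str, parameters: Mapping[str, float]) -> Reaction:
    """Parse ``"A + B -> C + D @ k"`` into a :class:`Reaction`.

    Either side may be ``"0"`` (or empty) for the empty complex.
    """
    if "@" not in text:
        raise ModelError(f"reaction '{text}': missing '@ rate_constant'")
    body, _, kname = text.rpartition("@")
    kname = kname.strip()
    if kname not in parameters:
        raise ModelError(f"reaction '{text}': unknown rate constant '{kname}'")
    if "->" not in body:
        raise ModelError(f"reaction '{text}': missing '->'")
    lhs, _, rhs = body.partition("->")

    def side(s: str) -> tuple[str, ...]:
        s = s.strip()
        if s in ("", "0", "∅"):
            return ()
        return tuple(tok.strip() for tok in s.split("+"))

    return Reaction(side(lhs), side(rhs), kname, float(parameters[kname]))


class ReactionNetwork:
    """A validated mass-action network with pre-compiled rate structure."""

    def __init__(
        self,
        species_names: Sequence[str],
        reactions: Iterable[Reaction],
        constant_inputs: Mapping[str, float] | None = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.species_names: tuple[str, ...] = tuple(species_names)
        if len(set(self.species_names)) != len(self.species_names):
            raise ModelError("duplicate species names")
        self.constant_inputs: dict[str, float] = dict(constant_inputs or {})
        for cname, cval in self.constant_inputs.items():
            if cname in self.species_names:
                raise ModelError(f"'{cname}' is both a species and a constant input")
            if cval < 0:
                raise ModelError(f"constant input {cname} = {cval} must be >= 0")
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self._index = {s: i for i, s in enumerate(self.species_names)}
        self._validate()
        self._compile()

    # -- basic views -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Distinct rate-constant names in first-appearance order."""
        return self._param_names

    @property
    def n_parameters(self) -> int:
        return len(self._param_names)

    def nominal_parameters(self) -> np.ndarray:
        """Rate-constant values from the model definition, in parameter order."""
        return self._p_nominal.copy()

    def species_index(self, name: str) -> int:
        return self._index[name]

    def parameter_index(self, name: str) -> int:
        return self._param_index[name]

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix N, shape (n_species, n_reactions)."""
        return self._N.copy()

    # -- construction helpers ---------------------------------------------

    def _validate(self) -> None:
        known = set(self.species_names) | set(self.constant_inputs)
        for r in self.reactions:
            for ident in (*r.reactants, *r.products):
                if ident not in known:
                    raise ModelError(
                        f"reaction '{r.format()}': '{ident}' is neither a "
                        "species nor a constant input"
                    )

    def _compile(self) -> None:
        ns, nr = self.n_species, self.n_reactions
        N = np.zeros((ns, nr))
        pnames: list[str] = []
        pindex: dict[str, int] = {}
        pvals: list[float] = []
        react_param = np.zeros(nr, dtype=int)
        const_factor = np.ones(nr)
        # reactant species indices; -1 marks "absent"
        ridx = -np.ones((nr, 2), dtype=int)
        for j, r in enumerate(self.reactions):
            if r.rate_constant_name not in pindex:
                pindex[r.rate_constant_name] = len(pnames)
                pnames.append(r.rate_constant_name)
                pvals.append(r.rate_constant_value)
            elif pvals[pindex[r.rate_constant_name]] != r.rate_constant_value:
                raise ModelError(
                    f"rate constant {r.rate_constant_name} given two values"
                )
            react_param[j] = pindex[r.rate_constant_name]
            slot = 0
            for ident in r.reactants:
                if ident in self._index:
                    i = self._index[ident]
                    N[i, j] -= 1.0
                    ridx[j, slot] = i
                    slot += 1
                else:
                    const_factor[j] *= self.constant_inputs[ident]
            for ident in r.products:
                if ident in self._index:
                    N[self._index[ident], j] += 1.0
        self._N = N
        self._param_names = tuple(pnames)
        self._param_index = pindex
        self._p_nominal = np.asarray(pvals)
        self._react_param = react_param
        self._const_factor = const_factor
        self._reactant_idx = ridx

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        params: dict[str, float] = {}
        for r in self.reactions:
            params[r.rate_constant_name] = r.rate_constant_value
        return {
            "name": self.name,
            "species": list(self.species_names),
            "constants": dict(self.constant_inputs),
            "parameters": params,
            "reactions": [r.format() for r in self.reactions],
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionNetwork({self.name or 'unnamed'}: "
            f"{self.n_species} species, {self.n_reactions} reactions)"
        )


def parse_model(text: str) -> ReactionNetwork:
    """Parse a declarative YAML model definition into a network.

    The document must provide ``species`` (list), ``reactions`` (list of
    ``"A + B -> C @ k"`` strings) and ``parameters`` (map of rate-constant
    values); ``constants`` (map of fixed concentrations) and ``name`` are
    optional.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelError("model definition must be a mapping")
    for key in ("species", "reactions", "parameters"):
        if key not in doc:
            raise ModelError(f"model definition missing '{key}'")
    params = doc["parameters"]
    for k, v in params.items():
        if not isinstance(v, (int, float)):
            raise ModelError(f"parameter {k} = {v!r} is not a number")
    reactions = [parse_reaction(line, params) for line in doc["reactions"]]
    return ReactionNetwork(
        doc["species"],
        reactions,
        constant_inputs=doc.get("constants") or {},
        name=doc.get("name", ""),
    )


def network_to_text(network: ReactionNetwork) -> str:
    """Serialize a network back to its YAML definition.

    Parameter values are written with :func:`repr` so a round-trip through
    :func:`parse_model` reproduces them bit-exactly.
    """
    d = network.to_dict()
    lines = []
    if d["name"]:
        lines.append(f"name: {d['name']}")
    lines.append("species: [" + ", ".join(d["species"]) + "]")
    if d["constants"]:
        lines.append("constants:")
        for k, v in d["constants"].items():
            lines.append(f"  {k}: {v!r}")
    lines.append("parameters:")
    for k, v in d["parameters"].items():
        lines.append(f"  {k}: {v!r}")
    lines.append("reactions:")
    for r in d["reactions"]:
        lines.append(f'  - "{r}"')
    return "\n".join(lines) + "\n"
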