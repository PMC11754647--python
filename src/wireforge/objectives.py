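"""Built-in objective functions and the custom-objective registry.

Each objective maps a design state to a finite scalar together with an
optimisation direction.  The optimisers minimise internally; a maximised
objective is negated at evaluation time.

Built-ins
---------
``porosity``
    Ratio of bounding-box volume to DNA volume, the DNA modelled as one
    cylinder per edge with the bundle diameter of the edge type.  Values
    approach 1 as the box fills with material; minimising porosity is a
    utility heuristic (denser structures).
``variation_index``
    Population standard deviation of edge lengths after normalising by
    their mean.  Zero for perfectly uniform meshes; minimising it favours
    regular polyhedra-like designs.
``scaffold_usage``
    Relative deviation |N_nt - L| / L of the estimated scaffold demand
    from a fixed scaffold length L (M13mp18's 7249 nt by default).
    Minimising it drives designs toward full use of one physical scaffold
    — a manufacturability goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constraints import M13MP18_NT
from .errors import DuplicateNameError, NonFiniteObjectiveError, ZeroVolumeError
from .mesh import DesignState, estimate_scaffold_nt


def porosity(state: DesignState) -> float:
    """Bounding-box volume over cylindrical-model DNA volume (>= 1 in practice)."""
    lengths = state.edge_lengths()
    if len(lengths) == 0:
        raise ZeroVolumeError("porosity undefined: design has no edges")
    radius = state.edge_type.bundle_diameter / 2.0
    v_dna = math.pi * radius * radius * float(lengths.sum())
    return state.box.volume / v_dna


def variation_index(state: DesignState) -> float:
    """Population standard deviation of mean-normalised edge lengths."""
    lengths = state.edge_lengths()
    if len(lengths) == 0:
        raise ZeroVolumeError("variation index undefined: design has no edges")
    normalized = lengths / lengths.mean()
    return float(np.std(normalized))


def scaffold_usage(state: DesignState, L: int = M13MP18_NT) -> float:
    """Relative deviation of the scaffold estimate from a fixed length L."""
    if L <= 0:
        raise ValueError("scaffold length L must be positive")
    return abs(estimate_scaffold_nt(state) - L) / L


@dataclass(frozen=True)
class ObjectiveSpec:
    """A named objective with a direction and an evaluation callable."""

    name: str
    direction: str  # "minimize" | "maximize"
    evaluate: Callable[[DesignState], float]
    params: dict | None = None

    def __post_init__(self):
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"direction must be minimize or maximize, got {self.direction!r}")

    def energy(self, state: DesignState) -> float:
        """Evaluate as a minimisation energy (maximised objectives negate)."""
        value = float(self.evaluate(state))
        if not math.isfinite(value):
            raise NonFiniteObjectiveError(
                f"objective {self.name!r} evaluated to {value!r}"
            )
        return -value if self.direction == "maximize" else value


_REGISTRY: dict[str, ObjectiveSpec] = {}


def register_custom_objective(
    name: str, direction: str, evaluate: Callable[[DesignState], float], params: dict | None = None
) -> ObjectiveSpec:
    """Register a user objective usable by both optimisers and the config loader."""
    if name in _REGISTRY or name in _BUILTINS:
        raise DuplicateNameError(f"objective {name!r} already registered")
    spec = ObjectiveSpec(name, direction, evaluate, params)
    _REGISTRY[name] = spec
    return spec


def unregister_custom_objective(name: str) -> None:
    _REGISTRY.pop(name, None)


def _builtin(name: str, direction: str, params: dict | None = None) -> ObjectiveSpec:
    if name == "porosity":
        return ObjectiveSpec("porosity", direction, porosity)
    if name == "variation_index":
        return ObjectiveSpec("variation_index", direction, variation_index)
    if name == "scaffold_usage":
        L = int((params or {}).get("L", M13MP18_NT))
        return ObjectiveSpec("scaffold_usage", direction, lambda s: scaffold_usage(s, L), {"L": L})
    raise KeyError(name)


_BUILTINS = ("porosity", "variation_index", "scaffold_usage")


def get_objective(name: str, direction: str = "minimize", params: dict | None = None) -> ObjectiveSpec:
    """Resolve an objective by name (built-in first, then the custom registry)."""
    if name in _BUILTINS:
        return _builtin(name, direction, params)
    if name in _REGISTRY:
        base = _REGISTRY[name]
        return ObjectiveSpec(base.name, direction or base.direction, base.evaluate, params)
    from .errors import UnknownObjectiveError

    raise UnknownObjectiveError(
        f"unknown objective {name!r}; built-ins are {', '.join(_BUILTINS)}"
    )
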