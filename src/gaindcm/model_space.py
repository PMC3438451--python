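"""Candidate model space for the hierarchical visual network.

Eight cortical sources (four bilateral areas) are arranged in a fixed
hierarchy: inferior occipital gyrus (IOG, level 1, the input station),
superior occipital gyrus (SOG, level 2), inferior parietal cortex
(IPC, level 3) and superior orbital gyrus (SOrbG, level 4).  Candidate
models differ along two axes:

* six extrinsic *architectures* — serial and parallel hierarchies, each
  with or without diagonal interhemispheric connections; and
* three *condition-effect* hypotheses — contrast-dependent modulation of
  superficial-pyramidal self-inhibition, of deep-pyramidal
  self-inhibition, or no modulation at all.

Backward connections always mirror forward connections, so an
architecture is fully determined by its forward edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

AREA_NAMES = ("IOG", "SOG", "IPC", "SOrbG")
HEMISPHERES = ("left", "right")
#: hierarchical level of each area within a hemisphere (1 = bottom)
AREA_LEVEL = {"IOG": 1, "SOG": 2, "IPC": 3, "SOrbG": 4}

VALID_EFFECT_TARGETS = ("sp_self", "dp_self", "none")


@dataclass(frozen=True, order=True)
class Area:
    """One cortical source: a named area in one hemisphere."""

    name: str
    hemisphere: str

    def __post_init__(self):
        if self.name not in AREA_NAMES:
            raise ValueError(f"unknown area {self.name!r}; valid: {AREA_NAMES}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r}; valid: {HEMISPHERES}"
            )

    @property
    def level(self) -> int:
        return AREA_LEVEL[self.name]

    @property
    def label(self) -> str:
        return f"{'L' if self.hemisphere == 'left' else 'R'}-{self.name}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def all_areas() -> List[Area]:
    """The eight sources, hemisphere-major, bottom-up within hemisphere."""
    return [Area(n, h) for h in HEMISPHERES for n in AREA_NAMES]


def area_index(area: Area) -> int:
    return all_areas().index(area)


Edge = Tuple[Area, Area]


@dataclass(frozen=True)
class Architecture:
    """An extrinsic connectivity pattern over the eight sources.

    ``forward_edges`` run from lower to strictly higher hierarchical
    level; ``backward_edges`` are their exact reversal.  Exogenous input
    enters the spiny stellate population of the ``input_areas`` (left
    and right IOG, the bottom of the hierarchy).
    """

    id: int
    name: str
    forward_edges: Tuple[Edge, ...]
    interhemispheric: bool

    @property
    def backward_edges(self) -> Tuple[Edge, ...]:
        return tuple((b, a) for (a, b) in self.forward_edges)

    @property
    def input_areas(self) -> Tuple[Area, ...]:
        return (Area("IOG", "left"), Area("IOG", "right"))

    @property
    def interhemispheric_edges(self) -> Tuple[Edge, ...]:
        return tuple(
            (a, b) for (a, b) in self.forward_edges if a.hemisphere != b.hemisphere
        )

    def validate(self) -> None:
        areas = set(all_areas())
        for a, b in self.forward_edges:
            if a not in areas or b not in areas:
                raise ValueError(f"edge {a}->{b} references unknown area")
            if b.level <= a.level:
                raise ValueError(
                    f"forward edge {a}->{b} does not ascend the hierarchy"
                )
        # every non-input area reachable from an input area via forward edges
        reached = set(self.input_areas)
        frontier = list(reached)
        adj: Dict[Area, List[Area]] = {}
        for a, b in self.forward_edges:
            adj.setdefault(a, []).append(b)
        while frontier:
            a = frontier.pop()
            for b in adj.get(a, ()):
                if b not in reached:
                    reached.add(b)
                    frontier.append(b)
        missing = areas - reached
        if missing:
            raise ValueError(
                "areas unreachable from input via forward edges: "
                + ", ".join(sorted(m.label for m in missing))
            )


def _chain(hemi: str, names: List[str]) -> List[Edge]:
    return [
        (Area(a, hemi), Area(b, hemi)) for a, b in zip(names[:-1], names[1:])
    ]


def _intra_edges(kind: str) -> List[Edge]:
    edges: List[Edge] = []
    for h in HEMISPHERES:
        if kind == "serial":
            edges += _chain(h, ["IOG", "SOG", "IPC", "SOrbG"])
        elif kind == "parallel":
            edges += [
                (Area("IOG", h), Area("SOG", h)),
                (Area("IOG", h), Area("IPC", h)),
                (Area("SOG", h), Area("SOrbG", h)),
                (Area("IPC", h), Area("SOrbG", h)),
            ]
        elif kind == "skip":
            edges += _chain(h, ["IOG", "SOG", "IPC", "SOrbG"])
            edges += [(Area("IOG", h), Area("IPC", h))]
        else:  # pragma: no cover - internal
            raise ValueError(kind)
    return edges


def _diagonal_edges() -> List[Edge]:
    """Diagonal cross-hemisphere forward edges between adjacent levels."""
    other = {"left": "right", "right": "left"}
    names = list(AREA_NAMES)
    edges: List[Edge] = []
    for h in HEMISPHERES:
        for lo, hi in zip(names[:-1], names[1:]):
            edges.append((Area(lo, h), Area(hi, other[h])))
    return edges


#: architecture id -> (intra-hemispheric kind, interhemispheric?)
_CATALOGUE = {
    1: ("serial", False),
    2: ("parallel", False),
    3: ("skip", False),
    4: ("parallel", True),
    5: ("serial", True),
    6: ("skip", True),
}

_KIND_LABEL = {
    "serial": "serial hierarchy",
    "parallel": "parallel hierarchy",
    "skip": "serial hierarchy with skip connections",
}


def build_architecture(id: int) -> Architecture:
    """Return one of the six candidate extrinsic architectures.

    Ids 1-3 are a serial chain, a parallel fan-out/fan-in, and a serial
    chain with an IOG->IPC skip, all purely intra-hemispheric; ids 4-6
    add diagonal interhemispheric connections to the same three
    patterns.  Id 5 — the serial hierarchy with diagonal
    interhemispheric connections — is the generating architecture of the
    synthetic study.
    """
    if id not in _CATALOGUE:
        raise ValueError(
            f"unknown architecture id {id}; valid ids: {sorted(_CATALOGUE)}"
        )
    kind, inter = _CATALOGUE[id]
    edges = _intra_edges(kind)
    name = _KIND_LABEL[kind]
    if inter:
        edges += _diagonal_edges()
        name += " with interhemispheric connections"
    arch = Architecture(
        id=id, name=name, forward_edges=tuple(edges), interhemispheric=inter
    )
    arch.validate()
    return arch


def all_architectures() -> List[Architecture]:
    return [build_architecture(i) for i in sorted(_CATALOGUE)]


@dataclass(frozen=True)
class ConditionEffectSpec:
    """How experimental conditions modulate intrinsic gain.

    ``target`` names the modulated self-connection: superficial-pyramidal
    self-inhibition (``sp_self``), deep-pyramidal self-inhibition
    (``dp_self``) or ``none``.  A single per-condition covariate drives
    one free modulation parameter per affected area, so the effective
    self-connection in condition *c* is ``baseline * exp(beta_area *
    covariate_c)``.
    """

    target: str
    covariate: Tuple[float, ...]
    affected_areas: Tuple[Area, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.target not in VALID_EFFECT_TARGETS:
            raise ValueError(
                f"unknown effect target {self.target!r}; valid: {VALID_EFFECT_TARGETS}"
            )

    @property
    def n_free(self) -> int:
        """Number of free modulation parameters (one per affected area)."""
        return 0 if self.target == "none" else len(self.affected_areas)

    @property
    def n_conditions(self) -> int:
        return len(self.covariate)


#: physical contrasts of the three stimulus conditions (fractions of max)
DEFAULT_CONTRASTS = (0.10, 0.25, 0.90)


def default_covariate(contrasts=DEFAULT_CONTRASTS) -> Tuple[float, ...]:
    """Mean-centred linear contrast covariate, proportional to physical contrast."""
    c = np.asarray(contrasts, dtype=float)
    return tuple(c - c.mean())


def build_effect_model(
    target: str,
    n_conditions: int,
    covariate: Optional[Tuple[float, ...]] = None,
) -> ConditionEffectSpec:
    """Build a condition-effect hypothesis over all eight areas.

    The ``sp_self`` and ``dp_self`` variants have one free modulation
    parameter per area (eight in total) driven by one covariate; the
    ``none`` variant has zero free parameters and an ignored covariate.
    """
    if target not in VALID_EFFECT_TARGETS:
        raise ValueError(
            f"unknown effect target {target!r}; valid: {VALID_EFFECT_TARGETS}"
        )
    if target != "none" and n_conditions < 2:
        raise ValueError("condition effects need at least 2 conditions")
    if covariate is None:
        if n_conditions == len(DEFAULT_CONTRASTS):
            covariate = default_covariate()
        else:
            covariate = tuple(
                np.arange(n_conditions) - (n_conditions - 1) / 2.0
            )
    if len(covariate) != n_conditions:
        raise ValueError("covariate length must equal number of conditions")
    areas = tuple(all_areas()) if target != "none" else tuple()
    return ConditionEffectSpec(
        target=target, covariate=tuple(covariate), affected_areas=areas
    )


@dataclass
class GroundTruth:
    """Complete generating configuration of a synthetic dataset.

    Holds everything needed to re-simulate the noiseless signal
    bit-exactly: the architecture, the effect model, the full parameter
    assignment (a free-parameter vector over the matching NetworkModel,
    log-scale) and the sensor-noise standard deviation.
    """

    architecture_id: int
    effect_target: str
    theta: np.ndarray
    param_names: List[str]
    noise_sd: float
    covariate: Tuple[float, ...]


# ---------------------------------------------------------------------------
# serialisation


def architecture_to_dict(arch: Architecture) -> dict:
    return {
        "id": arch.id,
        "name": arch.name,
        "interhemispheric": arch.interhemispheric,
        "forward_edges": [[a.label, b.label] for a, b in arch.forward_edges],
    }


def _area_from_label(label: str) -> Area:
    hemi, name = label.split("-", 1)
    return Area(name, "left" if hemi == "L" else "right")


def architecture_from_dict(d: dict) -> Architecture:
    arch = Architecture(
        id=int(d["id"]),
        name=str(d["name"]),
        interhemispheric=bool(d["interhemispheric"]),
        forward_edges=tuple(
            (_area_from_label(a), _area_from_label(b))
            for a, b in d["forward_edges"]
        ),
    )
    arch.validate()
    return arch


def save_model_space(path, architectures=None) -> None:
    """Write the architecture catalogue to a YAML file."""
    if architectures is None:
        architectures = all_architectures()
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"architectures": [architecture_to_dict(a) for a in architectures]},
            fh,
            sort_keys=False,
        )


def load_model_space(path) -> List[Architecture]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return [architecture_from_dict(a) for a in d["architectures"]]
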