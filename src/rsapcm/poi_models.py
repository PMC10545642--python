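"""Condition scheme and pattern-of-interest (POI) model matrices.

A POI is a hypothesis similarity matrix: the 12x12 matrix of condition-pair
correlations (entries restricted to {-1, 0, 1}) that a region would show if it
represented exactly one source of information -- e.g. perceived motion
direction, image valence, or the valence of the trial outcome. POIs are
compiled from declarative block specifications and serve as predictors in the
pattern-component regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Condition",
    "ConditionScheme",
    "POISpec",
    "POIMatrix",
    "POISpecError",
    "build_condition_scheme",
    "compile_poi",
    "default_poi_library",
    "extra_poi_specs",
    "default_poi_specs",
    "library_collinearity",
]

#: Table-style column order of the default library.
DEFAULT_POI_NAMES = [
    "PM_SD", "PM_NS", "PM_Lin", "RM_DS", "RM_NS", "Set",
    "IV_All", "IV_Lin", "IV_Neg", "IV_Pos", "OV_Lin", "OV_Neg", "OV_Pos",
]

N_CONDITIONS = 12


class POISpecError(ValueError):
    """A POI specification is invalid under the condition scheme."""


@dataclass(frozen=True)
class Condition:
    """One experimental condition.

    ``phase`` separates the motion-aftereffect (test image) conditions from the
    adaptation-video conditions; ``direction`` is the perceived MAE direction
    (approach / recede / static) or the physical video motion (contract /
    expand / alternate); ``valence`` is the image's emotional category for MAE
    conditions and ``None`` for videos.
    """

    index: int
    phase: str          # "mae" | "video"
    direction: str
    valence: str | None

    @property
    def label(self) -> str:
        if self.phase == "mae":
            return f"{_DIR_ABBR[self.direction]}-{_VAL_ABBR[self.valence]}"
        return f"Vid-{self.direction.capitalize()}"


_DIR_ABBR = {"approach": "App", "recede": "Rec", "static": "Stat"}
_VAL_ABBR = {"negative": "Neg", "neutral": "Neu", "positive": "Pos"}


@dataclass(frozen=True)
class ConditionScheme:
    """The canonical ordered set of the 12 task conditions."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) != N_CONDITIONS:
            raise ValueError("scheme must contain exactly 12 conditions")
        if [c.index for c in self.conditions] != list(range(N_CONDITIONS)):
            raise ValueError("condition indices must be 0..11 in order")
        n_mae = sum(c.phase == "mae" for c in self.conditions)
        if n_mae != 9:
            raise ValueError("scheme must contain 9 mae and 3 video conditions")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown condition label {label!r}") from None

    def select(self, selector: Mapping | Sequence[int]) -> list[int]:
        """Resolve a selector to condition indices.

        A selector is either an explicit index list, or a mapping with any of
        the keys ``phase``, ``direction``, ``valence`` (scalar or list) which
        are conjunctive attribute filters, or ``{"indices": [...]}``.
        """
        if isinstance(selector, Mapping):
            if "indices" in selector:
                idx = list(selector["indices"])
            else:
                idx = []
                for c in self.conditions:
                    ok = True
                    for key in ("phase", "direction", "valence"):
                        if key in selector:
                            want = selector[key]
                            wants = [want] if isinstance(want, (str, type(None))) else list(want)
                            if getattr(c, key) not in wants:
                                ok = False
                                break
                    if ok:
                        idx.append(c.index)
        else:
            idx = list(selector)
        if any(i not in range(N_CONDITIONS) for i in idx):
            raise POISpecError(f"selector {selector!r} addresses an out-of-range condition")
        return idx


def build_condition_scheme() -> ConditionScheme:
    """Canonical scheme: indices 0-8 are MAE conditions ordered
    (approach, recede, static) x (negative, neutral, positive); 9-11 are the
    adaptation videos (contract, expand, alternate).

    A contracting video produces an approaching aftereffect and an expanding
    video a receding one; the alternating video produces no aftereffect.
    """
    conds: list[Condition] = []
    i = 0
    for direction in ("approach", "recede", "static"):
        for valence in ("negative", "neutral", "positive"):
            conds.append(Condition(i, "mae", direction, valence))
            i += 1
    for direction in ("contract", "expand", "alternate"):
        conds.append(Condition(i, "video", direction, None))
        i += 1
    return ConditionScheme(tuple(conds))


@dataclass(frozen=True)
class POISpec:
    """Declarative POI: a list of blocks over condition selectors.

    Each block is ``(group_a, group_b, value)``. With ``group_b`` omitted
    (None) every within-``group_a`` pair -- including the diagonal -- takes
    ``value``; with ``group_b`` given every cross pair (a, b) and its mirror
    takes ``value``. Unlisted pairs take ``default_value``.
    """

    name: str
    description: str = ""
    blocks: tuple = ()
    default_value: int = 0

    @staticmethod
    def from_dict(d: Mapping) -> "POISpec":
        blocks = tuple(
            (b["group_a"], b.get("group_b"), int(b["value"])) for b in d.get("blocks", ())
        )
        return POISpec(
            name=d["name"],
            description=d.get("description", ""),
            blocks=blocks,
            default_value=int(d.get("default_value", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "blocks": [
                {"group_a": a, **({"group_b": b} if b is not None else {}), "value": v}
                for (a, b, v) in self.blocks
            ],
            "default_value": self.default_value,
        }


@dataclass(frozen=True)
class POIMatrix:
    """A compiled 12x12 model similarity matrix with entries in {-1, 0, 1}."""

    name: str
    matrix: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_CONDITIONS, N_CONDITIONS):
            raise ValueError("POI matrix must be 12x12")
        if not np.array_equal(m, m.T):
            raise ValueError(f"POI {self.name!r}: matrix must be symmetric")
        if not np.isin(m, (-1.0, 0.0, 1.0)).all():
            raise ValueError(f"POI {self.name!r}: entries must be in {{-1, 0, 1}}")
        if (np.diag(m) == -1).any():
            raise ValueError(f"POI {self.name!r}: diagonal cells may not be -1")
        object.__setattr__(self, "matrix", m)

    def vector(self) -> np.ndarray:
        """Upper triangle including the diagonal, row-major (78 values)."""
        iu = np.triu_indices(N_CONDITIONS)
        return self.matrix[iu]


def compile_poi(spec: POISpec, scheme: ConditionScheme) -> POIMatrix:
    """Compile a declarative spec into a POIMatrix.

    Raises :class:`POISpecError` on an empty selector or when two blocks
    assign different values to the same condition pair.
    """
    base = float(spec.default_value)
    m = np.full((N_CONDITIONS, N_CONDITIONS), base)
    assigned = np.zeros((N_CONDITIONS, N_CONDITIONS), dtype=bool)

    def _set(a: int, b: int, value: float) -> None:
        if assigned[a, b] and m[a, b] != value:
            la, lb = scheme.conditions[a].label, scheme.conditions[b].label
            raise POISpecError(
                f"POI {spec.name!r}: pair ({la}, {lb}) assigned both "
                f"{m[a, b]:g} and {value:g}"
            )
        m[a, b] = m[b, a] = value
        assigned[a, b] = assigned[b, a] = True

    for group_a, group_b, value in spec.blocks:
        idx_a = scheme.select(group_a)
        if not idx_a:
            raise POISpecError(f"POI {spec.name!r}: selector {group_a!r} is empty")
        if group_b is None:
            for i in idx_a:
                for j in idx_a:
                    if i <= j:
                        _set(i, j, value)
        else:
            idx_b = scheme.select(group_b)
            if not idx_b:
                raise POISpecError(f"POI {spec.name!r}: selector {group_b!r} is empty")
            for i in idx_a:
                for j in idx_b:
                    _set(min(i, j), max(i, j), value)
    return POIMatrix(name=spec.name, matrix=m, description=spec.description)


# ---------------------------------------------------------------------------
# Default library
# ---------------------------------------------------------------------------

def _sel(**kw) -> dict:
    return {k: v for k, v in kw.items() if v is not None}


_MOVING = _sel(phase="mae", direction=["approach", "recede"])
_STATIC = _sel(phase="mae", direction="static")
_APPROACH = _sel(phase="mae", direction="approach")
_RECEDE = _sel(phase="mae", direction="recede")
_POS = _sel(phase="mae", valence="positive")
_NEG = _sel(phase="mae", valence="negative")
_EMOTIONAL = _sel(phase="mae", valence=["positive", "negative"])
_VIDEOS = _sel(phase="video")
# outcome blocks: an approaching positive or receding negative image is a
# positive outcome; an approaching negative or receding positive image is a
# negative (maladaptive) outcome
_OUT_POS = {"indices": [2, 3]}   # App-Pos, Rec-Neg
_OUT_NEG = {"indices": [0, 5]}   # App-Neg, Rec-Pos


def default_poi_specs() -> list[POISpec]:
    """Declarative specs for the 13 default POIs, in table column order."""
    b = lambda a, bb, v: (a, bb, v)  # noqa: E731 - terse block literal
    return [
        POISpec("PM_SD", "Perceived motion with a distinct static representation",
                (b(_MOVING, None, 1), b(_STATIC, None, 1))),
        POISpec("PM_NS", "Perceived motion, nonspecific (static unrepresented)",
                (b(_MOVING, None, 1),)),
        POISpec("PM_Lin", "Linear perceived-motion axis: approach anticorrelated with recede",
                (b(_APPROACH, None, 1), b(_RECEDE, None, 1), b(_APPROACH, _RECEDE, -1))),
        POISpec("RM_DS", "Real motion, direction-specific: contract anticorrelated with expand",
                (b({"indices": [9]}, None, 1), b({"indices": [10]}, None, 1),
                 b({"indices": [9]}, {"indices": [10]}, -1))),
        POISpec("RM_NS", "Real motion, nonspecific: all adaptation videos alike",
                (b(_VIDEOS, None, 1),)),
        POISpec("Set", "Image-set identity: same images across directions within a valence category",
                (b(_NEG, None, 1), b(_sel(phase="mae", valence="neutral"), None, 1),
                 b(_POS, None, 1))),
        POISpec("IV_All", "Image valence, all salience: emotional images distinct from neutral",
                (b(_EMOTIONAL, None, 1),)),
        POISpec("IV_Lin", "Linear image-valence spectrum: positive anticorrelated with negative",
                (b(_POS, None, 1), b(_NEG, None, 1), b(_POS, _NEG, -1))),
        POISpec("IV_Neg", "Negative images versus all else",
                (b(_NEG, None, 1),)),
        POISpec("IV_Pos", "Positive images versus all else",
                (b(_POS, None, 1),)),
        POISpec("OV_Lin", "Linear outcome-valence spectrum: adaptive anticorrelated with maladaptive",
                (b(_OUT_POS, None, 1), b(_OUT_NEG, None, 1), b(_OUT_POS, _OUT_NEG, -1))),
        POISpec("OV_Neg", "Negative outcomes: approaching negative or receding positive images",
                (b(_OUT_NEG, None, 1),)),
        POISpec("OV_Pos", "Positive outcomes: approaching positive or receding negative images",
                (b(_OUT_POS, None, 1),)),
    ]


def extra_poi_specs() -> list[POISpec]:
    """Optional perceived-approach / perceived-recession POIs (not in the
    default library, which follows the 13 table columns)."""
    return [
        POISpec("PM_App", "Perceived approach only", ((_APPROACH, None, 1),)),
        POISpec("PM_Rec", "Perceived recession only", ((_RECEDE, None, 1),)),
    ]


def default_poi_library(scheme: ConditionScheme | None = None) -> list[POIMatrix]:
    """Compile the 13 default POIs in table column order."""
    scheme = scheme or build_condition_scheme()
    return [compile_poi(s, scheme) for s in default_poi_specs()]


def library_collinearity(library: Sequence[POIMatrix]) -> np.ndarray:
    """Pairwise cosine similarity of the vectorized library matrices.

    The library POIs deliberately overlap (that is why greedy selection is
    needed); this audit quantifies the overlap.
    """
    vecs = np.stack([p.vector() for p in library])
    norms = np.linalg.norm(vecs, axis=1)
    return (vecs @ vecs.T) / np.outer(norms, norms)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def load_poi_specs(path) -> list[POISpec]:
    """Read POI specs from a JSON file (a single spec or a list)."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, Mapping):
        data = [data]
    return [POISpec.from_dict(d) for d in data]


def save_poi_specs(specs: Iterable[POISpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=2)


def poi_to_table(poi: POIMatrix, scheme: ConditionScheme):
    """Compiled matrix as a labelled DataFrame (for delimited export)."""
    import pandas as pd

    labels = scheme.labels
    return pd.DataFrame(poi.matrix, index=labels, columns=labels)
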