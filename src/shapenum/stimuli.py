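"""Stimulus layouts, polarity assignment, trial schedules and rendering.

Stimuli are small sets of truncated Gaussian blobs (3-6 elements) presented
within a circular area of 8 deg diameter on a mid-gray background. Elements
sit either on the vertices of a regular polygon (triangle, square, pentagon,
hexagon), anywhere on the polygon's contour path excluding the vertices, or -
for the triangle-sampling experiments - three on the triangle vertices with
the remainder placed uniformly inside the closed triangle.

Coordinates are degrees of visual angle, origin at screen centre, y up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Stimulus constants (degrees of visual angle, Weber contrast, cd/m^2)
SIGMA_DEG = 0.08
SIZE_FACTOR = 5.0
CONTRAST = 0.90
ELEMENT_SIZE_DEG = SIZE_FACTOR * SIGMA_DEG  # truncated Gaussian extent, 0.4 deg
MIN_DISTANCE_DEG = 2.0 * ELEMENT_SIZE_DEG   # "twice their size", 0.8 deg
AREA_DIAMETER_DEG = 8.0
AREA_RADIUS_DEG = AREA_DIAMETER_DEG / 2.0
VERTEX_EXCLUSION_DEG = MIN_DISTANCE_DEG     # keep-out zone around vertices
BACKGROUND_CD_M2 = 65.5
VIEWING_DISTANCE_CM = 100.0

MAX_PLACEMENT_ATTEMPTS = 10_000

_SHAPE_VERTICES = {"triangle": 3, "square": 4, "pentagon": 5, "hexagon": 6}
_VERTEX_SHAPES = {v: k for k, v in _SHAPE_VERTICES.items()}


class InfeasibleGeometryError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the spacing constraints."""


class OutOfDisplayError(ValueError):
    """Raised when the stimulus area does not fit on the display."""


@dataclass(frozen=True)
class ElementSpec:
    sigma_deg: float = SIGMA_DEG
    size_factor: float = SIZE_FACTOR
    contrast: float = CONTRAST
    polarity: str = "white"

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.size_factor * self.sigma_deg <= 0:
            raise ValueError("element size must be positive")
        if self.polarity not in ("white", "black"):
            raise ValueError("polarity must be 'white' or 'black'")

    @property
    def element_size_deg(self) -> float:
        return self.size_factor * self.sigma_deg


@dataclass(frozen=True)
class ShapeSpec:
    kind: str
    circumradius_deg: float = AREA_RADIUS_DEG
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _SHAPE_VERTICES:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.circumradius_deg <= 0:
            raise ValueError("circumradius_deg must be positive")

    @property
    def n_vertices(self) -> int:
        return _SHAPE_VERTICES[self.kind]


@dataclass(frozen=True)
class Condition:
    """One cell of an experiment's 2 x {3,4,5,6} design."""

    experiment: int
    configuration: str          # "shape" or "random"
    n_elements: int
    polarity_scheme: str = "all_white"   # all_white | all_black | same | mixed

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2 or 3")
        if self.configuration not in ("shape", "random"):
            raise ValueError("configuration must be 'shape' or 'random'")
        if self.n_elements not in (3, 4, 5, 6):
            raise ValueError("n_elements must be in {3,4,5,6}")
        if self.polarity_scheme not in ("all_white", "all_black", "same", "mixed"):
            raise ValueError(f"bad polarity_scheme {self.polarity_scheme!r}")

    @property
    def shape_kind(self) -> str:
        """The virtual shape the condition is built on."""
        if self.experiment == 1:
            return _VERTEX_SHAPES[self.n_elements]
        return "triangle"

    @property
    def label(self) -> str:
        if self.experiment == 3:
            prefix = "S" if self.polarity_scheme != "mixed" else "D"
        else:
            prefix = "S" if self.configuration == "shape" else "R"
        return f"{prefix}{self.n_elements}"


def conditions_for_experiment(experiment: int) -> list[Condition]:
    """The eight conditions of each experiment."""
    if experiment in (1, 2):
        return [
            Condition(experiment, config, n)
            for config in ("shape", "random")
            for n in (3, 4, 5, 6)
        ]
    if experiment == 3:
        # polarity is the manipulated factor; geometry is triangle-sampling
        return [
            Condition(3, "shape", n, scheme)
            for scheme in ("same", "mixed")
            for n in (3, 4, 5, 6)
        ]
    raise ValueError("experiment must be 1, 2 or 3")


@dataclass
class StimulusLayout:
    centres: np.ndarray                 # (n, 2) degrees
    polarities: list[str]
    condition: Condition
    orientation_rad: float = 0.0
    element: ElementSpec = field(default_factory=ElementSpec)

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.centres)

    def min_pairwise_distance(self) -> float:
        if self.n < 2:
            return math.inf
        d = self.centres[:, None, :] - self.centres[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        return float(dist[np.triu_indices(self.n, 1)].min())

    def validate(self) -> None:
        r = np.sqrt((self.centres ** 2).sum(-1))
        if self.n and r.max() > AREA_RADIUS_DEG + 1e-9:
            raise ValueError("element centre outside the 8-deg stimulus area")
        if self.min_pairwise_distance() < MIN_DISTANCE_DEG - 1e-9:
            raise ValueError("minimum inter-element distance violated")
        if len(self.polarities) != self.n:
            raise ValueError("polarities and centres length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_deg": self.centres[:, 0],
                "y_deg": self.centres[:, 1],
                "polarity": self.polarities,
            }
        )


# ---------------------------------------------------------------------------
# geometry helpers

def polygon_vertices(shape: ShapeSpec) -> np.ndarray:
    """Vertices of the regular polygon, first vertex at the top for zero
    orientation, counter-clockwise."""
    n = shape.n_vertices
    angles = math.pi / 2 + shape.orientation_rad + 2 * math.pi * np.arange(n) / n
    return shape.circumradius_deg * np.column_stack([np.cos(angles), np.sin(angles)])


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def distance_to_contour(point: Sequence[float], shape: ShapeSpec) -> float:
    """Distance from a point to the polygon's boundary path."""
    verts = polygon_vertices(shape)
    p = np.asarray(point, dtype=float)
    n = len(verts)
    return min(
        _point_segment_distance(p, verts[i], verts[(i + 1) % n]) for i in range(n)
    )


def point_in_polygon(point: Sequence[float], shape: ShapeSpec, tol: float = 1e-12) -> bool:
    """Membership in the closed polygon (interior or boundary)."""
    verts = polygon_vertices(shape)
    p = np.asarray(point, dtype=float)
    n = len(verts)
    # regular polygon is convex and counter-clockwise: all cross products >= 0
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        if cross < -tol:
            return False
    return True


def _spacing_ok(point: np.ndarray, placed: list[np.ndarray],
                min_dist: float = MIN_DISTANCE_DEG) -> bool:
    return all(np.linalg.norm(point - q) >= min_dist for q in placed)


# ---------------------------------------------------------------------------
# placement operations

def place_on_vertices(condition: Condition, shape: ShapeSpec,
                      seed: int | None = None) -> StimulusLayout:
    """Vertex-anchored layouts.

    Experiment 1: every element on a polygon vertex. Experiments 2/3: the
    three triangle vertices plus ``n_elements - 3`` elements placed uniformly
    inside the closed triangle.
    """
    verts = polygon_vertices(shape)
    if condition.experiment == 1:
        if condition.n_elements != shape.n_vertices:
            raise ValueError("experiment 1 requires n_elements == n_vertices")
        centres = verts
    else:
        if shape.kind != "triangle":
            raise ValueError("experiments 2/3 sample a triangle")
        extra = condition.n_elements - shape.n_vertices
        if extra < 0:
            raise ValueError("need at least 3 elements for the triangle")
        if extra == 0:
            centres = verts
        else:
            rng = np.random.default_rng(seed)
            inner = _sample_within(shape, extra, rng, anchors=[v for v in verts])
            centres = np.vstack([verts, inner])
    layout = StimulusLayout(
        centres, ["white"] * len(centres), condition, shape.orientation_rad
    )
    layout.validate()
    return layout


def place_random_on_contour(shape: ShapeSpec, n: int, seed: int | None,
                            condition: Condition | None = None) -> StimulusLayout:
    """Elements anywhere on the polygon's contour path, excluding a keep-out
    zone around each vertex (experiment 1 random conditions)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    verts = polygon_vertices(shape)
    k = len(verts)
    edges = [(verts[i], verts[(i + 1) % k]) for i in range(k)]
    lengths = np.array([np.linalg.norm(b - a) for a, b in edges])
    probs = lengths / lengths.sum()
    placed: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            a, b = edges[rng.choice(k, p=probs)]
            t = rng.uniform()
            p = a + t * (b - a)
            if min(np.linalg.norm(p - v) for v in verts) < VERTEX_EXCLUSION_DEG:
                continue
            if _spacing_ok(p, placed):
                placed.append(p)
                break
        else:
            raise InfeasibleGeometryError(
                f"could not place contour element after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    condition = condition or Condition(1, "random", max(n, 3) if n else 3)
    layout = StimulusLayout(
        np.array(placed).reshape(-1, 2), ["white"] * n, condition,
        shape.orientation_rad,
    )
    if n:
        layout.validate()
    return layout


def _sample_within(shape: ShapeSpec, n: int, rng: np.random.Generator,
                   anchors: Iterable[np.ndarray] = (),
                   exclude_vertices: bool = False) -> np.ndarray:
    """Uniform samples in the closed triangle, rejection-sampled to honour
    inter-element spacing (including spacing to anchor points)."""
    verts = polygon_vertices(shape)
    if len(verts) != 3:
        raise ValueError("interior sampling is defined for triangles")
    a, b, c = verts
    placed = [np.asarray(p) for p in anchors]
    out: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            r1, r2 = rng.uniform(), rng.uniform()
            s1 = math.sqrt(r1)
            p = a * (1 - s1) + b * (s1 * (1 - r2)) + c * (s1 * r2)
            if exclude_vertices and min(
                np.linalg.norm(p - v) for v in verts
            ) < VERTEX_EXCLUSION_DEG:
                continue
            if _spacing_ok(p, placed):
                placed.append(p)
                out.append(p)
                break
        else:
            raise InfeasibleGeometryError(
                f"could not place interior element after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return np.array(out).reshape(-1, 2)


def place_random_within(shape: ShapeSpec, n: int, seed: int | None,
                        condition: Condition | None = None,
                        exclude_vertices: bool = False) -> StimulusLayout:
    """Elements uniformly in the closed triangle (experiments 2/3 random
    conditions use ``exclude_vertices=True``)."""
    rng = np.random.default_rng(seed)
    pts = _sample_within(shape, n, rng, exclude_vertices=exclude_vertices)
    condition = condition or Condition(2, "random", max(n, 3) if n else 3)
    layout = StimulusLayout(pts, ["white"] * n, condition, shape.orientation_rad)
    if n:
        layout.validate()
    return layout


def generate_layout(condition: Condition, orientation_rad: float,
                    seed: int | None) -> StimulusLayout:
    """Dispatch to the placement rule the condition calls for."""
    shape = ShapeSpec(condition.shape_kind, orientation_rad=orientation_rad)
    if condition.experiment == 1:
        if condition.configuration == "shape":
            layout = place_on_vertices(condition, shape)
        else:
            layout = place_random_on_contour(shape, condition.n_elements, seed,
                                             condition)
    else:
        if condition.configuration == "shape":
            layout = place_on_vertices(condition, shape, seed)
        else:
            layout = place_random_within(shape, condition.n_elements, seed,
                                         condition, exclude_vertices=True)
    scheme = condition.polarity_scheme
    return assign_polarity(layout, scheme, seed)


# ---------------------------------------------------------------------------
# polarity

def assign_polarity(layout: StimulusLayout, scheme: str,
                    seed: int | None = None) -> StimulusLayout:
    """Assign luminance polarities.

    ``mixed`` draws fair coins per element and resamples degenerate
    (all-equal) vectors; ``same`` picks all-white or all-black by a fair coin.
    """
    n = layout.n
    if scheme == "all_white":
        pol = ["white"] * n
    elif scheme == "all_black":
        pol = ["black"] * n
    elif scheme == "same":
        rng = np.random.default_rng(None if seed is None else seed + 1)
        pol = ["white" if rng.uniform() < 0.5 else "black"] * n
    elif scheme == "mixed":
        rng = np.random.default_rng(None if seed is None else seed + 1)
        while True:
            draws = rng.uniform(size=n) < 0.5
            if 0 < draws.sum() < n:
                break
        pol = ["white" if d else "black" for d in draws]
    else:
        raise ValueError(f"unknown polarity scheme {scheme!r}")
    out = replace(layout)
    out.polarities = pol
    return out


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class DisplayGeometry:
    width_px: int = 1024
    height_px: int = 768
    width_cm: float = 40.0
    distance_cm: float = VIEWING_DISTANCE_CM
    background_cd_m2: float = BACKGROUND_CD_M2

    @property
    def px_per_deg(self) -> float:
        cm_per_deg = self.distance_cm * math.tan(math.radians(1.0))
        return self.width_px / self.width_cm * cm_per_deg


def render(layout: StimulusLayout,
           display: DisplayGeometry = DisplayGeometry()) -> np.ndarray:
    """Render the layout to a luminance image (cd/m^2), y up, centred.

    Each element adds ``+- contrast * background * exp(-r^2 / (2 sigma^2))``,
    truncated at ``size_factor * sigma`` from its centre.
    """
    ppd = display.px_per_deg
    if AREA_DIAMETER_DEG * ppd > min(display.width_px, display.height_px):
        raise OutOfDisplayError("8-deg stimulus area exceeds the display")
    img = np.full((display.height_px, display.width_px),
                  display.background_cd_m2, dtype=float)
    xs = (np.arange(display.width_px) - (display.width_px - 1) / 2) / ppd
    ys = ((display.height_px - 1) / 2 - np.arange(display.height_px)) / ppd
    el = layout.element
    trunc = el.element_size_deg
    for (cx, cy), pol in zip(layout.centres, layout.polarities):
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        r2 = dy2[:, None] + dx2[None, :]
        blob = np.exp(-r2 / (2 * el.sigma_deg ** 2))
        blob[r2 > trunc ** 2] = 0.0
        sign = 1.0 if pol == "white" else -1.0
        img += sign * el.contrast * display.background_cd_m2 * blob
    return img


# ---------------------------------------------------------------------------
# trial schedules

@dataclass
class TrialSchedule:
    experiment: int
    rows: pd.DataFrame   # trial_index, condition_label, orientation_rad, layout_seed
    conditions: list[Condition]

    def __len__(self) -> int:
        return len(self.rows)

    def condition_for(self, label: str) -> Condition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def build_schedule(experiment: int, reps: int = 100,
                   seed: int | None = None) -> TrialSchedule:
    """Balanced randomized schedule: each of the 8 conditions ``reps`` times,
    per-trial orientation uniform in [0, 2pi), per-trial layout seeds split
    from the master seed."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    conds = conditions_for_experiment(experiment)
    rng = np.random.default_rng(seed)
    labels = np.repeat([c.label for c in conds], reps)
    order = rng.permutation(len(labels))
    labels = labels[order]
    orientations = rng.uniform(0, 2 * math.pi, size=len(labels))
    seed_seq = np.random.SeedSequence(seed)
    layout_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                    for s in seed_seq.spawn(len(labels))]
    rows = pd.DataFrame(
        {
            "trial_index": np.arange(len(labels)),
            "condition": labels,
            "orientation_rad": orientations,
            "layout_seed": layout_seeds,
        }
    )
    return TrialSchedule(experiment, rows, conds)


def schedule_layouts(schedule: TrialSchedule) -> list[StimulusLayout]:
    """Generate the layout for every trial of a schedule."""
    return [
        generate_layout(
            schedule.condition_for(row.condition), row.orientation_rad,
            int(row.layout_seed),
        )
        for row in schedule.rows.itertuples()
    ]


def save_layout_json(layout: StimulusLayout, path: str | Path) -> None:
    payload = {
        "condition": {
            "experiment": layout.condition.experiment,
            "configuration": layout.condition.configuration,
            "n_elements": layout.condition.n_elements,
            "polarity_scheme": layout.condition.polarity_scheme,
        },
        "orientation_rad": layout.orientation_rad,
        "centres_deg": layout.centres.tolist(),
        "polarities": layout.polarities,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
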