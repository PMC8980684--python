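"""Vessel-tree geometry.

A coronary artery system is modelled as a rooted tree of centerline
segments.  Each segment carries samples of arc length (mm, from its
proximal end), lumen radius and a disease-free reference radius.  Lesions
narrow the lumen by a smooth profile; the reference wall is the linear
taper of the healthy segment, so plaque volume is the integral of
(reference area - lumen area) over the lesion extent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import NotOnTreeError, RangeError, StructureError, ValidationError

#: default centerline sampling step (mm); sub-millimetre so that 1-2 mm
#: throats are resolved by several samples
DEFAULT_STEP_MM = 0.25

#: tolerance (mm, on radius) allowed between a child's proximal reference
#: radius and its parent's distal reference radius
JUNCTION_RADIUS_TOL = 0.15

_VESSEL_LABELS = ("LAD", "LCX", "RCA")

_PROFILES = ("cosine2", "rectangular")


@dataclass(eq=False)
class Segment:
    """One centerline branch: arc-length / lumen-radius / reference-radius samples."""

    id: str
    parent_id: str | None
    arc: np.ndarray
    lumen_radius: np.ndarray
    reference_radius: np.ndarray
    is_outlet: bool = False

    def __post_init__(self):
        self.arc = np.asarray(self.arc, dtype=float)
        self.lumen_radius = np.asarray(self.lumen_radius, dtype=float)
        self.reference_radius = np.asarray(self.reference_radius, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.arc.size
        if self.arc.ndim != 1 or n < 2:
            raise ValidationError(f"segment {self.id!r}: needs >=2 samples")
        if self.lumen_radius.shape != (n,) or self.reference_radius.shape != (n,):
            raise ValidationError(f"segment {self.id!r}: sample arrays must share length")
        if abs(self.arc[0]) > 1e-12:
            raise ValidationError(f"segment {self.id!r}: arc length must start at 0")
        if np.any(np.diff(self.arc) <= 0):
            raise ValidationError(f"segment {self.id!r}: arc length must strictly increase")
        if np.any(self.lumen_radius <= 0) or np.any(self.reference_radius <= 0):
            raise ValidationError(f"segment {self.id!r}: radii must be positive")
        if np.any(self.lumen_radius > self.reference_radius + 1e-9):
            raise ValidationError(
                f"segment {self.id!r}: lumen radius exceeds reference radius"
            )

    # -- convenience ----------------------------------------------------
    @property
    def length(self) -> float:
        return float(self.arc[-1])

    @property
    def prox_reference_diameter(self) -> float:
        return 2.0 * float(self.reference_radius[0])

    @property
    def dist_reference_diameter(self) -> float:
        return 2.0 * float(self.reference_radius[-1])

    def lumen_diameter(self) -> np.ndarray:
        return 2.0 * self.lumen_radius

    def copy(self) -> "Segment":
        return Segment(
            id=self.id,
            parent_id=self.parent_id,
            arc=self.arc.copy(),
            lumen_radius=self.lumen_radius.copy(),
            reference_radius=self.reference_radius.copy(),
            is_outlet=self.is_outlet,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Segment):
            return NotImplemented
        return (
            self.id == other.id
            and self.parent_id == other.parent_id
            and self.is_outlet == other.is_outlet
            and np.array_equal(self.arc, other.arc)
            and np.array_equal(self.lumen_radius, other.lumen_radius)
            and np.array_equal(self.reference_radius, other.reference_radius)
        )


@dataclass(eq=True)
class Lesion:
    """A focal stenosis on one segment, with plaque covariates.

    ``degree`` is percent diameter stenosis: the minimal lumen diameter in
    the lesion equals reference diameter x (1 - degree/100).
    """

    segment_id: str
    start: float
    length: float
    degree: float
    calcified_volume: float = 0.0
    noncalcified_volume: float = 0.0
    calcium_score: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.degree < 100.0):
            raise ValidationError(f"degree must lie in [0, 100), got {self.degree}")
        if self.length <= 0:
            raise ValidationError("lesion length must be positive")
        if self.start < 0:
            raise ValidationError("lesion start must be non-negative")
        for name in ("calcified_volume", "noncalcified_volume", "calcium_score"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.length

    def validate_on(self, segment: Segment) -> None:
        if segment.id != self.segment_id:
            raise NotOnTreeError(
                f"lesion targets segment {self.segment_id!r}, got {segment.id!r}"
            )
        if self.end > segment.length + 1e-9:
            raise RangeError(
                f"lesion [{self.start}, {self.end}] mm exceeds segment length "
                f"{segment.length} mm"
            )


def make_segment(
    length: float,
    prox_diameter: float,
    dist_diameter: float,
    n_samples: int | None = None,
    *,
    segment_id: str = "segment",
    parent_id: str | None = None,
    is_outlet: bool = True,
) -> Segment:
    """Build a straight, linearly tapered, disease-free segment.

    Reference radius tapers linearly from ``prox_diameter/2`` to
    ``dist_diameter/2``; lumen is initialized equal to reference.
    """
    if length <= 0 or prox_diameter <= 0 or dist_diameter <= 0:
        raise ValidationError("length and diameters must be positive")
    if n_samples is None:
        n_samples = max(2, int(math.ceil(length / DEFAULT_STEP_MM)) + 1)
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    arc = np.linspace(0.0, length, int(n_samples))
    radius = np.linspace(prox_diameter / 2.0, dist_diameter / 2.0, int(n_samples))
    return Segment(
        id=segment_id,
        parent_id=parent_id,
        arc=arc,
        lumen_radius=radius.copy(),
        reference_radius=radius,
        is_outlet=is_outlet,
    )


def _narrowing_weight(s: np.ndarray, lesion: Lesion, profile: str) -> np.ndarray:
    """Shape function in [0, 1]: 1 at the throat, 0 outside the lesion."""
    w = np.zeros_like(s)
    inside = (s >= lesion.start - 1e-12) & (s <= lesion.end + 1e-12)
    if profile == "cosine2":
        center = lesion.start + lesion.length / 2.0
        w[inside] = np.cos(np.pi * (s[inside] - center) / lesion.length) ** 2
    elif profile == "rectangular":
        w[inside] = 1.0
    else:
        raise ValidationError(f"unknown profile {profile!r}; choose from {_PROFILES}")
    return w


def apply_stenosis(segment: Segment, lesion: Lesion, profile: str = "cosine2") -> Segment:
    """Narrow the lumen of ``segment`` inside the lesion extent.

    The lumen radius is multiplied by ``1 - (degree/100) * w(s)`` where the
    default ``w`` is a C1 cosine-squared bump peaking at the lesion center,
    so the minimal lumen diameter equals reference x (1 - degree/100).
    Samples are refined inside the lesion (including the exact throat) so
    short lesions stay resolved.  Returns a new Segment.
    """
    lesion.validate_on(segment)
    if profile not in _PROFILES:
        raise ValidationError(f"unknown profile {profile!r}; choose from {_PROFILES}")
    if lesion.degree == 0.0:
        return segment.copy()

    # refinement grid over the lesion with an even interval count so the
    # midpoint (the throat of the cosine profile) is an exact sample
    n_int = max(40, int(math.ceil(lesion.length / DEFAULT_STEP_MM)))
    if n_int % 2:
        n_int += 1
    grid = np.linspace(lesion.start, lesion.end, n_int + 1)

    merged = np.sort(np.concatenate([segment.arc, grid]))
    keep = np.concatenate([[True], np.diff(merged) > 1e-9])
    arc = merged[keep]

    lumen = np.interp(arc, segment.arc, segment.lumen_radius)
    ref = np.interp(arc, segment.arc, segment.reference_radius)
    factor = 1.0 - (lesion.degree / 100.0) * _narrowing_weight(arc, lesion, profile)
    return Segment(
        id=segment.id,
        parent_id=segment.parent_id,
        arc=arc,
        lumen_radius=lumen * factor,
        reference_radius=ref,
        is_outlet=segment.is_outlet,
    )


def lesion_length(lesion: Lesion, segment: Segment) -> float:
    """Centerline distance from the proximal to the distal end of the lesion."""
    lesion.validate_on(segment)
    return lesion.length


@dataclass(frozen=True)
class PlaqueMetrics:
    """Quantitative burden of one lesion."""

    plaque_burden_pct: float
    plaque_volume_mm3: float
    total_vessel_volume_mm3: float
    min_lumen_area_mm2: float
    min_lumen_diameter_mm: float


def plaque_burden(segment: Segment, lesion: Lesion) -> PlaqueMetrics:
    """Plaque burden (%) of a lesion: plaque volume / total vessel volume.

    Plaque volume is the integral over the lesion of (reference area -
    lumen area); total vessel volume is the integral of reference area.
    Also reports minimal lumen area (mm^2) and diameter (mm) over the
    lesion.  Trapezoidal quadrature over the segment samples.
    """
    lesion.validate_on(segment)
    inside = (segment.arc > lesion.start) & (segment.arc < lesion.end)
    s = np.concatenate([[lesion.start], segment.arc[inside], [lesion.end]])
    r_lumen = np.interp(s, segment.arc, segment.lumen_radius)
    r_ref = np.interp(s, segment.arc, segment.reference_radius)
    a_lumen = np.pi * r_lumen**2
    a_ref = np.pi * r_ref**2
    plaque = float(np.trapezoid(a_ref - a_lumen, s))
    total = float(np.trapezoid(a_ref, s))
    return PlaqueMetrics(
        plaque_burden_pct=100.0 * plaque / total,
        plaque_volume_mm3=plaque,
        total_vessel_volume_mm3=total,
        min_lumen_area_mm2=float(a_lumen.min()),
        min_lumen_diameter_mm=2.0 * float(r_lumen.min()),
    )


@dataclass(eq=False)
class VesselTree:
    """Rooted tree of segments for one coronary artery system.

    The root segment's proximal end is the ostium (the aortic boundary
    node).  Leaf segments are outlets.  ``lesions`` records where stenoses
    sit; whether their narrowing has been applied to the lumen samples is
    up to the caller (see :func:`apply_lesions`).
    """

    segments: dict[str, Segment]
    root_id: str
    vessel_label: str
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    @classmethod
    def from_segments(
        cls,
        segments: Sequence[Segment],
        vessel_label: str,
        lesions: Sequence[Lesion] = (),
    ) -> "VesselTree":
        seg_map: dict[str, Segment] = {}
        for seg in segments:
            if seg.id in seg_map:
                raise StructureError(f"duplicate segment id {seg.id!r}")
            seg_map[seg.id] = seg
        roots = [s.id for s in segments if s.parent_id is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {roots}")
        return cls(seg_map, roots[0], vessel_label, list(lesions))

    def validate(self) -> None:
        if self.vessel_label not in _VESSEL_LABELS:
            raise ValidationError(
                f"vessel_label must be one of {_VESSEL_LABELS}, got {self.vessel_label!r}"
            )
        if self.root_id not in self.segments:
            raise StructureError(f"root {self.root_id!r} not among segments")
        roots = [sid for sid, s in self.segments.items() if s.parent_id is None]
        if roots != [self.root_id] and set(roots) != {self.root_id}:
            raise StructureError(f"expected single root {self.root_id!r}, found {roots}")
        g = nx.DiGraph()
        g.add_nodes_from(self.segments)
        for sid, seg in self.segments.items():
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise StructureError(
                        f"segment {sid!r} references unknown parent {seg.parent_id!r}"
                    )
                g.add_edge(seg.parent_id, sid)
        if not nx.is_directed_acyclic_graph(g):
            raise StructureError("segment graph contains a cycle")
        if self.segments and not nx.is_weakly_connected(g):
            raise StructureError("segment graph is disconnected")
        children = self.children_map()
        for sid, seg in self.segments.items():
            kids = children.get(sid, [])
            if bool(kids) == seg.is_outlet:
                raise StructureError(
                    f"segment {sid!r}: is_outlet={seg.is_outlet} inconsistent with "
                    f"{len(kids)} children"
                )
            parent = self.segments.get(seg.parent_id) if seg.parent_id else None
            if parent is not None:
                if seg.reference_radius[0] > parent.reference_radius[-1] + JUNCTION_RADIUS_TOL:
                    raise StructureError(
                        f"segment {sid!r}: proximal reference radius exceeds parent's "
                        "distal reference radius beyond tolerance"
                    )
        for lesion in self.lesions:
            if lesion.segment_id not in self.segments:
                raise NotOnTreeError(f"lesion references unknown segment {lesion.segment_id!r}")
            lesion.validate_on(self.segments[lesion.segment_id])

    # -- topology helpers ----------------------------------------------
    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {sid: [] for sid in self.segments}
        for sid, seg in self.segments.items():
            if seg.parent_id is not None:
                out[seg.parent_id].append(sid)
        return out

    def outlets(self) -> list[str]:
        return [sid for sid, seg in self.segments.items() if seg.is_outlet]

    def n_segments(self) -> int:
        return len(self.segments)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        stack = [self.root_id]
        children = self.children_map()
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(children[sid]))
        return order

    def copy(self) -> "VesselTree":
        return VesselTree(
            {sid: seg.copy() for sid, seg in self.segments.items()},
            self.root_id,
            self.vessel_label,
            [replace(l) for l in self.lesions],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, VesselTree):
            return NotImplemented
        return (
            self.root_id == other.root_id
            and self.vessel_label == other.vessel_label
            and self.lesions == other.lesions
            and set(self.segments) == set(other.segments)
            and all(self.segments[k] == other.segments[k] for k in self.segments)
        )


def apply_lesions(
    tree: VesselTree, lesions: Sequence[Lesion], profile: str = "cosine2"
) -> VesselTree:
    """Return a new tree whose lumen samples have the lesions applied."""
    segments = {sid: seg for sid, seg in tree.segments.items()}
    for lesion in lesions:
        if lesion.segment_id not in segments:
            raise NotOnTreeError(f"lesion references unknown segment {lesion.segment_id!r}")
        segments[lesion.segment_id] = apply_stenosis(
            segments[lesion.segment_id], lesion, profile
        )
    segments = {sid: (seg if seg is not tree.segments[sid] else seg.copy())
                for sid, seg in segments.items()}
    return VesselTree(segments, tree.root_id, tree.vessel_label, list(lesions))


def build_tree(spec: Mapping) -> VesselTree:
    """Construct a VesselTree from a topology description.

    ``spec`` maps::

        {"vessel_label": "LAD",
         "branches": [{"id", "parent" (absent/None for the root),
                       "length", "prox_diameter", "dist_diameter",
                       "n_samples" (optional)}, ...],
         "lesions": [{"segment_id", "start", "length", "degree", ...}, ...],
         "profile": "cosine2"}

    Lesions, when present, are applied to the lumen.
    """
    branches = spec.get("branches")
    if not branches:
        raise StructureError("spec must list at least one branch")
    ids = [b["id"] for b in branches]
    if len(set(ids)) != len(ids):
        raise StructureError("duplicate branch ids in spec")
    has_children = {b.get("parent") for b in branches if b.get("parent") is not None}
    segments = []
    for b in branches:
        segments.append(
            make_segment(
                b["length"],
                b["prox_diameter"],
                b["dist_diameter"],
                b.get("n_samples"),
                segment_id=b["id"],
                parent_id=b.get("parent"),
                is_outlet=b["id"] not in has_children,
            )
        )
    lesions = [Lesion(**l) for l in spec.get("lesions", [])]
    tree = VesselTree.from_segments(segments, spec.get("vessel_label", "LAD"))
    if lesions:
        tree = apply_lesions(tree, lesions, spec.get("profile", "cosine2"))
    return tree
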