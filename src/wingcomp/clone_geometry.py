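"""Landmark superposition of mosaic wings and boundary-crossing tests.

Wings are aligned by similarity transforms (translation + rotation +
isotropic scale, no reflection — wings share chirality) fitted to named
vein-intersection landmarks, either least-squares over all landmarks or
exactly through two anchor points (the two posterior-most landmarks).
Clone outlines are simple polygons; candidate compartment boundaries
are open polylines.  A clone "crosses" a boundary when its outline
occupies both sides of the polyline within the polyline's extent,
beyond a snapping tolerance epsilon; touching within epsilon is not a
crossing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "WingSpecimen",
    "SimilarityTransform",
    "CrossingReport",
    "fit_similarity",
    "superimpose",
    "crosses_boundary",
    "compartment_report",
    "read_specimen",
    "write_specimen",
    "specimens_to_svg",
]


class GeometryError(ValueError):
    pass


class LandmarkSet:
    """Ordered named 2-D points; names unique, no two points coincident."""

    def __init__(self, points: Mapping[str, Sequence[float]]):
        if len(points) < 2:
            raise GeometryError("need at least 2 landmarks")
        self._names = tuple(points)
        self._coords = np.asarray([points[n] for n in self._names], dtype=float)
        if self._coords.shape != (len(self._names), 2) or not np.all(
            np.isfinite(self._coords)
        ):
            raise GeometryError("landmarks must be finite 2-D points")
        for i in range(len(self._names)):
            for j in range(i + 1, len(self._names)):
                if np.allclose(self._coords[i], self._coords[j]):
                    raise GeometryError(
                        f"coincident landmarks {self._names[i]!r} and "
                        f"{self._names[j]!r}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def coords(self) -> np.ndarray:
        return self._coords.copy()

    def __getitem__(self, name: str) -> np.ndarray:
        return self._coords[self._names.index(name)].copy()

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        return LandmarkSet({n: self[n] for n in names})

    def as_dict(self) -> dict[str, list[float]]:
        return {n: [float(x) for x in self[n]] for n in self._names}

    @property
    def bbox_diagonal(self) -> float:
        span = self._coords.max(axis=0) - self._coords.min(axis=0)
        return float(np.hypot(*span))


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation by ``angle``, scaling by ``scale`` (> 0), then translation."""

    angle: float
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise GeometryError(f"scale must be positive, got {self.scale}")
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        angle = self.angle + other.angle
        scale = self.scale * other.scale
        translation = self.apply(other.translation.reshape(1, 2))[0]
        return SimilarityTransform(angle, scale, translation)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_angle = -self.angle
        c, s = math.cos(inv_angle), math.sin(inv_angle)
        R = inv_scale * np.array([[c, -s], [s, c]])
        return SimilarityTransform(inv_angle, inv_scale, -(R @ self.translation))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(0.0, 1.0, np.zeros(2))


@dataclass(frozen=True)
class WingSpecimen:
    """One digitized wing: landmarks, clone outlines, named boundaries."""

    specimen_id: str
    landmarks: LandmarkSet
    clones: tuple[np.ndarray, ...] = ()
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clones = tuple(np.asarray(c, dtype=float) for c in self.clones)
        for c in clones:
            if c.ndim != 2 or c.shape[0] < 3 or c.shape[1] != 2:
                raise GeometryError("clone polygons need >= 3 finite vertices")
            if not np.all(np.isfinite(c)):
                raise GeometryError("clone polygon with non-finite vertices")
            if not Polygon(c).is_simple:
                raise GeometryError(
                    f"self-intersecting clone polygon in {self.specimen_id!r}"
                )
        object.__setattr__(self, "clones", clones)
        bounds = {
            k: np.asarray(v, dtype=float) for k, v in self.boundaries.items()
        }
        for k, v in bounds.items():
            if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
                raise GeometryError(f"boundary {k!r} needs >= 2 points")
        object.__setattr__(self, "boundaries", bounds)

    def transformed(self, tf: SimilarityTransform) -> "WingSpecimen":
        return WingSpecimen(
            specimen_id=self.specimen_id,
            landmarks=LandmarkSet(
                {
                    n: tf.apply(self.landmarks[n].reshape(1, 2))[0]
                    for n in self.landmarks.names
                }
            ),
            clones=tuple(tf.apply(c) for c in self.clones),
            boundaries={k: tf.apply(v) for k, v in self.boundaries.items()},
        )


def fit_similarity(
    source: LandmarkSet,
    target: LandmarkSet,
    mode: str = "least_squares",
    anchors: Sequence[str] | None = None,
) -> SimilarityTransform:
    """Similarity transform mapping ``source`` landmarks onto ``target``.

    ``least_squares``: closed-form Procrustes fit over all shared
    landmark names (rotation + isotropic scale + translation minimizing
    summed squared distances; reflections are not allowed).
    ``two_point``: the unique similarity mapping the two ``anchors``
    exactly onto their targets.
    """
    if mode == "two_point":
        if anchors is None or len(anchors) != 2:
            raise GeometryError("two_point mode needs exactly 2 anchor names")
        names = list(anchors)
    else:
        names = [n for n in source.names if n in target.names]
    missing = [n for n in names if n not in source.names or n not in target.names]
    if missing:
        raise GeometryError(f"landmarks missing from one set: {missing}")
    if len(names) < 2:
        raise GeometryError("need at least 2 landmark correspondences")
    S = np.asarray([source[n] for n in names])
    T = np.asarray([target[n] for n in names])

    if mode == "two_point":
        zs = complex(*(S[1] - S[0]))
        zt = complex(*(T[1] - T[0]))
        if zs == 0 or zt == 0:
            raise GeometryError("degenerate (coincident) anchor pair")
        w = zt / zs
        angle = math.atan2(w.imag, w.real)
        scale = abs(w)
        tf = SimilarityTransform(angle, scale, np.zeros(2))
        translation = T[0] - tf.apply(S[0].reshape(1, 2))[0]
        return SimilarityTransform(angle, scale, translation)

    if mode != "least_squares":
        raise GeometryError(f"unknown mode {mode!r}")
    sc = S - S.mean(axis=0)
    tc = T - T.mean(axis=0)
    denom = float((sc * sc).sum())
    if denom == 0:
        raise GeometryError("degenerate source configuration")
    a = float((sc * tc).sum())  # sum of dot products
    b = float((sc[:, 0] * tc[:, 1] - sc[:, 1] * tc[:, 0]).sum())  # cross terms
    angle = math.atan2(b, a)
    scale = math.hypot(a, b) / denom
    if scale == 0:
        raise GeometryError("degenerate target configuration")
    tf0 = SimilarityTransform(angle, scale, np.zeros(2))
    translation = T.mean(axis=0) - tf0.apply(S.mean(axis=0).reshape(1, 2))[0]
    return SimilarityTransform(angle, scale, translation)


def superposition_residual(
    source: LandmarkSet, target: LandmarkSet, tf: SimilarityTransform
) -> float:
    names = [n for n in source.names if n in target.names]
    S = np.asarray([source[n] for n in names])
    T = np.asarray([target[n] for n in names])
    return float(np.sqrt(((tf.apply(S) - T) ** 2).sum(axis=1).mean()))


def superimpose(
    specimens: Sequence[WingSpecimen],
    reference_id: str,
    mode: str = "two_point",
    anchors: Sequence[str] | None = None,
) -> list[WingSpecimen]:
    """Map every specimen into the reference specimen's frame.

    The same fitted transform is applied to landmarks, clone polygons
    and boundaries.  The reference passes through unchanged; specimens
    lacking a needed landmark are skipped with a logged reason.  In
    ``two_point`` mode with no ``anchors`` given, the reference's last
    two landmark names are used (the posterior pair, by the convention
    that landmarks are listed anterior to posterior).
    """
    by_id = {sp.specimen_id: sp for sp in specimens}
    if reference_id not in by_id:
        raise GeometryError(f"reference specimen {reference_id!r} not found")
    reference = by_id[reference_id]
    if mode == "two_point" and anchors is None:
        anchors = reference.landmarks.names[-2:]
    needed = list(anchors) if anchors else list(reference.landmarks.names)
    out: list[WingSpecimen] = []
    for sp in specimens:
        if sp.specimen_id == reference_id:
            out.append(sp)
            continue
        absent = [n for n in needed if n not in sp.landmarks.names]
        if absent:
            logger.warning(
                "skipping specimen %r: missing landmarks %s",
                sp.specimen_id,
                absent,
            )
            continue
        tf = fit_similarity(sp.landmarks, reference.landmarks, mode, anchors)
        out.append(sp.transformed(tf))
    return out


# ---------------------------------------------------------------------------
# boundary crossing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossingReport:
    crosses: bool
    crossing_segments: tuple[tuple[int, int], ...]  # (polygon edge, polyline seg)


def classify_side(
    points: np.ndarray, polyline: np.ndarray, epsilon: float
) -> np.ndarray:
    """Side of the polyline for each point: +1 / -1, or 0 if unclassified.

    Each point is classified against its nearest polyline segment.  A
    point is unclassified (0) when it is within ``epsilon`` of the
    polyline (touching), or when its nearest polyline point is a vertex
    rather than a segment interior — which covers both ends beyond the
    polyline's extent and the wedge regions at bends, where a side is
    not locally well defined.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    P = np.asarray(polyline, dtype=float)
    starts, ends = P[:-1], P[1:]
    d = ends - starts  # (m, 2)
    seg_len2 = (d * d).sum(axis=1)
    w = pts[:, None, :] - starts[None, :, :]  # (k, m, 2)
    t_raw = (w * d[None]).sum(axis=2) / seg_len2[None]
    t = np.clip(t_raw, 0.0, 1.0)
    proj = starts[None] + t[:, :, None] * d[None]
    dist2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
    nearest = dist2.argmin(axis=1)
    out = np.zeros(len(pts))
    for i, (p, j) in enumerate(zip(pts, nearest)):
        if np.sqrt(dist2[i, j]) <= epsilon:
            continue  # touching: unclassified
        if not (0.0 < t_raw[i, j] < 1.0):
            continue  # nearest point is a polyline vertex
        q = proj[i, j]
        cross = d[j, 0] * (p[1] - q[1]) - d[j, 1] * (p[0] - q[0])
        out[i] = np.sign(cross)
    return out


def crosses_boundary(
    polygon: np.ndarray,
    polyline: np.ndarray,
    epsilon: float = 0.0,
) -> CrossingReport:
    """Does the polygon occupy both sides of the boundary polyline?

    True iff the polygon outline has points strictly on both sides of
    the polyline within the polyline's extent (more than ``epsilon``
    away); touching within ``epsilon`` is false.  The report lists the
    (polygon edge, polyline segment) index pairs that intersect.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise GeometryError("polygon needs >= 3 vertices")
    if not Polygon(poly).is_simple:
        raise GeometryError("self-intersecting polygon")
    line = np.asarray(polyline, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2:
        raise GeometryError("polyline needs >= 2 points")

    verts = np.vstack([poly, poly[:1]])
    crossing_segments = []
    probe_pts = [poly]
    # classification changes sign where an edge crosses the polyline, and
    # flips classified/unclassified across the perpendiculars bounding
    # each segment's slab (projection parameter 0 or 1)
    perpendiculars = []
    for si in range(len(line) - 1):
        direction = line[si + 1] - line[si]
        perpendiculars.append((line[si], direction))
        perpendiculars.append((line[si + 1], direction))
    for ei in range(len(poly)):
        a, b = verts[ei], verts[ei + 1]
        edge = LineString([a, b])
        params: list[float] = []  # cut positions along this edge
        for si in range(len(line) - 1):
            seg = LineString([line[si], line[si + 1]])
            inter = edge.intersection(seg)
            if inter.is_empty:
                continue
            crossing_segments.append((ei, si))
            for geom in getattr(inter, "geoms", [inter]):
                for xy in getattr(geom, "coords", []):
                    params.append(float(edge.project(shapely_point(xy))))
        d_edge = b - a
        for origin, direction in perpendiculars:
            denom = float(d_edge @ direction)
            if denom != 0.0:
                t = float((origin - a) @ direction) / denom
                if 0.0 < t < 1.0:
                    params.append(t * edge.length)
        cuts = sorted({0.0, edge.length, *params})
        mids = [(lo + hi) / 2.0 for lo, hi in zip(cuts[:-1], cuts[1:])]
        if mids:
            probe_pts.append(
                np.asarray([edge.interpolate(t).coords[0] for t in mids])
            )
    probes = np.vstack(probe_pts)
    sides = classify_side(probes, line, epsilon)
    crosses = bool((sides > 0).any() and (sides < 0).any())
    if not crosses:
        crossing_segments = []
    return CrossingReport(
        crosses=crosses, crossing_segments=tuple(sorted(set(crossing_segments)))
    )


def shapely_point(xy):
    from shapely.geometry import Point

    return Point(xy)


def smooth_edge_along(
    polygon: np.ndarray, polyline: np.ndarray, epsilon: float, k: int = 3
) -> bool:
    """True when >= k consecutive polygon vertices lie within epsilon of
    the polyline (one operationalization of a clone edge running
    smoothly along a compartment boundary)."""
    poly = np.asarray(polygon, dtype=float)
    line = LineString(np.asarray(polyline, dtype=float))
    near = np.array([line.distance(shapely_point(p)) <= epsilon for p in poly])
    if near.sum() < k:
        return False
    # circular runs
    doubled = np.concatenate([near, near])
    run = 0
    for flag in doubled:
        run = run + 1 if flag else 0
        if run >= k:
            return True
    return False


def default_epsilon(landmarks: LandmarkSet) -> float:
    """Scale-free snapping tolerance: 1e-6 x landmark bbox diagonal."""
    return 1e-6 * landmarks.bbox_diagonal


def compartment_report(
    specimens: Sequence[WingSpecimen],
    boundaries: Mapping[str, np.ndarray],
    epsilon: float | None = None,
    smooth_epsilon: float | None = None,
    k: int = 3,
) -> pd.DataFrame:
    """Per-boundary tally of clone crossings in a common frame.

    Columns: boundary, clones_tested, clones_crossing, clones_smooth_edge.
    ``epsilon`` defaults to the scale-free landmark tolerance of the
    first specimen; ``smooth_epsilon`` (for the smooth-edge flag)
    defaults to 100x that, since digitized outlines track a boundary far
    more coarsely than landmarks are placed.
    """
    rows = []
    for name, line in boundaries.items():
        tested = crossing = smooth = 0
        for sp in specimens:
            eps = epsilon
            if eps is None:
                eps = default_epsilon(sp.landmarks)
            seps = smooth_epsilon if smooth_epsilon is not None else 100 * eps
            for clone in sp.clones:
                tested += 1
                if crosses_boundary(clone, line, eps).crosses:
                    crossing += 1
                if smooth_edge_along(clone, line, seps, k=k):
                    smooth += 1
        rows.append(
            dict(
                boundary=name,
                clones_tested=tested,
                clones_crossing=crossing,
                clones_smooth_edge=smooth,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# specimen I/O (JSON) and SVG overlay
# ---------------------------------------------------------------------------


def read_specimen(path: str) -> WingSpecimen:
    with open(path) as fh:
        raw = json.load(fh)
    return WingSpecimen(
        specimen_id=raw["id"],
        landmarks=LandmarkSet(raw["landmarks"]),
        clones=tuple(np.asarray(c, dtype=float) for c in raw.get("clones", [])),
        boundaries={
            k: np.asarray(v, dtype=float)
            for k, v in raw.get("boundaries", {}).items()
        },
    )


def write_specimen(specimen: WingSpecimen, path: str) -> None:
    payload = {
        "id": specimen.specimen_id,
        "landmarks": specimen.landmarks.as_dict(),
        "clones": [np.asarray(c).tolist() for c in specimen.clones],
        "boundaries": {
            k: np.asarray(v).tolist() for k, v in specimen.boundaries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def specimens_to_svg(
    specimens: Sequence[WingSpecimen],
    boundaries: Mapping[str, np.ndarray] | None = None,
    width: int = 640,
) -> str:
    """Minimal SVG overlay of superimposed clone outlines and boundaries."""
    all_pts = [sp.landmarks.coords for sp in specimens]
    for sp in specimens:
        all_pts.extend(sp.clones)
    if boundaries:
        all_pts.extend(np.asarray(v) for v in boundaries.values())
    pts = np.vstack(all_pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    scale = (width - 20) / span.max()
    height = int(span[1] * scale) + 20

    def xy(p):
        q = (p - lo) * scale + 10
        return f"{q[0]:.2f},{height - q[1]:.2f}"  # y-up -> SVG y-down

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}">'
    ]
    for sp in specimens:
        for clone in sp.clones:
            path = " ".join(xy(p) for p in clone)
            parts.append(
                f'<polygon points="{path}" fill="#d9822b" fill-opacity="0.15" '
                'stroke="#d9822b" stroke-width="1"/>'
            )
        for n in sp.landmarks.names:
            q = (sp.landmarks[n] - lo) * scale + 10
            parts.append(
                f'<circle cx="{q[0]:.2f}" cy="{height - q[1]:.2f}" r="2.5" '
                'fill="red"/>'
            )
    for name, line in (boundaries or {}).items():
        path = " ".join(xy(p) for p in np.asarray(line, dtype=float))
        parts.append(
            f'<polyline points="{path}" fill="none" stroke="black" '
            'stroke-dasharray="6 4" stroke-width="1.5"/>'
        )
        q = (np.asarray(line, dtype=float)[0] - lo) * scale + 10
        parts.append(
            f'<text x="{q[0]:.2f}" y="{height - q[1]:.2f}" '
            f'font-size="12">{name}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
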