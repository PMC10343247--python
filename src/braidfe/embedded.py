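"""Embedded bar-fiber reinforcement for hexahedral host meshes.

A fiber is a polyline with a cross-sectional area and an axial modulus.  It
carries axial stiffness only: its displacement is interpolated from the host
hexahedron's shape functions, so no extra degrees of freedom are added and
the fiber stiffness simply superposes onto the host element stiffness,
``K_e = k_m + sum_i k_f_i``.

The axial fiber strain follows from the tensor rotation of the host strain
onto the fiber direction (l, m, n)::

    eps_f = l^2 eps_x + m^2 eps_y + n^2 eps_z + m n gam_yz + n l gam_zx + l m gam_xy

(with engineering shears in the (x, y, z, yz, zx, xy) Voigt order of the
element kernel), and the fiber stiffness is the line integral
``k_f = int B'^T Ef B' A h dx'`` over the segment with half-length metric
``h``, integrated with a 2-point Gauss rule (exact for affine hosts).

Fibers crossing element faces are split at the crossings so every embedded
segment has a single host element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .hexfem import ElementStiffness, HexMesh, shape_functions, strain_matrix

__all__ = [
    "FiberPath",
    "EmbeddedSegment",
    "ElementLocator",
    "segment_fibers",
    "direction_row",
    "fiber_strain_row",
    "fiber_stiffness",
    "superpose",
]

#: segments shorter than this (mm) are discarded after splitting
MIN_SEGMENT_LENGTH = 1e-6

_GAUSS1D = (-1.0 / math.sqrt(3.0), 1.0 / math.sqrt(3.0))


@dataclass(frozen=True)
class FiberPath:
    """Polyline fiber: vertices (mm), cross-sectional area (mm^2), axial
    modulus Ef (MPa) and an optional role tag."""

    points: np.ndarray
    area: float
    Ef: float
    tag: str = "fiber"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise ValueError("fiber path needs at least 2 points")
        if self.area <= 0:
            raise ValueError("fiber area must be positive")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("consecutive fiber path points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class EmbeddedSegment:
    """Straight fiber segment contained in a single host hexahedron."""

    element: int
    p0: np.ndarray
    p1: np.ndarray
    xi0: np.ndarray  # natural coordinates of p0 in the host
    xi1: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "xi0", "xi1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def h(self) -> float:
        """Half-length metric dx/dx' of the segment parametrized on [-1, 1]."""
        return 0.5 * self.length

    @property
    def direction(self) -> np.ndarray:
        """Unit direction cosines (l1, m1, n1)."""
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


class ElementLocator:
    """Finds the host element and natural coordinates of physical points.

    Candidate elements come from a KD-tree over element centroids; the
    natural coordinates are then recovered by Newton iteration on the
    trilinear map (tolerance 1e-12 on the residual, 50 iterations max).
    """

    def __init__(self, mesh: HexMesh, inclusion_tol: float = 1e-6):
        self.mesh = mesh
        self.tol = inclusion_tol
        corners = mesh.nodes[mesh.elements]
        self._centroids = corners.mean(axis=1)
        self._elo = corners.min(axis=1)
        self._ehi = corners.max(axis=1)
        self._tree = cKDTree(0.5 * (self._elo + self._ehi))
        diag = np.linalg.norm(self._ehi - self._elo, axis=1)
        # any element containing p has its bbox center within half its
        # diagonal of p; search with the largest such radius, filter by bbox
        self._search_r = 0.5 * float(diag.max()) * (1.0 + 1e-9) + 1e-9
        #: typical element edge length, used by the fiber splitter
        self.typical_size = float(diag.mean()) / math.sqrt(3.0)
        self._margin = 1e-6 * diag.max()
        self._scale = float(np.linalg.norm(np.subtract(*mesh.bbox()[::-1]))) or 1.0

    def _in_bbox(self, element: int, p) -> bool:
        return bool(
            np.all(p >= self._elo[element] - self._margin)
            and np.all(p <= self._ehi[element] + self._margin)
        )

    def invert(self, element: int, p) -> np.ndarray | None:
        """Natural coordinates of ``p`` in ``element`` (Newton), or None."""
        X = self.mesh.element_coords(element)
        p = np.asarray(p, dtype=float)
        xi = np.zeros(3)
        for _ in range(50):
            N, dN = shape_functions(xi)
            r = p - N @ X
            if np.linalg.norm(r) < 1e-12 * self._scale:
                break
            J = dN.T @ X  # J[a,b] = dx_b/dxi_a
            try:
                xi = xi + np.linalg.solve(J.T, r)
            except np.linalg.LinAlgError:
                return None
            if np.abs(xi).max() > 3.0:  # diverging: point is far outside
                return None
        else:
            return None
        return xi

    def locate(
        self, p, hint: int | None = None, exclude=None
    ) -> tuple[int, np.ndarray] | None:
        """Host element id and clipped natural coordinates of point ``p``.

        ``hint`` is tried first; elements in ``exclude`` are skipped (used
        by the fiber splitter to avoid re-accepting just-exited or merely
        grazing elements through the inclusion tolerance band)."""
        p = np.asarray(p, dtype=float)
        exclude = exclude or ()
        candidates: list[int] = []
        if hint is not None:
            candidates.append(hint)
        ball = self._tree.query_ball_point(p, self._search_r)
        ball.sort(key=lambda e: float(np.linalg.norm(self._centroids[e] - p)))
        candidates.extend(ball)
        seen = set()
        for e in candidates:
            if e in seen or e in exclude or not self._in_bbox(e, p):
                continue
            seen.add(e)
            xi = self.invert(e, p)
            if xi is not None and np.abs(xi).max() <= 1.0 + self.tol:
                return e, np.clip(xi, -1.0, 1.0)
        return None

    def host(self, p, hint: int | None = None) -> int | None:
        found = self.locate(p, hint=hint)
        return None if found is None else found[0]


def segment_fibers(
    mesh: HexMesh,
    path: FiberPath,
    locator: ElementLocator | None = None,
    *,
    drop_outside: bool = False,
) -> list[EmbeddedSegment]:
    """Split a fiber path at element boundaries and assign host elements.

    Each polyline edge is marched host by host: the element containing the
    point just past the current parameter is found, the parameter at which
    the path exits that element is bracketed by forward scanning and then
    refined by bisection, and the in-between piece becomes one embedded
    segment.  Splits are therefore exact element-boundary crossings even
    when elements much thinner than the scan step are traversed, and the
    union of the segment lengths equals the path length.

    Raises a ``ValueError`` naming the offending coordinates when a point of
    the path lies outside every element, unless ``drop_outside`` is set (then
    the uncovered portions are discarded).
    """
    if locator is None:
        locator = ElementLocator(mesh)

    segments: list[EmbeddedSegment] = []
    hint: int | None = None
    for a, b in zip(path.points[:-1], path.points[1:]):
        L = float(np.linalg.norm(b - a))
        step = max(locator.typical_size / 2.0, 10 * MIN_SEGMENT_LENGTH) / L
        eps = min(1e-9, 0.01 * step)

        def point(t: float) -> np.ndarray:
            return a + t * (b - a)

        def inside(e: int, t: float) -> bool:
            # tighter than the locator acceptance so splits land on faces
            xi = locator.invert(e, point(t))
            return xi is not None and np.abs(xi).max() <= 1.0 + 1e-9

        t = 0.0
        excluded: set[int] = set()
        while t < 1.0 - eps:
            if (1.0 - t) * L < MIN_SEGMENT_LENGTH:
                break
            found = locator.locate(
                point(min(t + eps, 1.0)),
                hint=None if hint in excluded else hint,
                exclude=excluded,
            )
            if found is None:
                if not drop_outside:
                    raise ValueError(
                        f"fiber point {point(t + eps)} (tag {path.tag!r}) lies "
                        "outside every mesh element"
                    )
                # scan forward for re-entry, bisect the entry parameter
                t_in = next(
                    (s for s in np.arange(t + step, 1.0 + step, step)
                     if locator.locate(point(min(s, 1.0)), hint=hint)),
                    None,
                )
                if t_in is None:
                    break
                lo, hi = t, min(t_in, 1.0)
                for _ in range(50):
                    mid = 0.5 * (lo + hi)
                    if locator.locate(point(mid), hint=hint) is None:
                        lo = mid
                    else:
                        hi = mid
                t = hi
                continue
            h = found[0]
            hint = h
            # bracket the exit of host h by forward scanning, then bisect
            t_exit = 1.0
            if not inside(h, 1.0):
                lo = t
                hi = next(
                    s for s in np.arange(t + step, 1.0 + step, step)
                    if not inside(h, min(s, 1.0))
                )
                hi = min(hi, 1.0)
                for _ in range(50):
                    mid = 0.5 * (lo + hi)
                    if inside(h, mid):
                        lo = mid
                    else:
                        hi = mid
                t_exit = 0.5 * (lo + hi)
            if t_exit <= t + eps:
                # h only grazed the path through the inclusion tolerance
                # band; retry the same parameter with h excluded
                excluded.add(h)
                if len(excluded) > 30:
                    raise ValueError(
                        f"fiber segmentation stalled at t={t} in element {h} "
                        f"(tag {path.tag!r})"
                    )
                continue
            p0, p1 = point(t), point(t_exit)
            if np.linalg.norm(p1 - p0) >= MIN_SEGMENT_LENGTH:
                xi0 = locator.invert(h, point(t + eps * (t_exit - t)))
                xi1 = locator.invert(h, point(t_exit - eps * (t_exit - t)))
                if xi0 is None or xi1 is None:
                    raise ValueError(
                        f"inverse mapping failed for fiber segment in element {h}"
                    )
                segments.append(
                    EmbeddedSegment(
                        element=h, p0=p0, p1=p1,
                        xi0=np.clip(xi0, -1, 1), xi1=np.clip(xi1, -1, 1),
                    )
                )
            t = t_exit
            excluded = {h}
    return segments


def direction_row(direction) -> np.ndarray:
    """Voigt transform row mapping engineering strain to axial fiber strain.

    For unit direction (l, m, n) the row is
    ``[l^2, m^2, n^2, m n, n l, l m]`` in (x, y, z, yz, zx, xy) ordering;
    it doubles as the Voigt representation of the uniaxial stress direction
    d (x) d used when volume-averaging fiber stress.
    """
    l, m, n = np.asarray(direction, dtype=float)
    return np.array([l * l, m * m, n * n, m * n, n * l, l * m])


def fiber_strain_row(
    segment: EmbeddedSegment, nodes: np.ndarray, s: float = 0.0
) -> np.ndarray:
    """B' (1x24): nodal displacements -> axial fiber strain at local x'=s.

    The natural coordinates along the segment are interpolated linearly
    between the endpoint coordinates (exact for affine host geometry).
    """
    xi = 0.5 * (1.0 - s) * segment.xi0 + 0.5 * (1.0 + s) * segment.xi1
    B, _ = strain_matrix(nodes, xi)
    return direction_row(segment.direction) @ B


def fiber_stiffness(
    segment: EmbeddedSegment, nodes: np.ndarray, Ef: float, area: float
) -> np.ndarray:
    """24x24 stiffness contribution of one embedded segment.

    Two-point Gauss integration of ``B'^T Ef B' A h`` along the fiber
    coordinate x' in [-1, 1]; symmetric PSD of rank <= 2.
    """
    k = np.zeros((24, 24))
    for s in _GAUSS1D:
        Bp = fiber_strain_row(segment, nodes, s)
        k += np.outer(Bp, Bp) * (Ef * area * segment.h)
    return k


def superpose(
    km: ElementStiffness, fiber_contributions: list[tuple[int, np.ndarray]]
) -> ElementStiffness:
    """Superpose fiber stiffness contributions onto a matrix element.

    ``fiber_contributions`` is a list of (element_id, 24x24) pairs; every id
    must match the matrix element's id.
    """
    k = km.k.copy()
    for eid, kf in fiber_contributions:
        if eid != km.element_id:
            raise ValueError(
                f"fiber contribution for element {eid} superposed onto "
                f"element {km.element_id}"
            )
        k = k + kf
    return ElementStiffness(k=k, element_id=km.element_id)
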