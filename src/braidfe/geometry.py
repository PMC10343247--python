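"""Parametric generator for the braided crescent (meniscus) lattice.

The implant plan view is a crescent bounded by two elliptical arcs sharing
their horn axis: an outer convex arc (set by the design length and width)
and an inner concave arc.  A mapped block parametrization
``(u, v, w)`` — ``u`` along the arc from horn to horn, ``v`` from the inner
to the outer boundary, ``w`` through the thickness — yields both the
hexahedral matrix mesh and, because fiber paths are generated in the same
parameter space, fibers that are guaranteed to lie inside the solid.  The
cross-section is a wedge: full design height at the outer boundary,
tapering linearly to a thin inner edge.

The braid architecture follows the three-level, five-layer design: levels
(1, 1, 2, 2, 3) from bottom to top with per-level transverse/longitudinal
fiber counts (6/13, 4/12, 2/8), transverse fibers as half-moon arcs,
longitudinal fibers fanning from the inner to the outer edge, and vertical
interlock loops binding adjacent layers at fiber crossings.  Because the
wedge is thin at the inner edge, the upper levels are necessarily placed
toward the tall outer rim and their transverse fibers sit closer together
than in their standalone (planar) level patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import GeometryConfig, RunConfig
from .embedded import FiberPath
from .hexfem import HexMesh, box_mesh
from .homogenize import RVCSpec
from .materials import IsotropicMaterial

__all__ = [
    "MeniscusDesign",
    "CrescentMap",
    "TrussLattice",
    "build_level",
    "build_meniscus",
    "build_rvc",
]

#: the design block of the run configuration doubles as the design record
MeniscusDesign = GeometryConfig

#: fibers are kept below this thickness fraction so they never pierce the
#: sloped top surface
WMAX = 0.95


class CrescentMap:
    """Mapped-block parametrization of the crescent wedge solid.

    The plan outline is a crescent between two elliptical arcs sharing the
    horn axis: the outer arc rises to the full design width, the inner
    (concave) arc to ``inner_apex_fraction * width``.  A small trim near the
    horns keeps the mapped hexahedra non-degenerate; the map is rescaled in
    closed form so the bounding box of the solid equals the design
    (length, width, height) exactly.
    """

    def __init__(self, design: MeniscusDesign, trim: float = 0.04):
        self.design = design
        self.trim = trim
        W = design.width_mm
        h_i = design.inner_apex_fraction * W
        if not (0.0 < h_i < W):
            raise ValueError("inner apex must lie strictly between horn line and apex")
        self._h_i = h_i
        self._xscale = 1.0 / math.cos(math.pi * trim)
        self._ymin = h_i * math.sin(math.pi * trim)

    def thickness(self, v):
        """Local wedge thickness t(v), linear from the thin inner edge."""
        d = self.design
        return d.inner_thickness_mm + (d.height_mm - d.inner_thickness_mm) * np.asarray(v)

    def map(self, u, v, w) -> np.ndarray:
        """Physical coordinates of parameter points (u, v, w) in [0,1]^3."""
        u, v, w = np.broadcast_arrays(
            np.asarray(u, float), np.asarray(v, float), np.asarray(w, float)
        )
        d = self.design
        W = d.width_mm
        s = math.pi * (self.trim + u * (1.0 - 2.0 * self.trim))
        x = -0.5 * d.length_mm * np.cos(s) * self._xscale
        y_raw = ((1.0 - v) * self._h_i + v * W) * np.sin(s)
        y = (y_raw - self._ymin) * W / (W - self._ymin)
        z = w * self.thickness(v)
        return np.stack([x, y, z], axis=-1)

    def breadth(self, u=0.5) -> float:
        """Radial (inner-to-outer) plan width at parameter u."""
        p = self.map(np.array([u, u]), np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        return float(np.linalg.norm(p[1, :2] - p[0, :2]))

    def arc_length(self, v=1.0, n=400) -> float:
        us = np.linspace(0, 1, n + 1)
        p = self.map(us, np.full(n + 1, v), np.zeros(n + 1))
        return float(np.linalg.norm(np.diff(p[:, :2], axis=0), axis=1).sum())

    def v_min_for_height(self, z: float, wmax: float = WMAX) -> float:
        """Smallest v whose local thickness accommodates height z."""
        d = self.design
        need = z / wmax
        if need <= d.inner_thickness_mm:
            return 0.0
        v = (need - d.inner_thickness_mm) / (d.height_mm - d.inner_thickness_mm)
        if v >= 1.0:
            raise ValueError(f"height z={z} mm does not fit inside the wedge")
        return v

    def grid(self, resolution: float = 1.5) -> "MappedGrid":
        """Structured parameter grid of the solid at a target edge length."""
        d = self.design
        # even nu keeps the apex (u = 0.5) on the node grid so the generated
        # bounding box matches the design box exactly
        nu = 2 * max(3, round(0.5 * self.arc_length() / resolution))
        nv = max(3, round(self.breadth() / resolution))
        nw = max(3, round(d.height_mm / resolution))
        uu = np.linspace(0, 1, nu + 1)
        vv = np.linspace(0, 1, nv + 1)
        ww = np.linspace(0, 1, nw + 1)
        U, V, W = np.meshgrid(uu, vv, ww, indexing="ij")
        nodes = self.map(U, V, W)
        return MappedGrid(uu=uu, vv=vv, ww=ww, nodes=nodes)

    def mesh(self, resolution: float = 1.5) -> HexMesh:
        """Structured hexahedral mesh of the solid at a target edge length."""
        return self.grid(resolution).mesh()


@dataclass
class MappedGrid:
    """Discretized crescent map: grid lines in (u, v, w) and node coords.

    ``interp`` evaluates the *piecewise-trilinear* map of the mesh, so
    points produced with it lie inside the faceted solid by construction —
    which is what the fiber generators use, guaranteeing locatability of
    every fiber path regardless of how coarsely the curved boundary is
    faceted.
    """

    uu: np.ndarray
    vv: np.ndarray
    ww: np.ndarray
    nodes: np.ndarray  # (nu+1, nv+1, nw+1, 3)

    def interp(self, u, v, w) -> np.ndarray:
        u, v, w = np.broadcast_arrays(
            np.asarray(u, float), np.asarray(v, float), np.asarray(w, float)
        )
        out = np.zeros(u.shape + (3,))
        idx = []
        loc = []
        for t, axis in ((u, self.uu), (v, self.vv), (w, self.ww)):
            i = np.clip(np.searchsorted(axis, t) - 1, 0, len(axis) - 2)
            idx.append(i)
            loc.append((t - axis[i]) / (axis[i + 1] - axis[i]))
        iu, iv, iw = idx
        tu, tv, tw = loc
        for du in (0, 1):
            for dv in (0, 1):
                for dw in (0, 1):
                    wgt = (
                        (tu if du else 1 - tu)
                        * (tv if dv else 1 - tv)
                        * (tw if dw else 1 - tw)
                    )
                    out += wgt[..., None] * self.nodes[iu + du, iv + dv, iw + dw]
        return out

    def mesh(self) -> HexMesh:
        nu, nv, nw = len(self.uu) - 1, len(self.vv) - 1, len(self.ww) - 1
        nodes = self.nodes.reshape(-1, 3, order="C")
        # C-order raveling of (nu+1, nv+1, nw+1): index = k + (nw+1)*(j + (nv+1)*i)
        def nid(i, j, k):
            return k + (nw + 1) * (j + (nv + 1) * i)

        elems = []
        for k in range(nw):
            for j in range(nv):
                for i in range(nu):
                    elems.append(
                        [
                            nid(i, j, k), nid(i + 1, j, k),
                            nid(i + 1, j + 1, k), nid(i, j + 1, k),
                            nid(i, j, k + 1), nid(i + 1, j, k + 1),
                            nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                        ]
                    )
        mesh = HexMesh(nodes, np.asarray(elems, dtype=np.int64))
        mesh.check_jacobians()
        return mesh


@dataclass
class TrussLattice:
    """Collection of tagged fiber paths making up (part of) the braid."""

    fibers: list[FiberPath] = field(default_factory=list)
    design: MeniscusDesign | None = None

    def by_tag(self, prefix: str) -> list[FiberPath]:
        return [f for f in self.fibers if f.tag.startswith(prefix)]

    @property
    def total_length(self) -> float:
        return sum(f.length for f in self.fibers)

    def extend(self, other: "TrussLattice") -> None:
        self.fibers.extend(other.fibers)


def _level_ratio(design: MeniscusDesign, level: int, kind: str) -> float:
    """Length of a level's fibers relative to level 1, from the nominal
    design lengths (transverse) or cumulative shortenings (longitudinal)."""
    if kind == "transverse":
        ref = design.transverse_lengths_mm[0]
        return design.transverse_lengths_mm[level - 1] / ref
    ref = design.length_mm * 26.0 / 32.0  # nominal longitudinal length scales with design
    short = sum(design.longitudinal_shortening_mm[:level])
    return max(0.15, (ref - short) / ref)


def build_level(
    design: MeniscusDesign,
    level: int,
    *,
    z: float | None = None,
    crescent: CrescentMap | None = None,
    bar_modulus: float = 1.0,
    layer: int | None = None,
    check_gap: bool = True,
    mapper=None,
) -> TrussLattice:
    """Planar braid pattern of one level (1..3): transverse half-moon arcs
    plus fanning longitudinal fibers.

    With ``z=None`` the pattern is laid out at the bottom plane over the
    full crescent breadth (the standalone level pattern); with a height the
    fibers are restricted to the portion of the wedge that accommodates it.
    ``check_gap`` rejects parameter combinations whose same-level transverse
    arcs would come closer than the configured gap.
    """
    if level not in range(1, len(design.transverse_counts) + 1):
        raise ValueError(f"level must be in 1..{len(design.transverse_counts)}")
    cres = crescent or CrescentMap(design)
    mapper = mapper or cres.map
    area = design.fiber_width_mm * design.fiber_height_mm
    n_t = design.transverse_counts[level - 1]
    n_l = design.longitudinal_counts[level - 1]
    tag_sfx = f"L{level}" + ("" if layer is None else f"/layer{layer}")

    if z is None:
        v_lo, zfun = 0.0, (lambda v: np.zeros_like(v))
    else:
        v_lo = cres.v_min_for_height(z)
        zfun = lambda v: z / cres.thickness(v)

    lattice = TrussLattice(design=design)
    if n_t > 0:
        spacing = (1.0 - v_lo) / n_t * cres.breadth()
        if check_gap and spacing < design.gap_mm:
            raise ValueError(
                f"level {level}: transverse fiber spacing {spacing:.2f} mm is "
                f"below the configured gap {design.gap_mm} mm"
            )
    ratio_t = _level_ratio(design, level, "transverse")
    for j in range(n_t):
        v_j = v_lo + (j + 0.5) / n_t * (1.0 - v_lo)
        u0, u1 = 0.5 * (1 - ratio_t), 0.5 * (1 + ratio_t)
        us = np.linspace(u0, u1, max(12, int(24 * ratio_t)))
        vs = np.full_like(us, v_j)
        pts = mapper(us, vs, zfun(vs))
        lattice.fibers.append(
            FiberPath(points=pts, area=area, Ef=bar_modulus, tag=f"transverse/{tag_sfx}")
        )

    ratio_l = _level_ratio(design, level, "longitudinal")
    for k in range(n_l):
        u_k = (k + 0.5) / n_l
        v_start = v_lo + (1.0 - ratio_l) * (1.0 - v_lo)
        vs = np.linspace(v_start, 1.0, 12)
        us = np.full_like(vs, u_k)
        pts = mapper(us, vs, zfun(vs))
        lattice.fibers.append(
            FiberPath(points=pts, area=area, Ef=bar_modulus, tag=f"longitudinal/{tag_sfx}")
        )
    return lattice


def build_meniscus(
    design: MeniscusDesign,
    *,
    bar_modulus: float = 1.0,
    interlock_modulus: float | None = None,
    resolution: float = 1.5,
) -> tuple[TrussLattice, HexMesh]:
    """Full braided implant: stacked level lattices at the five layer
    heights, vertical interlock loops at fiber crossings of adjacent
    layers, and the wedge matrix mesh.  Every fiber path lies inside the
    mesh by construction (shared parametrization)."""
    cres = CrescentMap(design)
    grid = cres.grid(resolution)
    mesh = grid.mesh()
    H, n_layers = design.height_mm, design.n_layers
    layer_z = [(i + 0.5) * H / n_layers for i in range(n_layers)]

    lattice = TrussLattice(design=design)
    for i, level in enumerate(design.level_of_layer):
        lattice.extend(
            build_level(
                design, level, z=layer_z[i], crescent=cres,
                bar_modulus=bar_modulus, layer=i, check_gap=False,
                mapper=grid.interp,
            )
        )

    # vertical interlock loops (two yarn legs each) binding adjacent layers
    ilk_E = bar_modulus if interlock_modulus is None else interlock_modulus
    ilk_area = 2.0 * math.pi * (0.5 * design.interlock_diameter_mm) ** 2
    for i in range(n_layers - 1):
        lvl_lo = design.level_of_layer[i]
        z0, z1 = layer_z[i], layer_z[i + 1]
        n_t = design.transverse_counts[lvl_lo - 1]
        n_l = design.longitudinal_counts[lvl_lo - 1]
        if n_t == 0 or n_l == 0:
            continue
        v_lo0 = cres.v_min_for_height(z0)
        for j in range(n_t):
            v_j = v_lo0 + (j + 0.5) / n_t * (1.0 - v_lo0)
            if z1 > WMAX * float(cres.thickness(v_j)):
                continue  # upper layer does not reach this radial band
            for k in range(n_l):
                u_k = (k + 0.5) / n_l
                p = grid.interp(
                    np.array([u_k, u_k]),
                    np.array([v_j, v_j]),
                    np.array([z0, z1]) / float(cres.thickness(v_j)),
                )
                lattice.fibers.append(
                    FiberPath(points=p, area=ilk_area, Ef=ilk_E,
                              tag=f"interlock/{i}-{i + 1}")
                )
    return lattice, mesh


def build_rvc(
    label: str,
    config: RunConfig | None = None,
    *,
    bundle_axial_modulus: float | None = None,
    resolution: float | None = None,
) -> RVCSpec:
    """Periodic unit cells of the multi-scale chain.

    * ``micro`` — unidirectional bundle cell: hexagonal fiber packing
      (one full fiber at the cell center, four quarter fibers at the
      corners) in a rectangular cell of aspect sqrt(3), fibers realized as
      embedded bars whose total cross-section matches the fiber volume
      fraction Vf.
    * ``top`` / ``bottom`` — meso cells with one longitudinal and one
      transverse bundle bar in crossed layers, mirror images of each other.
    * ``interior`` — like ``top`` plus the vertical interlock loop.

    ``bundle_axial_modulus`` (MPa) feeds the meso bars; by default it comes
    from the bridging model (the multi-scale chain passes the micro-FE
    value instead).  Embedded bar moduli are reduced by the matrix modulus
    when overlap correction is enabled, so the doubly-counted matrix volume
    is compensated.
    """
    cfg = config or RunConfig()
    pcu = cfg.matrix()
    ndiv = int(resolution) if resolution is not None else cfg.mesh.rvc_divisions
    correct = cfg.mesh.overlap_correction

    if label == "micro":
        fiber = cfg.fiber()
        Vf = cfg.bridging.Vf
        a = 1.0  # mm, transverse cell width; aspect sqrt(3) for hex packing
        b = a * math.sqrt(3.0)
        mesh = box_mesh((1.0, a, b), (2, ndiv, ndiv))
        Ef = fiber.E11 - pcu.E if correct else fiber.E11
        A_cs = a * b
        d = a / (ndiv * 2.0)  # corner-bar inset, strictly inside the corner elements
        def bar(y, z, frac):
            return FiberPath(
                points=[[1e-6, y, z], [1.0 - 1e-6, y, z]],
                area=Vf * A_cs * frac, Ef=Ef, tag="bundle-fiber",
            )
        fibers = [
            bar(a / 2, b / 2, 0.5),
            bar(d, d, 0.125), bar(a - d, d, 0.125),
            bar(d, b - d, 0.125), bar(a - d, b - d, 0.125),
        ]
        return RVCSpec(mesh=mesh, matrix=pcu, fibers=fibers, label="micro")

    if label not in ("top", "interior", "bottom"):
        raise ValueError(f"unknown RVC label {label!r}")

    geo = cfg.geometry
    if bundle_axial_modulus is None:
        from .bridging import bundle_constants

        bundle_axial_modulus = bundle_constants(
            cfg.fiber(), pcu, cfg.bridging_params()
        ).E11
    Eb = bundle_axial_modulus - pcu.E if correct else bundle_axial_modulus

    pitch = geo.fiber_width_mm + geo.gap_mm          # in-plane period, 4 mm
    h = 2.0 * geo.fiber_height_mm                    # two 1 mm layers
    area = geo.fiber_width_mm * geo.fiber_height_mm  # bundle cross-section
    mesh = box_mesh((pitch, h, pitch), (ndiv, ndiv, ndiv))
    y_lo, y_hi = 0.25 * h, 0.75 * h
    y_long, y_trans = (y_hi, y_lo) if label in ("top", "interior") else (y_lo, y_hi)
    fibers = [
        FiberPath(points=[[1e-6, y_long, pitch / 2], [pitch - 1e-6, y_long, pitch / 2]],
                  area=area, Ef=Eb, tag="bundle-longitudinal"),
        FiberPath(points=[[pitch / 2, y_trans, 1e-6], [pitch / 2, y_trans, pitch - 1e-6]],
                  area=area, Ef=Eb, tag="bundle-transverse"),
    ]
    if label == "interior":
        ilk_area = 2.0 * math.pi * (0.5 * geo.interlock_diameter_mm) ** 2
        fibers.append(
            FiberPath(points=[[pitch / 2, 1e-6, pitch / 2], [pitch / 2, h - 1e-6, pitch / 2]],
                      area=ilk_area, Ef=Eb, tag="interlock")
        )
    return RVCSpec(mesh=mesh, matrix=pcu, fibers=fibers, label=label)
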