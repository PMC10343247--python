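"""Macro-scale comparison: braided implant vs pure-matrix implant.

Both models share the same wedge mesh of the crescent solid; the reinforced
model additionally embeds the full braided lattice as bar fibers carrying
the bundle axial modulus.  The bottom surface is fully fixed and the total
load is applied as a uniform pressure on the sloped top (wedge) surface,
converted to consistent vertical nodal forces through the projected face
areas so the resultant equals the requested load exactly.

"Resistance to deformation" is quantified as the inverse of the maximum
downward displacement of the loaded surface at equal load; the improvement
of the reinforced model over the matrix model is
``(u_matrix / u_reinforced - 1) * 100`` per load case, which is constant
across load cases in this linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .bridging import bundle_constants
from .config import RunConfig
from .geometry import build_meniscus
from .homogenize import FEModel

__all__ = [
    "LoadCase",
    "SimulationResult",
    "MacroModel",
    "improvement_ratio",
    "compare",
]


@dataclass(frozen=True)
class LoadCase:
    """Total compressive load (N) applied to the top wedge surface."""

    newtons: float

    def __post_init__(self) -> None:
        if self.newtons < 0:
            raise ValueError("load must be non-negative")


@dataclass
class SimulationResult:
    """Load sweep of one macro model."""

    tag: str  # "reinforced" | "pure_matrix"
    loads: tuple[float, ...]
    max_displacement: tuple[float, ...]  # mm, downward, per load
    pressure: tuple[float, ...]  # MPa, mean top-surface pressure per load

    def curve(self) -> np.ndarray:
        """(n, 2) stress (MPa) vs vertical deformation (mm) curve, through
        the origin."""
        return np.vstack(
            [[0.0, 0.0]]
            + [[d, p] for d, p in zip(self.max_displacement, self.pressure)]
        )


def _boundary_faces(mesh):
    """(element, local-face, node-tuple) triples of boundary faces."""
    # local faces of the hexahedron in the package node ordering
    local = [
        (0, 1, 2, 3),  # bottom
        (4, 5, 6, 7),  # top
        (0, 1, 5, 4),
        (1, 2, 6, 5),
        (2, 3, 7, 6),
        (3, 0, 4, 7),
    ]
    seen: dict[tuple, tuple] = {}
    for e in range(mesh.n_elements):
        conn = mesh.elements[e]
        for lf, face in enumerate(local):
            nodes = tuple(conn[i] for i in face)
            key = tuple(sorted(nodes))
            if key in seen:
                del seen[key]
            else:
                seen[key] = (e, lf, nodes)
    return list(seen.values())


def _top_faces(mesh, min_up_normal: float = 0.5):
    """Boundary faces whose outward normal points mostly upward."""
    faces = []
    for e, lf, nodes in _boundary_faces(mesh):
        q = mesh.nodes[list(nodes)]
        n = np.cross(q[2] - q[0], q[3] - q[1])
        n = n / np.linalg.norm(n)
        centroid = mesh.nodes[mesh.elements[e]].mean(axis=0)
        if np.dot(n, q.mean(axis=0) - centroid) < 0:
            n = -n
        if n[2] > min_up_normal:
            faces.append((nodes, q))
    if not faces:
        raise ValueError("no upward-facing boundary faces found")
    return faces


def _pressure_forces(mesh) -> tuple[np.ndarray, float]:
    """Vertical nodal forces for unit pressure on the top surface and the
    projected (plan) area of that surface."""
    g = 1.0 / np.sqrt(3.0)
    gp = [(-g, -g), (g, -g), (g, g), (-g, g)]
    f = np.zeros(3 * mesh.n_nodes)
    area = 0.0
    for nodes, q in _top_faces(mesh):
        for xi, eta in gp:
            N = 0.25 * np.array(
                [
                    (1 - xi) * (1 - eta),
                    (1 + xi) * (1 - eta),
                    (1 + xi) * (1 + eta),
                    (1 - xi) * (1 + eta),
                ]
            )
            dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
            deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
            jz = abs(np.cross(dxi @ q, deta @ q)[2])  # projected area element
            area += jz
            for i, nd in enumerate(nodes):
                f[3 * nd + 2] -= N[i] * jz  # downward unit pressure
    return f, area


def _interior_nodes(mesh) -> np.ndarray:
    """Boolean mask of nodes not on any boundary face."""
    on_boundary = np.zeros(mesh.n_nodes, dtype=bool)
    for _, _, nodes in _boundary_faces(mesh):
        on_boundary[list(nodes)] = True
    return ~on_boundary


class MacroModel:
    """Assembled and factorized macro model of the implant."""

    def __init__(
        self,
        config: RunConfig | None = None,
        *,
        reinforced: bool = True,
        resolution: float | None = None,
        perturb: float = 0.0,
        seed: int = 0,
    ):
        cfg = config or RunConfig()
        self.config = cfg
        self.tag = "reinforced" if reinforced else "pure_matrix"
        res = resolution if resolution is not None else cfg.mesh.macro_resolution_mm
        pcu = cfg.matrix()
        bundle = bundle_constants(cfg.fiber(), pcu, cfg.bridging_params())
        bar_E = bundle.E11 - pcu.E if cfg.mesh.overlap_correction else bundle.E11
        lattice, mesh = build_meniscus(
            cfg.geometry, bar_modulus=bar_E, resolution=res
        )
        if perturb > 0.0:
            # optional robustness jitter of interior nodes; the pipeline
            # itself is otherwise seed-free and deterministic.  The
            # amplitude scales with the smallest element dimension so thin
            # elements near the horns cannot invert.
            rng = np.random.default_rng(seed)
            corners = mesh.nodes[mesh.elements]
            min_side = float((corners.max(axis=1) - corners.min(axis=1)).min())
            interior = _interior_nodes(mesh)
            mesh.nodes[interior] += rng.uniform(
                -perturb * min_side, perturb * min_side, (interior.sum(), 3)
            )
            mesh.check_jacobians()
        fibers = lattice.fibers if reinforced else []
        self.lattice = lattice if reinforced else None
        self.model = FEModel(mesh, pcu, fibers)

        self._f_unit, self.top_area = _pressure_forces(mesh)
        fixed = np.zeros(3 * mesh.n_nodes, dtype=bool)
        bottom = np.abs(mesh.nodes[:, 2]) < 1e-9
        if not bottom.any():
            raise ValueError("no bottom-surface nodes found to fix")
        fixed[np.repeat(np.nonzero(bottom)[0] * 3, 3) + np.tile([0, 1, 2], bottom.sum())] = True
        self._free = ~fixed
        self._top_nodes = np.unique(
            [nd for nodes, _ in _top_faces(mesh) for nd in nodes]
        )
        self._lu, self.active_segments = self._factorize_tension_only()

    def _factorize_tension_only(self):
        """Factorize the constrained system with slack fibers removed.

        Textile yarns carry tension but buckle under compression, so fiber
        segments whose axial strain is compressive in the solved state are
        deactivated and the system re-solved until the active set is stable
        (the active set is load-level independent in this linear-elastic,
        scale-invariant setting).  Deactivation only ever removes positive
        semi-definite contributions, so the reinforced model can approach
        but never undercut the pure-matrix stiffness.
        """
        free = self._free
        f = self._f_unit[free]
        nseg = len(self.model.segments)
        active = np.ones(nseg, dtype=bool)
        lu = None
        for _ in range(20):
            K = self.model.K_matrix + self.model.fiber_stiffness_matrix(active)
            lu = spla.splu(K[free][:, free].tocsc())
            if nseg == 0:
                break
            u = np.zeros_like(self._f_unit)
            u[free] = lu.solve(f)
            new_active = self.model.fiber_strains(u) > -1e-14
            if np.array_equal(new_active, active):
                break
            active = new_active
        return lu, active

    def run_case(self, load: LoadCase | float) -> tuple[float, float]:
        """Solve one load case; returns (max downward top displacement mm,
        mean top pressure MPa)."""
        if not isinstance(load, LoadCase):
            load = LoadCase(float(load))
        pressure = load.newtons / self.top_area
        u = self.displacement(load)
        w_top = -u[3 * self._top_nodes + 2]
        return float(w_top.max()), pressure

    def displacement(self, load: LoadCase | float) -> np.ndarray:
        if not isinstance(load, LoadCase):
            load = LoadCase(float(load))
        pressure = load.newtons / self.top_area
        f = self._f_unit * pressure
        u = np.zeros_like(f)
        u[self._free] = self._lu.solve(f[self._free])
        return u

    def simulate(self, loads=None) -> SimulationResult:
        loads = tuple(loads if loads is not None else self.config.loads.newtons)
        disps, press = zip(*(self.run_case(L) for L in loads))
        return SimulationResult(
            tag=self.tag, loads=loads, max_displacement=disps, pressure=press
        )


def improvement_ratio(
    reinforced: SimulationResult, matrix: SimulationResult
) -> dict[str, object]:
    """Deformation-resistance improvement of the reinforced implant, percent.

    Per load case ``(u_matrix / u_reinforced - 1) * 100`` plus the mean over
    the load set; load sets must match.
    """
    if reinforced.loads != matrix.loads:
        raise ValueError(
            f"load sets differ: {reinforced.loads} vs {matrix.loads}"
        )
    per_load = tuple(
        (um / ur - 1.0) * 100.0
        for um, ur in zip(matrix.max_displacement, reinforced.max_displacement)
    )
    return {
        "per_load_percent": per_load,
        "mean_percent": float(np.mean(per_load)),
        "loads": reinforced.loads,
    }


def compare(
    config: RunConfig | None = None,
    *,
    resolution: float | None = None,
    loads=None,
) -> dict[str, object]:
    """Full comparison: reinforced vs pure-matrix implant on the same mesh."""
    cfg = config or RunConfig()
    reinforced = MacroModel(cfg, reinforced=True, resolution=resolution)
    matrix = MacroModel(cfg, reinforced=False, resolution=resolution)
    r = reinforced.simulate(loads)
    m = matrix.simulate(loads)
    return {
        "reinforced": r,
        "pure_matrix": m,
        "improvement": improvement_ratio(r, m),
    }
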