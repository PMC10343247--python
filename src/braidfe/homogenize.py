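"""Periodic unit-cell homogenization of embedded-fiber hexahedral models.

The effective stiffness of a representative volume cell (RVC) is obtained
from six load cases with prescribed unit macroscopic strains.  Periodic
boundary conditions tie each node on a "max" face to its image on the
opposite "min" face so that the displacement difference equals the macro
strain times the face offset; the ties are eliminated master-slave, which
satisfies them exactly and keeps the pipeline deterministic.  Column j of
the effective stiffness C is the volume-averaged stress under unit macro
strain j; engineering constants are read from S = C^-1.

Voigt ordering everywhere is (x, y, z, yz, zx, xy) with engineering shear
strains.  The fiber axis of a unit cell is x ("L"), the vertical/transverse
direction is y ("T") and the remaining in-plane direction z ("Z"), matching
the (EL, ET, EZ, vLT, GLT, GLZ, GTZ) table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .embedded import (
    ElementLocator,
    EmbeddedSegment,
    FiberPath,
    direction_row,
    fiber_stiffness,
    fiber_strain_row,
    segment_fibers,
)
from .hexfem import HexMesh, elastic_matrix, gauss2, strain_matrix
from .materials import IsotropicMaterial, TransverselyIsotropicMaterial

__all__ = [
    "RVCSpec",
    "HomogenizedElasticity",
    "FEModel",
    "assemble",
    "periodic_transform",
    "apply_periodic_bc",
    "homogenize",
    "multiscale_chain",
    "strain_voigt_to_tensor",
]


def strain_voigt_to_tensor(eps) -> np.ndarray:
    """Engineering Voigt strain (x,y,z,yz,zx,xy) to symmetric tensor."""
    e = np.asarray(eps, dtype=float)
    return np.array(
        [
            [e[0], 0.5 * e[5], 0.5 * e[4]],
            [0.5 * e[5], e[1], 0.5 * e[3]],
            [0.5 * e[4], 0.5 * e[3], e[2]],
        ]
    )


@dataclass
class RVCSpec:
    """A periodic unit-cell model: mesh, matrix material and embedded fibers.

    ``fibers`` carry the *bar* modulus actually integrated along the fiber;
    builders that correct for the matrix volume overlapped by embedded bars
    pass ``E_fiber - E_matrix`` here.
    """

    mesh: HexMesh
    matrix: IsotropicMaterial
    fibers: list[FiberPath] = field(default_factory=list)
    label: str = "cell"
    periodic: tuple[bool, bool, bool] = (True, True, True)


@dataclass(frozen=True)
class HomogenizedElasticity:
    """Effective 6x6 stiffness of a cell with derived engineering constants."""

    C: np.ndarray
    label: str = "cell"

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        asym = np.abs(C - C.T).max() / max(np.abs(C).max(), 1e-30)
        if asym > 1e-6:
            raise ValueError(
                f"effective stiffness asymmetric (relative asymmetry {asym:.3g})"
            )
        C = 0.5 * (C + C.T)
        w = np.linalg.eigvalsh(C)
        if w.min() <= 0:
            raise ValueError(f"effective stiffness not positive definite: eigs {w}")
        object.__setattr__(self, "C", C)

    @property
    def S(self) -> np.ndarray:
        return np.linalg.inv(self.C)

    def engineering_constants(self) -> dict[str, float]:
        """Constants (MPa) in the (EL, ET, EZ, vLT, GLT, GLZ, GTZ) layout."""
        S = self.S
        return {
            "EL": 1.0 / S[0, 0],
            "ET": 1.0 / S[1, 1],
            "EZ": 1.0 / S[2, 2],
            "vLT": -S[1, 0] / S[0, 0],
            "GLT": 1.0 / S[5, 5],  # xy shear couples L and T
            "GLZ": 1.0 / S[4, 4],  # zx shear couples L and Z
            "GTZ": 1.0 / S[3, 3],  # yz shear couples T and Z
        }


class FEModel:
    """Assembled embedded-fiber model with cached element quadrature data."""

    def __init__(
        self,
        mesh: HexMesh,
        materials,
        fibers: list[FiberPath] | None = None,
        locator: ElementLocator | None = None,
        drop_outside: bool = False,
    ):
        """``materials`` is a single IsotropicMaterial / 6x6 stiffness array,
        or a callable ``element_id -> 6x6 stiffness`` for mixed models."""
        self.mesh = mesh
        self.fibers = list(fibers or [])
        if callable(materials):
            self._D = materials
        else:
            D = (
                elastic_matrix(materials)
                if isinstance(materials, IsotropicMaterial)
                else np.asarray(materials, dtype=float)
            )
            self._D = lambda e: D

        rule = gauss2()
        self._gauss = rule
        # cache B, detJ per element/point and the element stiffnesses
        self._Bs: list[list[tuple[np.ndarray, float]]] = []
        self._ke: list[np.ndarray] = []
        for e in range(mesh.n_elements):
            X = mesh.element_coords(e)
            D = self._D(e)
            data = []
            k = np.zeros((24, 24))
            for xi, w in zip(rule.points, rule.weights):
                B, detJ = strain_matrix(X, xi)
                data.append((B, detJ * w))
                k += (B.T @ D @ B) * (detJ * w)
            self._Bs.append(data)
            self._ke.append(0.5 * (k + k.T))

        # embed fibers; their stiffness is kept per segment so callers can
        # reassemble with a subset active (tension-only macro analysis)
        if self.fibers and locator is None:
            locator = ElementLocator(mesh)
        self.segments: list[tuple[EmbeddedSegment, float, float]] = []
        self._seg_k: list[np.ndarray] = []
        for path in self.fibers:
            for seg in segment_fibers(mesh, path, locator, drop_outside=drop_outside):
                self.segments.append((seg, path.Ef, path.area))
                X = mesh.element_coords(seg.element)
                self._seg_k.append(fiber_stiffness(seg, X, path.Ef, path.area))

        self.volume = float(mesh.volumes().sum())
        self.K_matrix = self._assemble_matrix()
        self.K = self.K_matrix + self.fiber_stiffness_matrix()

    def _assemble_matrix(self) -> sp.csr_matrix:
        ndof = 3 * self.mesh.n_nodes
        nel = self.mesh.n_elements
        rows = np.empty(nel * 576, dtype=np.int64)
        cols = np.empty(nel * 576, dtype=np.int64)
        vals = np.empty(nel * 576)
        for e in range(nel):
            dofs = (3 * self.mesh.elements[e][:, None] + np.arange(3)).ravel()
            rows[e * 576 : (e + 1) * 576] = np.repeat(dofs, 24)
            cols[e * 576 : (e + 1) * 576] = np.tile(dofs, 24)
            vals[e * 576 : (e + 1) * 576] = self._ke[e].ravel()
        K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
        return 0.5 * (K + K.T)

    def fiber_stiffness_matrix(self, active=None) -> sp.csr_matrix:
        """Sparse stiffness of the embedded fibers (optionally a subset)."""
        ndof = 3 * self.mesh.n_nodes
        if active is None:
            active = np.ones(len(self.segments), dtype=bool)
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            return sp.csr_matrix((ndof, ndof))
        rows = np.empty(len(idx) * 576, dtype=np.int64)
        cols = np.empty(len(idx) * 576, dtype=np.int64)
        vals = np.empty(len(idx) * 576)
        for n, i in enumerate(idx):
            seg = self.segments[i][0]
            dofs = self.element_dofs(seg.element)
            rows[n * 576 : (n + 1) * 576] = np.repeat(dofs, 24)
            cols[n * 576 : (n + 1) * 576] = np.tile(dofs, 24)
            vals[n * 576 : (n + 1) * 576] = self._seg_k[i].ravel()
        K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
        return 0.5 * (K + K.T)

    def fiber_strains(self, u: np.ndarray) -> np.ndarray:
        """Mid-segment axial strain of every embedded segment under ``u``."""
        eps = np.empty(len(self.segments))
        for i, (seg, _, _) in enumerate(self.segments):
            X = self.mesh.element_coords(seg.element)
            eps[i] = fiber_strain_row(seg, X, 0.0) @ u[self.element_dofs(seg.element)]
        return eps

    def element_dofs(self, e: int) -> np.ndarray:
        return (3 * self.mesh.elements[e][:, None] + np.arange(3)).ravel()

    def average_stress(self, u: np.ndarray) -> np.ndarray:
        """Volume-averaged Voigt stress of a displacement field."""
        sig = np.zeros(6)
        for e in range(self.mesh.n_elements):
            ue = u[self.element_dofs(e)]
            D = self._D(e)
            for B, dv in self._Bs[e]:
                sig += (D @ (B @ ue)) * dv
        for seg, Ef, area in self.segments:
            ue = u[self.element_dofs(seg.element)]
            X = self.mesh.element_coords(seg.element)
            row = direction_row(seg.direction)
            for s in (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)):
                eps_f = fiber_strain_row(seg, X, s) @ ue
                sig += row * (Ef * eps_f * area * seg.h)
        return sig / self.volume


def assemble(mesh: HexMesh, materials, fibers=None) -> sp.csr_matrix:
    """Global sparse stiffness of a (possibly fiber-reinforced) mesh."""
    return FEModel(mesh, materials, fibers).K


def periodic_transform(
    mesh: HexMesh,
    periodic: tuple[bool, bool, bool] = (True, True, True),
    tol: float = 1e-8,
) -> tuple[np.ndarray, sp.csr_matrix]:
    """Master-slave reduction map for periodic faces.

    Returns ``(rep, P)`` where ``rep[i]`` is the representative (master) node
    of node i — itself unless the node lies on a periodic "max" face — and
    ``P`` the (ndof x nmaster_dof) selection matrix with ``u = P q + g`` for
    an affine offset ``g`` that depends on the macro strain.

    Raises when a max-face node has no matching min-face image, listing the
    offending nodes.
    """
    lo, hi = mesh.bbox()
    folded = mesh.nodes.copy()
    for ax in range(3):
        if periodic[ax]:
            on_max = np.abs(mesh.nodes[:, ax] - hi[ax]) < tol
            folded[on_max, ax] = lo[ax]
    tree = cKDTree(mesh.nodes)
    dist, rep = tree.query(folded)
    bad = np.nonzero(dist > tol)[0]
    if len(bad):
        raise ValueError(
            f"periodic faces are not node-matched; offending nodes {bad[:10]} "
            f"at {mesh.nodes[bad[:3]]}"
        )
    # masters are nodes that are their own representative
    masters = np.nonzero(rep == np.arange(len(rep)))[0]
    col_of = -np.ones(len(rep), dtype=np.int64)
    col_of[masters] = np.arange(len(masters))
    rows = np.arange(3 * len(rep))
    cols = (3 * col_of[rep][:, None] + np.arange(3)).ravel()
    P = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(3 * len(rep), 3 * len(masters)),
    ).tocsr()
    return rep, P


def apply_periodic_bc(
    model: FEModel,
    macro_strain,
    periodic: tuple[bool, bool, bool] = (True, True, True),
):
    """Constrained system for one macro strain: returns (K_r, f_r, P, g, free).

    ``u = P q + g`` with the slave offsets ``g = eps . (x - x_master)``; the
    reduced system is ``K_r q = f_r`` with ``K_r = P^T K P`` and
    ``f_r = -P^T K g``.  ``free`` masks out the three pinned translation
    DOFs (the master closest to the cell corner).
    """
    rep, P = periodic_transform(model.mesh, periodic)
    eps = strain_voigt_to_tensor(macro_strain)
    g = ((model.mesh.nodes - model.mesh.nodes[rep]) @ eps.T).ravel()
    Kr = (P.T @ model.K @ P).tocsc()
    fr = -P.T @ (model.K @ g)
    masters = np.nonzero(rep == np.arange(len(rep)))[0]
    lo, _ = model.mesh.bbox()
    corner = masters[np.argmin(np.linalg.norm(model.mesh.nodes[masters] - lo, axis=1))]
    pin_col = np.searchsorted(masters, corner)
    free = np.ones(Kr.shape[0], dtype=bool)
    free[3 * pin_col : 3 * pin_col + 3] = False
    return Kr, fr, P, g, free


class _PeriodicSolver:
    """Factorizes the reduced periodic system once for all six load cases."""

    def __init__(self, model: FEModel, periodic=(True, True, True)):
        self.model = model
        self.rep, self.P = periodic_transform(model.mesh, periodic)
        Kr = (self.P.T @ model.K @ self.P).tocsc()
        masters = np.nonzero(self.rep == np.arange(len(self.rep)))[0]
        lo, _ = model.mesh.bbox()
        corner = masters[
            np.argmin(np.linalg.norm(model.mesh.nodes[masters] - lo, axis=1))
        ]
        pin = np.searchsorted(masters, corner)
        self.free = np.ones(Kr.shape[0], dtype=bool)
        self.free[3 * pin : 3 * pin + 3] = False
        self._lu = spla.splu(Kr[self.free][:, self.free].tocsc())

    def solve(self, macro_strain) -> np.ndarray:
        """Full periodic displacement field for one macro strain case."""
        eps = strain_voigt_to_tensor(macro_strain)
        nodes = self.model.mesh.nodes
        g = ((nodes - nodes[self.rep]) @ eps.T).ravel()
        fr = -(self.P.T @ (self.model.K @ g))
        q = np.zeros(self.P.shape[1])
        q[self.free] = self._lu.solve(fr[self.free])
        return self.P @ q + g


def homogenize(spec: RVCSpec, model: FEModel | None = None) -> HomogenizedElasticity:
    """Effective elasticity of a periodic cell from six unit-strain cases.

    Checks the Hill energy condition (macroscopic stress:strain energy equal
    to the volume-averaged microscopic energy) to 1e-6 relative for every
    load case before returning.
    """
    if model is None:
        model = FEModel(spec.mesh, spec.matrix, spec.fibers)
    solver = _PeriodicSolver(model, spec.periodic)
    C = np.zeros((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = 1.0
        u = solver.solve(e)
        C[:, j] = model.average_stress(u)
        micro = u @ (model.K @ u) / model.volume
        macro = C[j, j]
        if abs(micro - macro) > 1e-6 * max(abs(macro), 1e-30):
            raise ArithmeticError(
                f"Hill condition violated in case {j}: micro energy density "
                f"{micro:.9g} vs macro {macro:.9g}"
            )
    return HomogenizedElasticity(C=C, label=spec.label)


def multiscale_chain(
    config=None, *, resolution: float | None = None
) -> dict[str, HomogenizedElasticity]:
    """Micro -> meso chain: homogenize the unidirectional micro cell, assign
    its axial modulus to the bundle bars of the meso cells, homogenize those.

    Returns results keyed ``micro``, ``top``, ``interior``, ``bottom``.
    """
    from .config import RunConfig
    from .geometry import build_rvc

    cfg = config or RunConfig()
    micro_spec = build_rvc("micro", cfg, resolution=resolution)
    results = {"micro": homogenize(micro_spec)}
    bundle_EL = results["micro"].engineering_constants()["EL"]
    for label in ("top", "interior", "bottom"):
        spec = build_rvc(label, cfg, bundle_axial_modulus=bundle_EL,
                         resolution=resolution)
        results[label] = homogenize(spec)
    return results
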