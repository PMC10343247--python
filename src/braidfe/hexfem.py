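"""8-node hexahedral isoparametric element kernel.

Trilinear shape functions on the parent cube [-1,1]^3, engineering-strain
Voigt ordering (x, y, z, yz, zx, xy), full 2x2x2 Gauss integration.  The
element kernel is the work-horse behind both the matrix phase of the
embedded-fiber model and all unit-cell homogenizations.

Node ordering is the standard counter-clockwise bottom face then top face:

    0 (-1,-1,-1)  1 (+1,-1,-1)  2 (+1,+1,-1)  3 (-1,+1,-1)
    4 (-1,-1,+1)  5 (+1,-1,+1)  6 (+1,+1,+1)  7 (-1,+1,+1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "XI_NODES",
    "QuadratureRule",
    "gauss2",
    "HexMesh",
    "box_mesh",
    "shape_functions",
    "trilinear_map",
    "jacobian",
    "strain_matrix",
    "elastic_matrix",
    "ElementStiffness",
    "element_stiffness",
]

#: natural coordinates of the 8 element nodes
XI_NODES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class QuadratureRule:
    """Quadrature points in the parent cube; weights sum to its volume 8."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        wts = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if pts.shape[1] != 3 or pts.shape[0] != wts.shape[0]:
            raise ValueError("points must be (n,3) with matching weights")
        if abs(wts.sum() - 8.0) > 1e-12:
            raise ValueError(f"weights must sum to 8, got {wts.sum()}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)


def gauss2() -> QuadratureRule:
    """Full 2x2x2 Gauss rule (exact for affine-geometry elements)."""
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[sx * g, sy * g, sz * g]
                    for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
    return QuadratureRule(points=pts, weights=np.ones(8))


def shape_functions(xi) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions and their natural-coordinate gradients.

    Returns ``(N, dN)`` with ``N`` of shape (8,) and ``dN`` of shape (8, 3),
    ``dN[i, a] = dN_i/dxi_a``.  Evaluation outside the parent cube is
    permitted (needed by the inverse-mapping searches of the embedded-fiber
    module); partition of unity and zero gradient-sum hold everywhere.
    """
    xi = np.asarray(xi, dtype=float)
    t = 1.0 + XI_NODES * xi  # (8, 3) of (1 + xi_i * xi)
    N = 0.125 * t[:, 0] * t[:, 1] * t[:, 2]
    dN = 0.125 * np.stack(
        [
            XI_NODES[:, 0] * t[:, 1] * t[:, 2],
            t[:, 0] * XI_NODES[:, 1] * t[:, 2],
            t[:, 0] * t[:, 1] * XI_NODES[:, 2],
        ],
        axis=1,
    )
    return N, dN


def trilinear_map(nodes: np.ndarray, xi) -> np.ndarray:
    """Physical coordinates of natural point ``xi`` in the element."""
    N, _ = shape_functions(xi)
    return N @ np.asarray(nodes, dtype=float)


def jacobian(nodes: np.ndarray, xi) -> tuple[np.ndarray, float]:
    """Jacobian J (J[a,b] = dx_b/dxi_a) and its determinant at ``xi``."""
    _, dN = shape_functions(xi)
    J = dN.T @ np.asarray(nodes, dtype=float)
    return J, float(np.linalg.det(J))


def strain_matrix(nodes: np.ndarray, xi) -> tuple[np.ndarray, float]:
    """Strain-displacement matrix B (6x24) and |J| at natural point ``xi``.

    B maps the stacked nodal displacement vector (ux0, uy0, uz0, ux1, ...)
    to engineering strain (eps_x, eps_y, eps_z, gam_yz, gam_zx, gam_xy).
    Raises on a non-positive Jacobian determinant (inverted or degenerate
    element geometry).
    """
    nodes = np.asarray(nodes, dtype=float)
    _, dN = shape_functions(xi)
    J = dN.T @ nodes
    detJ = float(np.linalg.det(J))
    if detJ <= 0.0:
        raise ValueError(
            f"non-positive Jacobian determinant {detJ:.3g} at xi={np.asarray(xi)}; "
            "element is inverted or degenerate"
        )
    dNdx = np.linalg.solve(J, dN.T).T  # (8, 3), dN_i/dx_b
    B = np.zeros((6, 24))
    for i in range(8):
        dx, dy, dz = dNdx[i]
        c = 3 * i
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c + 1] = dz
        B[3, c + 2] = dy
        B[4, c] = dz
        B[4, c + 2] = dx
        B[5, c] = dy
        B[5, c + 1] = dx
    return B, detJ


def elastic_matrix(mat) -> np.ndarray:
    """Isotropic elasticity matrix D (6x6, MPa) in engineering Voigt form.

    D = E(1-v)/((1+v)(1-2v)) * [[1, v/(1-v), v/(1-v); ...], diag (1-2v)/(2(1-v))].
    Raises for v -> 0.5 (incompressible limit, singular prefactor).
    """
    E, v = mat.E, mat.v
    if abs(1.0 - 2.0 * v) < 1e-12:
        raise ValueError("v = 0.5 (incompressible) makes the elastic matrix singular")
    c = E * (1.0 - v) / ((1.0 + v) * (1.0 - 2.0 * v))
    off = v / (1.0 - v)
    shear = (1.0 - 2.0 * v) / (2.0 * (1.0 - v))
    D = np.zeros((6, 6))
    D[:3, :3] = off
    np.fill_diagonal(D[:3, :3], 1.0)
    D[3, 3] = D[4, 4] = D[5, 5] = shear
    return c * D


@dataclass(frozen=True)
class ElementStiffness:
    """24x24 element stiffness (N/mm) tagged with its element id."""

    k: np.ndarray
    element_id: int = 0

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        if k.shape != (24, 24):
            raise ValueError("element stiffness must be 24x24")
        scale = np.abs(k).max()
        if scale > 0 and np.abs(k - k.T).max() > 1e-9 * scale:
            raise ValueError("element stiffness is not symmetric")
        object.__setattr__(self, "k", k)


def element_stiffness(
    nodes: np.ndarray,
    D: np.ndarray,
    element_id: int = 0,
    rule: QuadratureRule | None = None,
) -> ElementStiffness:
    """Element stiffness k = sum_g B^T D B |J| w over the Gauss rule.

    ``D`` may be any symmetric 6x6 material matrix (isotropic matrix phase
    or a homogenized anisotropic stiffness in the macro model).
    """
    if rule is None:
        rule = gauss2()
    k = np.zeros((24, 24))
    for xi, w in zip(rule.points, rule.weights):
        B, detJ = strain_matrix(nodes, xi)
        k += (B.T @ D @ B) * (detJ * w)
    k = 0.5 * (k + k.T)  # remove round-off asymmetry
    return ElementStiffness(k=k, element_id=element_id)


class HexMesh:
    """8-node hexahedral mesh: node coordinates (mm) and 0-based connectivity.

    Parameters
    ----------
    nodes : (n, 3) float array of coordinates.
    elements : (m, 8) int array of node indices, in the module's node order.
    check : validate connectivity bounds and (for meshes below 20k nodes)
        absence of duplicate nodes within 1e-9 mm.
    """

    def __init__(self, nodes, elements, check: bool = True):
        self.nodes = np.asarray(nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(elements, dtype=np.int64).reshape(-1, 8)
        if check:
            self._validate()

    def _validate(self) -> None:
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references missing nodes")
        if len(self.nodes) <= 20000:
            from scipy.spatial import cKDTree

            pairs = cKDTree(self.nodes).query_pairs(1e-9)
            if pairs:
                raise ValueError(f"duplicate nodes within 1e-9 mm: {sorted(pairs)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self, e: int) -> np.ndarray:
        return self.nodes[self.elements[e]]

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    def volumes(self, rule: QuadratureRule | None = None) -> np.ndarray:
        """Per-element volume by Gauss integration of |J|."""
        if rule is None:
            rule = gauss2()
        vols = np.empty(self.n_elements)
        for e in range(self.n_elements):
            X = self.element_coords(e)
            vols[e] = sum(jacobian(X, xi)[1] * w
                          for xi, w in zip(rule.points, rule.weights))
        return vols

    def check_jacobians(self, rule: QuadratureRule | None = None) -> None:
        """Raise if any element has a non-positive |J| at a quadrature point."""
        if rule is None:
            rule = gauss2()
        for e in range(self.n_elements):
            X = self.element_coords(e)
            for xi in rule.points:
                _, detJ = jacobian(X, xi)
                if detJ <= 0:
                    raise ValueError(
                        f"element {e} has non-positive Jacobian ({detJ:.3g})"
                    )


def box_mesh(
    lengths=(1.0, 1.0, 1.0),
    divisions=(1, 1, 1),
    origin=(0.0, 0.0, 0.0),
) -> HexMesh:
    """Structured hexahedral mesh of an axis-aligned box."""
    lengths = np.asarray(lengths, dtype=float)
    nx, ny, nz = (int(d) for d in divisions)
    xs = [np.linspace(o, o + L, n + 1)
          for o, L, n in zip(origin, lengths, (nx, ny, nz))]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return HexMesh(nodes, np.array(elems, dtype=np.int64))
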