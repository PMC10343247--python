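"""Linear-elastic constituent and fiber-bundle material models.

Two material symmetries are needed for a braided fiber/matrix composite:
the isotropic matrix (polycarbonate polyurethane, PCU) and transversely
isotropic fibers or matrix-impregnated fiber bundles (Kevlar yarns), whose
distinguished axis is the fiber direction (axis 1 / "L").

All moduli are stored in MPa (the package-internal N-mm-MPa unit system);
helpers accept GPa at the configuration boundary only.

Voigt ordering used by the compliance matrices in this module is
(11, 22, 33, 23, 12, 13); with a transversely isotropic axis-1 material the
two axial shear slots are numerically identical, so these matrices can be
used interchangeably with the (x, y, z, yz, zx, xy) engineering ordering of
the finite-element kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsotropicMaterial",
    "TransverselyIsotropicMaterial",
    "BridgingParams",
    "shear_modulus",
]


def shear_modulus(E: float, v: float) -> float:
    """Isotropic shear modulus G = 0.5 E / (1 + v).

    Parameters
    ----------
    E : Young's modulus (any unit; the result carries the same unit).
    v : Poisson's ratio, restricted to the thermodynamically stable
        open interval (-1, 0.5).
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not (-1.0 < v < 0.5):
        raise ValueError(f"Poisson's ratio must lie in (-1, 0.5), got {v}")
    return 0.5 * E / (1.0 + v)


@dataclass(frozen=True)
class IsotropicMaterial:
    """Isotropic linear-elastic solid defined by (E, v); G is derived.

    Attributes
    ----------
    E : Young's modulus, MPa.
    v : Poisson's ratio.
    """

    E: float
    v: float

    def __post_init__(self) -> None:
        shear_modulus(self.E, self.v)  # validates E and v

    @property
    def G(self) -> float:
        """Shear modulus, MPa (derived, G = 0.5 E / (1 + v))."""
        return shear_modulus(self.E, self.v)

    def compliance(self) -> np.ndarray:
        """6x6 compliance in Voigt order (11, 22, 33, 23, 12, 13), 1/MPa."""
        E, v, G = self.E, self.v, self.G
        S = np.zeros((6, 6))
        S[:3, :3] = -v / E
        np.fill_diagonal(S[:3, :3], 1.0 / E)
        S[3, 3] = S[4, 4] = S[5, 5] = 1.0 / G
        return S

    def stiffness(self) -> np.ndarray:
        """6x6 stiffness (inverse of :meth:`compliance`), MPa."""
        return np.linalg.inv(self.compliance())


@dataclass(frozen=True)
class TransverselyIsotropicMaterial:
    """Transversely isotropic solid with fiber axis along direction 1.

    Five independent constants: axial modulus ``E11``, transverse modulus
    ``E22``, axial Poisson ratio ``v12``, transverse Poisson ratio ``v23``
    and axial shear modulus ``G12``.  The transverse shear modulus is not
    independent; in the isotropic transverse plane it satisfies
    ``G23 = E22 / (2 + 2 v23)`` and is derived unless supplied explicitly,
    in which case it must agree with that identity.

    All moduli in MPa.
    """

    E11: float
    E22: float
    v12: float
    v23: float
    G12: float
    G23: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("E11", "E22", "G12"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        g23 = self.E22 / (2.0 + 2.0 * self.v23)
        if g23 <= 0:
            raise ValueError(
                f"v23={self.v23} implies non-positive transverse shear modulus"
            )
        if self.G23 is None:
            object.__setattr__(self, "G23", g23)
        elif abs(self.G23 - g23) > 1e-9 * abs(g23):
            raise ValueError(
                f"G23={self.G23} inconsistent with E22/(2+2*v23)={g23!r}"
            )

    def compliance(self) -> np.ndarray:
        """6x6 compliance in Voigt order (11, 22, 33, 23, 12, 13), 1/MPa.

        Symmetric by construction; the (1,2) and (1,3) couplings both carry
        the axial Poisson ratio v12, the (2,3) coupling carries v23.
        """
        S = np.zeros((6, 6))
        S[0, 0] = 1.0 / self.E11
        S[1, 1] = S[2, 2] = 1.0 / self.E22
        S[0, 1] = S[0, 2] = S[1, 0] = S[2, 0] = -self.v12 / self.E11
        S[1, 2] = S[2, 1] = -self.v23 / self.E22
        S[3, 3] = 1.0 / self.G23
        S[4, 4] = S[5, 5] = 1.0 / self.G12
        return S

    def stiffness(self) -> np.ndarray:
        return np.linalg.inv(self.compliance())

    @classmethod
    def from_isotropic(cls, mat: IsotropicMaterial) -> "TransverselyIsotropicMaterial":
        """Degenerate transversely isotropic view of an isotropic solid."""
        return cls(E11=mat.E, E22=mat.E, v12=mat.v, v23=mat.v, G12=mat.G)

    def engineering_constants(self) -> dict[str, float]:
        """Constants in the (EL, ET, EZ, vLT, GLT, GLZ, GTZ) table layout.

        L is the fiber axis, T and Z the two transverse directions (equal by
        transverse isotropy).  Moduli in MPa.
        """
        return {
            "EL": self.E11,
            "ET": self.E22,
            "EZ": self.E22,
            "vLT": self.v12,
            "GLT": self.G12,
            "GLZ": self.G12,
            "GTZ": self.G23,
        }


@dataclass(frozen=True)
class BridgingParams:
    """Parameters of the bridging micromechanics model.

    Attributes
    ----------
    Vf : fiber volume fraction of the impregnated bundle, in (0, 1).
    alpha : bridging parameter controlling the in-plane (axial) shear
        modulus G12 of the bundle; the literature range is 0.3-0.6.
    beta : bridging parameter controlling the transverse modulus E22;
        literature range 0.3-0.6.
    """

    Vf: float
    alpha: float = 0.30
    beta: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.Vf < 1.0):
            raise ValueError(f"Vf must lie in (0, 1), got {self.Vf}")
        for name in ("alpha", "beta"):
            val = getattr(self, name)
            if not (0.0 < val < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {val}")
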