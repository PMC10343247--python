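"""Bridging-model micromechanics for matrix-impregnated fiber bundles.

The bridging model relates the volume-averaged stress in the matrix to the
volume-averaged stress in the fiber of a unidirectional composite through a
bridging matrix ``A``::

    sigma_m = A . sigma_f

from which the bundle compliance follows in closed form,

    S = (Vf * S_f + Vm * S_m A) (Vf * I + Vm * A)^-1,

with ``S_f``/``S_m`` the fiber/matrix compliances, ``Vf`` the fiber volume
fraction and ``Vm = 1 - Vf``.  The non-trivial entries of ``A`` are fixed by
classical micromechanics limits; two dimensionless bridging parameters
``beta`` and ``alpha`` interpolate the transverse-normal and axial-shear
entries between the Reuss and Voigt extremes.

Voigt ordering throughout is (11, 22, 33, 23, 12, 13), so slot 4 is the
transverse shear and slots 5-6 the axial shears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .materials import (
    BridgingParams,
    IsotropicMaterial,
    TransverselyIsotropicMaterial,
)

__all__ = [
    "BridgingMatrix",
    "bridging_matrix",
    "bundle_compliance",
    "bundle_constants",
    "backsolve_params",
]

#: relative tolerance on the rule-of-mixtures identity for the axial modulus
_ROM_RTOL = 1e-3


@dataclass(frozen=True)
class BridgingMatrix:
    """6x6 bridging matrix ``A`` mapping average fiber stress to matrix stress."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (6, 6):
            raise ValueError("bridging matrix must be 6x6")
        object.__setattr__(self, "A", A)

    # named entries, mirroring the conventional a_ij notation
    @property
    def a11(self) -> float:
        return self.A[0, 0]

    @property
    def a12(self) -> float:
        return self.A[0, 1]

    @property
    def a22(self) -> float:
        return self.A[1, 1]

    @property
    def a55(self) -> float:
        return self.A[4, 4]

    @property
    def a66(self) -> float:
        return self.A[5, 5]


def bridging_matrix(
    fiber: TransverselyIsotropicMaterial,
    matrix: IsotropicMaterial,
    params: BridgingParams,
) -> BridgingMatrix:
    """Assemble the bridging matrix ``A`` for a fiber/matrix pair.

    Entries:

    * ``a11 = Em / E11f`` — axial entry, the Reuss (iso-stress is exact in
      the axial direction only for the *matrix* average; this choice makes
      the axial modulus reproduce the rule of mixtures exactly);
    * ``a22 = a33 = a44 = beta + (1 - beta) Em / E22f`` — transverse normal
      and transverse shear entries, interpolated by ``beta``;
    * ``a55 = a66 = alpha + (1 - alpha) Gm / G12f`` — axial shear entries,
      interpolated by ``alpha``;
    * ``a12 = a13 = (S12f - S12m) / (S11f - S11m) * (a11 - a22)`` — the
      coupling required for the bundle compliance to stay symmetric to
      leading order; remaining off-diagonals vanish.
    """
    Em, vm, Gm = matrix.E, matrix.v, matrix.G
    a11 = Em / fiber.E11
    a22 = params.beta + (1.0 - params.beta) * Em / fiber.E22
    a55 = params.alpha + (1.0 - params.alpha) * Gm / fiber.G12

    S11f, S12f = 1.0 / fiber.E11, -fiber.v12 / fiber.E11
    S11m, S12m = 1.0 / Em, -vm / Em
    if abs(S11f - S11m) < 1e-15 * abs(S11m):
        a12 = 0.0  # identical axial compliances: no normal coupling needed
    else:
        a12 = (S12f - S12m) / (S11f - S11m) * (a11 - a22)

    A = np.zeros((6, 6))
    A[0, 0] = a11
    A[1, 1] = A[2, 2] = A[3, 3] = a22
    A[4, 4] = A[5, 5] = a55
    A[0, 1] = A[0, 2] = a12
    return BridgingMatrix(A)


def bundle_compliance(
    fiber: TransverselyIsotropicMaterial,
    matrix: IsotropicMaterial,
    params: BridgingParams,
    *,
    coupled: bool = False,
) -> np.ndarray:
    """Symmetrized 6x6 bundle compliance from the bridging closed form.

    By default each Voigt mode is homogenized by its own diagonal entry of
    the bridging matrix (the per-mode closed forms of the bridging model)::

        S_kk = (Vf S_kk^f + Vm a_kk S_kk^m) / (Vf + Vm a_kk)

    with the axial Poisson ratio following the rule of mixtures
    ``v12 = Vf v12f + Vm vm`` (an identity of the bridging model) and the
    transverse Poisson ratio fixed by transverse isotropy,
    ``v23 = E22/(2 G23) - 1``, so that the transverse-shear mode and the
    transverse plane stay mutually consistent.

    With ``coupled=True`` the full matrix product
    ``(Vf S_f + Vm S_m A)(Vf I + Vm A)^-1`` including the normal-coupling
    entry ``a12`` is evaluated instead and symmetrized as ``(S + S^T)/2``.
    The coupling stiffens the transverse normal response noticeably for
    extreme fiber/matrix contrast; the per-mode form is the package default
    because it matches the published closed-form expressions for each
    engineering constant.
    """
    Vf, Vm = params.Vf, 1.0 - params.Vf
    bm = bridging_matrix(fiber, matrix, params)
    A = bm.A
    M = Vf * np.eye(6) + Vm * A
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(Vf I + Vm A) is ill-conditioned (cond={cond:.3g}); "
            "bridging parameter set is degenerate"
        )
    if coupled:
        S = (Vf * fiber.compliance() + Vm * matrix.compliance() @ A) @ np.linalg.inv(M)
        return 0.5 * (S + S.T)

    Sf, Sm = fiber.compliance(), matrix.compliance()

    def mode(k: int) -> float:
        a = A[k, k]
        return (Vf * Sf[k, k] + Vm * a * Sm[k, k]) / (Vf + Vm * a)

    S = np.zeros((6, 6))
    S[0, 0] = mode(0)
    S[1, 1] = S[2, 2] = mode(1)
    S[3, 3] = mode(3)  # transverse shear, bridged by a44 = a22
    S[4, 4] = S[5, 5] = mode(4)  # axial shears, bridged by a55 = a66

    v12 = Vf * fiber.v12 + Vm * matrix.v
    S[0, 1] = S[0, 2] = S[1, 0] = S[2, 0] = -v12 * S[0, 0]
    # transverse isotropy: G23 = E22/(2+2 v23)  =>  v23 = E22/(2 G23) - 1
    v23 = S[3, 3] / (2.0 * S[1, 1]) - 1.0
    S[1, 2] = S[2, 1] = -v23 * S[1, 1]
    return S


def bundle_constants(
    fiber: TransverselyIsotropicMaterial,
    matrix: IsotropicMaterial,
    params: BridgingParams,
    *,
    coupled: bool = False,
) -> TransverselyIsotropicMaterial:
    """Elastic constants of the matrix-impregnated bundle.

    Engineering constants are read off the symmetrized bundle compliance:
    ``E11 = 1/S11``, ``E22 = 1/S22``, ``v12 = -S12/S11``, ``v23 = -S23/S22``
    and ``G12 = 1/S55``.  The transverse shear modulus of the returned
    material follows the transverse-isotropy identity G23 = E22/(2+2 v23)
    (exactly equal to 1/S44 in the default per-mode evaluation), so every
    returned material is exactly transversely isotropic.

    The axial modulus of the bridging model satisfies the rule of mixtures
    ``E11 = Vf E11f + Vm Em`` identically; a violation beyond 0.1 % flags a
    numerically degenerate parameter set and raises.
    """
    S = bundle_compliance(fiber, matrix, params, coupled=coupled)
    E11 = 1.0 / S[0, 0]
    E22 = 1.0 / S[1, 1]
    v12 = -S[0, 1] / S[0, 0]
    v23 = -S[1, 2] / S[1, 1]
    G12 = 1.0 / S[4, 4]

    rom = params.Vf * fiber.E11 + (1.0 - params.Vf) * matrix.E
    if abs(E11 - rom) > _ROM_RTOL * rom:
        raise ArithmeticError(
            f"bridging axial modulus {E11:.6g} violates the rule-of-mixtures "
            f"identity {rom:.6g}; parameter set is ill-conditioned"
        )
    return TransverselyIsotropicMaterial(E11=E11, E22=E22, v12=v12, v23=v23, G12=G12)


def backsolve_params(
    target: TransverselyIsotropicMaterial,
    fiber: TransverselyIsotropicMaterial,
    matrix: IsotropicMaterial,
    *,
    rtol: float = 5e-3,
) -> BridgingParams:
    """Recover (Vf, beta, alpha) that reproduce a target bundle.

    ``Vf`` follows from inverting the rule of mixtures on the axial modulus;
    ``beta`` and ``alpha`` are then found by scalar root-finding so that the
    full bridging evaluation matches the target transverse modulus ``E22``
    and axial shear modulus ``G12``.  Raises ``ValueError`` when a target
    constant is not attainable for any parameter in (0, 1), reporting the
    attainable range.
    """
    lo, hi = sorted((matrix.E, fiber.E11))
    if not (lo <= target.E11 <= hi):
        raise ValueError(
            f"target E11={target.E11:.6g} outside attainable range "
            f"[{lo:.6g}, {hi:.6g}] MPa"
        )
    Vf = (target.E11 - matrix.E) / (fiber.E11 - matrix.E)
    eps = 1e-9
    Vf = min(max(Vf, eps), 1.0 - eps)

    def _solve(name: str, extract, target_val: float) -> float:
        def f(p: float) -> float:
            kw = {"Vf": Vf, "alpha": 0.5, "beta": 0.5}
            kw[name] = p
            return extract(bundle_constants(fiber, matrix, BridgingParams(**kw))) - target_val

        a, b = 1e-6, 1.0 - 1e-6
        fa, fb = f(a), f(b)
        # degenerate targets (e.g. Vf -> 0) make both endpoints near-roots
        if abs(fa) < 1e-9 * abs(target_val):
            return a
        if abs(fb) < 1e-9 * abs(target_val):
            return b
        if fa * fb > 0:
            lo_v = min(fa, fb) + target_val
            hi_v = max(fa, fb) + target_val
            raise ValueError(
                f"no {name} in (0,1) attains the target (attainable range "
                f"[{lo_v:.6g}, {hi_v:.6g}] MPa at Vf={Vf:.4f})"
            )
        return optimize.brentq(f, a, b, xtol=1e-12, rtol=1e-14)

    beta = _solve("beta", lambda m: m.E22, target.E22)
    alpha = _solve("alpha", lambda m: m.G12, target.G12)
    params = BridgingParams(Vf=Vf, alpha=alpha, beta=beta)

    check = bundle_constants(fiber, matrix, params)
    for attr in ("E11", "E22", "G12"):
        t, c = getattr(target, attr), getattr(check, attr)
        if abs(c - t) > rtol * abs(t):
            raise ValueError(
                f"back-solved parameters reproduce {attr}={c:.6g}, "
                f"target {t:.6g} (beyond {rtol:.1%})"
            )
    return params
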