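"""Constitutive laws for passive myocardium and active fibre tension.

Passive tissue: transversely isotropic hyperelastic energy

    W = sum_{i=1..3} a_i (I1bar - 3)^i + b1 (I4 - 1)^2 + b2 (I4 - 1)^4
        + kappa/2 (J - 1)^2

with I1bar = J^(-2/3) I1 the isochoric first invariant and I4 = a0.C.a0 the
squared fibre stretch.  Near-incompressibility is enforced by the quadratic
volumetric penalty (kappa >> a1), so |J - 1| stays well below 1% at
physiological stress levels.  The published coefficients were identified
from quasi-static biaxial tests; a scalar rate factor (default 6) scales
all of a1..a3, b1, b2 to account for the stiffer response at heart-beat
strain rates.

Active fibres: a uniaxial Cauchy stress - logarithmic elastic strain law

    sigma = E0 * exp(eps) * (exp(eps) - 1)    for eps > 0, else 0

with E0 = 200 kPa, acting only in tension (zero compression stiffness).
The fibres occupy a volume fraction (default 0.8) of each element and
contribute sigma * vf * (f x f) to the total Cauchy stress, f being the
deformed unit fibre direction.

All kernels accept complex-valued deformation gradients so that consistent
tangents can be obtained by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

_I3 = np.eye(3)


@dataclass(frozen=True)
class PassiveParams:
    """Passive hyperelastic coefficients (kPa) and penalty bulk modulus."""

    a1: float = 0.347
    a2: float = 13.438
    a3: float = 48.846
    b1: float = 0.436
    b2: float = 27.692
    rate_factor: float = 6.0
    kappa: float = 1000.0

    def validate(self) -> None:
        if min(self.a1, self.a2, self.a3, self.b1, self.b2) < 0:
            raise ValueError("passive coefficients must be non-negative")
        if self.rate_factor <= 0:
            raise ValueError("rate_factor must be positive")


@dataclass(frozen=True)
class ActiveParams:
    """Active fibre law: initial modulus E0 (kPa) and fibre volume fraction."""

    E0: float = 200.0
    fibre_volume_fraction: float = 0.8

    def validate(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if not 0.0 < self.fibre_volume_fraction <= 1.0:
            raise ValueError("fibre volume fraction must be in (0, 1]")


def apply_rate_factor(params: PassiveParams) -> PassiveParams:
    """Scale a1..a3, b1, b2 by the rate factor (kappa unchanged).

    The returned parameters carry ``rate_factor = 1`` so the scaling cannot
    be applied twice by accident.
    """
    f = params.rate_factor
    return replace(params, a1=params.a1 * f, a2=params.a2 * f, a3=params.a3 * f,
                   b1=params.b1 * f, b2=params.b2 * f, rate_factor=1.0)


# -- invariant-level energy --------------------------------------------------

def passive_energy(I1, I4, params: PassiveParams):
    """Strain-energy density (kPa) as a function of the invariants.

    This is the incompressible (J = 1) form used for biaxial fitting and
    hand checks; the 3D kernels add the volumetric penalty.
    """
    I1 = np.asarray(I1, dtype=float)
    I4 = np.asarray(I4, dtype=float)
    if not (np.all(np.isfinite(I1)) and np.all(np.isfinite(I4))):
        raise ValueError("non-finite invariants")
    e1 = I1 - 3.0
    e4 = I4 - 1.0
    W = (params.a1 * e1 + params.a2 * e1**2 + params.a3 * e1**3
         + params.b1 * e4**2 + params.b2 * e4**4)
    return W


def active_fibre_stress(eps, params: ActiveParams):
    """Uniaxial active Cauchy stress (kPa) at logarithmic elastic strain eps.

    Tension-only: zero for eps <= 0, with slope E0 at eps -> 0+.
    """
    eps = np.asarray(eps)
    ex = np.exp(eps)
    sig = params.E0 * ex * (ex - 1.0)
    return np.where(np.real(eps) > 0.0, sig, np.zeros_like(sig))


# -- 3D tensor kernels -------------------------------------------------------

def det3(A):
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def inv3(A, det=None):
    if det is None:
        det = det3(A)
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    inv[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    inv[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    inv[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    inv[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    inv[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    inv[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    inv[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    inv[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return inv / det[..., None, None]


def strain_energy_density(F, a0, params: PassiveParams):
    """Full passive energy (kPa) at deformation gradient F, fibre a0.

    Isochoric isotropic part + fibre part on the full I4 + volumetric
    penalty.  Vectorised over leading axes of F; a0 broadcasts.
    """
    F = np.asarray(F)
    a0 = np.asarray(a0)
    C = np.einsum("...ki,...kj->...ij", F, F)
    J = det3(F)
    I1 = np.einsum("...ii->...", C)
    I1b = J ** (-2.0 / 3.0) * I1
    I4 = np.einsum("...i,...ij,...j->...", a0, C, a0)
    e1 = I1b - 3.0
    e4 = I4 - 1.0
    W = (params.a1 * e1 + params.a2 * e1**2 + params.a3 * e1**3
         + params.b1 * e4**2 + params.b2 * e4**4
         + 0.5 * params.kappa * (J - 1.0) ** 2)
    return W


def _pk2_passive_parts(F, a0, params: PassiveParams, volumetric: bool):
    C = np.swapaxes(F, -1, -2) @ F
    J = det3(F)
    if np.any(np.real(J) <= 0):
        raise ValueError("non-positive Jacobian in deformation state")
    Cinv = inv3(C, det=J * J)
    I1 = C[..., 0, 0] + C[..., 1, 1] + C[..., 2, 2]
    Jm23 = J ** (-2.0 / 3.0)
    I1b = Jm23 * I1
    Ca = C @ a0[..., None]                                     # (...,3,1)
    I4 = (a0[..., None, :] @ Ca)[..., 0, 0]
    e1 = I1b - 3.0
    W1 = params.a1 + 2.0 * params.a2 * e1 + 3.0 * params.a3 * e1**2
    W4 = 2.0 * params.b1 * (I4 - 1.0) + 4.0 * params.b2 * (I4 - 1.0) ** 3
    A0 = a0[..., :, None] * a0[..., None, :]
    eye = np.broadcast_to(_I3, C.shape)
    S = 2.0 * (W1 * Jm23)[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    S = S + 2.0 * W4[..., None, None] * A0
    if volumetric:
        S = S + (params.kappa * (J - 1.0) * J)[..., None, None] * Cinv
    return S, J


def pk1_passive_deviatoric(F, a0, params: PassiveParams):
    """First Piola stress of the isochoric + fibre passive parts (no penalty)."""
    S, _ = _pk2_passive_parts(F, a0, params, volumetric=False)
    return F @ S


def pk1_volumetric(F, params: PassiveParams):
    """First Piola stress of the volumetric penalty kappa/2 (J-1)^2."""
    J = det3(F)
    if np.any(np.real(J) <= 0):
        raise ValueError("non-positive Jacobian in deformation state")
    Finv = inv3(F, det=J)
    FinvT = np.swapaxes(Finv, -1, -2)
    return (params.kappa * (J - 1.0) * J)[..., None, None] * FinvT


def pk1_active(F, a0, active: ActiveParams, eps_active, eps_ref=0.0, enabled=True):
    """First Piola stress of the embedded contracting fibres.

    ``eps_active`` is the prescribed contraction strain (<= 0 once the
    element is shortening); ``eps_ref`` the fibre log-stretch at end
    diastole, from which the elastic strain is measured; ``enabled``
    broadcasts a per-element activation mask.
    """
    F = np.asarray(F)
    Fa = (F @ a0[..., None])[..., 0]
    I4 = np.sum(Fa * Fa, axis=-1)
    eps_e = 0.5 * np.log(I4) - eps_ref - eps_active
    ex = np.exp(eps_e)
    sig = active.E0 * ex * (ex - 1.0)
    active_mask = np.real(eps_e) > 0.0
    if enabled is not True:
        active_mask = active_mask & enabled
    sig = np.where(active_mask, sig, np.zeros_like(sig))
    sig = sig * active.fibre_volume_fraction
    # Cauchy sigma * (f x f) with f = Fa/lam; P = J sigma F^-T
    # J sigma_ij Finv_Jj = sig/I4 * Fa_i Fa_j * J * Finv_Jj
    J = det3(F)
    Finv = inv3(F, det=J)
    ff = (Fa[..., :, None] * Fa[..., None, :]) * (sig / I4)[..., None, None]
    return J[..., None, None] * (ff @ np.swapaxes(Finv, -1, -2))


def passive_stress(F, a0, params: PassiveParams):
    """Total passive Cauchy stress (kPa) at deformation gradient F.

    Includes isochoric, fibre and volumetric-penalty contributions; zero at
    the identity; symmetric.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    S, J = _pk2_passive_parts(F, a0, params, volumetric=True)
    P = np.einsum("...iK,...KJ->...iJ", F, S)
    sig = np.einsum("...iJ,...kJ->...ik", P, F) / J[..., None, None]
    return sig


def cauchy_total(F, a0, passive: PassiveParams, active: ActiveParams,
                 eps_active, eps_ref, enabled=True):
    """Total Cauchy stress (passive + embedded active fibres)."""
    sig = passive_stress(F, a0, passive)
    J = det3(F)
    P_act = pk1_active(F, a0, active, eps_active, eps_ref, enabled)
    sig = sig + np.einsum("...iJ,...kJ->...ik", P_act, F) / J[..., None, None]
    return sig


def fibre_cauchy_stress(F, a0, passive: PassiveParams, active: ActiveParams,
                        eps_active, eps_ref, enabled=True):
    """Cauchy stress resolved along the deformed fibre direction f.sigma.f."""
    sig = cauchy_total(F, a0, passive, active, eps_active, eps_ref, enabled)
    Fa = np.einsum("...iJ,...J->...i", np.asarray(F, float), a0)
    f = Fa / np.linalg.norm(Fa, axis=-1, keepdims=True)
    return np.einsum("...i,...ij,...j->...", f, sig, f)
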