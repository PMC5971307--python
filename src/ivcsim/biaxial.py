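"""Synthetic biaxial testing of passive myocardium and parameter recovery.

Stands in for the published biaxial stress-stretch records used to identify
the passive constitutive parameters.  A planar myocardial sheet with the
fibre direction in-plane is loaded along equibiaxial and off-biaxial
stretch paths; exact incompressibility fixes the thickness stretch at
lambda_t = 1/(lambda_f * lambda_c) and the traction-free thickness
direction eliminates the hydrostatic pressure, giving the closed-form
membrane stresses

    sigma_f = 2 W1 (lambda_f^2 - lambda_t^2) + 2 W4 lambda_f^2
    sigma_c = 2 W1 (lambda_c^2 - lambda_t^2)

with W1 = dW/dI1 and W4 = dW/dI4 of the incompressible energy.  Gaussian
noise of a configurable standard deviation is added to the stresses; the
coefficients are then recovered by bounded nonlinear least squares.

The generator's defaults emulate a typical biaxial protocol: five stretch
ratios (1:1, 1:0.75, 0.75:1, 1:0.5, 0.5:1), stretches up to 1.10, 20 samples
per path and 0.1 kPa stress noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .materials import PassiveParams

DEFAULT_RATIOS = ((1.0, 1.0), (1.0, 0.75), (0.75, 1.0), (1.0, 0.5), (0.5, 1.0))


@dataclass(frozen=True)
class BiaxialProtocol:
    """Loading paths of a planar biaxial test."""

    ratios: tuple = DEFAULT_RATIOS       # (r_fibre, r_cross) per path
    samples_per_path: int = 20
    max_stretch: float = 1.10
    noise_sd: float = 0.1                # kPa, additive on both stresses
    seed: int = 0

    def validate(self):
        if self.samples_per_path < 5:
            raise ValueError("need at least 5 samples per path")
        if self.max_stretch <= 1.0:
            raise ValueError("max_stretch must exceed 1")


@dataclass
class BiaxialDataset:
    lam_fibre: np.ndarray
    lam_cross: np.ndarray
    sigma_fibre: np.ndarray    # kPa
    sigma_cross: np.ndarray    # kPa
    true_params: PassiveParams | None = None
    protocol: BiaxialProtocol | None = None


def _dW(I1, I4, p: PassiveParams):
    e1 = I1 - 3.0
    W1 = p.a1 + 2.0 * p.a2 * e1 + 3.0 * p.a3 * e1**2
    W4 = 2.0 * p.b1 * (I4 - 1.0) + 4.0 * p.b2 * (I4 - 1.0) ** 3
    return W1, W4


def biaxial_stress_closed_form(lam_fibre, lam_cross, params: PassiveParams):
    """Cauchy stresses (sigma_fibre, sigma_cross) in kPa for an
    incompressible planar-biaxial state with the fibre in-plane."""
    lf = np.asarray(lam_fibre, float)
    lc = np.asarray(lam_cross, float)
    if np.any(lf <= 0) or np.any(lc <= 0):
        raise ValueError("stretches must be positive")
    lt2 = 1.0 / (lf * lc) ** 2
    I1 = lf**2 + lc**2 + lt2
    I4 = lf**2
    W1, W4 = _dW(I1, I4, params)
    sig_f = 2.0 * W1 * (lf**2 - lt2) + 2.0 * W4 * lf**2
    sig_c = 2.0 * W1 * (lc**2 - lt2)
    return sig_f, sig_c


def generate_biaxial_dataset(protocol: BiaxialProtocol = BiaxialProtocol(),
                             params: PassiveParams = PassiveParams()) -> BiaxialDataset:
    """Evaluate the closed form along every path and add Gaussian noise."""
    protocol.validate()
    rng = np.random.default_rng(protocol.seed)
    lf_all, lc_all = [], []
    for rf, rc in protocol.ratios:
        s = np.linspace(0.0, 1.0, protocol.samples_per_path)
        amp = protocol.max_stretch - 1.0
        lf_all.append(1.0 + amp * rf * s)
        lc_all.append(1.0 + amp * rc * s)
    lf = np.concatenate(lf_all)
    lc = np.concatenate(lc_all)
    sf, sc = biaxial_stress_closed_form(lf, lc, params)
    if protocol.noise_sd > 0:
        sf = sf + rng.normal(0.0, protocol.noise_sd, sf.shape)
        sc = sc + rng.normal(0.0, protocol.noise_sd, sc.shape)
    return BiaxialDataset(lam_fibre=lf, lam_cross=lc, sigma_fibre=sf,
                          sigma_cross=sc, true_params=params, protocol=protocol)


@dataclass
class FitResult:
    params: PassiveParams
    residual: float                       # sum of squared stress residuals
    recovery_error: dict | None = None    # per-parameter relative error
    bounds_active: bool = False


def fit_passive_params(data: BiaxialDataset,
                       init: PassiveParams | None = None) -> FitResult:
    """Recover (a1, a2, a3, b1, b2) from a biaxial dataset.

    Bounded (non-negative) nonlinear least squares on the stacked fibre and
    cross-fibre stress residuals.  Raises if the fibre direction carries no
    stretch signal (b-parameters unidentifiable) or the optimiser fails.
    """
    if data.lam_fibre.size < 10:
        raise ValueError("need at least 10 records")
    if len({(round(f, 6), round(c, 6))
            for f, c in zip(data.lam_fibre[::1], data.lam_cross[::1])}) < 2:
        raise ValueError("need at least 2 distinct loading states")
    if np.max(data.lam_fibre) <= 1.0 + 1e-9:
        raise ValueError(
            "fibre direction never stretched beyond 1: b1, b2 are unidentifiable")
    init = init or PassiveParams()
    x0 = np.array([init.a1, init.a2, init.a3, init.b1, init.b2], float)

    def resid(x):
        p = replace(init, a1=x[0], a2=x[1], a3=x[2], b1=x[3], b2=x[4])
        sf, sc = biaxial_stress_closed_form(data.lam_fibre, data.lam_cross, p)
        return np.concatenate([sf - data.sigma_fibre, sc - data.sigma_cross])

    sol = least_squares(resid, x0, bounds=(0.0, np.inf), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale="jac")
    if not sol.success:
        raise RuntimeError(f"least-squares fit failed: {sol.message}")
    fitted = replace(init, a1=sol.x[0], a2=sol.x[1], a3=sol.x[2],
                     b1=sol.x[3], b2=sol.x[4])
    recovery = None
    if data.true_params is not None:
        recovery = {}
        for name in ("a1", "a2", "a3", "b1", "b2"):
            truth = getattr(data.true_params, name)
            est = getattr(fitted, name)
            recovery[name] = abs(est - truth) / abs(truth) if truth != 0 else abs(est)
    bounds_active = bool(np.any(sol.x < 1e-12))
    return FitResult(params=fitted, residual=float(2.0 * sol.cost),
                     recovery_error=recovery, bounds_active=bounds_active)
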