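"""Quasi-static nonlinear solver: passive filling and isovolumic contraction.

The filling phase inflates the (unloaded) ventricle to the end-diastolic
pressure with the contractile fibres switched off, using incremental
follower-pressure substeps and Newton iteration.

The isovolumic phase marches time in fixed steps.  At each step the cavity
volume is constrained to its end-diastolic value; the cavity pressure is
the Lagrange multiplier of that scalar constraint and is solved together
with the displacements in a bordered Newton system

    [ K      -g ] [du]   [ -(f_int - p g) ]
    [ g^T     0 ] [dp] = [  V_ED - V(u)   ]

where g = dV/du is simultaneously the follower pressure-load direction (the
nodal load of an enclosed fluid at pressure p is exactly p dV/du) and K
includes the load stiffness -p d2V/du2.  This is mechanically equivalent to
enclosing the cavity with incompressible hydrostatic fluid elements.

Inertia and viscosity are neglected (quasi-static, with the passive
rate-stiffening folded into the material constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .activation import ActivationSchedule
from .fem import CavityFunctional, FEModel
from .geometry import LVMesh, ML_PER_MM3
from .materials import ActiveParams, PassiveParams

KPA_TO_MMHG = 7.50062


class NewtonError(RuntimeError):
    """Raised when the Newton loop fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class SolverConfig:
    dt: float = 1.0                   # ms
    newton_tol: float = 1e-6          # relative residual
    max_newton: int = 30
    filling_substeps: int = 8
    volume_tol: float = 1e-8          # relative cavity-volume constraint
    max_time: float = 220.0           # ms
    p_ed: float = 1.3                 # kPa
    p_stop: float = 10.7              # kPa
    strain_cap: float = 0.25


@dataclass
class MechanicalState:
    u: np.ndarray                     # (N,3) displacement, mm
    pressure: float                   # kPa
    volume: float                     # ml
    time: float = 0.0                 # ms


@dataclass
class PressureTrace:
    time: np.ndarray                  # ms
    pressure: np.ndarray              # kPa
    volume: np.ndarray                # ml


@dataclass
class SimulationResult:
    trace: PressureTrace
    layer_stress: np.ndarray          # (T, n_layers) total fibre Cauchy stress, kPa
    layer_active_stress: np.ndarray   # (T, n_layers) active myocyte stress, kPa
    layer_fractions: np.ndarray       # (n_layers,) mean depth fraction per layer
    scenario: str = ""
    reached_p_stop: bool = True
    max_pressure: float = 0.0
    volume_drift: float = 0.0         # max |V - V_ED|/V_ED during IVC
    final_displacement: np.ndarray | None = None   # (N,3) at the last step

    def end_profile(self, active: bool = False):
        """Transmural fibre-stress profile (depth %, stress kPa) at the final
        time; ``active`` selects the myocyte (contractile) stress instead of
        the total tissue stress."""
        series = self.layer_active_stress if active else self.layer_stress
        return 100.0 * self.layer_fractions, series[-1]


class LVSimulator:
    """Couples an FE model of the wall with the cavity-volume functional."""

    def __init__(self, mesh: LVMesh, passive: PassiveParams, active: ActiveParams,
                 config: SolverConfig | None = None,
                 basal_bc: str = "fixed"):
        self.mesh = mesh
        self.config = config or SolverConfig()
        self.model = FEModel(mesh.nodes, mesh.hexes, mesh.fibres, passive, active)
        zb = mesh.dims.base_plane_height * mesh.scale_factor
        self.cavity = CavityFunctional(mesh.nodes, mesh.endo_faces, zb)
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        if basal_bc == "fixed":
            fixed[mesh.basal_nodes, :] = True
        elif basal_bc == "symmetry":
            fixed[mesh.basal_nodes, 2] = True
        else:
            raise ValueError(f"unknown basal_bc {basal_bc!r}")
        self.free = np.flatnonzero(~fixed.ravel())
        self.ndof = mesh.n_nodes * 3

    # -- Newton steps -------------------------------------------------------

    def _factor_fixed_pressure(self, u, p, with_active):
        K = self.model.stiffness(u.ravel(), with_active)
        if p != 0.0:
            K = K - p * self.cavity.hessian(u)
        return spla.splu(K[self.free][:, self.free].tocsc())

    def _newton_fixed_pressure(self, u, p, with_active):
        """Newton loop at prescribed pressure with lazy tangent refresh:
        the factorised Jacobian is reused while the residual keeps
        contracting and refreshed otherwise (exact residuals throughout)."""
        cfg = self.config
        free = self.free
        lu = None
        res_prev = np.inf
        refactors = 0
        for it in range(cfg.max_newton):
            g = self.cavity.gradient(u)
            f_int = self.model.internal_force(u.ravel(), with_active)
            Rf = (f_int - p * g)[free]
            ref = max(np.linalg.norm(f_int[free]), abs(p) * np.linalg.norm(g[free]), 1e-6)
            res = np.linalg.norm(Rf) / ref
            if res < cfg.newton_tol:
                return u, res
            if lu is None or res > 0.5 * res_prev:
                if lu is not None:
                    refactors += 1
                    if refactors > cfg.max_newton:
                        break
                lu = self._factor_fixed_pressure(u, p, with_active)
            res_prev = res
            du = lu.solve(-Rf)
            u = u.copy()
            u.ravel()[free] += du
        raise NewtonError(
            f"Newton did not converge at p={p:.4g} kPa (last residual {res:.3e})",
            residual=res)

    def solve_filling(self, p_ed: float | None = None,
                      u0: np.ndarray | None = None) -> MechanicalState:
        """Inflate the passive ventricle to end-diastolic pressure.

        Uses incremental load substeps with automatic bisection on Newton
        failure.  Contractile fibres are inactive throughout.
        """
        cfg = self.config
        p_ed = cfg.p_ed if p_ed is None else p_ed
        u = np.zeros((self.mesh.n_nodes, 3)) if u0 is None else u0.copy()
        if p_ed == 0.0:
            return MechanicalState(u=u, pressure=0.0, volume=self.cavity_volume(u))
        p = 0.0
        dp = p_ed / cfg.filling_substeps
        while p < p_ed - 1e-12:
            p_try = min(p + dp, p_ed)
            try:
                u_new, _ = self._newton_fixed_pressure(u, p_try, with_active=False)
            except NewtonError:
                dp *= 0.5
                if dp < p_ed / (64 * cfg.filling_substeps):
                    raise
                continue
            u, p = u_new, p_try
        return MechanicalState(u=u, pressure=p_ed, volume=self.cavity_volume(u))

    def cavity_volume(self, u) -> float:
        return self.cavity.volume(u) * ML_PER_MM3

    # -- isovolumic phase ---------------------------------------------------

    def _factor_isovolumic(self, u, p):
        K = self.model.stiffness(u.ravel(), with_active=True)
        K = K - p * self.cavity.hessian(u)
        gf = self.cavity.gradient(u)[self.free]
        A = sp.bmat([[K[self.free][:, self.free], -sp.csr_matrix(gf[:, None])],
                     [sp.csr_matrix(gf[None, :]), None]], format="csc")
        return spla.splu(A)

    def _newton_isovolumic(self, u, p, V_ed_mm3):
        """Bordered Newton for the volume-constrained step (modified Newton
        with lazy refactorisation; residuals are always exact)."""
        cfg = self.config
        free = self.free
        n_f = free.size
        lu = None
        res_prev = np.inf
        refactors = 0
        for it in range(cfg.max_newton):
            g = self.cavity.gradient(u)
            f_int = self.model.internal_force(u.ravel(), with_active=True)
            Rf = (f_int - p * g)[free]
            V = self.cavity.volume(u)
            rV = V - V_ed_mm3
            ref = max(np.linalg.norm(f_int[free]), abs(p) * np.linalg.norm(g[free]), 1e-6)
            res = np.linalg.norm(Rf) / ref
            if res < cfg.newton_tol and abs(rV) / V_ed_mm3 < cfg.volume_tol:
                return u, p, res
            if lu is None or res > 0.5 * res_prev:
                if lu is not None:
                    refactors += 1
                    if refactors > cfg.max_newton:
                        break
                lu = self._factor_isovolumic(u, p)
            res_prev = res
            rhs = np.concatenate([-Rf, [-rV]])
            sol = lu.solve(rhs)
            u = u.copy()
            u.ravel()[free] += sol[:n_f]
            p += sol[n_f]
        raise NewtonError(
            f"isovolumic Newton did not converge (residual {res:.3e})", residual=res)

    def solve_ivc(self, ed_state: MechanicalState, schedule: ActivationSchedule,
                  p_stop: float | None = None, record_layers: bool = True) -> SimulationResult:
        """March the isovolumic contraction from the end-diastolic state.

        Records the pressure trace on a uniform grid from t = 0 (endocardial
        depolarisation) and per-layer fibre-stress histories; terminates when
        the cavity pressure reaches ``p_stop`` (diastolic aortic pressure) or
        the maximum simulated time elapses.
        """
        cfg = self.config
        p_stop = cfg.p_stop if p_stop is None else p_stop
        dt = cfg.dt
        self.model.set_ed_reference(ed_state.u.ravel())
        V_ed = self.cavity.volume(ed_state.u)

        layer_ids = np.arange(1, self.mesh.n_layers + 1)
        lw = [(self.mesh.layer == k) for k in layer_ids]
        vol_w = [self.mesh.elem_volumes[m] / self.mesh.elem_volumes[m].sum() for m in lw]
        layer_fracs = np.array([self.mesh.depth_fraction[m].mean() for m in lw])

        def layer_stress(u):
            s, sa = self.model.fibre_stress(u.ravel())
            tot = np.array([(s[m] * w).sum() for m, w in zip(lw, vol_w)])
            act = np.array([(sa[m] * w).sum() for m, w in zip(lw, vol_w)])
            return tot, act

        t_first = float(np.min(schedule.onset))
        n_pre = max(int(np.floor(t_first / dt)), 0)

        times = [0.0]
        pressures = [ed_state.pressure]
        volumes = [ed_state.volume]
        stresses, active_stresses = [], []
        if record_layers:
            s0, a0 = layer_stress(ed_state.u)
            stresses.append(s0)
            active_stresses.append(a0)
        # latent period: no element active, state unchanged
        for i in range(1, n_pre + 1):
            times.append(i * dt)
            pressures.append(ed_state.pressure)
            volumes.append(ed_state.volume)
            if record_layers:
                stresses.append(stresses[0])
                active_stresses.append(active_stresses[0])

        u, p = ed_state.u.copy(), ed_state.pressure
        u_prev = u.copy()
        p_prev = p
        reached = False
        drift = 0.0
        t = n_pre * dt
        while t < cfg.max_time - 1e-9:
            t += dt
            eps_a = schedule.contraction_strain(t, cfg.strain_cap)
            self.model.set_activation(eps_a, t >= schedule.onset)
            # linear extrapolation predictor
            u_guess = u + (u - u_prev)
            p_guess = p + (p - p_prev)
            u_prev, p_prev = u, p
            try:
                u, p, _ = self._newton_isovolumic(u_guess, p_guess, V_ed)
            except NewtonError:
                u, p, _ = self._newton_isovolumic(u_prev, p_prev, V_ed)
            V = self.cavity.volume(u)
            drift = max(drift, abs(V - V_ed) / V_ed)
            times.append(t)
            pressures.append(p)
            volumes.append(V * ML_PER_MM3)
            if record_layers:
                st, ac = layer_stress(u)
                stresses.append(st)
                active_stresses.append(ac)
            if p >= p_stop:
                reached = True
                break

        trace = PressureTrace(np.asarray(times), np.asarray(pressures),
                              np.asarray(volumes))
        return SimulationResult(
            trace=trace,
            final_displacement=u.copy(),
            layer_stress=np.asarray(stresses) if record_layers else np.zeros((0, 0)),
            layer_active_stress=(np.asarray(active_stresses) if record_layers
                                 else np.zeros((0, 0))),
            layer_fractions=layer_fracs,
            scenario=schedule.scenario.name,
            reached_p_stop=reached,
            max_pressure=float(np.max(pressures)),
            volume_drift=drift,
        )


def layer_stress_summary(result: SimulationResult):
    """Per-layer fibre-stress time series and end-time transmural profile.

    Returns ``(times, layer_stress, depth_pct, end_profile)``.
    """
    depth_pct, prof = result.end_profile()
    return result.trace.time, result.layer_stress, depth_pct, prof
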