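"""Backward-displacement recovery of the zero-pressure reference geometry.

The imaged / constructed end-diastolic (ED) geometry carries the
end-diastolic pressure, so it cannot serve as the stress-free reference.
The fixed-point iteration of the backward-displacement method updates a
candidate reference X by

    X^(k+1) = X^(k) + relaxation * (X_ED - (X^(k) + u(X^(k))))

where u(X) is the displacement obtained by inflating candidate X to the ED
pressure with the passive material.  At convergence, re-inflating the
unloaded geometry reproduces the ED nodal positions to within the
tolerance.  Layer indices and fibre directions are carried over unchanged
(directions re-normalised).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LVMesh
from .materials import ActiveParams, PassiveParams
from .solver import LVSimulator, SolverConfig


@dataclass
class UnloadingConfig:
    max_iterations: int = 25
    tolerance: float = 0.05      # mm, max nodal mismatch
    relaxation: float = 1.0

    def validate(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class UnloadingReport:
    iterations: int
    mismatch_history: list[float]
    unloaded_volume: float        # ml
    converged: bool = True


def compute_unloaded(ed_mesh: LVMesh, p_ed: float, passive: PassiveParams,
                     active: ActiveParams | None = None,
                     config: UnloadingConfig | None = None,
                     solver_config: SolverConfig | None = None):
    """Return ``(unloaded_mesh, report)`` for the given ED mesh and pressure.

    Contraction is off throughout (purely passive inflation).  Raises if the
    iteration does not reach the nodal tolerance within ``max_iterations`` or
    an iterate produces inverted elements.
    """
    config = config or UnloadingConfig()
    config.validate()
    active = active or ActiveParams()
    solver_config = solver_config or SolverConfig()
    X_ed = ed_mesh.nodes.copy()

    if p_ed == 0.0:
        from .geometry import cavity_volume
        return ed_mesh, UnloadingReport(1, [0.0], cavity_volume(ed_mesh))

    X = X_ed.copy()
    history: list[float] = []
    for it in range(1, config.max_iterations + 1):
        candidate = ed_mesh.with_nodes(X)
        try:
            sim = LVSimulator(candidate, passive, active, solver_config)
        except ValueError as exc:
            raise RuntimeError(f"unloading iterate {it} has inverted elements: {exc}")
        state = sim.solve_filling(p_ed)
        mismatch = float(np.max(np.linalg.norm(X + state.u - X_ed, axis=1)))
        history.append(mismatch)
        if mismatch <= config.tolerance:
            from .geometry import cavity_volume
            unloaded = ed_mesh.with_nodes(X)
            return unloaded, UnloadingReport(it, history, cavity_volume(unloaded))
        X = X + config.relaxation * (X_ed - (X + state.u))
    raise RuntimeError(
        f"backward-displacement iteration did not converge in "
        f"{config.max_iterations} iterations (last mismatch {history[-1]:.4f} mm)")
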