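"""Low-level finite-element machinery.

Total-Lagrangian formulation on 8-node trilinear hexahedra with selective
reduced integration: the isochoric passive stress and the active fibre
stress are integrated at the full 2x2x2 Gauss rule, the volumetric penalty
at the element centre only (standard cure for volumetric locking of
near-incompressible trilinear bricks).

Consistent tangent stiffness is obtained by complex-step differentiation of
the element internal-force vector with respect to its 24 nodal dofs, batched
over a leading perturbation axis — exact to machine precision and valid for
any element-level nonlinearity (including the tension-only active law away
from its kink).

The cavity is handled as a scalar functional V(u): volume enclosed by the
deformed endocardial surface plus the fixed basal cap.  Its gradient g(u)
is the (follower) pressure load direction — for an enclosed fluid the
nodal pressure load is exactly p * dV/du — and its Hessian supplies the
load-stiffness term.  V is a cubic polynomial in the nodal coordinates, so
g comes from one complex step and H from exact central differences of g.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import HEX_GAUSS, LVMesh, hex_shape_gradients, quad_shape, QUAD_GAUSS
from .materials import (ActiveParams, PassiveParams, pk1_active,
                        pk1_passive_deviatoric, pk1_volumetric)

_CS_H = 1e-30


class CavityFunctional:
    """Volume of the cavity enclosed by a quad face set + flat basal cap."""

    def __init__(self, nodes: np.ndarray, faces: np.ndarray, z_base: float = 0.0):
        self.X = np.asarray(nodes, float)
        self.faces = np.asarray(faces, np.int64)
        self.z_base = float(z_base)
        self.N, self.dN = quad_shape(QUAD_GAUSS)       # (4,4), (4,4,2)
        self.n_nodes = self.X.shape[0]
        # flat cap contribution: boundary ring is fixed, computed once
        self._cap = 0.0
        if self.z_base != 0.0:
            from .geometry import _boundary_ring
            ring = _boundary_ring(self.faces)
            xy = self.X[ring][:, :2]
            area = 0.5 * abs(np.sum(xy[:, 0] * np.roll(xy[:, 1], -1)
                                    - np.roll(xy[:, 0], -1) * xy[:, 1]))
            self._cap = self.z_base * area / 3.0

    def _vol_faces(self, xf):
        """Volume integral over faces, xf (...,Ef,4,3) possibly complex."""
        xg = np.einsum("ga,...fai->...fgi", self.N, xf)
        tg = np.einsum("gak,...fai->...fgik", self.dN, xf)
        n = np.cross(tg[..., 0], tg[..., 1], axis=-1)
        return np.einsum("...fgi,...fgi->...", xg, n) / 3.0

    def volume(self, u: np.ndarray) -> float:
        xf = (self.X + u)[self.faces]
        return float(np.real(self._vol_faces(xf))) + self._cap

    def gradient(self, u: np.ndarray) -> np.ndarray:
        """dV/du as a dense (n_nodes*3,) vector (complex step, exact)."""
        xf = (self.X + np.asarray(u, float))[self.faces]       # (Ef,4,3)
        pert = np.zeros((12, 1, 4, 3), complex)
        for d in range(12):
            pert[d, 0, d // 3, d % 3] = 1j * _CS_H
        v = self._vol_faces_per_face(xf[None, ...] + pert)      # (12, Ef)
        gf = v.imag / _CS_H                                     # (12, Ef)
        g = np.zeros(self.n_nodes * 3)
        dofs = (self.faces[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 12)
        np.add.at(g, dofs.T.reshape(12, -1).T.ravel(), gf.T.ravel())
        return g

    def _vol_faces_per_face(self, xf):
        xg = np.einsum("ga,...fai->...fgi", self.N, xf)
        tg = np.einsum("gak,...fai->...fgik", self.dN, xf)
        n = np.cross(tg[..., 0], tg[..., 1], axis=-1)
        return np.einsum("...fgi,...fgi->...f", xg, n) / 3.0

    def hessian(self, u: np.ndarray) -> sp.csr_matrix:
        """d2V/du2 as a sparse matrix; exact (V is cubic in coordinates)."""
        x = self.X + np.asarray(u, float)
        xf = x[self.faces]
        delta = 1e-2
        pert_c = np.zeros((12, 4, 3), complex)
        for d in range(12):
            pert_c[d, d // 3, d % 3] = 1j * _CS_H
        pert_r = np.zeros((12, 4, 3))
        for d in range(12):
            pert_r[d, d // 3, d % 3] = delta
        # (12c, 12r, 2sign, Ef, 4, 3)
        signs = np.array([1.0, -1.0])
        big = (xf[None, None, None] + pert_c[:, None, None, None]
               + (signs[None, None, :, None, None, None] * pert_r[None, :, None, None]))
        v = self._vol_faces_per_face(big)                       # (12,12,2,Ef)
        Hf = (v.imag[:, :, 0] - v.imag[:, :, 1]) / (_CS_H * 2 * delta)  # (12,12,Ef)
        Hf = 0.5 * (Hf + np.swapaxes(Hf, 0, 1))
        dofs = (self.faces[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(-1, 12)
        rows = np.repeat(dofs[:, :, None], 12, axis=2)          # (Ef,12,12)
        cols = np.repeat(dofs[:, None, :], 12, axis=1)
        data = np.moveaxis(Hf, 2, 0)                            # (Ef,12,12)
        n = self.n_nodes * 3
        return sp.coo_matrix((data.ravel(), (rows.ravel(), cols.ravel())),
                             shape=(n, n)).tocsr()


class FEModel:
    """Assembled quasi-static model for one reference configuration."""

    def __init__(self, nodes, hexes, fibres, passive: PassiveParams,
                 active: ActiveParams, elem_active_mask=None):
        self.X = np.asarray(nodes, float)
        self.hexes = np.asarray(hexes, np.int64)
        self.a0 = np.asarray(fibres, float)[:, None, :]          # (E,1,3) bcast gp
        self.passive = passive
        self.active = active
        E = self.hexes.shape[0]
        self.n_nodes = self.X.shape[0]
        self.ndof = self.n_nodes * 3

        dNdxi = hex_shape_gradients(HEX_GAUSS)                   # (8,8,3)
        Xe = self.X[self.hexes]                                  # (E,8,3)
        J = np.einsum("eak,gal->egkl", Xe, dNdxi)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("non-positive element Jacobian in reference mesh")
        Jinv = np.linalg.inv(J)
        self.dNdX = np.einsum("gal,eglk->egak", dNdxi, Jinv)     # (E,8gp,8a,3)
        self.wdetJ = detJ                                        # unit weights
        dNdxi_c = hex_shape_gradients(np.zeros((1, 3)))          # (1,8,3)
        Jc = np.einsum("eak,gal->egkl", Xe, dNdxi_c)[:, 0]
        detJc = np.linalg.det(Jc)
        self.dNdXc = np.einsum("gal,elk->eak", dNdxi_c, np.linalg.inv(Jc))
        self.volc = detJc * 8.0                                  # centre weight
        self.elem_volumes = detJ.sum(axis=1)

        dof = (self.hexes[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(E, 24)
        self.edof = dof
        self._rows = np.repeat(dof[:, :, None], 24, axis=2).ravel()
        self._cols = np.repeat(dof[:, None, :], 24, axis=1).ravel()

        # activation context (set per time step by the simulator)
        self.eps_active = np.zeros(E)       # prescribed contraction strain (<=0)
        self.eps_ref = np.zeros((E, 8))     # end-diastolic fibre log-stretch per gp
        self.contract_on = np.zeros(E, bool)
        if elem_active_mask is None:
            elem_active_mask = np.ones(E, bool)
        self.has_fibres = np.asarray(elem_active_mask, bool)

    # -- kinematics ---------------------------------------------------------

    def _def_grads(self, u_e):
        """F at the 8 Gauss points and at the centre; u_e (...,E,8,3)."""
        F8 = np.einsum("...eai,egaJ->...egiJ", u_e, self.dNdX)
        F8 = F8 + np.eye(3)
        Fc = np.einsum("...eai,eaJ->...eiJ", u_e, self.dNdXc)
        Fc = Fc + np.eye(3)
        return F8, Fc

    def _pk1_dev(self, F8, with_active: bool):
        """Deviatoric (isochoric + fibre passive + active) first Piola stress."""
        P8 = pk1_passive_deviatoric(F8, self.a0, self.passive)
        if with_active and np.any(self.contract_on):
            enabled = (self.contract_on & self.has_fibres)[:, None]
            P8 = P8 + pk1_active(F8, self.a0, self.active,
                                 self.eps_active[:, None],
                                 self.eps_ref, enabled)
        return P8

    def element_internal_force(self, u_e, with_active: bool):
        """Internal nodal forces (...,E,8,3) for element displacements u_e."""
        F8, Fc = self._def_grads(u_e)
        P8 = self._pk1_dev(F8, with_active)
        f = np.einsum("...egiJ,egaJ,eg->...eai", P8, self.dNdX, self.wdetJ,
                      optimize=True)
        Pc = pk1_volumetric(Fc, self.passive)
        f = f + np.einsum("...eiJ,eaJ,e->...eai", Pc, self.dNdXc, self.volc,
                          optimize=True)
        return f

    def internal_force(self, u: np.ndarray, with_active: bool = True) -> np.ndarray:
        """Assembled internal force vector (ndof,)."""
        u_e = u.reshape(self.n_nodes, 3)[self.hexes]
        f_e = self.element_internal_force(u_e, with_active)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.ravel(), np.real(f_e).reshape(-1))
        return f

    def stiffness(self, u: np.ndarray, with_active: bool = True) -> sp.csr_matrix:
        """Consistent tangent via complex-step dP/dF at each Gauss point.

        K_e[ai, bk] = sum_g w A_iJkL dN_a/dX_J dN_b/dX_L with A = dP/dF
        obtained from 9 batched complex perturbations of F.
        """
        u_e = u.reshape(self.n_nodes, 3)[self.hexes]             # (E,8,3)
        F8, Fc = self._def_grads(u_e)
        pert = (1j * _CS_H) * np.eye(9).reshape(9, 1, 1, 3, 3)
        P = self._pk1_dev(F8[None] + pert, with_active)          # (9,E,8,3,3)
        A = (P.imag / _CS_H).reshape(3, 3, *P.shape[1:])         # (k,L,E,8,i,J)
        Aw = A * self.wdetJ[None, None, :, :, None, None]
        K_e = np.einsum("kLegiJ,egaJ,egbL->eaibk", Aw, self.dNdX, self.dNdX,
                        optimize=True)
        pert_c = (1j * _CS_H) * np.eye(9).reshape(9, 1, 3, 3)
        Pc = pk1_volumetric(Fc[None] + pert_c, self.passive)     # (9,E,3,3)
        Ac = (Pc.imag / _CS_H).reshape(3, 3, *Pc.shape[1:])      # (k,L,E,i,J)
        K_e = K_e + np.einsum("kLeiJ,eaJ,ebL,e->eaibk", Ac, self.dNdXc,
                              self.dNdXc, self.volc, optimize=True)
        K = sp.coo_matrix((K_e.reshape(-1, 24, 24).ravel(),
                           (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()

    # -- state-dependent activation ----------------------------------------

    def set_ed_reference(self, u: np.ndarray) -> None:
        """Store the end-diastolic fibre log-stretch (per Gauss point)."""
        u_e = u.reshape(self.n_nodes, 3)[self.hexes]
        F8, _ = self._def_grads(u_e)
        Fa = np.einsum("egiJ,egJ->egi", F8, np.broadcast_to(self.a0, F8.shape[:2] + (3,)))
        self.eps_ref = 0.5 * np.log(np.einsum("egi,egi->eg", Fa, Fa))

    def set_activation(self, eps_active: np.ndarray, contract_on: np.ndarray) -> None:
        self.eps_active = np.asarray(eps_active, float)
        self.contract_on = np.asarray(contract_on, bool)

    # -- output -------------------------------------------------------------

    def fibre_stress(self, u: np.ndarray):
        """Per-element Cauchy stress along the deformed fibre direction.

        Returns ``(total, active)``: the tissue stress resolved on the
        deformed fibre (volume-averaged over Gauss points, volumetric part
        from the centre) and the active myocyte stress sigma_a of the
        contraction law (the tension in the contractile fibres themselves,
        zero before activation).
        """
        from .materials import det3

        u_e = u.reshape(self.n_nodes, 3)[self.hexes]
        F8, Fc = self._def_grads(u_e)
        a0 = np.broadcast_to(self.a0, F8.shape[:2] + (3,))
        P8 = pk1_passive_deviatoric(F8, self.a0, self.passive)
        if np.any(self.contract_on):
            enabled = (self.contract_on & self.has_fibres)[:, None]
            P8 = P8 + pk1_active(F8, self.a0, self.active,
                                 self.eps_active[:, None], self.eps_ref, enabled)
        J8 = det3(F8)
        sig8 = np.einsum("egiJ,egkJ->egik", P8, F8) / J8[..., None, None]
        Fa = np.einsum("egiJ,egJ->egi", F8, a0)
        f_dir = Fa / np.linalg.norm(Fa, axis=-1, keepdims=True)
        s_ff = np.einsum("egi,egik,egk->eg", f_dir, sig8, f_dir)
        w = self.wdetJ / self.wdetJ.sum(axis=1, keepdims=True)
        s_elem = np.einsum("eg,eg->e", s_ff, w)
        # volumetric (hydrostatic) part evaluated at the element centre:
        # Cauchy contribution of the penalty is kappa*(J-1)*I
        Jc = det3(Fc)
        s_elem = s_elem + self.passive.kappa * (Jc - 1.0)
        # active myocyte stress (uniaxial law evaluated at the Gauss points)
        I4 = np.einsum("egi,egi->eg", Fa, Fa)
        eps_e = 0.5 * np.log(I4) - self.eps_ref - self.eps_active[:, None]
        ex = np.exp(eps_e)
        sig_a = self.active.E0 * ex * (ex - 1.0)
        on = (self.contract_on & self.has_fibres)[:, None] & (eps_e > 0.0)
        sig_a = np.where(on, sig_a, 0.0)
        s_active = np.einsum("eg,eg->e", sig_a, w)
        return s_elem, s_active


def model_from_mesh(mesh: LVMesh, passive: PassiveParams, active: ActiveParams) -> FEModel:
    return FEModel(mesh.nodes, mesh.hexes, mesh.fibres, passive, active)
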