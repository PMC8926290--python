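"""Measurement-optimized electrostatics: the ESP natural-orbital trick.

When only monomer A is quantum, every classical piece of E1_pol can be folded
ahead of time: the A-nuclei/B interaction and the A-core/B interaction are
scalars, and the remaining active-space contribution is Tr(gamma_act W) with
W the active-MO image of monomer B's electrostatic potential. Diagonalizing
W = U w U^T turns that trace into sum_s w_s <n_s>: after rotating the state
into the ESP natural-orbital basis, the whole quantum part of the
electrostatic energy is a single commuting group of occupation-number
(Z-basis) measurements — one measurement circuit instead of one per matrix
element.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .active_space import OrbitalPartition
from .integrals import CrossIntegrals, SCFState
from .qsim import Statevector, apply_orbital_transform, _bit

__all__ = ["ESPMeasurementPlan", "build_esp_plan", "e1_pol_from_plan"]


@dataclass(frozen=True)
class ESPMeasurementPlan:
    """Diagonalized active-space ESP image plus the classical offset."""

    w_active: np.ndarray        # active-MO ESP matrix W_tt'
    eigvals: np.ndarray         # w_s, sorted nonincreasing
    eigvecs: np.ndarray         # U (columns), orthogonal, det +1
    classical_offset: float     # nuclear(A)-B plus core(A)-B energy

    def as_dict(self) -> dict:
        return {
            "eigvals": self.eigvals.tolist(),
            "classical_offset": self.classical_offset,
        }


def esp_image_ao(cross: CrossIntegrals, gamma_b_ao: np.ndarray) -> np.ndarray:
    """Monomer B's electrostatic potential in monomer A's AO basis:
    nuclear attraction by B's nuclei plus the Coulomb field of B's density."""
    return cross.v_b_on_a + np.einsum("pqrs,rs->pq", cross.eri_aabb,
                                      gamma_b_ao, optimize=True)


def build_esp_plan(cross: CrossIntegrals, part_a: OrbitalPartition,
                   scf_a: SCFState, gamma_b_ao: np.ndarray) -> ESPMeasurementPlan:
    """Fold all classical contributions and diagonalize the active-space ESP.

    Monomer B's density is fixed and classical here; its AO 1-RDM is the only
    thing needed from that side.
    """
    w_ao = esp_image_ao(cross, gamma_b_ao)
    # nuclei of A with all of B (B's nuclei and electrons)
    offset = cross.v_nn + float(np.sum(gamma_b_ao * cross.v_a_on_b))
    c_core = scf_a.mo_coeff[:, list(part_a.core)]
    d_core = 2.0 * c_core @ c_core.T
    offset += float(np.sum(d_core * w_ao))
    c_act = scf_a.mo_coeff[:, list(part_a.active)]
    w_active = c_act.T @ w_ao @ c_act
    vals, vecs = np.linalg.eigh(w_active)
    order = np.argsort(-vals, kind="stable")  # nonincreasing, index tie-break
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic signs; keep det +1 so the rotation is circuit-realizable
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, -1] = -vecs[:, -1]
    return ESPMeasurementPlan(w_active, vals, vecs, float(offset))


def occupations(sv: Statevector) -> np.ndarray:
    """Spatial-orbital occupation expectations <n_t> (diagonal Z-basis
    measurement)."""
    n = sv.n_orb
    idx = np.arange(len(sv.amplitudes))
    p2 = sv.amplitudes ** 2
    return np.array([
        float(np.sum(p2 * (_bit(idx, t) + _bit(idx, n + t)))) for t in range(n)
    ])


def e1_pol_from_plan(sv_a: Statevector, plan: ESPMeasurementPlan) -> float:
    """Electrostatic energy from one commuting measurement group: rotate the
    active state into the ESP natural-orbital basis and accumulate
    sum_s w_s <n_s> plus the classical offset."""
    n = sv_a.n_orb
    if plan.w_active.shape != (n, n):
        raise ValueError("plan dimensioned for a different active space")
    rotated = apply_orbital_transform(sv_a, plan.eigvecs.T)
    occ = occupations(rotated)
    return float(plan.eigvals @ occ) + plan.classical_offset
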