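"""Free-energy terms of the site-binding rotational-isomeric-state model.

Every term is returned in kBT units.  The total free energy of a microstate
(s, c) is

    F = F_rot + F_p + F_SR + F_LR + F_length + F_angle + F_SEV + W

with F_rot the intrinsic torsional energy of the rotatable bonds, F_p the
proton-binding term ln10 (pH - pK) sum(s_i), F_SR a chemically specific
nearest-ionizable-neighbour coupling that depends on the rotational state of
the middle bond, F_LR screened Debye-Hueckel electrostatics between all
non-adjacent ionizable pairs, harmonic bond-length and bond-angle elasticity,
a hard-sphere excluded-volume term (0 or +inf) and the mechanical work
-F r_z of a stretching force applied along the laboratory z axis.

Two charge modes are supported: *fluctuating* (constant-pH sampling, site
occupancies s_i in {0,1}) and *smeared* (constant-charge sampling, every
site carries the mean charge theta; the one-body proton term then drops out
of the sampling problem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .chain import ChainTopology, Conformation, Coordinates


class SingularityError(ValueError):
    """Two interacting point charges coincide."""


@dataclass(frozen=True)
class ElectrostaticEnvironment:
    """Aqueous 1:1 electrolyte at 298.15 K.

    ``bjerrum_length`` may be set to 0 to switch all electrostatics off
    (non-interacting-site limit).
    """

    ionic_strength: float          # M
    bjerrum_length: float = units.BJERRUM_NM   # nm
    temperature: float = units.TEMPERATURE_K   # K

    @property
    def debye_length(self) -> float:
        """kappa^-1 in nm (inf at zero ionic strength)."""
        return units.debye_length_nm(self.ionic_strength)

    @property
    def kappa(self) -> float:
        """Inverse screening length in nm^-1."""
        return units.kappa_per_nm(self.ionic_strength)


def site_charges(mode: str, *, protonation: np.ndarray | None = None,
                 theta: float | None = None, n_sites: int | None = None
                 ) -> np.ndarray:
    """Per-site charge vector: s_i (fluctuating) or theta (smeared)."""
    if mode in ("fluctuating", "sgcmc"):
        if protonation is None:
            raise ValueError("fluctuating mode needs a protonation vector")
        return np.asarray(protonation, dtype=float)
    if mode in ("smeared", "ccmc"):
        if theta is None or n_sites is None:
            raise ValueError("smeared mode needs theta and n_sites")
        if not 0.0 <= theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        return np.full(n_sites, float(theta))
    raise ValueError(f"unknown charge mode {mode!r}")


def rotational_energy(conformation: Conformation,
                      eps_rot=(0.0, 0.0, 0.0)) -> float:
    """Intrinsic torsional energy sum over rotatable bonds (kBT)."""
    eps = np.asarray(eps_rot, dtype=float)
    if eps[1] != eps[2]:
        raise ValueError("symmetric chain requires eps_rot(g+) == eps_rot(g-)")
    states = conformation.dihedral_states
    if states.size == 0:
        return 0.0
    return float(eps[states].sum())


def protonation_energy(protonation: np.ndarray, pH: float, pK: float) -> float:
    """Proton-binding free energy ln10 (pH - pK) sum(s_i) (kBT)."""
    s = np.asarray(protonation)
    return units.LN10 * (pH - pK) * float(s.sum())


def long_range_energy(charges: np.ndarray, site_positions: np.ndarray,
                      env: ElectrostaticEnvironment) -> float:
    """Screened-Coulomb energy over ionizable pairs (i, j) with j >= i + 2.

    Nearest-neighbour ionizable pairs are excluded: their interaction is
    carried by the chemically specific short-range term.
    """
    q = np.asarray(charges, dtype=float)
    pos = np.asarray(site_positions, dtype=float)
    n = q.size
    if n < 3 or env.bjerrum_length == 0.0:
        return 0.0
    kappa = env.kappa
    lb = env.bjerrum_length
    total = 0.0
    for i in range(n - 2):
        d = pos[i + 2:] - pos[i]
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        qq = q[i] * q[i + 2:]
        if np.any((dist == 0.0) & (qq != 0.0)):
            raise SingularityError("coincident charged sites")
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(qq == 0.0, 0.0,
                               lb / dist * np.exp(-kappa * dist) * qq)
        total += float(contrib.sum())
    return total


def short_range_energy(charges: np.ndarray, conformation: Conformation,
                       eps_int=(1.0, 3.0, 3.0)) -> float:
    """Nearest-ionizable-neighbour coupling (kBT).

    ``eps_int`` is given per RIS state of the middle bond in log10 units
    (the ln10 prefactor makes it act like a pK shift); the pair (i, i+1)
    contributes ln10 * eps_int(state of middle bond i) * q_i q_{i+1}.
    """
    eps = np.asarray(eps_int, dtype=float)
    if eps[1] != eps[2]:
        raise ValueError("symmetric chain requires eps_int(g+) == eps_int(g-)")
    q = np.asarray(charges, dtype=float)
    states = conformation.dihedral_states
    if states.size != q.size - 1:
        raise ValueError("need one middle-bond state per consecutive pair")
    return units.LN10 * float((eps[states] * q[:-1] * q[1:]).sum())


def elastic_energy(conformation: Conformation, topology: ChainTopology) -> float:
    """Harmonic bond-stretching + angle-bending energy (kBT)."""
    dl = np.asarray(conformation.bond_lengths) - topology.l0
    da = np.radians(np.asarray(conformation.bond_angles) - topology.alpha0)
    return float(0.5 * topology.k_length_kt * (dl * dl).sum()
                 + 0.5 * topology.k_angle_kt * (da * da).sum())


def mechanical_work(coords: Coordinates, force_pN: float) -> float:
    """Stretching work -F r_z in kBT; F in pN along the laboratory z axis."""
    rz = coords.positions[-1, 2] - coords.positions[0, 2]
    return -force_pN * rz / units.KT_PN_NM


def sev_overlap(coords: Coordinates, topology: ChainTopology) -> bool:
    """Hard-sphere clash test over node pairs at least 4 bonds apart.

    Pairs closer along the chain (1-2 to 1-4) are excluded: their distances
    are controlled by the bonded terms.  With all radii zero (excluded
    volume off) the answer is always False.
    """
    radii = topology.node_radii
    if np.all(radii == 0.0):
        return False
    pos = coords.positions
    n = pos.shape[0]
    for i in range(n - 4):
        d = pos[i + 4:] - pos[i]
        dist2 = np.einsum("ij,ij->i", d, d)
        rsum = radii[i] + radii[i + 4:]
        if np.any(dist2 <= rsum * rsum):
            return True
    return False


def total_free_energy(topology: ChainTopology, conformation: Conformation,
                      coords: Coordinates, env: ElectrostaticEnvironment, *,
                      mode: str = "fluctuating",
                      protonation: np.ndarray | None = None,
                      theta: float | None = None,
                      pH: float = 7.0,
                      force_pN: float = 0.0,
                      sev_enabled: bool = False) -> float:
    """Total microstate free energy in kBT; +inf on a hard-sphere clash.

    In smeared (constant-charge) mode the one-body proton term is dropped
    and every pair charge product is theta^2.
    """
    if sev_enabled and sev_overlap(coords, topology):
        return math.inf
    q = site_charges(mode, protonation=protonation, theta=theta,
                     n_sites=topology.n_ionizable)
    total = rotational_energy(conformation, topology.eps_rot)
    if mode in ("fluctuating", "sgcmc"):
        total += protonation_energy(q, pH, topology.pK)
    site_pos = coords.positions[topology.site_nodes]
    total += long_range_energy(q, site_pos, env)
    total += short_range_energy(q, conformation, topology.eps_int)
    total += elastic_energy(conformation, topology)
    total += mechanical_work(coords, force_pN)
    return total
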