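"""Metropolis Monte Carlo over coupled ionization and conformational moves.

Two sampling modes are provided.  In constant-pH (semi-grand canonical,
``sgcmc``) mode the proton chemical potential is fixed through the pH and
site occupancies fluctuate; the move set is site flips, single-bond
rotational-isomeric pivots and (optionally) Gaussian elastic perturbations
of bond lengths and angles.  In constant-charge (``ccmc``) mode every site
carries the frozen mean charge theta and only conformational moves are
performed.

``run_simulation`` drives ``n_replicates`` independent Markov chains with
sub-seeds derived from the master seed and aggregates time-averaged
observables with replicate-to-replicate standard errors.  The heavy inner
loop lives in the compiled kernel (:mod:`sbris._kernel`); the
``propose_*`` functions in this module are slow reference implementations
that recompute full state energies, used to validate the kernel's
incremental bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _kernel, chain, energy, units
from .chain import ChainTopology, Conformation, Coordinates
from .energy import ElectrostaticEnvironment
from .observables import SimulationResult, assemble_result


class ModeError(RuntimeError):
    """A move or observable was requested in an incompatible charge mode."""


@dataclass(frozen=True)
class SimulationSettings:
    """Control variables of one simulation condition.

    ``n_steps`` counts elementary move attempts in total; the first
    ``n_equilibration`` attempts are discarded.  ``move_mix`` maps move
    names (``protonation_flip``, ``rotation``, ``elastic_perturbation``) to
    proposal probabilities; if omitted a default mix for the mode is used.
    ``bjerrum_length`` can be set to 0 to switch electrostatics off.
    """

    mode: str = "sgcmc"
    pH: float = 7.0
    theta_input: float | None = None
    ionic_strength: float = 1.0       # M
    force: float = 0.0                # pN along z
    sev_enabled: bool = False
    elastic_sampling: bool = False
    n_steps: int = 11_000_000
    n_equilibration: int = 1_000_000
    move_mix: Mapping[str, float] | None = None
    seed: int = 0
    n_replicates: int = 8
    sample_stride: int = 50
    n_blocks: int = 16
    bjerrum_length: float = units.BJERRUM_NM
    pivot_shorter: bool = True
    global_rotation_step: float = 1.0  # rad, max angle of whole-chain moves
    sigma_length: float | None = None  # nm; default 2/sqrt(k_length_kt)
    sigma_angle: float | None = None   # rad; default 2/sqrt(k_angle_kt)

    def __post_init__(self):
        if self.mode not in ("sgcmc", "ccmc"):
            raise ValueError("mode must be 'sgcmc' or 'ccmc'")
        if self.mode == "ccmc" and self.theta_input is None:
            raise ValueError("ccmc mode requires theta_input")
        if self.mode == "ccmc" and not 0.0 <= self.theta_input <= 1.0:
            raise ValueError("theta_input must lie in [0, 1]")
        if not 0 <= self.n_equilibration < self.n_steps:
            raise ValueError("need 0 <= n_equilibration < n_steps")

    @property
    def environment(self) -> ElectrostaticEnvironment:
        return ElectrostaticEnvironment(self.ionic_strength,
                                        bjerrum_length=self.bjerrum_length)

    def resolved_move_mix(self) -> dict[str, float]:
        """Proposal probabilities, validated and normalized."""
        grot = 0.1 if self.pivot_shorter else 0.0
        if self.move_mix is not None:
            mix = {"protonation_flip": 0.0, "rotation": 0.0,
                   "elastic_perturbation": 0.0, "global_rotation": 0.0}
            mix.update(self.move_mix)
        elif self.mode == "sgcmc":
            mix = ({"protonation_flip": 0.2, "rotation": 0.5 + grot,
                    "elastic_perturbation": 0.2} if self.elastic_sampling
                   else {"protonation_flip": 0.25, "rotation": 0.65 + grot,
                         "elastic_perturbation": 0.0})
            mix["global_rotation"] = grot
            mix["rotation"] -= grot
        else:
            mix = ({"protonation_flip": 0.0, "rotation": 0.75 - grot,
                    "elastic_perturbation": 0.25,
                    "global_rotation": grot} if self.elastic_sampling
                   else {"protonation_flip": 0.0, "rotation": 1.0 - grot,
                         "elastic_perturbation": 0.0,
                         "global_rotation": grot})
        total = sum(mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("move_mix must sum to 1")
        if self.mode == "ccmc" and mix["protonation_flip"] != 0.0:
            raise ValueError("protonation flips are not allowed in ccmc mode")
        if not self.elastic_sampling and mix["elastic_perturbation"] != 0.0:
            raise ValueError("elastic moves require elastic_sampling=True")
        if not self.pivot_shorter and mix["global_rotation"] != 0.0:
            raise ValueError(
                "global rotations are incompatible with the anchored "
                "(pivot_shorter=False) frame")
        return mix


def desk_settings(**overrides) -> SimulationSettings:
    """Desk-scale preset: 1e6 equilibration + 1e7 production, 8 replicates."""
    base = dict(n_steps=11_000_000, n_equilibration=1_000_000, n_replicates=8)
    base.update(overrides)
    return SimulationSettings(**base)


def full_settings(**overrides) -> SimulationSettings:
    """Full-scale preset: 5e7 equilibration + 1e9 production, 16 replicates."""
    base = dict(n_steps=1_050_000_000, n_equilibration=50_000_000,
                n_replicates=16)
    base.update(overrides)
    return SimulationSettings(**base)


@dataclass
class SystemState:
    """Microstate: occupancies (or smeared theta), internals, coordinates."""

    topology: ChainTopology
    conformation: Conformation
    coordinates: Coordinates
    protonation: np.ndarray | None = None   # (N,) 0/1, sgcmc
    theta: float | None = None              # ccmc
    energy: float = 0.0

    @property
    def mode(self) -> str:
        return "sgcmc" if self.protonation is not None else "ccmc"

    def charges(self) -> np.ndarray:
        return energy.site_charges(
            "fluctuating" if self.mode == "sgcmc" else "smeared",
            protonation=self.protonation, theta=self.theta,
            n_sites=self.topology.n_ionizable)


def initial_state(topology: ChainTopology,
                  settings: SimulationSettings) -> SystemState:
    """All-trans equilibrium-geometry start; occupancies set by pH vs pK."""
    conf = chain.all_trans_conformation(topology)
    coords = chain.build_coordinates(topology, conf)
    if settings.mode == "sgcmc":
        s0 = 1.0 if settings.pH <= topology.pK else 0.0
        prot = np.full(topology.n_ionizable, s0)
        theta = None
    else:
        prot = None
        theta = settings.theta_input
    st = SystemState(topology, conf, coords, prot, theta)
    st.energy = _state_energy(st, settings)
    return st


def _state_energy(state: SystemState, settings: SimulationSettings) -> float:
    return energy.total_free_energy(
        state.topology, state.conformation, state.coordinates,
        settings.environment,
        mode="fluctuating" if state.mode == "sgcmc" else "smeared",
        protonation=state.protonation, theta=state.theta,
        pH=settings.pH, force_pN=settings.force,
        sev_enabled=settings.sev_enabled)


def metropolis_accept(delta_energy: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE)); +inf always rejects."""
    if delta_energy <= 0.0:
        return True
    if math.isinf(delta_energy):
        return False
    return rng.random() < math.exp(-delta_energy)


def propose_protonation_flip(state: SystemState,
                             settings: SimulationSettings,
                             rng: np.random.Generator):
    """Toggle one uniformly chosen site; returns (candidate, dE)."""
    if state.mode != "sgcmc":
        raise ModeError("protonation flips require sgcmc mode")
    i = int(rng.integers(state.topology.n_ionizable))
    cand = SystemState(state.topology, state.conformation.copy(),
                       state.coordinates,
                       state.protonation.copy(), None)
    cand.protonation[i] = 1.0 - cand.protonation[i]
    cand.energy = _state_energy(cand, settings)
    return cand, cand.energy - state.energy


def propose_rotation(state: SystemState, settings: SimulationSettings,
                     rng: np.random.Generator):
    """Reassign one rotatable bond to one of its two alternative states."""
    nrot = state.topology.rotatable_bonds.size
    if nrot == 0:
        raise ValueError("chain has no rotatable bonds")
    k = int(rng.integers(nrot))
    old = int(state.conformation.dihedral_states[k])
    new = (old + 1 + int(rng.integers(2))) % 3
    conf = state.conformation.copy()
    conf.dihedral_states[k] = new
    cand = SystemState(state.topology, conf,
                       chain.build_coordinates(state.topology, conf),
                       None if state.protonation is None
                       else state.protonation.copy(),
                       state.theta)
    cand.energy = _state_energy(cand, settings)
    return cand, cand.energy - state.energy


def propose_elastic_perturbation(state: SystemState,
                                 settings: SimulationSettings,
                                 rng: np.random.Generator):
    """Gaussian step on one bond length or one bond angle."""
    if not settings.elastic_sampling:
        raise ModeError("elastic moves require elastic_sampling=True")
    topo = state.topology
    conf = state.conformation.copy()
    sig_l = settings.sigma_length or 2.0 / math.sqrt(topo.k_length_kt)
    sig_a = settings.sigma_angle or 2.0 / math.sqrt(topo.k_angle_kt)
    if rng.random() < 0.5:
        j = int(rng.integers(topo.n_bonds))
        conf.bond_lengths[j] = max(conf.bond_lengths[j]
                                   + rng.normal(0.0, sig_l), 1e-3)
    else:
        j = int(rng.integers(topo.n_bonds - 1))
        conf.bond_angles[j] += math.degrees(rng.normal(0.0, sig_a))
    cand = SystemState(topo, conf, chain.build_coordinates(topo, conf),
                       None if state.protonation is None
                       else state.protonation.copy(), state.theta)
    cand.energy = _state_energy(cand, settings)
    return cand, cand.energy - state.energy


def replicate_seeds(master_seed: int, n_replicates: int) -> np.ndarray:
    """Deterministic sub-seeds (< 2^31) from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n_replicates) % (2 ** 31 - 1)).astype(np.int64)


def run_replicate(topology: ChainTopology, settings: SimulationSettings,
                  sub_seed: int) -> dict:
    """Run one Markov chain in the compiled kernel; return raw accumulators."""
    mix = settings.resolved_move_mix()
    st = initial_state(topology, settings)
    env = settings.environment

    pos = st.coordinates.positions.copy()
    q = st.charges().astype(np.float64)
    rot_state = st.conformation.dihedral_states.astype(np.int64)
    bond_len = st.conformation.bond_lengths.astype(np.float64)
    bond_ang = np.radians(st.conformation.bond_angles.astype(np.float64))
    site_nodes = topology.site_nodes.astype(np.int64)
    rot_bonds = topology.rotatable_bonds.astype(np.int64)
    radii = (topology.node_radii if settings.sev_enabled
             else np.zeros(topology.n_nodes)).astype(np.float64)

    nbond = topology.n_bonds
    ncorr = max(nbond - nbond // 2 - 1, 1)
    out_scal = np.zeros(_kernel.N_SCALARS)
    out_corr = np.zeros(ncorr)
    out_blocks = np.zeros((settings.n_blocks, _kernel.N_BLOCK_COLS))
    out_counts = np.zeros(8, dtype=np.int64)

    sig_l = settings.sigma_length or 2.0 / math.sqrt(topology.k_length_kt)
    sig_a = settings.sigma_angle or 2.0 / math.sqrt(topology.k_angle_kt)

    e_final = _kernel.run_kernel(
        int(sub_seed), settings.n_steps, settings.n_equilibration,
        settings.sample_stride, settings.n_blocks,
        pos, q, rot_state, bond_len, bond_ang, site_nodes, rot_bonds,
        settings.mode == "sgcmc", settings.pH, topology.pK,
        env.bjerrum_length, env.kappa,
        np.asarray(topology.eps_rot, dtype=np.float64),
        np.asarray(topology.eps_int, dtype=np.float64),
        topology.l0, topology.alpha0_rad,
        topology.k_length_kt, topology.k_angle_kt,
        settings.force / units.KT_PN_NM,
        settings.sev_enabled, radii,
        mix["protonation_flip"], mix["rotation"], mix["global_rotation"],
        settings.global_rotation_step,
        sig_l, sig_a, settings.pivot_shorter,
        out_scal, out_corr, out_blocks, out_counts)

    # energy-drift check: incremental total vs from-scratch recomputation
    final_conf = Conformation(rot_state.astype(np.int8), bond_len,
                              np.degrees(bond_ang))
    final_state = SystemState(
        topology, final_conf, Coordinates(pos),
        q if settings.mode == "sgcmc" else None,
        settings.theta_input if settings.mode == "ccmc" else None)
    e_check = _state_energy(final_state, settings)
    if math.isinf(e_check):  # clash impossible: kernel rejects them
        raise RuntimeError("kernel produced an overlapping state")

    return {"scalars": out_scal, "corr": out_corr, "blocks": out_blocks,
            "counts": out_counts, "energy_incremental": e_final,
            "energy_recomputed": e_check, "final_state": final_state,
            "seed": int(sub_seed)}


def run_simulation(settings: SimulationSettings,
                   topology: ChainTopology | None = None) -> SimulationResult:
    """Run all replicates of one condition and aggregate the observables."""
    if topology is None:
        topology = chain.build_topology(50)
    settings.resolved_move_mix()  # validate early
    seeds = replicate_seeds(settings.seed, settings.n_replicates)
    raws = [run_replicate(topology, settings, s) for s in seeds]
    return assemble_result(settings, topology, raws)
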