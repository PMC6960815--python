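"""Exact statistical mechanics of tiny rigid chains by brute-force enumeration.

For a rigid chain (equilibrium bond lengths and angles, elastic sampling
off) the microstate space is the product of 2^N protonation vectors and
3^(N-1) rotational-isomeric conformations.  For N up to about 8 the
Boltzmann sum can be evaluated exactly, which makes this module the primary
correctness oracle for the Monte Carlo engine.

The degree of protonation, binding capacitance, gauche probability and
end-to-end moments are computed as exact Boltzmann-weighted averages,
including the stretching work and (optionally) hard-sphere excluded volume.
Note that with an applied force the enumeration is performed in the
construction frame (first node anchored, first bond along z), so Monte
Carlo comparisons at nonzero force must use the same anchored-frame pivot
convention (``pivot_shorter=False``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import chain, energy, units
from .chain import ChainTopology


class StateSpaceTooLarge(ValueError):
    """The enumeration would exceed the configured state-count cap."""


MAX_STATES = 1_000_000


@dataclass(frozen=True)
class EnumerationResult:
    """Exact Boltzmann averages over the full (s, c) state space."""

    log_partition: float
    theta: float | None
    capacitance: float | None
    p_gauche: float
    mean_sq_end_to_end: float
    mean_rz: float

    @property
    def partition_function(self) -> float:
        return math.exp(self.log_partition)


def ideal_titration(pH: float, pK: float) -> float:
    """Degree of protonation of independent identical sites."""
    return 1.0 / (1.0 + 10.0 ** (pH - pK))


def enumerate_states(topology: ChainTopology, settings) -> EnumerationResult:
    """Exact averages for a rigid chain under the given settings.

    ``settings`` is a :class:`~sbris.engine.SimulationSettings`; elastic
    sampling must be off.  Raises :class:`StateSpaceTooLarge` when
    2^N * 3^(N-1) exceeds ``MAX_STATES``.
    """
    if settings.elastic_sampling:
        raise ValueError("enumeration requires rigid geometry")
    N = topology.n_ionizable
    n_rot = topology.rotatable_bonds.size
    n_conf = 3 ** n_rot
    sgcmc = settings.mode == "sgcmc"
    n_s = 2 ** N if sgcmc else 1
    if n_conf * n_s > MAX_STATES:
        raise StateSpaceTooLarge(
            f"{n_conf * n_s} states exceed the cap of {MAX_STATES}")

    env = settings.environment
    beta_f = settings.force / units.KT_PN_NM
    eps_rot = np.asarray(topology.eps_rot)
    eps_int = np.asarray(topology.eps_int)

    if sgcmc:
        # all protonation vectors as a (2^N, N) bit matrix
        S = ((np.arange(n_s)[:, None] >> np.arange(N)[None, :]) & 1
             ).astype(float)
        Np = S.sum(axis=1)
        fp = units.LN10 * (settings.pH - topology.pK) * Np
    else:
        S = np.full((1, N), float(settings.theta_input))
        Np = S.sum(axis=1)
        fp = np.zeros(1)

    # pair index lists over ionizable sites
    lr_pairs = [(i, j) for i in range(N - 2) for j in range(i + 2, N)]

    log_w = np.empty((n_conf, n_s))
    ng_arr = np.empty(n_conf)
    r2_arr = np.empty(n_conf)
    rz_arr = np.empty(n_conf)

    for ci, states in enumerate(
            itertools.product(range(3), repeat=n_rot)):
        st = np.array(states, dtype=np.int8)
        conf = chain.all_trans_conformation(topology, st)
        coords = chain.build_coordinates(topology, conf)
        ng_arr[ci] = float((st != 0).sum())
        r = chain.end_to_end_vector(coords)
        r2_arr[ci] = float(r @ r)
        rz_arr[ci] = float(r[2])

        if settings.sev_enabled and energy.sev_overlap(coords, topology):
            log_w[ci, :] = -np.inf
            continue

        e_conf = float(eps_rot[st].sum()) - beta_f * r[2]
        site_pos = coords.positions[topology.site_nodes]
        # quadratic coupling of s with screened Coulomb + short-range terms
        e_s = fp.copy()
        if env.bjerrum_length > 0.0:
            for i, j in lr_pairs:
                d = float(np.linalg.norm(site_pos[j] - site_pos[i]))
                w = env.bjerrum_length / d * math.exp(-env.kappa * d)
                e_s += w * S[:, i] * S[:, j]
        for i in range(N - 1):
            e_s += units.LN10 * eps_int[st[i]] * S[:, i] * S[:, i + 1]
        log_w[ci, :] = -(e_conf + e_s)

    flat = log_w.ravel()
    log_z = float(logsumexp(flat))
    p = np.exp(flat - log_z).reshape(n_conf, n_s)
    p_conf = p.sum(axis=1)
    p_s = p.sum(axis=0)

    mean_np = float(p_s @ Np)
    mean_np2 = float(p_s @ (Np * Np))
    return EnumerationResult(
        log_partition=log_z,
        theta=mean_np / N if sgcmc else settings.theta_input,
        capacitance=mean_np2 - mean_np ** 2 if sgcmc else None,
        p_gauche=float(p_conf @ ng_arr) / max(n_rot, 1),
        mean_sq_end_to_end=float(p_conf @ r2_arr),
        mean_rz=float(p_conf @ rz_arr),
    )


def capacitance_by_finite_difference(topology: ChainTopology, settings,
                                     dpH: float = 1e-4) -> float:
    """C = N dtheta/dmu via exact finite differences of the enumeration.

    The reduced proton chemical potential decreases by ln10 per pH unit,
    so C = -N/ln10 * dtheta/dpH.
    """
    from dataclasses import replace
    hi = enumerate_states(topology, replace(settings, pH=settings.pH + dpH))
    lo = enumerate_states(topology, replace(settings, pH=settings.pH - dpH))
    return -topology.n_ionizable * (hi.theta - lo.theta) / (
        2.0 * dpH * units.LN10)
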