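"""Thermal-average observables and their uncertainties.

Observables are aggregated over independent replicates: the reported value
is the replicate mean and the uncertainty the standard error of that mean.
Per-replicate block averages are kept so that autocorrelation-aware errors
can be inspected.

Estimators
----------
degree of protonation    theta = <N+> / N
binding capacitance      C = <N+^2> - <N+>^2  (= N dtheta/dmu)
gauche probability       P(g) = <M_g> / M_rot  (rotatable bonds only)
persistence length       lp = <r^2> / (2 M l0) + l0 / 2
  (projection variant)   lp/l0 = sum_{j>=c} <b_c . b_j> from a central bond
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _kernel
from .chain import ChainTopology


class Estimate(NamedTuple):
    """A thermal average with its standard error."""

    value: float
    se: float

    def __str__(self):
        return f"{self.value:.6g} +/- {self.se:.2g}"


class UndefinedCapacitanceError(RuntimeError):
    """Capacitance requested for frozen-charge (ccMC) sampling."""


def error_estimate(values) -> Estimate:
    """Replicate mean with standard error of the mean.

    With a single replicate the SE is not available and is reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if v.size == 1:
        return Estimate(float(v[0]), math.nan)
    return Estimate(float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size)))


def block_standard_error(block_means) -> float:
    """SE of the run mean from (approximately independent) block means."""
    b = np.asarray(block_means, dtype=float)
    if b.size < 2:
        return math.nan
    return float(b.std(ddof=1) / math.sqrt(b.size))


def degree_of_protonation(nplus_means, n_sites: int) -> Estimate:
    """theta = <N+>/N from per-replicate mean proton counts."""
    m = np.asarray(nplus_means, dtype=float) / n_sites
    return error_estimate(m)


def capacitance_from_moments(mean_np, mean_np2) -> Estimate:
    """C = <N+^2> - <N+>^2 per replicate, averaged over replicates."""
    c = np.asarray(mean_np2, dtype=float) - np.asarray(mean_np, float) ** 2
    return error_estimate(c)


def gauche_probability(gauche_means, n_rotatable: int) -> Estimate:
    """P(g) = <M_g>/M_rot; the denominator counts rotatable bonds only.

    Frozen-trans bonds are excluded from the denominator so that the
    free-chain limit (three isoenergetic states) is 2/3.
    """
    p = np.asarray(gauche_means, dtype=float) / n_rotatable
    return error_estimate(p)


def persistence_length_from_r2(mean_sq_end_to_end: float,
                               topology: ChainTopology) -> float:
    """lp = <r^2>/(2 M l0) + l0/2 (nm)."""
    if mean_sq_end_to_end < 0:
        raise ValueError("<r^2> must be >= 0")
    M, l0 = topology.n_bonds, topology.l0
    return mean_sq_end_to_end / (2.0 * M * l0) + l0 / 2.0


def persistence_length_projection(corr_tail, l0: float) -> float:
    """lp from summed bond-direction projections off a central bond (nm).

    ``corr_tail[k]`` is the mean projection <b_c . b_{c+k}> (k = 0
    included, giving the unit self term); the estimator is l0 times the
    sum, averaged over the three chain phases at the chain centre.
    """
    return l0 * float(np.asarray(corr_tail, dtype=float).sum())


def kirkwood_shumaker_energy(Q: float, C: float, R: float, env) -> float:
    """Interaction free energy of two identical charge regulators (kBT).

    beta U = lB Q^2 / R - (lB/R)^2 Q C - (lB/R)^2 C^2 / 2: mean-charge
    repulsion plus the (attractive) regulation and fluctuation terms.
    """
    if R <= 0:
        raise ValueError("separation R must be > 0")
    lb = env.bjerrum_length
    return (lb * Q * Q / R - (lb / R) ** 2 * Q * C
            - 0.5 * (lb / R) ** 2 * C * C)


@dataclass
class SimulationResult:
    """Aggregated averages of one simulation condition."""

    mode: str
    pH: float | None
    theta_input: float | None
    ionic_strength: float
    force: float
    theta: Estimate
    capacitance: Estimate | None
    p_gauche: Estimate
    extension_z: Estimate
    mean_sq_end_to_end: Estimate
    persistence_length: Estimate
    persistence_length_projection: Estimate
    bond_length_mean: Estimate
    bond_length_var: Estimate
    bond_angle_var: Estimate
    replicates: pd.DataFrame
    corr_tail: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def require_capacitance(self) -> Estimate:
        if self.capacitance is None:
            raise UndefinedCapacitanceError(
                "capacitance is undefined for frozen-charge sampling")
        return self.capacitance

    def to_row(self) -> dict:
        """Flat record for CSV result tables."""
        cap = self.capacitance or Estimate(math.nan, math.nan)
        return {
            "mode": self.mode, "pH": self.pH, "theta_input": self.theta_input,
            "ionic_strength": self.ionic_strength, "force": self.force,
            "theta": self.theta.value, "theta_se": self.theta.se,
            "capacitance": cap.value, "capacitance_se": cap.se,
            "p_gauche": self.p_gauche.value, "p_gauche_se": self.p_gauche.se,
            "lp": self.persistence_length.value,
            "lp_se": self.persistence_length.se,
            "lp_proj": self.persistence_length_projection.value,
            "Lz": self.extension_z.value, "Lz_se": self.extension_z.se,
            "r2": self.mean_sq_end_to_end.value,
            "r2_se": self.mean_sq_end_to_end.se,
            "n_replicates": int(self.replicates.shape[0]),
        }


def assemble_result(settings, topology: ChainTopology,
                    raws: list[dict]) -> SimulationResult:
    """Reduce raw kernel accumulators of all replicates into a result."""
    K = _kernel
    n_sites = topology.n_ionizable
    n_rot = topology.rotatable_bonds.size
    M, l0 = topology.n_bonds, topology.l0
    sgcmc = settings.mode == "sgcmc"

    rows = []
    corr_sum = None
    block_se = {"theta": [], "p_gauche": [], "rz": [], "r2": []}
    for raw in raws:
        sc = raw["scalars"]
        ns = sc[K.S_NS]
        mnp = sc[K.S_NP] / ns
        mnp2 = sc[K.S_NP2] / ns
        mg = sc[K.S_G] / ns
        rz = sc[K.S_RZ] / ns
        r2 = sc[K.S_R2] / ns
        ml = sc[K.S_L] / (ns * M)
        ml2 = sc[K.S_L2] / (ns * M)
        ma = sc[K.S_A] / (ns * (M - 1))
        ma2 = sc[K.S_A2] / (ns * (M - 1))
        corr = raw["corr"] / (3.0 * ns)
        corr_sum = corr if corr_sum is None else corr_sum + corr
        cnt = raw["counts"]
        rows.append({
            "seed": raw["seed"], "n_samples": ns,
            "theta": mnp / n_sites if sgcmc else settings.theta_input,
            "capacitance": mnp2 - mnp * mnp if sgcmc else math.nan,
            "p_gauche": mg / n_rot,
            "p_gauche_plus": sc[K.S_GP] / ns / n_rot,
            "rz": rz, "r2": r2,
            "lp": persistence_length_from_r2(r2, topology),
            "lp_proj": persistence_length_projection(corr, l0),
            "bond_length_mean": ml, "bond_length_var": ml2 - ml * ml,
            "bond_angle_var": ma2 - ma * ma,
            "acc_flip": cnt[3] / cnt[0] if cnt[0] else math.nan,
            "acc_rotation": cnt[4] / cnt[1] if cnt[1] else math.nan,
            "acc_elastic": cnt[5] / cnt[2] if cnt[2] else math.nan,
            "acc_global": cnt[7] / cnt[6] if cnt[6] else math.nan,
            "energy_drift": abs(raw["energy_incremental"]
                                - raw["energy_recomputed"]),
        })
        blk = raw["blocks"]
        bns = blk[:, K.B_NS]
        ok = bns > 0
        block_se["theta"].append(block_standard_error(
            blk[ok, K.B_NP] / bns[ok] / n_sites))
        block_se["p_gauche"].append(block_standard_error(
            blk[ok, K.B_G] / bns[ok] / n_rot))
        block_se["rz"].append(block_standard_error(blk[ok, K.B_RZ] / bns[ok]))
        block_se["r2"].append(block_standard_error(blk[ok, K.B_R2] / bns[ok]))

    df = pd.DataFrame(rows)
    theta = (error_estimate(df["theta"]) if sgcmc
             else Estimate(settings.theta_input, 0.0))
    cap = error_estimate(df["capacitance"]) if sgcmc else None
    diagnostics = {
        "acceptance": {m: float(df[f"acc_{m}"].mean())
                       for m in ("flip", "rotation", "elastic", "global")},
        "max_energy_drift": float(df["energy_drift"].max()),
        "p_gauche_plus": {
            "value": float(df["p_gauche_plus"].mean()),
            "se": float(df["p_gauche_plus"].std(ddof=1)
                        / math.sqrt(max(len(df), 2)))
            if len(df) > 1 else math.nan,
        },
        "block_se": {k: float(np.nanmean(v)) for k, v in block_se.items()},
    }
    return SimulationResult(
        mode=settings.mode,
        pH=settings.pH if sgcmc else None,
        theta_input=settings.theta_input,
        ionic_strength=settings.ionic_strength,
        force=settings.force,
        theta=theta,
        capacitance=cap,
        p_gauche=error_estimate(df["p_gauche"]),
        extension_z=error_estimate(df["rz"]),
        mean_sq_end_to_end=error_estimate(df["r2"]),
        persistence_length=error_estimate(df["lp"]),
        persistence_length_projection=error_estimate(df["lp_proj"]),
        bond_length_mean=error_estimate(df["bond_length_mean"]),
        bond_length_var=error_estimate(df["bond_length_var"]),
        bond_angle_var=error_estimate(df["bond_angle_var"]),
        replicates=df,
        corr_tail=corr_sum / len(raws),
        diagnostics=diagnostics,
    )
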