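# Methods

## The model

The simulator describes a single linear weak polyelectrolyte patterned on
linear poly(ethylene imine): one titratable amine followed by two inert
backbone nodes, repeated.  With `N` ionizable sites the chain has `3N - 2`
nodes and `M = 3N - 3` bonds (N = 50 gives 148 nodes, 147 bonds).  A
microstate couples two sets of discrete degrees of freedom,

* the protonation vector `s`, one occupancy per ionizable site
  (site-binding description), and
* the rotational-isomeric states of the rotatable dihedrals, restricted to
  trans (0°) and gauche± (±120°) measured from the planar all-trans
  geometry.  Only the middle bond between two consecutive ionizable nodes
  rotates; all other bonds are frozen in trans.

plus, optionally, continuous bond lengths and angles.  The free energy of a
microstate, in kBT at 298.15 K, is the sum of

| term | form | default parameters |
|------|------|--------------------|
| torsional | Σ ε_rot(φ_j) over rotatable bonds | ε_rot ≡ 0 (isoenergetic states) |
| proton binding | ln10 (pH − pK) Σ s_i | pK = 9 |
| short-range pair | ln10 Σ ε_int(φ of middle bond) q_i q_{i+1} | ε_int(t)=1, ε_int(g±)=3 (log10 units) |
| screened Coulomb | Σ_{j≥i+2} (ℓB/d_ij) e^{−κ d_ij} q_i q_j | ℓB = 0.7 nm, κ⁻¹ = 0.304/√I nm |
| bond stretching | Σ k_l/2 (l − l0)² | l0 = 0.15 nm, k_l = 300 kcal mol⁻¹ Å⁻² |
| angle bending | Σ k_a/2 (α − α0)² | α0 = 120°, k_a = 0.01 kcal mol⁻¹ deg⁻² |
| excluded volume | hard spheres, pairs ≥ 4 bonds apart | R = 1.55 Å (ionizable) / 1.7 Å (inert), off by default |
| stretching work | −F r_z | F in pN along the laboratory z axis |

Unit conversions are fixed at 298.15 K: 1 kcal mol⁻¹ = 1.6878 kBT and
kBT = 4.1164 pN nm.  The short-range parameters are dimensionless log10
(pK-shift-like) units; the ln10 prefactor makes a protonated pair across a
trans bond cost one pK unit and across a gauche bond three.  The
nearest-ionizable-neighbour pair is excluded from the Coulomb sum because
the short-range term owns it; excluded-volume checks skip pairs closer than
four bonds because bonded terms control those distances.

Two charge modes:

* **Constant pH (SGCMC).**  Semi-grand canonical sampling at fixed proton
  chemical potential: occupancies flip during the run, so the mean charge
  θ = ⟨N₊⟩/N and its variance, the binding capacitance C = ⟨N₊²⟩−⟨N₊⟩²
  (= N ∂θ/∂μ), are outputs.  Charge regulation and charge fluctuations are
  both active.
* **Constant charge (ccMC).**  Every site carries the frozen mean charge
  θ (taken from the matching SGCMC run at zero force); pair charge
  products become θ², the one-body proton term drops, and only
  conformational moves run.  Comparing the two modes at equal θ isolates
  the effect of charge fluctuations.  θ ∈ {0, 1} reproduces the frozen
  all-0/all-1 fluctuating states exactly, term by term.

## Monte Carlo moves

Metropolis sampling with four symmetric proposal types:

1. **site flip** (SGCMC only) — toggle one uniformly chosen site; the
   energy delta touches the one-body term and the pair terms of that site;
2. **rotational pivot** — assign one rotatable bond one of its two
   alternative states and rigidly rotate the shorter chain arm about the
   bond axis.  Intra-arm distances are invariant, so only cross-arm
   Coulomb pairs are recomputed;
3. **elastic perturbation** (optional) — Gaussian step on one bond length
   (arm translation along the bond) or one interior angle (arm rotation
   about the local bending normal).  Step widths default to twice the
   thermal width 1/√k.  Out-of-domain proposals (non-positive length,
   angle outside (0°, 180°)) are rejected;
4. **global rotation** — rigid rotation of the whole chain about a random
   axis by a uniform angle in ±1 rad.  Only the stretching work changes.

The fourth move exists because arm pivots alone cannot reorient the chain
globally: whichever arm is shorter moves, so the orientation of the central
stem is frozen at its initial value and, under an applied force, extensions
stay biased toward the starting orientation.  With global rotations the
sampler reproduces the exact orientation-averaged ensemble of a tiny chain
(weights sinh(x)/x, x = βF|r|) to within statistical error.  Default move
mixes: SGCMC rigid 0.25/0.65/0.10 (flip/pivot/global), SGCMC elastic
0.2/0.5/0.2/0.1, ccMC rigid 0.9/0.1, ccMC elastic 0.65/0.25/0.1.

An *anchored* variant (`pivot_shorter=False`) always pivots the downstream
arm and forbids global rotations; it fixes the first node and bond in the
laboratory frame, which makes the sampled ensemble identical to the state
space of the exact enumeration oracle.  It exists for validation at
nonzero force; production runs use the free-orientation sampler.

Hard-sphere overlaps reject a move before any energy is evaluated, so the
running energy never contains the excluded-volume sentinel.  The kernel
maintains the total energy incrementally; every replicate re-derives the
final-state energy from scratch and the difference (reported as
`max_energy_drift`, typically < 1e-10 kBT) is a standing self-check of all
delta-energy bookkeeping.

Runs start from the all-trans chain with occupancies set to the Henderson–
Hasselbalch side of pK (all 1 below pK, all 0 above).  Replicates receive
sub-seeds spawned from the master seed through `numpy.random.SeedSequence`;
a fixed master seed reproduces every table bit-identically.

## Observables and errors

θ, C, the gauche fraction P(g) = ⟨M_g⟩/M_rot (rotatable bonds only — the
only denominator consistent with the uncharged-chain limit of 2/3),
⟨r_z⟩, ⟨r²⟩ and the persistence length are accumulated every
`sample_stride` (default 50) attempts.  Two lp estimators are kept:

* `lp = ⟨r²⟩/(2 M l0) + l0/2` (the quantity reported by default), and
* the summed projection of bond directions onto a central reference bond,
  averaged over the three chain phases of the repeat unit (validation
  only; the two agree within ~6% for long uncharged chains).

The reported uncertainty of every observable is the standard error over
independent replicates; 16 per-replicate block means provide an
autocorrelation-aware cross-check (`diagnostics["block_se"]`).  A
Kirkwood–Shumaker helper gives the pair free energy of two identical
charge regulators, βU = ℓB Q²/R − (ℓB/R)² QC − (ℓB/R)² C²/2, used to
reason about fluctuation-induced attraction.

## Scaling analysis

Force–extension curves are analysed in two sub-regimes of the low-force
region F < kBT/lp:

* F < 0.3 pN: zero-intercept weighted fit of Lz = (M l0/3) βF lK, giving
  the Kuhn length lK and, through lK = 2lp − l0, a fluctuation–dissipation
  consistency check against the zero-force lp;
* the Pincus window, nominally 0.3–1 pN: weighted least squares of
  log Lz vs log F; the slope is 1/ν − 1.

For stiff conditions (highly charged chain at low ionic strength,
lp ≈ 8 nm) the low-force boundary kBT/lp ≈ 0.5 pN falls inside the nominal
window, and the upper part of 0.3–1 pN is already in freely-jointed-chain
saturation, which flattens the log-log slope and inflates the fitted ν.
`scaling.pincus_window(lp)` therefore caps the window at kBT/lp computed
from the zero-force persistence length of the same condition; all ν values
quoted by the package use the capped window.  Fits are weighted by 1/SE²
of the extensions.  Exponents outside 0.45–0.8 are flagged, not hidden.
The ν(θ) summary is an (SE-weighted) straight-line fit against the
zero-force SGCMC θ of each condition.

## Problem sizes

The desk preset runs 10⁶ equilibration plus 10⁷ production attempts over 8
replicates per condition; the `full` preset runs the full-scale
protocol (5×10⁷ equilibration plus 10⁹ production over 16 replicates).  The test suite uses condition-dependent
sizes between 5×10⁵ and 2×10⁶ attempts with 3–6 replicates, which puts
every tested quantity's replicate SE one to two orders of magnitude below
the tolerance it is checked against.  The exact-enumeration oracle covers
chains up to N≈8 (2^N·3^(N−1) ≤ 10⁶ states) and is the primary gate for
engine correctness; continuous elastic marginals are validated against
their Gaussian closed forms instead, since enumeration handles discrete
states only.

## What the simulations do and do not emulate

The model keeps atomistic bond geometry but represents electrostatics at
the Debye–Hückel level with a uniform dielectric: no explicit counterions
or condensation, no dielectric discontinuities, no solvent structure, no
hydrogen-bond-specific torsional preferences, no tacticity or branching.
Conclusions about trends (charge regulation softening the chain, the
ν(θ) crossover) transfer to real weak polyelectrolytes; absolute numbers
(titration midpoints, lp in nm) inherit the coarse parameterization.
The per-condition capped Pincus window matters only for stiff
low-screening conditions; flexible conditions use the nominal window
unchanged.
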