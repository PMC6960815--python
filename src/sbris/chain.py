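"""Chain topology and internal-to-Cartesian geometry.

The chain is a coarse-grained linear weak polyelectrolyte patterned on
linear poly(ethylene imine): one titratable (ionizable) node followed by two
inert backbone nodes, repeated, starting and ending on an ionizable node.
With ``N`` ionizable sites the chain has ``3N - 2`` nodes and ``3N - 3``
bonds.  Only the middle bond between two consecutive ionizable nodes is
rotatable; every other bond is frozen in the *trans* state.  Rotatable
dihedrals take the three rotational-isomeric-state values
trans (0), gauche+ (+120 deg) and gauche- (-120 deg), measured from the
planar all-trans geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from . import units

#: RIS state codes and their dihedral offsets from trans (radians).
STATE_TRANS, STATE_GAUCHE_PLUS, STATE_GAUCHE_MINUS = 0, 1, 2
STATE_PHI = np.array([0.0, 2.0 * math.pi / 3.0, -2.0 * math.pi / 3.0])
STATE_LABELS = ("t", "g+", "g-")
_LABEL_TO_STATE = {"t": 0, "g+": 1, "g-": 2}


class TopologyError(ValueError):
    """Raised for chain definitions that violate the node pattern."""


@dataclass(frozen=True)
class ChainTopology:
    """Static description of the chain.

    Parameters follow the default coarse-grained parameter set: bond length
    0.15 nm, bond angle 120 deg, C-C-like elastic constants, hard-sphere
    radii 1.55 A (ionizable) / 1.7 A (inert), pK = 9.  ``eps_rot`` are the
    intrinsic torsional energies of the three RIS states in kBT (all zero by
    default, i.e. isoenergetic rotational states); ``eps_int`` are the
    short-range site-site interaction parameters per RIS state of the
    connecting middle bond, in log10 (pK-shift-like) units.
    """

    n_ionizable: int
    node_is_ionizable: np.ndarray  # bool, (n_nodes,)
    rotatable_bonds: np.ndarray    # int, (n_ionizable - 1,), 0-indexed bond ids
    l0: float = 0.15               # nm
    alpha0: float = 120.0          # degrees
    k_length: float = 300.0        # kcal mol^-1 A^-2
    k_angle: float = 0.01          # kcal mol^-1 deg^-2
    radius_ionizable: float = 0.155  # nm
    radius_inert: float = 0.17       # nm
    pK: float = 9.0
    eps_rot: tuple[float, float, float] = (0.0, 0.0, 0.0)   # kBT
    eps_int: tuple[float, float, float] = (1.0, 3.0, 3.0)   # log10 units

    def __post_init__(self):
        if self.eps_rot[1] != self.eps_rot[2]:
            raise ValueError(
                "symmetric chain requires eps_rot(g+) == eps_rot(g-)")
        if self.eps_int[1] != self.eps_int[2]:
            raise ValueError(
                "symmetric chain requires eps_int(g+) == eps_int(g-)")

    # -- derived sizes -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_is_ionizable.size

    @property
    def n_bonds(self) -> int:
        return self.n_nodes - 1

    @property
    def site_nodes(self) -> np.ndarray:
        """Node indices of the ionizable sites, in chain order."""
        return np.flatnonzero(self.node_is_ionizable)

    @property
    def node_radii(self) -> np.ndarray:
        """Hard-sphere radius per node (nm)."""
        return np.where(self.node_is_ionizable,
                        self.radius_ionizable, self.radius_inert)

    @property
    def alpha0_rad(self) -> float:
        return math.radians(self.alpha0)

    @property
    def k_length_kt(self) -> float:
        """Stretching constant in kBT nm^-2."""
        return units.k_length_to_kt_nm2(self.k_length)

    @property
    def k_angle_kt(self) -> float:
        """Bending constant in kBT rad^-2."""
        return units.k_angle_to_kt_rad2(self.k_angle)


@dataclass
class Conformation:
    """Internal coordinates of a microstate.

    ``dihedral_states`` holds one RIS code (0=t, 1=g+, 2=g-) per rotatable
    bond; ``bond_lengths`` (nm) one value per bond; ``bond_angles``
    (degrees) one value per interior node.
    """

    dihedral_states: np.ndarray
    bond_lengths: np.ndarray
    bond_angles: np.ndarray

    def copy(self) -> "Conformation":
        return Conformation(self.dihedral_states.copy(),
                            self.bond_lengths.copy(),
                            self.bond_angles.copy())

    @property
    def state_labels(self) -> list[str]:
        return [STATE_LABELS[s] for s in self.dihedral_states]


@dataclass
class Coordinates:
    """Cartesian node positions, (n_nodes, 3), in nm."""

    positions: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]


def build_topology(n_ionizable: int, **parameters) -> ChainTopology:
    """Build the LPEI-like topology with ``n_ionizable`` titratable sites.

    Ionizable nodes sit at chain positions 0, 3, 6, ... (one every third
    position); rotatable bonds are the middle bonds between consecutive
    ionizable nodes (0-indexed bond ids 1, 4, ..., 3*(N-1) - 2).

    Extra keyword arguments override the default physical parameters
    (``l0``, ``alpha0``, ``k_length``, ``k_angle``, ``radius_ionizable``,
    ``radius_inert``, ``pK``, ``eps_rot``, ``eps_int``).
    """
    if n_ionizable < 2:
        raise TopologyError("a chain needs at least 2 ionizable sites")
    n_nodes = 3 * n_ionizable - 2
    kinds = np.zeros(n_nodes, dtype=bool)
    kinds[::3] = True
    rot = np.arange(1, 3 * n_ionizable - 4, 3, dtype=np.int64)
    topo = ChainTopology(n_ionizable=n_ionizable, node_is_ionizable=kinds,
                         rotatable_bonds=rot, **parameters)
    assert rot.size == n_ionizable - 1
    return topo


def all_trans_conformation(topology: ChainTopology,
                           states: Sequence[int] | None = None) -> Conformation:
    """Equilibrium-geometry conformation; all-trans unless ``states`` given.

    ``states`` may use integer codes or the labels 't', 'g+', 'g-'.
    """
    n_rot = topology.rotatable_bonds.size
    if states is None:
        codes = np.zeros(n_rot, dtype=np.int8)
    else:
        codes = np.array([_LABEL_TO_STATE.get(s, s) for s in states],
                         dtype=np.int8)
        if codes.size != n_rot:
            raise ValueError("one dihedral state per rotatable bond required")
    lengths = np.full(topology.n_bonds, topology.l0)
    angles = np.full(topology.n_bonds - 1, topology.alpha0)
    return Conformation(codes, lengths, angles)


def _bond_phis(topology: ChainTopology, conformation: Conformation) -> np.ndarray:
    """Dihedral offset from trans per bond (radians); frozen bonds are 0."""
    phis = np.zeros(topology.n_bonds)
    phis[topology.rotatable_bonds] = STATE_PHI[conformation.dihedral_states]
    return phis


def build_coordinates(topology: ChainTopology,
                      conformation: Conformation) -> Coordinates:
    """Convert internal coordinates into Cartesian node positions.

    Node 0 sits at the origin, bond 0 points along +z and bond 1 lies in the
    x-z plane; each further node is placed by the standard natural-extension
    (NeRF) construction.  The dihedral of bond j is defined over nodes
    (j-1, j, j+1, j+2); an offset of zero from the planar zig-zag means
    *trans*.
    """
    n = topology.n_nodes
    lengths = np.asarray(conformation.bond_lengths, dtype=float)
    angles = np.radians(np.asarray(conformation.bond_angles, dtype=float))
    if lengths.size != topology.n_bonds or angles.size != topology.n_bonds - 1:
        raise ValueError("conformation does not match topology dimensions")
    phis = _bond_phis(topology, conformation)

    pos = np.zeros((n, 3))
    pos[1] = (0.0, 0.0, lengths[0])
    if n > 2:
        a = angles[0]
        pos[2] = pos[1] + lengths[1] * np.array(
            [math.sin(a), 0.0, -math.cos(a)])
    for m in range(3, n):
        # torsion about bond m-2: pi + phi so that phi = 0 is trans
        tau = math.pi + phis[m - 2]
        pos[m] = _nerf(pos[m - 3], pos[m - 2], pos[m - 1],
                       lengths[m - 1], angles[m - 2], tau)
    return Coordinates(pos)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          l: float, alpha: float, tau: float) -> np.ndarray:
    """Place d with |cd| = l, angle(b,c,d) = alpha, dihedral(a,b,c,d) = tau."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # collinear frame: any perpendicular will do
        n = np.cross(bc, [1.0, 0.0, 0.0])
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            n = np.cross(bc, [0.0, 1.0, 0.0])
            nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_dir = (-math.cos(alpha) * bc
             + math.sin(alpha) * (math.cos(tau) * m + math.sin(tau) * n))
    return c + l * d_dir


def measure_internal(positions: np.ndarray):
    """Recover (bond_lengths, bond_angles_deg, phi_rad per bond) from positions.

    ``phi`` is the dihedral offset from trans, in (-pi, pi]; bonds 0 and
    n_bonds-1 carry phi = 0 by convention (no dihedral defined).
    """
    pos = np.asarray(positions, dtype=float)
    vecs = np.diff(pos, axis=0)
    lengths = np.linalg.norm(vecs, axis=1)
    u = vecs / lengths[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", -u[:-1], u[1:]), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    nb = vecs.shape[0]
    phis = np.zeros(nb)
    for j in range(1, nb - 1):
        b1, b2, b3 = vecs[j - 1], vecs[j], vecs[j + 1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        tau = math.atan2(np.dot(m1, n2), np.dot(n1, n2))
        phi = math.pi - tau  # offset from trans, sign matching construction
        if phi > math.pi:
            phi -= 2.0 * math.pi
        phis[j] = phi
    return lengths, angles, phis


def contour_length(topology: ChainTopology, convention: str = "geometric") -> float:
    """Maximum extension used to normalize force-extension curves (nm).

    ``convention='geometric'`` (default) returns the all-trans end-to-end
    distance M * l0 * cos((pi - alpha0)/2), the true geometric maximum of
    the zig-zag chain.  ``convention='site'`` returns the variant built on
    the number of ionizable sites, N * l0 * cos((pi - alpha0)/2), sometimes
    used as the normalization constant of published extension curves.
    """
    proj = topology.l0 * math.cos((math.pi - topology.alpha0_rad) / 2.0)
    if convention == "geometric":
        return topology.n_bonds * proj
    if convention == "site":
        return topology.n_ionizable * proj
    raise ValueError("convention must be 'geometric' or 'site'")


def end_to_end_vector(coords: Coordinates) -> np.ndarray:
    """End-to-end vector r = r_last - r_first (nm)."""
    pos = coords.positions
    if pos.shape[0] < 2:
        raise ValueError("need at least two nodes")
    return pos[-1] - pos[0]


def pair_distances(coords: Coordinates) -> np.ndarray:
    """Full node-node distance matrix (nm)."""
    pos = coords.positions
    d = pos[:, None, :] - pos[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def write_xyz(fh: IO[str], topology: ChainTopology, coords: Coordinates,
              comment: str = "") -> None:
    """Write an XYZ snapshot; ionizable nodes tagged N, inert nodes C."""
    pos = coords.positions
    fh.write(f"{pos.shape[0]}\n{comment}\n")
    for kind, (x, y, z) in zip(topology.node_is_ionizable, pos):
        tag = "N" if kind else "C"
        fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")
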