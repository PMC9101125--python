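"""Additive molecular-mechanics potential with per-term decomposition.

The total energy of a conformation is

    E = sum_bonds Kb (b - b0)^2
      + sum_angles Ktheta (theta - theta0)^2
      + sum_{nonb ij} [ Aij/rij^12 - Bij/rij^6 + kC qi qj / rij ]
      + sum_dihedrals sum_{n=1..3} Vn [1 + cos(n phi - gamma)]

with kC = 332.0522 kcal A / (mol e^2), Lorentz-Berthelot combination for
Aij/Bij, nonbonded pairs restricted to atoms three or more bonds apart,
1-4 pairs divided by the scaling divisors (1.2 electrostatic, 2.0 van der
Waals by default), and no distance cutoff — the molecules here are small.
The dihedral sum is linear in the Vn coefficients at fixed coordinates,
which is what makes the torsion fit a linear least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .errors import (InvalidPeriodicity, MissingParameter, ShapeMismatch,
                     ZeroDistance)
from .io import (ConformerSet, ForceFieldParameters, MolecularTemplate,
                 canonical_quad)

COULOMB_CONSTANT = 332.0522   # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components in kcal/mol; ``total`` is their exact sum."""

    bond: float
    angle: float
    vdw: float
    coulomb: float
    dihedral: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.vdw + self.coulomb + self.dihedral


def dihedral_term_energy(phi_deg: float,
                         terms: Sequence[Tuple[int, float, float]]) -> float:
    """Fourier dihedral energy sum_n Vn [1 + cos(n phi - gamma)]."""
    e = 0.0
    for n, vn, gamma in terms:
        if n not in (1, 2, 3):
            raise InvalidPeriodicity(f"periodicity {n} not in {{1,2,3}}")
        if gamma not in (0.0, 180.0):
            raise InvalidPeriodicity(f"gamma {gamma} not in {{0,180}}")
        e += vn * (1.0 + np.cos(np.radians(n * phi_deg - gamma)))
    return float(e)


class Topology:
    """Indexed interaction lists for one template under one parameter set.

    Built once per (template, parameters) pair; ``evaluate`` then reduces to
    vectorized array arithmetic over frames.
    """

    def __init__(self, template: MolecularTemplate,
                 params: ForceFieldParameters,
                 charges: Optional[np.ndarray] = None):
        self.template = template
        self.params = params
        self.charges = (np.asarray(charges, float) if charges is not None
                        else template.charges)
        g = template.graph()
        types = template.atom_types

        # bonds
        self.bond_idx = np.array(template.bonds, dtype=int).reshape(-1, 2)
        kb, b0 = [], []
        for a, b in template.bonds:
            term = params.bond(types[a], types[b])
            if term is None:
                raise MissingParameter(f"bond {types[a]}-{types[b]}")
            kb.append(term[0])
            b0.append(term[1])
        self.bond_k = np.array(kb)
        self.bond_0 = np.array(b0)

        # angles: center j, neighbors i < k
        ang_idx, ka, t0 = [], [], []
        for j in g.nodes:
            nbrs = sorted(g.neighbors(j))
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    i, k = nbrs[x], nbrs[y]
                    term = params.angle(types[i], types[j], types[k])
                    if term is None:
                        raise MissingParameter(
                            f"angle {types[i]}-{types[j]}-{types[k]}")
                    ang_idx.append((i, j, k))
                    ka.append(term[0])
                    t0.append(np.radians(term[1]))
        self.angle_idx = np.array(ang_idx, dtype=int).reshape(-1, 3)
        self.angle_k = np.array(ka)
        self.angle_0 = np.array(t0)

        # proper dihedrals: every path i-j-k-l over each central bond
        self.dihedral_idx: List[Tuple[int, int, int, int]] = []
        self.dihedral_quads: List[Tuple[str, ...]] = []
        self.dihedral_terms: List[List[Tuple[int, float, float]]] = []
        for j, k in template.bonds:
            for i in g.neighbors(j):
                if i == k:
                    continue
                for l in g.neighbors(k):
                    if l == j or l == i:
                        continue
                    terms = params.dihedral(types[i], types[j],
                                            types[k], types[l])
                    if terms is None:
                        raise MissingParameter(
                            "dihedral "
                            f"{types[i]}-{types[j]}-{types[k]}-{types[l]}")
                    self.dihedral_idx.append((i, j, k, l))
                    self.dihedral_quads.append(canonical_quad(
                        (types[i], types[j], types[k], types[l])))
                    self.dihedral_terms.append(list(terms))
        self._dih_idx_arr = np.array(self.dihedral_idx, dtype=int).reshape(-1, 4)

        # nonbonded pairs: graph distance >= 3; distance == 3 is scaled 1-4
        dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
        n = template.n_atoms
        pairs, scale14 = [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = dist.get(i, {}).get(j, 99)
                if d >= 3:
                    pairs.append((i, j))
                    scale14.append(d == 3)
        self.pair_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        scale14 = np.array(scale14, dtype=bool)
        rstar = np.empty(n)
        eps = np.empty(n)
        for i, t in enumerate(types):
            if t not in params.lj:
                raise MissingParameter(f"Lennard-Jones type {t}")
            rstar[i], eps[i] = params.lj[t]
        ii, jj = self.pair_idx[:, 0], self.pair_idx[:, 1]
        rij = rstar[ii] + rstar[jj]
        eij = np.sqrt(eps[ii] * eps[jj])
        self.pair_A = eij * rij ** 12
        self.pair_B = 2.0 * eij * rij ** 6
        self.pair_qq = (COULOMB_CONSTANT * self.charges[ii] * self.charges[jj])
        vdw_div = np.where(scale14, params.scnb, 1.0)
        ee_div = np.where(scale14, params.scee, 1.0)
        self.pair_A = self.pair_A / vdw_div
        self.pair_B = self.pair_B / vdw_div
        self.pair_qq = self.pair_qq / ee_div

    # ---- geometry kernels (vectorized over interaction lists) ----

    def _distances(self, coords, idx):
        return np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)

    def _angles(self, coords):
        i, j, k = (self.angle_idx[:, c] for c in range(3))
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    def dihedral_angles(self, coords) -> np.ndarray:
        """Signed torsion angle (degrees) of every proper dihedral."""
        idx = self._dih_idx_arr
        if len(idx) == 0:
            return np.empty(0)
        p = coords[idx]          # (ndih, 4, 3)
        b1 = p[:, 1] - p[:, 0]
        b2 = p[:, 2] - p[:, 1]
        b3 = p[:, 3] - p[:, 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
        m = np.cross(n1, b2n)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m, n2)
        return np.degrees(np.arctan2(y, x))

    def evaluate(self, coords: np.ndarray) -> EnergyBreakdown:
        coords = np.asarray(coords, float)
        if coords.shape != (self.template.n_atoms, 3):
            raise ShapeMismatch(
                f"coords shape {coords.shape}, expected "
                f"({self.template.n_atoms}, 3)")
        b = self._distances(coords, self.bond_idx)
        e_bond = float(np.sum(self.bond_k * (b - self.bond_0) ** 2))
        th = self._angles(coords)
        e_angle = float(np.sum(self.angle_k * (th - self.angle_0) ** 2))
        r = self._distances(coords, self.pair_idx)
        if np.any(r < 1e-9):
            raise ZeroDistance("overlapping nonbonded atoms")
        e_vdw = float(np.sum(self.pair_A / r ** 12 - self.pair_B / r ** 6))
        e_coul = float(np.sum(self.pair_qq / r))
        phis = self.dihedral_angles(coords)
        e_dih = 0.0
        for phi, terms in zip(phis, self.dihedral_terms):
            e_dih += dihedral_term_energy(float(phi), terms)
        return EnergyBreakdown(bond=e_bond, angle=e_angle, vdw=e_vdw,
                               coulomb=e_coul, dihedral=e_dih)


def evaluate(template: MolecularTemplate, coords: np.ndarray,
             params: ForceFieldParameters,
             charges: Optional[np.ndarray] = None) -> EnergyBreakdown:
    """Single-frame energy with per-term decomposition."""
    return Topology(template, params, charges=charges).evaluate(coords)


def batch_energies(template: MolecularTemplate, frames: ConformerSet,
                   params: ForceFieldParameters,
                   charges: Optional[np.ndarray] = None
                   ) -> List[EnergyBreakdown]:
    """Element-wise :func:`evaluate` over a conformer set, order preserved."""
    topo = Topology(template, params, charges=charges)
    out = []
    for i, frame in enumerate(frames.frames):
        try:
            out.append(topo.evaluate(frame))
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return out
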