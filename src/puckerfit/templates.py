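"""Synthetic furanose test-set construction.

The fitting workflow is exercised on a set of 24 synthetic tetrahydrofuran
templates carrying fluoro and hydroxy substituents at the C2'/C3' positions
in all up/down stereochemistries, including the gem-difluoro patterns.  The
set is built programmatically from idealized geometry (planar closed ring,
tetrahedral substitution) with GAFF-style atom types assigned by simple
environment rules; it is a synthetic stand-in for a published test set of
mono- and difluoro furanoses, constructed so that all seven fitted
fluoro/hydroxy dihedral classes occur in at least one template.

Charges are simple per-type values balanced to net zero on the carbons:
they play the role of the externally supplied initial (pre-polarization)
charge set that the workflow refines.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import least_squares

from .geometry import RingAtomOrder
from .io import ForceFieldParameters, MolecularTemplate, read_frcmod

# ring bond targets, Angstrom: C1'-C2', C2'-C3', C3'-C4', C4'-O4', O4'-C1'
_RING_BONDS = [1.526, 1.526, 1.526, 1.428, 1.418]
_CH = 1.092
_CF = 1.350
_CO = 1.423
_OH = 0.973
_HALF_TET = np.radians(54.75)   # half the tetrahedral angle

# per-type base charges (e); carbons balance the remainder
_BASE_Q = {"os": -0.40, "oh": -0.60, "ho": 0.42, "f": -0.22,
           "hc": 0.05, "h1": 0.07, "h2": 0.09}

# substitution patterns: (name, (C2'-up, C2'-down), (C3'-up, C3'-down))
_SUBS = ["H", "F", "OH"]


def substitution_patterns() -> List[Tuple[str, Tuple[str, str], Tuple[str, str]]]:
    """The 24 fluoro/hydroxy substitution patterns of the test set."""
    pats = []
    # 4 mono-fluoro (2'/3' x up/down)
    pats.append(("T01", ("F", "H"), ("H", "H")))
    pats.append(("T02", ("H", "F"), ("H", "H")))
    pats.append(("T03", ("H", "H"), ("F", "H")))
    pats.append(("T04", ("H", "H"), ("H", "F")))
    # 16 disubstituted: {F, OH} x {F, OH} at 2'/3', all four stereochemistries
    i = 5
    for s2 in ("F", "OH"):
        for s3 in ("F", "OH"):
            for u2 in (0, 1):
                for u3 in (0, 1):
                    sub2 = (s2, "H") if u2 == 0 else ("H", s2)
                    sub3 = (s3, "H") if u3 == 0 else ("H", s3)
                    pats.append((f"T{i:02d}", sub2, sub3))
                    i += 1
    # 2 gem-difluoro
    pats.append(("T21", ("F", "F"), ("H", "H")))
    pats.append(("T22", ("H", "H"), ("F", "F")))
    # 2 mono-hydroxy
    pats.append(("T23", ("OH", "H"), ("H", "H")))
    pats.append(("T24", ("H", "H"), ("OH", "H")))
    return pats


def _planar_ring_coords() -> np.ndarray:
    """A closed planar 5-ring with the target bond lengths (z = 0)."""
    # start from a regular pentagon and least-squares the bond lengths in 2D
    r0 = 1.45 / (2 * np.sin(np.pi / 5))
    ang = 2 * np.pi * np.arange(5) / 5
    start = np.column_stack([r0 * np.cos(ang), r0 * np.sin(ang)])

    def resid(flat):
        r = flat.reshape(5, 2)
        res = []
        for i in range(5):
            res.append(np.linalg.norm(r[(i + 1) % 5] - r[i]) - _RING_BONDS[i])
        # soft regularizer keeps the solution near the pentagon
        res.extend(0.01 * (flat - start.ravel()))
        return np.array(res)

    sol = least_squares(resid, start.ravel(), method="lm", xtol=1e-15)
    xy = sol.x.reshape(5, 2)
    return np.column_stack([xy, np.zeros(5)])


def _tet_dirs(r, k):
    """The two exocyclic tetrahedral directions (up, down) at ring atom k."""
    u = r[(k + 1) % 5] - r[k]
    v = r[(k - 1) % 5] - r[k]
    e_a = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
    e_a /= np.linalg.norm(e_a)
    e_b = np.array([0.0, 0.0, 1.0])     # ring normal of the planar ring
    up = np.cos(_HALF_TET) * e_a + np.sin(_HALF_TET) * e_b
    dn = np.cos(_HALF_TET) * e_a - np.sin(_HALF_TET) * e_b
    return up, dn


def build_template(name: str, sub2: Tuple[str, str],
                   sub3: Tuple[str, str]) -> MolecularTemplate:
    """Construct one substituted tetrahydrofuran template."""
    ring = _planar_ring_coords()
    # ring order C1', C2', C3', C4', O4' maps onto ring rows 0..4
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    elements = ["C", "C", "C", "C", "O"]
    coords = [ring[i] for i in range(5)]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]

    subs_by_ring_atom = {0: ("H", "H"), 1: sub2, 2: sub3, 3: ("H", "H")}

    def add_atom(nm, el, xyz, anchor):
        names.append(nm)
        elements.append(el)
        coords.append(np.asarray(xyz, float))
        bonds.append((anchor, len(names) - 1))
        return len(names) - 1

    for k in (0, 1, 2, 3):
        up, dn = _tet_dirs(ring, k)
        pos_label = f"{k + 1}'"
        for slot, d in (("u", up), ("d", dn)):
            sub = subs_by_ring_atom[k][0 if slot == "u" else 1]
            if sub == "H":
                add_atom(f"H{pos_label}{slot}", "H", ring[k] + _CH * d, k)
            elif sub == "F":
                add_atom(f"F{pos_label}", "F", ring[k] + _CF * d, k)
            elif sub == "OH":
                o = add_atom(f"O{pos_label}", "O", ring[k] + _CO * d, k)
                # H at 108 deg from the O->C direction, tilted off the shell
                v = d                                   # C->O unit vector
                p = np.cross(v, ring[(k + 1) % 5] - ring[k])
                p /= np.linalg.norm(p)
                h_dir = 0.309 * v + 0.951 * p
                add_atom(f"HO{pos_label}", "H",
                         np.asarray(coords[o]) + _OH * h_dir, o)
            else:  # pragma: no cover
                raise ValueError(sub)

    # GAFF-style atom types from the local environment
    atom_types = []
    nbrs: Dict[int, List[int]] = {i: [] for i in range(len(names))}
    for a, b in bonds:
        nbrs[a].append(b)
        nbrs[b].append(a)
    for i, el in enumerate(elements):
        if el == "C":
            atom_types.append("c3")
        elif el == "F":
            atom_types.append("f")
        elif el == "O":
            atom_types.append("os" if i == 4 else "oh")
        else:  # hydrogen
            anchor = nbrs[i][0]
            if elements[anchor] == "O":
                atom_types.append("ho")
            else:
                n_en = sum(elements[j] in ("O", "F", "N")
                           for j in nbrs[anchor])
                atom_types.append({0: "hc", 1: "h1", 2: "h2"}.get(n_en, "h3"))

    charges = np.array([_BASE_Q.get(t, 0.0) for t in atom_types])
    carbons = [i for i, t in enumerate(atom_types) if t == "c3"]
    charges[carbons] = -charges.sum() / len(carbons)
    charges[0] -= charges.sum()         # kill float residue exactly

    return MolecularTemplate(
        name=name, atom_names=names, elements=elements, atom_types=atom_types,
        charges=charges, coords=np.array(coords), bonds=bonds,
        net_charge=0.0, ring_order=RingAtomOrder((0, 1, 2, 3, 4)))


def build_test_set() -> List[MolecularTemplate]:
    """All 24 templates of the synthetic fluoro/hydroxy furanose test set."""
    return [build_template(n, s2, s3) for n, s2, s3 in substitution_patterns()]


def default_parameters() -> ForceFieldParameters:
    """GAFF-like starting parameters covering every type in the test set.

    Values are representative of a general small-molecule force field (they
    are the refinement starting point, not a verbatim published set).
    """
    with resources.as_file(
            resources.files("puckerfit.data") / "gaff_like.frcmod") as p:
        return read_frcmod(p)
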