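"""Molecular templates, force-field parameter files, conformer sets and
reference-energy tables.

Formats handled here: SYBYL mol2 (templates: names, GAFF-style atom types,
partial charges, bonds), PDB single/multi-model and multi-frame XYZ
(trajectories; read through MDAnalysis), the Amber frcmod parameter dialect,
and reference energies as a tab-separated table.  Coordinates are Angstrom,
energies kcal/mol, angles degrees at every interface.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (ChargeMismatch, InconsistentFrame, ParseError,
                     RingNotFound, UnsupportedPhase)
from .geometry import PuckerState, RingAtomOrder

_ELECTRONEGATIVE = {"O", "N", "F", "Cl", "Br", "S"}


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if (a,) <= (b,) else (b, a)


def canonical_triple(t: Sequence[str]) -> Tuple[str, ...]:
    t = tuple(t)
    return min(t, t[::-1])


def canonical_quad(q: Sequence[str]) -> Tuple[str, ...]:
    """Canonical dihedral key: lexicographically smaller of forward/reverse."""
    q = tuple(q)
    return min(q, q[::-1])


# ---------------------------------------------------------------------------
# MolecularTemplate
# ---------------------------------------------------------------------------

@dataclass
class MolecularTemplate:
    """A small molecule with types, charges, coordinates and a furanose ring.

    Attributes
    ----------
    name : str
        Template identifier (e.g. ``"T01"``).
    atom_names, elements, atom_types : list of str
        Per-atom name, element symbol and force-field atom type.
    charges : ndarray
        Partial charges in elementary charge units; must sum to
        ``net_charge`` within 1e-6.
    coords : ndarray, shape (n, 3)
        Cartesian coordinates in Angstrom.
    bonds : list of (int, int)
        Zero-based bonded pairs; the bond graph must be connected.
    ring_order : RingAtomOrder
        Indices of C1', C2', C3', C4', O4' in that chemical order.
    """

    name: str
    atom_names: List[str]
    elements: List[str]
    atom_types: List[str]
    charges: np.ndarray
    coords: np.ndarray
    bonds: List[Tuple[int, int]]
    net_charge: float = 0.0
    ring_order: Optional[RingAtomOrder] = None

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.atom_types)
                == len(self.charges) == len(self.coords) == n):
            raise ValueError("inconsistent per-atom array lengths")
        if abs(self.charges.sum() - self.net_charge) > 1e-6:
            raise ChargeMismatch(
                f"{self.name}: charges sum to {self.charges.sum():.6f}, "
                f"declared net {self.net_charge:g}")
        if self.ring_order is None:
            self.ring_order = detect_ring(self)
        self._validate_ring()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def _validate_ring(self):
        g = self.graph()
        if not nx.is_connected(g):
            raise ValueError(f"{self.name}: bond graph is not connected")
        idx = self.ring_order.indices
        for k in range(5):
            if not g.has_edge(idx[k], idx[(k + 1) % 5]):
                raise RingNotFound(
                    f"{self.name}: ring order atoms {idx[k]} and "
                    f"{idx[(k + 1) % 5]} are not bonded")

    def exocyclic_anchors(self) -> Dict[int, List[int]]:
        """Map ring-atom index -> non-ring atoms anchored to it.

        Every non-ring atom is assigned to the ring atom through which its
        bond path enters the ring (substituents ride with that anchor when
        the ring is re-embedded).
        """
        g = self.graph()
        ring = set(self.ring_order.indices)
        g_exo = g.copy()
        # remove ring-ring edges so components hang off single ring atoms
        for k in range(5):
            a = self.ring_order.indices[k]
            b = self.ring_order.indices[(k + 1) % 5]
            g_exo.remove_edge(a, b)
        anchors: Dict[int, List[int]] = {}
        for comp in nx.connected_components(g_exo):
            ring_members = comp & ring
            if len(ring_members) != 1:
                continue
            anchor = ring_members.pop()
            exo = sorted(comp - {anchor})
            if exo:
                anchors[anchor] = exo
        return anchors

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"])


def detect_ring(template: MolecularTemplate) -> RingAtomOrder:
    """Auto-detect the furanose ring: the unique 5-cycle containing exactly
    one oxygen.  C1' is taken as the ring-oxygen neighbor carrying the
    greater number of electronegative exocyclic substituents (the anomeric
    carbon); ties fall to the lower atom index.
    """
    g = nx.Graph()
    g.add_nodes_from(range(template.n_atoms))
    g.add_edges_from(template.bonds)
    cycles = [c for c in nx.cycle_basis(g) if len(c) == 5]
    cycles = [c for c in cycles
              if sum(template.elements[i] == "O" for i in c) == 1]
    if len(cycles) != 1:
        raise RingNotFound(
            f"{template.name}: expected one 5-cycle with a single oxygen, "
            f"found {len(cycles)}")
    cyc = cycles[0]
    o4 = next(i for i in cyc if template.elements[i] == "O")
    return _order_ring(template, g, cyc, o4)


def _order_ring(template, g, cyc, o4) -> RingAtomOrder:
    pos = cyc.index(o4)
    nbrs = (cyc[(pos - 1) % 5], cyc[(pos + 1) % 5])

    def anomeric_score(c):
        return sum(template.elements[j] in _ELECTRONEGATIVE
                   for j in g.neighbors(c) if j not in cyc)

    s0, s1 = anomeric_score(nbrs[0]), anomeric_score(nbrs[1])
    if (s0, -nbrs[0]) >= (s1, -nbrs[1]):
        c1 = nbrs[0]
    else:
        c1 = nbrs[1]
    # walk the cycle from C1' away from O4'
    order = [c1]
    prev = o4
    cur = c1
    cyc_set = set(cyc)
    for _ in range(3):
        nxt = next(j for j in g.neighbors(cur)
                   if j in cyc_set and j != prev)
        order.append(nxt)
        prev, cur = cur, nxt
    order.append(o4)
    return RingAtomOrder(tuple(order))


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

_MOL2_EL_FROM_TYPE = {
    "f": "F", "cl": "Cl", "br": "Br", "i": "I", "s": "S", "p": "P",
}


def _element_from(name: str, mol2_type: str) -> str:
    base = mol2_type.split(".")[0]
    if base[:1].isupper():
        return base
    low = base.lower()
    if low in _MOL2_EL_FROM_TYPE:
        return _MOL2_EL_FROM_TYPE[low]
    if low.startswith("h"):
        return "H"
    if low.startswith("c"):
        return "C"
    if low.startswith("o"):
        return "O"
    if low.startswith("n"):
        return "N"
    # fall back to the leading letters of the atom name
    letters = "".join(ch for ch in name if ch.isalpha())
    return letters[:1].upper() or "C"


def read_template(path, fmt: Optional[str] = None,
                  net_charge: Optional[float] = None,
                  ring_order: Optional[RingAtomOrder] = None) -> MolecularTemplate:
    """Read a molecular template from a mol2 (or single-model PDB) file.

    Atom types are taken verbatim from the mol2 atom-type column.  The net
    charge defaults to the nearest integer of the charge-column sum; a sum
    further than 1e-3 e from that integer raises :class:`ChargeMismatch`.
    The furanose ring is auto-detected unless ``ring_order`` is given.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "mol2":
        return _read_mol2(path, net_charge, ring_order)
    if fmt == "pdb":
        return _read_pdb_template(path, net_charge, ring_order)
    raise ParseError(f"unsupported template format: {fmt}")


def _read_mol2(path, net_charge, ring_order) -> MolecularTemplate:
    lines = Path(path).read_text().splitlines()
    section = None
    mol_name = Path(path).stem
    names, types, charges, coords, bonds = [], [], [], [], []
    mol_lines = []
    for ln_no, raw in enumerate(lines, 1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            continue
        if not line or line.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_lines.append(line)
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln_no}: short mol2 ATOM line")
            names.append(parts[1])
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            types.append(parts[5])
            charges.append(float(parts[8]) if len(parts) > 8 else 0.0)
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln_no}: short mol2 BOND line")
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
    if mol_lines:
        mol_name = mol_lines[0]
    if not names:
        raise ParseError(f"{path}: no atoms found")
    qsum = float(np.sum(charges))
    if net_charge is None:
        net_charge = round(qsum)
        if abs(qsum - net_charge) > 1e-3:
            raise ChargeMismatch(
                f"{path}: charge column sums to {qsum:.4f}, not an integer "
                f"net charge")
    elements = [_element_from(n, t) for n, t in zip(names, types)]
    return MolecularTemplate(
        name=mol_name, atom_names=names, elements=elements, atom_types=types,
        charges=np.array(charges), coords=np.array(coords), bonds=bonds,
        net_charge=float(net_charge), ring_order=ring_order)


def write_template(path, template: MolecularTemplate) -> None:
    """Write a template as SYBYL mol2 (charges in the USER_CHARGES column)."""
    out = _io.StringIO()
    out.write("@<TRIPOS>MOLECULE\n")
    out.write(f"{template.name}\n")
    out.write(f"{template.n_atoms} {len(template.bonds)} 1 0 0\n")
    out.write("SMALL\nUSER_CHARGES\n")
    out.write("@<TRIPOS>ATOM\n")
    for i in range(template.n_atoms):
        x, y, z = template.coords[i]
        out.write(
            f"{i + 1:>7d} {template.atom_names[i]:<8s}"
            f"{x:>10.4f}{y:>10.4f}{z:>10.4f} "
            f"{template.atom_types[i]:<6s} 1 LIG {template.charges[i]:>12.6f}\n")
    out.write("@<TRIPOS>BOND\n")
    for k, (a, b) in enumerate(template.bonds, 1):
        out.write(f"{k:>6d}{a + 1:>6d}{b + 1:>6d} 1\n")
    Path(path).write_text(out.getvalue())


def _read_pdb_template(path, net_charge, ring_order) -> MolecularTemplate:
    raise ParseError(
        "PDB templates carry no atom types/charges/bonds; supply mol2")


# ---------------------------------------------------------------------------
# ForceFieldParameters / frcmod
# ---------------------------------------------------------------------------

@dataclass
class ForceFieldParameters:
    """Typed constants of the additive potential.

    ``bonds``: pair key -> (Kb [kcal/mol/A^2], b0 [A]);
    ``angles``: triple key -> (Ktheta [kcal/mol/rad^2], theta0 [deg]);
    ``dihedrals``: canonical quad key -> list of (n, Vn [kcal/mol], gamma [deg]);
    ``lj``: type -> (rstar [A], eps [kcal/mol]);
    ``scee``/``scnb``: 1-4 electrostatic and van der Waals scaling divisors.
    """

    bonds: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    angles: Dict[Tuple[str, ...], Tuple[float, float]] = field(default_factory=dict)
    dihedrals: Dict[Tuple[str, ...], List[Tuple[int, float, float]]] = field(default_factory=dict)
    lj: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    masses: Dict[str, float] = field(default_factory=dict)
    scee: float = 1.2
    scnb: float = 2.0
    title: str = "puckerfit parameters"

    def copy(self) -> "ForceFieldParameters":
        return ForceFieldParameters(
            bonds=dict(self.bonds),
            angles=dict(self.angles),
            dihedrals={k: list(v) for k, v in self.dihedrals.items()},
            lj=dict(self.lj), masses=dict(self.masses),
            scee=self.scee, scnb=self.scnb, title=self.title)

    # --- lookups (specific keys shadow wildcards) ---

    def bond(self, a: str, b: str):
        return self.bonds.get(canonical_pair(a, b))

    def angle(self, a: str, b: str, c: str):
        return self.angles.get(canonical_triple((a, b, c)))

    def dihedral(self, a: str, b: str, c: str, d: str):
        key = canonical_quad((a, b, c, d))
        if key in self.dihedrals:
            return self.dihedrals[key]
        wkey = canonical_quad(("X", b, c, "X"))
        return self.dihedrals.get(wkey)

    def set_dihedral(self, quad, terms) -> None:
        self.dihedrals[canonical_quad(quad)] = [
            (int(n), float(v), float(g)) for n, v, g in terms]


def _split_types(field_str: str, n: int):
    parts = [p.strip() for p in field_str.split("-")]
    if len(parts) != n or any(not p for p in parts):
        raise ValueError(field_str)
    return tuple(parts)


def read_frcmod(path, strict_phase: bool = True) -> ForceFieldParameters:
    """Parse an Amber frcmod parameter-modification file.

    DIHE lines carry (IDIVF, PK, PHASE, PN); the stored barrier is
    Vn = PK / IDIVF and a negative PN flags additional Fourier terms for the
    same type quadruple on following lines.  Multi-term dihedrals are
    aggregated under one canonical key.  PHASE values outside {0, 180} raise
    :class:`UnsupportedPhase` unless ``strict_phase`` is False.
    """
    params = ForceFieldParameters()
    section = None
    lines = Path(path).read_text().splitlines()
    if lines:
        params.title = lines[0].strip()
    widths = {"BOND": 5, "ANGLE": 8, "DIHE": 11, "IMPROPER": 11}
    for ln_no, raw in enumerate(lines[1:], 2):
        stripped = raw.strip()
        upper = stripped.upper()
        if upper in ("MASS", "BOND", "ANGLE", "DIHE", "NONBON", "NONB",
                     "IMPROPER"):
            section = "NONBON" if upper == "NONB" else upper
            continue
        if not stripped:
            continue
        try:
            if section == "MASS":
                parts = stripped.split()
                params.masses[parts[0]] = float(parts[1])
            elif section == "BOND":
                w = widths["BOND"]
                types = _split_types(raw[:w], 2)
                kb, b0 = (float(x) for x in raw[w:].split()[:2])
                params.bonds[canonical_pair(*types)] = (kb, b0)
            elif section == "ANGLE":
                w = widths["ANGLE"]
                types = _split_types(raw[:w], 3)
                kt, t0 = (float(x) for x in raw[w:].split()[:2])
                params.angles[canonical_triple(types)] = (kt, t0)
            elif section == "DIHE":
                w = widths["DIHE"]
                types = _split_types(raw[:w], 4)
                idivf, pk, phase, pn = (float(x) for x in raw[w:].split()[:4])
                if phase not in (0.0, 180.0):
                    if strict_phase:
                        raise UnsupportedPhase(
                            f"{path}:{ln_no}: PHASE {phase} not in {{0,180}}")
                key = canonical_quad(types)
                vn = pk / idivf
                n = int(round(abs(pn)))
                params.dihedrals.setdefault(key, []).append((n, vn, phase))
            elif section == "NONBON":
                parts = stripped.split()
                params.lj[parts[0]] = (float(parts[1]), float(parts[2]))
            elif section == "IMPROPER":
                continue  # impropers are out of scope; skip silently
        except UnsupportedPhase:
            raise
        except Exception as exc:
            raise ParseError(f"{path}:{ln_no}: {exc!r} in line {raw!r}") from exc
    return params


def write_frcmod(path, params: ForceFieldParameters) -> None:
    """Write parameters in the Amber frcmod dialect (fixed-width columns,
    PK = Vn with IDIVF = 1, negative PN marks continuation terms)."""
    out = _io.StringIO()
    out.write(params.title + "\n")
    out.write("MASS\n")
    for t, m in params.masses.items():
        out.write(f"{t:<2s} {m:>10.3f}\n")
    out.write("\nBOND\n")
    for (a, b), (kb, b0) in params.bonds.items():
        out.write(f"{a:<2s}-{b:<2s}  {kb:>8.2f}  {b0:>8.4f}\n")
    out.write("\nANGLE\n")
    for key, (kt, t0) in params.angles.items():
        a, b, c = key
        out.write(f"{a:<2s}-{b:<2s}-{c:<2s}  {kt:>8.3f}  {t0:>8.3f}\n")
    out.write("\nDIHE\n")
    for key, terms in params.dihedrals.items():
        a, b, c, d = key
        for i, (n, vn, gamma) in enumerate(terms):
            pn = -float(n) if i < len(terms) - 1 else float(n)
            out.write(
                f"{a:<2s}-{b:<2s}-{c:<2s}-{d:<2s}   1  {vn:>10.5f}  "
                f"{gamma:>8.3f}  {pn:>6.1f}\n")
    out.write("\nNONBON\n")
    for t, (rstar, eps) in params.lj.items():
        out.write(f"  {t:<2s}  {rstar:>8.4f}  {eps:>8.4f}\n")
    out.write("\n")
    Path(path).write_text(out.getvalue())


# ---------------------------------------------------------------------------
# ConformerSet
# ---------------------------------------------------------------------------

@dataclass
class ConformerSet:
    """Ordered coordinate frames with per-frame provenance tags."""

    frames: np.ndarray                       # (n_frames, n_atoms, 3)
    template_ids: List[str]
    window_indices: List[int]
    targets: List[Optional[PuckerState]]
    provenance: List[str]
    seed: Optional[int] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        n = len(self.frames)
        for name in ("template_ids", "window_indices", "targets", "provenance"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != frame count")

    def __len__(self) -> int:
        return len(self.frames)

    def subset(self, idx) -> "ConformerSet":
        idx = np.asarray(idx, dtype=int)
        return ConformerSet(
            frames=self.frames[idx],
            template_ids=[self.template_ids[i] for i in idx],
            window_indices=[self.window_indices[i] for i in idx],
            targets=[self.targets[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
            seed=self.seed)

    @staticmethod
    def concatenate(sets: Sequence["ConformerSet"]) -> "ConformerSet":
        return ConformerSet(
            frames=np.concatenate([s.frames for s in sets]),
            template_ids=sum([s.template_ids for s in sets], []),
            window_indices=sum([s.window_indices for s in sets], []),
            targets=sum([s.targets for s in sets], []),
            provenance=sum([s.provenance for s in sets], []),
            seed=sets[0].seed if sets else None)


def read_trajectory(path, fmt: Optional[str] = None) -> ConformerSet:
    """Read a multi-model PDB or multi-frame XYZ file into a ConformerSet
    (provenance ``"external"``)."""
    import MDAnalysis as mda
    import warnings
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in ("pdb", "xyz"):
        raise ParseError(f"unsupported trajectory format: {fmt}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            frames = np.array([u.atoms.positions.copy().astype(float)
                               for _ in u.trajectory])
    except Exception as exc:
        raise InconsistentFrame(f"{path}: {exc}") from exc
    n = len(frames)
    return ConformerSet(
        frames=frames,
        template_ids=[path.stem] * n,
        window_indices=[-1] * n,
        targets=[None] * n,
        provenance=["external"] * n)


def write_trajectory(path, conformers: ConformerSet,
                     template: MolecularTemplate,
                     fmt: Optional[str] = None) -> None:
    """Write frames as multi-model PDB or multi-frame XYZ."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if conformers.frames.shape[1] != template.n_atoms:
        raise InconsistentFrame("frame atom count != template atom count")
    out = _io.StringIO()
    if fmt == "pdb":
        for m, frame in enumerate(conformers.frames, 1):
            out.write(f"MODEL     {m:>4d}\n")
            for i in range(template.n_atoms):
                x, y, z = frame[i]
                name = template.atom_names[i].replace("'", "")[:4]
                out.write(
                    f"ATOM  {i + 1:>5d} {name:<4s} LIG A   1    "
                    f"{x:>8.3f}{y:>8.3f}{z:>8.3f}  1.00  0.00          "
                    f"{template.elements[i]:>2s}\n")
            out.write("ENDMDL\n")
        out.write("END\n")
    elif fmt == "xyz":
        for m, frame in enumerate(conformers.frames):
            out.write(f"{template.n_atoms}\n")
            out.write(f"frame {m} template {conformers.template_ids[m]}\n")
            for i in range(template.n_atoms):
                x, y, z = frame[i]
                out.write(f"{template.elements[i]:<3s} "
                          f"{x:>14.8f} {y:>14.8f} {z:>14.8f}\n")
    else:
        raise ParseError(f"unsupported trajectory format: {fmt}")
    path.write_text(out.getvalue())


# ---------------------------------------------------------------------------
# ReferenceEnergyTable
# ---------------------------------------------------------------------------

@dataclass
class ReferenceEnergyTable:
    """Per-frame reference (QM-like) energies in kcal/mol."""

    table: pd.DataFrame   # columns: template_id, frame_id, energy, environment

    REQUIRED = ("template_id", "frame_id", "energy", "environment")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not np.all(np.isfinite(self.table["energy"].to_numpy(float))):
            raise ValueError("non-finite reference energies")

    @property
    def energies(self) -> np.ndarray:
        return self.table["energy"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


def read_reference_energies(path) -> ReferenceEnergyTable:
    df = pd.read_csv(path, sep="\t")
    return ReferenceEnergyTable(df)


def write_reference_energies(path, ref: ReferenceEnergyTable) -> None:
    ref.table.to_csv(path, sep="\t", index=False,
                     float_format="%.10f")
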