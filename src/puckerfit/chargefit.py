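"""Atom-centered point-charge fitting to electrostatic-potential grids.

Charges are fit by constrained linear least squares: minimize the squared
misfit between the grid potentials and the Coulomb potential of the atomic
point charges, subject to the exact net-charge constraint enforced through
a Lagrange multiplier, with an optional harmonic restraint toward a prior
charge set.  Potentials are in kcal/(mol e) using the same electrostatic
constant as the energy model, so fitted charges are directly consistent
with it.

The implicitly-polarized (IpolQ) combination takes the midpoint of the
vacuum and solvated-environment fits, approximating the charge set of a
solute polarized halfway between gas phase and solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .energy import COULOMB_CONSTANT
from .errors import (Mismatch, ParseError, PointOnAtom, SingularSystem)
from .io import MolecularTemplate

#: grid points are never placed closer than this to any atom (A)
MIN_GRID_DISTANCE = 1.0


@dataclass
class ESPGrid:
    """Spatial points with electrostatic potentials for one environment.

    ``potentials`` are in kcal/(mol e); ``environment`` is ``"vacuum"`` or
    ``"solvated"``.
    """

    points: np.ndarray          # (m, 3) A
    potentials: np.ndarray      # (m,)
    environment: str
    template_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.potentials = np.asarray(self.potentials, float).ravel()
        if len(self.points) != len(self.potentials):
            raise Mismatch("point/potential count mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @staticmethod
    def concatenate(grids: Sequence["ESPGrid"]) -> "ESPGrid":
        envs = {g.environment for g in grids}
        if len(envs) != 1:
            raise Mismatch(f"cannot concatenate environments {envs}")
        return ESPGrid(
            points=np.concatenate([g.points for g in grids]),
            potentials=np.concatenate([g.potentials for g in grids]),
            environment=grids[0].environment,
            template_id=grids[0].template_id)


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) with an exact net charge."""

    charges: np.ndarray
    net_charge: float
    environment: str = "vacuum"

    def __post_init__(self):
        self.charges = np.asarray(self.charges, float).ravel()
        if abs(self.charges.sum() - self.net_charge) > 1e-8:
            raise Mismatch(
                f"charges sum to {self.charges.sum():.10f}, "
                f"declared net {self.net_charge:g}")

    def __len__(self) -> int:
        return len(self.charges)


def read_esp_grid(path) -> ESPGrid:
    """Read a whitespace (x, y, z, V) table; the one-line header names the
    environment and source template."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}: missing '# environment=... template=...' header")
    header = dict(tok.split("=", 1) for tok in lines[0][1:].split()
                  if "=" in tok)
    data = np.loadtxt(lines[1:], ndmin=2)
    if data.shape[1] != 4:
        raise ParseError(f"{path}: expected 4 columns, got {data.shape[1]}")
    return ESPGrid(points=data[:, :3], potentials=data[:, 3],
                   environment=header.get("environment", "vacuum"),
                   template_id=header.get("template", ""))


def write_esp_grid(path, grid: ESPGrid) -> None:
    with open(path, "w") as fh:
        fh.write(f"# environment={grid.environment} "
                 f"template={grid.template_id}\n")
        for p, v in zip(grid.points, grid.potentials):
            fh.write(f"{p[0]:>14.8f} {p[1]:>14.8f} {p[2]:>14.8f} "
                     f"{v:>16.10f}\n")


def make_shell_grid(template: MolecularTemplate, inner_scale: float = 1.4,
                    outer_scale: float = 2.0, density: float = 1.0,
                    seed: int = 0,
                    lj_radii: Optional[dict] = None) -> np.ndarray:
    """Seeded random points between scaled van-der-Waals shells.

    A point is kept when it lies at least ``inner_scale * r*`` (and never
    less than 1 A) from every atom and within ``outer_scale * r*`` of at
    least one atom.  ``density`` is the target point density in points/A^3
    of the sampling box, so doubling it doubles the expected count.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    radii = _atom_radii(template, lj_radii)
    coords = template.coords
    lo = coords.min(axis=0) - outer_scale * radii.max()
    hi = coords.max(axis=0) + outer_scale * radii.max()
    volume = float(np.prod(hi - lo))
    n_samples = max(int(round(density * volume)), 1)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    inner = np.maximum(inner_scale * radii, MIN_GRID_DISTANCE)
    keep = np.all(d >= inner[None, :], axis=1) & np.any(
        d <= outer_scale * radii[None, :], axis=1)
    return pts[keep]


def _atom_radii(template, lj_radii):
    default = {"C": 1.908, "O": 1.70, "F": 1.75, "H": 1.38, "N": 1.82}
    radii = np.empty(template.n_atoms)
    for i in range(template.n_atoms):
        if lj_radii and template.atom_types[i] in lj_radii:
            radii[i] = lj_radii[template.atom_types[i]][0]
        else:
            radii[i] = default.get(template.elements[i], 1.7)
        radii[i] = max(radii[i], 0.6)   # polar hydrogens get a floor
    return radii


def coulomb_design(points: np.ndarray, atom_coords: np.ndarray) -> np.ndarray:
    """Design matrix A with A[p, a] = kC / |r_p - r_a|."""
    d = np.linalg.norm(np.asarray(points, float)[:, None, :]
                       - np.asarray(atom_coords, float)[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise PointOnAtom("grid point coincides with an atom")
    return COULOMB_CONSTANT / d


@dataclass
class ChargeFitResults:
    """Fitted charge set with uncertainties and fit diagnostics."""

    charge_set: ChargeSet
    bse: np.ndarray
    rms_potential_error: float
    residuals: np.ndarray
    lagrange_multiplier: float

    @property
    def charges(self) -> np.ndarray:
        return self.charge_set.charges

    def summary(self) -> str:
        lines = ["ESP charge fit",
                 "==============",
                 f"atoms: {len(self.charge_set)}   grid points: "
                 f"{len(self.residuals)}",
                 f"net charge: {self.charge_set.net_charge:g} e   "
                 f"RMS potential error: {self.rms_potential_error:.6g} "
                 "kcal/(mol e)",
                 "",
                 f"{'atom':>5s} {'q (e)':>12s} {'se':>12s}"]
        for i, (q, s) in enumerate(zip(self.charges, self.bse)):
            lines.append(f"{i:>5d} {q:>12.6f} {s:>12.6f}")
        return "\n".join(lines)


class ESPChargeModel:
    """Constrained least-squares model for ESP charges.

    Multi-conformer fits are expressed by passing several (grid, coords)
    pairs; their design blocks are stacked (a joint fit over concatenated
    grids).
    """

    def __init__(self, grids, atom_coords, net_charge: float):
        if isinstance(grids, ESPGrid):
            grids = [grids]
            atom_coords = [atom_coords]
        if len(grids) != len(atom_coords):
            raise Mismatch("one coordinate set per grid required")
        if any(len(g) == 0 for g in grids):
            raise Mismatch("empty ESP grid")
        n_atoms = {np.asarray(c).shape[0] for c in atom_coords}
        if len(n_atoms) != 1:
            raise Mismatch("inconsistent atom counts across conformers")
        self.n_atoms = n_atoms.pop()
        self.A = np.concatenate([
            coulomb_design(g.points, c) for g, c in zip(grids, atom_coords)])
        self.V = np.concatenate([g.potentials for g in grids])
        if len(self.V) < self.n_atoms:
            raise Mismatch("fewer grid points than atoms")
        self.net_charge = float(net_charge)
        self.environment = grids[0].environment

    def fit(self, restraint_weight: float = 0.0,
            prior: Optional[ChargeSet] = None) -> ChargeFitResults:
        """Solve the KKT system of the constrained least-squares problem."""
        A, V = self.A, self.V
        n = self.n_atoms
        q0 = np.zeros(n) if prior is None else np.asarray(prior.charges, float)
        if len(q0) != n:
            raise Mismatch("prior charge count mismatch")
        H = A.T @ A + restraint_weight * np.eye(n)
        g = A.T @ V + restraint_weight * q0
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = H
        kkt[:n, n] = 1.0
        kkt[n, :n] = 1.0
        rhs = np.concatenate([g, [self.net_charge]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError as exc:
            raise SingularSystem(str(exc)) from exc
        if not np.all(np.isfinite(sol)):
            raise SingularSystem("non-finite KKT solution")
        q, lam = sol[:n], sol[n]
        q = q - (q.sum() - self.net_charge) / n     # exact constraint
        resid = V - A @ q
        rms = float(np.sqrt(np.mean(resid ** 2)))
        # covariance of the equality-constrained estimator
        dof = max(len(V) - n, 1)
        sigma2 = float(resid @ resid) / dof
        try:
            Hinv = np.linalg.inv(H)
            ones = np.ones((n, 1))
            corr = Hinv @ ones @ np.linalg.inv(ones.T @ Hinv @ ones) @ ones.T @ Hinv
            bse = np.sqrt(np.maximum(np.diag(sigma2 * (Hinv - corr)), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(n, np.nan)
        cs = ChargeSet(charges=q, net_charge=self.net_charge,
                       environment=self.environment)
        return ChargeFitResults(charge_set=cs, bse=bse,
                                rms_potential_error=rms, residuals=resid,
                                lagrange_multiplier=float(lam))


def fit_esp_charges(grid: ESPGrid, atom_coords: np.ndarray, net_charge: float,
                    restraint_weight: float = 0.0,
                    prior: Optional[ChargeSet] = None) -> ChargeSet:
    """Convenience wrapper returning just the fitted :class:`ChargeSet`."""
    model = ESPChargeModel(grid, atom_coords, net_charge)
    return model.fit(restraint_weight=restraint_weight, prior=prior).charge_set


def combine_ipolq(q_vac: ChargeSet, q_solv: ChargeSet) -> ChargeSet:
    """Implicitly polarized charges: the vacuum/solvated midpoint."""
    if len(q_vac) != len(q_solv):
        raise Mismatch("atom count mismatch")
    if abs(q_vac.net_charge - q_solv.net_charge) > 1e-8:
        raise Mismatch("net charge mismatch")
    return ChargeSet(charges=0.5 * (q_vac.charges + q_solv.charges),
                     net_charge=q_vac.net_charge, environment="ipolq")


def make_ipolq_refitter(grids, templates, restraint_weight: float = 1e-4):
    """Charge-refit stage for the alternating parameterization loop.

    ``grids`` maps template name -> (vacuum ESPGrid, solvated ESPGrid);
    ``templates`` maps name -> template.  The returned callable fits both
    environments (restrained weakly toward the current charges for
    stability) and returns the IpolQ midpoint charges per template.
    """

    def refit(problem) -> dict:
        out = {}
        for name, (g_vac, g_solv) in grids.items():
            tpl = templates[name]
            prior = ChargeSet(
                charges=problem.charges.get(name, tpl.charges),
                net_charge=tpl.net_charge)
            q_vac = fit_esp_charges(g_vac, tpl.coords, tpl.net_charge,
                                    restraint_weight=restraint_weight,
                                    prior=prior)
            q_solv = fit_esp_charges(g_solv, tpl.coords, tpl.net_charge,
                                     restraint_weight=restraint_weight,
                                     prior=prior)
            out[name] = combine_ipolq(q_vac, q_solv).charges
        return out

    return refit


def converged_charges(prev: ChargeSet, new: ChargeSet, tol: float = 0.05,
                      floor: float = 0.01) -> bool:
    """The 5% rule for charges: every atom's charge changed by less than
    ``tol`` relative to its previous value (with a ``floor`` e guard)."""
    if len(prev) != len(new):
        raise Mismatch("atom count mismatch")
    rel = np.abs(new.charges - prev.charges) / np.maximum(
        np.abs(prev.charges), floor)
    return bool(np.all(rel < tol))
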