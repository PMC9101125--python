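"""Self-consistent synthetic reference data for parameter-recovery testing.

A hidden "true" parameter set (randomized torsion coefficients for the
adjustable classes), hidden per-template charge sets with a polarization
perturbation, and hidden per-molecule energy offsets are drawn from a
seeded generator.  Reference energies are then exact MM energies under the
hidden parameters (plus optional Gaussian noise), and ESP grids are exact
Coulomb potentials of the hidden charges — so every fitting stage has an
analytically known right answer.  The per-molecule offset is deliberately
nonzero: a fitter without free offset columns cannot recover the hidden
coefficients, which is exactly the failure mode it guards against.

The oracle tests machinery, not chemistry: it makes no attempt to
reproduce real electron-correlation energetics or gauche/anomeric physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chargefit import ChargeSet, ESPGrid, coulomb_design, make_shell_grid
from .energy import Topology
from .io import (ConformerSet, ForceFieldParameters, MolecularTemplate,
                 ReferenceEnergyTable, canonical_quad)
from .torsionfit import DEFAULT_ADJUSTABLE, PERIODICITIES


@dataclass
class OracleSpec:
    """Hidden truth: parameters, charges, perturbations, offsets, noise."""

    params: ForceFieldParameters
    charges: Dict[str, np.ndarray]          # hidden vacuum charges per template
    delta_q: Dict[str, np.ndarray]          # polarization perturbation per template
    offsets: Dict[str, float]               # hidden per-molecule energy offset
    sigma: float = 0.0                      # Gaussian noise, kcal/mol
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def hidden_terms(self, key) -> list:
        return self.params.dihedrals[canonical_quad(key)]


def make_oracle(seed: int, templates: Sequence[MolecularTemplate],
                base_params: ForceFieldParameters,
                adjustable=DEFAULT_ADJUSTABLE,
                sigma: float = 0.0,
                vn_range: Tuple[float, float] = (0.05, 2.0),
                dq_range: float = 0.05,
                offset_range: float = 20.0) -> OracleSpec:
    """Draw a hidden truth, deterministically per seed.

    Hidden Vn are uniform in ``vn_range`` kcal/mol with gamma random in
    {0, 180} for each periodicity n = 1..3 of each adjustable class; the
    polarization perturbation is uniform in +/- ``dq_range`` e with exact
    zero sum per molecule; hidden offsets are uniform in
    +/- ``offset_range`` kcal/mol.
    """
    rng = np.random.default_rng(seed)
    params = base_params.copy()
    for key in adjustable:
        terms = []
        for n in PERIODICITIES:
            vn = rng.uniform(*vn_range)
            gamma = 180.0 * rng.integers(0, 2)
            terms.append((n, float(vn), float(gamma)))
        params.set_dihedral(key, terms)
    charges, delta_q, offsets = {}, {}, {}
    for tpl in templates:
        q = tpl.charges + rng.uniform(-0.02, 0.02, tpl.n_atoms)
        q -= (q.sum() - tpl.net_charge) / tpl.n_atoms
        charges[tpl.name] = q
        dq = rng.uniform(-dq_range, dq_range, tpl.n_atoms)
        dq -= dq.mean()                     # zero-sum polarization
        delta_q[tpl.name] = dq
        offsets[tpl.name] = float(rng.uniform(-offset_range, offset_range))
    return OracleSpec(params=params, charges=charges, delta_q=delta_q,
                      offsets=offsets, sigma=sigma, seed=int(seed))


def reference_energies(frames: ConformerSet, oracle: OracleSpec,
                       templates: Dict[str, MolecularTemplate],
                       environment: str = "vacuum",
                       noise_seed: Optional[int] = None,
                       charges: Optional[Dict[str, np.ndarray]] = None
                       ) -> ReferenceEnergyTable:
    """QM-like reference energies: exact MM under the hidden parameters and
    charges, plus the hidden per-molecule offset and N(0, sigma^2) noise.

    ``charges`` overrides the hidden vacuum charge sets per template (e.g.
    to emulate references consistent with the implicitly polarized
    charges)."""
    rng = np.random.default_rng(
        oracle.seed + 1 if noise_seed is None else noise_seed)
    topos: Dict[str, Topology] = {}
    rows = []
    for i, frame in enumerate(frames.frames):
        name = frames.template_ids[i]
        if name not in topos:
            q = (charges or {}).get(name, oracle.charges[name])
            topos[name] = Topology(templates[name], oracle.params,
                                   charges=q)
        e = topos[name].evaluate(frame).total + oracle.offsets[name]
        if oracle.sigma > 0:
            e += rng.normal(0.0, oracle.sigma)
        rows.append((name, i, e, environment))
    df = pd.DataFrame(rows, columns=["template_id", "frame_id", "energy",
                                     "environment"])
    return ReferenceEnergyTable(df)


def oracle_esp_grids(template: MolecularTemplate, oracle: OracleSpec,
                     density: float = 2.0, seed: Optional[int] = None
                     ) -> Tuple[ESPGrid, ESPGrid]:
    """Vacuum and solvated ESP grids over the same point set.

    Vacuum potentials come from the hidden vacuum charges; solvated
    potentials from the same charges plus the polarization perturbation,
    so the IpolQ midpoint has the analytic answer q_vac + delta_q / 2.
    """
    pts = make_shell_grid(template, density=density,
                          seed=oracle.seed if seed is None else seed,
                          lj_radii=oracle.params.lj)
    A = coulomb_design(pts, template.coords)
    q_vac = oracle.charges[template.name]
    q_solv = q_vac + oracle.delta_q[template.name]
    vac = ESPGrid(points=pts, potentials=A @ q_vac,
                  environment="vacuum", template_id=template.name)
    solv = ESPGrid(points=pts, potentials=A @ q_solv,
                   environment="solvated", template_id=template.name)
    return vac, solv


def expected_ipolq(oracle: OracleSpec, template_name: str) -> np.ndarray:
    """The analytic IpolQ answer for a noiseless oracle grid pair."""
    return (oracle.charges[template_name]
            + 0.5 * oracle.delta_q[template_name])
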