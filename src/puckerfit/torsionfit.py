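"""Torsion Fourier-coefficient fitting against reference energies.

The dihedral part of the additive potential is linear in the barrier
coefficients Vn at fixed coordinates, so fitting Vn to the residual between
reference (QM-like) and fixed-parameter MM energies is a linear
least-squares problem once the phase offset gamma is constrained to
{0, 180}: a term Vn [1 + cos(n phi - 180)] equals Vn [1 - cos(n phi)], so
the sign of an unconstrained linear coefficient on (1 + cos(n phi)) decides
gamma analytically — negative coefficients are reported as (|Vn|, 180),
which is exactly equivalent up to a constant absorbed by the mandatory
per-molecule energy offsets (reference and MM energy zeros are
incommensurate, so the offsets are always part of the model).

An outer refinement loop alternates the torsion fit with a charge-refit
stage and stops when both pass the 5%-change convergence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .energy import Topology
from .errors import (DimensionMismatch, KeyMismatch, NoAdjustableTerms,
                     NotConverged, RankDeficient)
from .io import (ConformerSet, ForceFieldParameters, MolecularTemplate,
                 canonical_quad)

#: the seven fluoro/hydroxy dihedral classes refined by default
DEFAULT_ADJUSTABLE: Tuple[Tuple[str, str, str, str], ...] = tuple(
    canonical_quad(q) for q in (
        ("c3", "c3", "c3", "oh"),
        ("c3", "c3", "c3", "f"),
        ("c3", "c3", "oh", "ho"),
        ("f", "c3", "c3", "f"),
        ("f", "c3", "c3", "oh"),
        ("f", "c3", "c3", "os"),
        ("oh", "c3", "c3", "oh"),
    ))

PERIODICITIES = (1, 2, 3)
#: relative-change floor (kcal/mol) guarding the 5% rule near zero
CONVERGENCE_FLOOR = 0.01


@dataclass
class FitProblem:
    """One joint torsion-fit problem over one or more templates.

    ``entries`` pairs each template with its conformer ensemble and the
    aligned per-frame reference energies (kcal/mol).  ``adjustable`` lists
    the dihedral type classes whose (Vn, gamma) are free; every other term
    of ``base_params`` stays fixed.
    """

    entries: List[Tuple[MolecularTemplate, ConformerSet, np.ndarray]]
    base_params: ForceFieldParameters
    adjustable: Sequence[Tuple[str, str, str, str]] = DEFAULT_ADJUSTABLE
    per_molecule_offset: bool = True
    charges: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.adjustable = tuple(canonical_quad(q) for q in self.adjustable)
        if not self.adjustable:
            raise NoAdjustableTerms("no adjustable dihedral classes")
        for tpl, conf, ref in self.entries:
            if len(conf) != len(np.asarray(ref)):
                raise DimensionMismatch(
                    f"{tpl.name}: {len(conf)} frames vs "
                    f"{len(np.asarray(ref))} reference energies")

    def molecule_names(self) -> List[str]:
        return [tpl.name for tpl, _, _ in self.entries]


def _zeroed_params(params: ForceFieldParameters,
                   adjustable) -> ForceFieldParameters:
    """Copy of ``params`` with the adjustable classes explicitly emptied
    (an empty specific entry shadows any wildcard at lookup)."""
    out = params.copy()
    for key in adjustable:
        out.dihedrals[canonical_quad(key)] = []
    return out


def build_design_matrix(problem: FitProblem):
    """Linearized design for the residual-energy fit.

    Returns ``(X, y, columns)``: one row per frame; one column per
    (adjustable class, n) pair holding the sum of (1 + cos(n phi)) over the
    matching torsions of that frame, plus one indicator column per molecule
    when offsets are enabled.  The response is the reference energy minus
    the MM energy evaluated with the adjustable classes zeroed.
    """
    fixed = _zeroed_params(problem.base_params, problem.adjustable)
    rows_X, rows_y = [], []
    keys = list(problem.adjustable)
    nmol = len(problem.entries)
    any_adjustable = False
    for mol_i, (tpl, conf, ref) in enumerate(problem.entries):
        charges = problem.charges.get(tpl.name)
        topo = Topology(tpl, fixed, charges=charges)
        match = [[d for d, quad in enumerate(topo.dihedral_quads)
                  if quad == key] for key in keys]
        if any(match[k] for k in range(len(keys))):
            any_adjustable = True
        ref = np.asarray(ref, float)
        for f_i, frame in enumerate(conf.frames):
            eb = topo.evaluate(frame)
            phis = np.radians(topo.dihedral_angles(frame))
            feat = np.zeros(len(keys) * len(PERIODICITIES) + nmol)
            for k in range(len(keys)):
                ph = phis[match[k]]
                for j, n in enumerate(PERIODICITIES):
                    feat[k * len(PERIODICITIES) + j] = np.sum(
                        1.0 + np.cos(n * ph))
            feat[len(keys) * len(PERIODICITIES) + mol_i] = 1.0
            rows_X.append(feat)
            rows_y.append(ref[f_i] - eb.total)
    if not any_adjustable:
        raise NoAdjustableTerms(
            "no adjustable dihedral class occurs in any template")
    X = np.array(rows_X)
    y = np.array(rows_y)
    columns = ([(key, n) for key in keys for n in PERIODICITIES]
               + [("offset", name) for name in problem.molecule_names()])
    if not problem.per_molecule_offset:
        X = X[:, : len(keys) * len(PERIODICITIES)]
        columns = columns[: len(keys) * len(PERIODICITIES)]
    # drop identically zero columns (classes absent from every template):
    # they carry no information and would only force the ridge fallback
    keep = [j for j in range(X.shape[1])
            if columns[j][0] == "offset" or np.any(X[:, j] != 0.0)]
    return X[:, keep], y, [columns[j] for j in keep]


@dataclass
class TorsionFitResults:
    """Fitted torsion coefficients with uncertainties and diagnostics.

    ``terms`` maps each adjustable class to its reported Fourier terms
    (n, Vn >= 0, gamma in {0, 180}); ``coef``/``bse`` are the raw signed
    linear coefficients and their standard errors in design-column order.
    """

    terms: Dict[Tuple[str, ...], List[Tuple[int, float, float]]]
    offsets: Dict[str, float]
    coef: np.ndarray
    bse: np.ndarray
    columns: List
    residuals: np.ndarray
    sse: float
    rank_deficient: bool = False
    iterations: int = 1
    converged: bool = True
    log: List[dict] = field(default_factory=list)

    @property
    def nobs(self) -> int:
        return len(self.residuals)

    def apply_to(self, params: ForceFieldParameters) -> ForceFieldParameters:
        """Copy of ``params`` with the fitted terms installed."""
        out = params.copy()
        for key, terms in self.terms.items():
            out.set_dihedral(key, terms)
        return out

    def summary(self) -> str:
        lines = ["Torsion fit results",
                 "===================",
                 f"frames: {self.nobs}   SSE: {self.sse:.6g} kcal^2/mol^2"
                 f"   iterations: {self.iterations}"
                 f"   converged: {self.converged}",
                 "",
                 f"{'dihedral class':<16s} {'n':>2s} {'Vn':>10s} "
                 f"{'gamma':>6s} {'se(Vn)':>10s}"]
        se = dict(zip(self.columns, self.bse))
        for key, terms in self.terms.items():
            label = "-".join(key)
            for n, vn, gamma in terms:
                lines.append(f"{label:<16s} {n:>2d} {vn:>10.5f} "
                             f"{gamma:>6.0f} {se.get((key, n), np.nan):>10.5f}")
        lines.append("")
        for name, off in self.offsets.items():
            lines.append(f"offset[{name}] = {off:.4f} kcal/mol")
        return "\n".join(lines)


class TorsionFitModel:
    """Linear least-squares model for the torsion coefficients.

    The model is built from a :class:`FitProblem`; :meth:`fit` solves the
    linearized problem by ordinary least squares (with a flagged ridge
    fallback when the design is rank deficient) and returns
    :class:`TorsionFitResults`.
    """

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.X, self.y, self.columns = build_design_matrix(problem)
        if self.X.shape[0] < self.X.shape[1]:
            raise RankDeficient(
                f"{self.X.shape[0]} frames < {self.X.shape[1]} columns")

    def fit(self, ridge: float = 1e-8) -> TorsionFitResults:
        X, y = self.X, self.y
        ncol = X.shape[1]
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rank_deficient = rank < ncol
        if rank_deficient:
            # ridge fallback keeps the fit defined; flagged in the result
            XtX = X.T @ X + ridge * np.eye(ncol)
            coef = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ coef
        sse = float(resid @ resid)
        dof = max(X.shape[0] - ncol, 1)
        sigma2 = sse / dof
        XtX = X.T @ X + (ridge * np.eye(ncol) if rank_deficient else 0.0)
        try:
            cov = sigma2 * np.linalg.inv(XtX)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(ncol, np.nan)

        terms: Dict[Tuple[str, ...], List[Tuple[int, float, float]]] = {}
        offsets: Dict[str, float] = {}
        for c, col in zip(coef, self.columns):
            if col[0] == "offset":
                offsets[col[1]] = float(c)
            else:
                key, n = col
                # sign of the linear coefficient decides gamma analytically
                if c >= 0:
                    vn, gamma = float(c), 0.0
                else:
                    vn, gamma = float(-c), 180.0
                if vn == 0.0:
                    gamma = 0.0
                terms.setdefault(key, []).append((n, vn, gamma))
        return TorsionFitResults(
            terms=terms, offsets=offsets, coef=coef, bse=bse,
            columns=self.columns, residuals=resid, sse=sse,
            rank_deficient=rank_deficient)


def fit_torsions(problem: FitProblem) -> TorsionFitResults:
    """Convenience wrapper: build the model and fit."""
    return TorsionFitModel(problem).fit()


def _terms_map(x) -> Dict[Tuple[str, ...], Dict[int, Tuple[float, float]]]:
    """Normalize a results object / params / raw dict to key -> n -> (Vn, gamma)."""
    if isinstance(x, TorsionFitResults):
        src = x.terms
    elif isinstance(x, ForceFieldParameters):
        src = x.dihedrals
    else:
        src = x
    out: Dict[Tuple[str, ...], Dict[int, Tuple[float, float]]] = {}
    for key, terms in src.items():
        ck = canonical_quad(key)
        out[ck] = {int(n): (float(v), float(g)) for n, v, g in terms}
    return out


def check_convergence(prev, new, tol: float = 0.05,
                      floor: float = CONVERGENCE_FLOOR) -> bool:
    """The 5% convergence rule: every Vn changed by less than ``tol``
    relative to its previous value (with a small absolute floor guarding
    division near zero) and every gamma is unchanged."""
    pm, nm = _terms_map(prev), _terms_map(new)
    if set(nm) - set(pm):
        raise KeyMismatch(f"keys only in new result: {set(nm) - set(pm)}")
    for key, nterms in nm.items():
        pterms = pm[key]
        for n, (vn, gamma) in nterms.items():
            v_prev, g_prev = pterms.get(n, (0.0, 0.0))
            if abs(vn - v_prev) / max(abs(v_prev), floor) >= tol:
                return False
            if gamma != g_prev and max(vn, v_prev) >= floor:
                return False
    return True


def iterate_fit(problem: FitProblem,
                charge_refitter: Optional[Callable] = None,
                max_outer: int = 10,
                tol: float = 0.05) -> TorsionFitResults:
    """Alternating torsion-fit / charge-refit outer loop.

    ``charge_refitter`` is called as ``charge_refitter(problem)`` after each
    torsion fit and must return a dict template-name -> per-atom charge
    array (or None for an identity stage).  The supplied starting
    parameters seed only the first iteration; from then on each fit is
    compared with the previous iteration's values and the loop stops when
    the torsion 5% rule passes and the charges moved by less than ``tol``
    (same floor rule, in e).

    Raises
    ------
    NotConverged
        If ``max_outer`` iterations pass without convergence; the exception
        carries the best (last) result in its ``result`` attribute.
    """
    prev_vals = None   # first iteration has no previous *fit* to compare
    result: Optional[TorsionFitResults] = None
    log: List[dict] = []
    if max_outer < 1:
        exc = NotConverged("max_outer < 1: no iterations run")
        exc.result = None
        raise exc
    for it in range(1, max_outer + 1):
        result = TorsionFitModel(problem).fit()
        torsion_ok = (prev_vals is not None
                      and check_convergence(prev_vals, result, tol=tol))
        # charge refit stage
        charges_ok = True
        max_dq = 0.0
        if charge_refitter is not None:
            new_charges = charge_refitter(problem) or {}
            for name, q_new in new_charges.items():
                tpl = next(t for t, _, _ in problem.entries if t.name == name)
                q_prev = problem.charges.get(name, tpl.charges)
                dq = np.abs(np.asarray(q_new) - q_prev)
                rel = dq / np.maximum(np.abs(q_prev), CONVERGENCE_FLOOR)
                max_dq = max(max_dq, float(rel.max(initial=0.0)))
                if np.any(rel >= tol):
                    charges_ok = False
                problem.charges[name] = np.asarray(q_new, float)
        log.append({"iteration": it, "sse": result.sse,
                    "torsion_converged": torsion_ok,
                    "charges_converged": charges_ok,
                    "max_charge_rel_change": max_dq})
        prev_vals = result.terms
        if torsion_ok and charges_ok:
            result.iterations = it
            result.converged = True
            result.log = log
            return result
    result.iterations = max_outer
    result.converged = False
    result.log = log
    exc = NotConverged(f"not converged after {max_outer} outer iterations")
    exc.result = result
    raise exc
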