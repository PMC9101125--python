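"""Pseudorotation geometry of five-membered (furanose) rings.

The pucker of a furanose ring is described by the Altona–Sundaralingam pair
(P, tau_m): a phase angle P in [0, 360) locating the pucker around the
pseudorotation cycle (P = 0 is the C3'-endo "North" twist, P = 180 the
C2'-endo "South" twist) and a non-negative amplitude tau_m, the maximum
endocyclic torsion.  The five ring torsions are related to (P, tau_m) by

    nu_j = tau_m * cos(P + 144 deg * (j - 2)),      j = 0..4

with nu_2 the torsion about the C2'-C3' bond.  Inverting this relation gives

    tan P = ((nu_4 + nu_1) - (nu_3 + nu_0)) / (2 nu_2 (sin 36 + sin 72))

which this module resolves with a two-argument arctangent so that all four
quadrants and the cos P = 0 meridians are handled exactly.

Atom quadruples per torsion, for ring atoms ordered (C1', C2', C3', C4', O4'):

    nu_0 : C4'-O4'-C1'-C2'
    nu_1 : O4'-C1'-C2'-C3'
    nu_2 : C1'-C2'-C3'-C4'
    nu_3 : C2'-C3'-C4'-O4'
    nu_4 : C3'-C4'-O4'-C1'
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from .errors import CollinearPoints, EmbeddingNotConverged, ZeroAmplitude

if TYPE_CHECKING:  # pragma: no cover
    from .io import MolecularTemplate

# sin 36 + sin 72, the denominator constant of the phase formula
_AS_DENOM = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))

# offsets 144*(j-2) degrees for j = 0..4
_NU_OFFSETS = 144.0 * (np.arange(5) - 2)


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase/amplitude pair.

    Parameters
    ----------
    phase_deg : float
        Phase angle P, normalized to [0, 360).
    amplitude_deg : float
        Pucker amplitude tau_m in degrees, >= 0.
    """

    phase_deg: float
    amplitude_deg: float

    def __post_init__(self):
        if self.amplitude_deg < 0:
            raise ValueError("amplitude_deg must be non-negative")
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)
        object.__setattr__(self, "amplitude_deg", float(self.amplitude_deg))

    @property
    def phase_signed(self) -> float:
        """Phase mapped to (-180, 180], the convention used for %North."""
        p = self.phase_deg % 360.0
        return p if p <= 180.0 else p - 360.0


@dataclass(frozen=True)
class RingAtomOrder:
    """Indices of the five ring atoms in the order C1', C2', C3', C4', O4'."""

    indices: tuple

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) != 5 or len(set(idx)) != 5:
            raise ValueError("ring order needs 5 distinct atom indices")
        object.__setattr__(self, "indices", idx)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of p4 relative to p1 is positive; cis = 0, trans = 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise CollinearPoints("three consecutive dihedral points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    # fold -180 onto +180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def torsions_from_phase(state: PuckerState) -> np.ndarray:
    """Endocyclic torsions nu_0..nu_4 (degrees) for a pucker state."""
    return state.amplitude_deg * np.cos(
        np.radians(state.phase_deg + _NU_OFFSETS)
    )


def phase_from_torsions(nu: Sequence[float]) -> PuckerState:
    """Invert nu_j = tau_m cos(P + 144 (j-2)) for (P, tau_m).

    Uses atan2 on the numerator/denominator of the tangent formula, which
    resolves the quadrant and stays exact where cos P = 0.

    Raises
    ------
    ZeroAmplitude
        If all torsions are below 1e-6 degrees (planar ring).
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("expected exactly 5 endocyclic torsions")
    if np.max(np.abs(nu)) < 1e-6:
        raise ZeroAmplitude("phase undefined for a planar ring")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])       # 2 tau_m sinP (s36+s72)
    den = 2.0 * nu[2] * _AS_DENOM                 # 2 tau_m cosP (s36+s72)
    phase = np.degrees(np.arctan2(num, den))
    amplitude = np.hypot(num, den) / (2.0 * _AS_DENOM)
    return PuckerState(phase_deg=phase, amplitude_deg=amplitude)


def ring_torsions(coords: np.ndarray, order: RingAtomOrder) -> np.ndarray:
    """The five endocyclic torsions (degrees) from full-molecule coordinates."""
    coords = np.asarray(coords, dtype=float)
    r = [coords[i] for i in order.indices]
    nu = np.empty(5)
    for j in range(5):
        nu[j] = dihedral_angle(
            r[(j + 3) % 5], r[(j + 4) % 5], r[j % 5], r[(j + 1) % 5]
        )
    return nu


def phase_from_ring_coords(coords: np.ndarray, order: RingAtomOrder) -> PuckerState:
    """Pucker state from Cartesian ring coordinates (rigid-motion invariant)."""
    return phase_from_torsions(ring_torsions(coords, order))


# ---------------------------------------------------------------------------
# Cartesian embedding of a ring at a target pucker
# ---------------------------------------------------------------------------

_J = np.arange(5)
_TORS_IDX = np.stack([(_J + 3) % 5, (_J + 4) % 5, _J, (_J + 1) % 5], axis=1)


def _ring_internal_residuals(flat, target_nu_deg, bond_ref, angle_ref,
                             w_t, w_b, w_a, w_p):
    """Weighted residuals for the ring embedding: per-torsion deviations,
    bond/angle restraints, and the two phase-defining linear combinations
    (numerator/denominator of the tangent formula) pinned strongly so the
    measured (P, tau_m) match the target exactly."""
    r = flat.reshape(5, 3)
    p = r[_TORS_IDX]                       # (5, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    nu = np.degrees(np.arctan2(np.einsum("ij,ij->i", m, n2),
                               np.einsum("ij,ij->i", n1, n2)))
    d_t = (nu - target_nu_deg + 180.0) % 360.0 - 180.0
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * _AS_DENOM
    num_t = ((target_nu_deg[4] + target_nu_deg[1])
             - (target_nu_deg[3] + target_nu_deg[0]))
    den_t = 2.0 * target_nu_deg[2] * _AS_DENOM
    nxt = np.roll(r, -1, axis=0)
    d_b = np.linalg.norm(nxt - r, axis=1) - bond_ref
    u = np.roll(r, 1, axis=0) - r
    v = nxt - r
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    d_a = np.arccos(np.clip(cosang, -1.0, 1.0)) - angle_ref
    return np.concatenate([
        w_t * np.radians(d_t), w_b * d_b, w_a * d_a,
        w_p * np.radians([num - num_t, den - den_t])])


def _ring_nu(r):
    """Endocyclic torsions (degrees) of bare 5-ring coordinates."""
    nu = np.empty(5)
    for j in range(5):
        nu[j] = dihedral_angle(
            r[(j + 3) % 5], r[(j + 4) % 5], r[j % 5], r[(j + 1) % 5])
    return nu


def _local_frame(origin, prev_pt, next_pt):
    """Orthonormal frame at a ring atom, defined by its two ring neighbors."""
    u = next_pt - origin
    v = prev_pt - origin
    e1 = u + v
    e1 /= np.linalg.norm(e1)
    e3 = np.cross(u, v)
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def embed_ring(template: "MolecularTemplate", target: PuckerState,
               max_iter: int = 500, torsion_tol_deg: float = 1.0) -> np.ndarray:
    """Re-embed all atoms of ``template`` so the ring adopts ``target``.

    The five ring atoms are optimized directly in Cartesian space by damped
    Gauss-Newton least squares over three residual groups: per-torsion
    deviations from the target cosine pattern, harmonic bond-length (tight)
    and bond-angle (soft) restraints to template values, and — dominating
    everything — the two phase-defining torsion combinations, so that the
    *measured* (P, tau_m) of the result match the target to well under
    1e-3 degree.  A closed ring with fixed bond lengths has only four
    pucker degrees of freedom against five cosine targets, so a small
    residual pattern deviation (well under ``torsion_tol_deg``) is
    unavoidable and is absorbed by the soft angle restraints; the phase
    itself is exact.  Exocyclic substituents ride rigidly in the local
    frame of their anchor ring atom (frame spanned by the anchor and its
    two ring neighbors); they are not relaxed here.

    Returns the full (n_atoms, 3) coordinate array.

    Raises
    ------
    EmbeddingNotConverged
        If the maximum deviation from the target torsion pattern exceeds
        ``torsion_tol_deg`` after optimization.
    """
    if target.amplitude_deg >= 60.0:
        raise ValueError("amplitude >= 60 deg is outside the furanose range")
    coords0 = np.asarray(template.coords, dtype=float)
    order = template.ring_order
    ring_idx = list(order.indices)
    r0 = coords0[ring_idx].copy()

    bond_ref = np.linalg.norm(np.roll(r0, -1, axis=0) - r0, axis=1)
    u = np.roll(r0, 1, axis=0) - r0
    v = np.roll(r0, -1, axis=0) - r0
    angle_ref = np.arccos(np.clip(
        np.einsum("ij,ij->i", u, v)
        / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)), -1, 1))

    target_nu = torsions_from_phase(target)

    # start from the template ring nudged towards the target out-of-plane
    # pattern; a planar start has a mirror degeneracy the nudge breaks.
    start = r0.copy()
    centroid = start.mean(axis=0)
    normal = np.zeros(3)
    for i in range(5):
        normal += np.cross(start[i] - centroid, start[(i + 1) % 5] - centroid)
    nrm = np.linalg.norm(normal)
    if nrm > 1e-12:
        normal /= nrm
        # out-of-plane displacement pattern conjugate to the torsion
        # convention (90 deg phase lead, empirically verified)
        zpat = np.cos(np.radians(target.phase_deg + 144.0 * np.arange(5) + 90.0))
        start += 0.008 * max(target.amplitude_deg, 5.0) * np.outer(zpat, normal)

    # weights: torsion pattern ~1/0.01 deg, bonds ~1/0.0004 A, angles
    # ~1/40 deg (nearly free), phase combinations ~1/0.001 deg (pinned)
    w_t = 1.0 / np.radians(0.01)
    w_b = 1.0 / 0.0002
    w_a = 1.0 / np.radians(40.0)
    w_p = 1.0 / np.radians(0.001)

    sol = least_squares(
        _ring_internal_residuals, start.ravel(),
        args=(target_nu, bond_ref, angle_ref, w_t, w_b, w_a, w_p),
        method="lm", max_nfev=max_iter * 16,
        xtol=1e-12, ftol=1e-12, gtol=1e-14)
    r_new = sol.x.reshape(5, 3)

    achieved = _ring_nu(r_new)
    dev = np.abs((achieved - target_nu + 180.0) % 360.0 - 180.0)
    if target.amplitude_deg > 1e-9 and np.max(dev) > torsion_tol_deg:
        raise EmbeddingNotConverged(
            f"max torsion deviation {np.max(dev):.3f} deg > {torsion_tol_deg}")

    # carry exocyclic atoms rigidly with their anchor ring atom
    new_coords = coords0.copy()
    for k, idx in enumerate(ring_idx):
        new_coords[idx] = r_new[k]
    anchors = template.exocyclic_anchors()
    for k, idx in enumerate(ring_idx):
        exo = anchors.get(idx, [])
        if not exo:
            continue
        prev_i = ring_idx[(k - 1) % 5]
        next_i = ring_idx[(k + 1) % 5]
        F_old = _local_frame(coords0[idx], coords0[prev_i], coords0[next_i])
        F_new = _local_frame(r_new[k],
                             new_coords[prev_i], new_coords[next_i])
        R = F_new @ F_old.T
        for a in exo:
            new_coords[a] = r_new[k] + R @ (coords0[a] - coords0[idx])
    return new_coords
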