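"""Pseudorotation scans, randomized pose ensembles and RMSD culling.

A scan walks the phase circle at a fixed interval (default 18 degrees, i.e.
20 windows) at constant amplitude, embedding the template ring at each
window.  Randomized poses perturb only the exocyclic torsions of the scan
frame — the ring geometry is the controlled variable and stays frozen at
the window's embedded coordinates.  Near-duplicate frames are removed by a
greedy keep-first pairwise cull at a Kabsch-RMSD threshold (default 1 A,
heavy atoms only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmbeddingNotConverged, ShapeMismatch
from .geometry import PuckerState, embed_ring
from .io import ConformerSet, MolecularTemplate


@dataclass(frozen=True)
class ScanSpec:
    """Specification of a pseudorotation scan / pose ensemble.

    ``interval_deg`` must divide 360; ``amplitude_deg`` is the constant
    pucker amplitude of the scan (a typical furanose value by default);
    ``poses_per_window`` > 1 adds seeded random exocyclic-torsion
    perturbations (uniform in +/- ``perturb_deg``).
    """

    interval_deg: float = 18.0
    amplitude_deg: float = 35.0
    poses_per_window: int = 1
    perturb_deg: float = 30.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.interval_deg <= 0 or 360.0 % self.interval_deg != 0:
            raise ValueError("interval_deg must divide 360")
        if self.poses_per_window < 1:
            raise ValueError("poses_per_window must be >= 1")

    @property
    def n_windows(self) -> int:
        return int(round(360.0 / self.interval_deg))

    def window_phases(self) -> np.ndarray:
        return self.interval_deg * np.arange(self.n_windows)


def scan_pseudorotation(template: MolecularTemplate,
                        spec: ScanSpec) -> ConformerSet:
    """One embedded frame per phase window (deterministic)."""
    frames, targets, windows = [], [], []
    for w, phase in enumerate(spec.window_phases()):
        target = PuckerState(phase_deg=phase,
                             amplitude_deg=spec.amplitude_deg)
        try:
            frames.append(embed_ring(template, target))
        except EmbeddingNotConverged as exc:
            raise EmbeddingNotConverged(
                f"{template.name} window {w} (P={phase:g}): {exc}") from exc
        targets.append(target)
        windows.append(w)
    n = len(frames)
    return ConformerSet(
        frames=np.array(frames),
        template_ids=[template.name] * n,
        window_indices=windows, targets=targets,
        provenance=["scan"] * n, seed=spec.seed)


def _rotatable_exocyclic(template: MolecularTemplate):
    """Rotatable exocyclic torsion axes: bonds from a ring atom to an
    exocyclic heavy atom that carries further atoms (e.g. C-OH).  Returns
    (anchor, pivot, moved-atom-indices) triples."""
    g = template.graph()
    ring = set(template.ring_order.indices)
    axes = []
    for anchor in template.ring_order.indices:
        for pivot in g.neighbors(anchor):
            if pivot in ring or template.elements[pivot] == "H":
                continue
            g_cut = g.copy()
            g_cut.remove_edge(anchor, pivot)
            import networkx as nx
            comp = nx.node_connected_component(g_cut, pivot) - {pivot}
            if comp:
                axes.append((anchor, pivot, sorted(comp)))
    return axes


def random_poses(template: MolecularTemplate, spec: ScanSpec,
                 seed: Optional[int] = None,
                 base_scan: Optional[ConformerSet] = None) -> ConformerSet:
    """Per window, ``poses_per_window`` frames: the scan frame with its
    exocyclic torsions randomly rotated (uniform within the perturbation
    range); ring atoms stay at the window's embedded geometry.  Identical
    seeds give bitwise-identical coordinate sets.  ``base_scan`` reuses an
    existing one-frame-per-window scan instead of re-embedding."""
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    base = (base_scan if base_scan is not None
            else scan_pseudorotation(template, spec))
    if len(base) != spec.n_windows:
        raise ValueError("base_scan window count does not match spec")
    axes = _rotatable_exocyclic(template)
    frames, targets, windows = [], [], []
    for w in range(len(base)):
        ref = base.frames[w]
        for _ in range(spec.poses_per_window):
            frame = ref.copy()
            for anchor, pivot, moved in axes:
                ang = rng.uniform(-spec.perturb_deg, spec.perturb_deg)
                axis = frame[pivot] - frame[anchor]
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(np.radians(ang) * axis)
                frame[moved] = (rot.apply(frame[moved] - frame[pivot])
                                + frame[pivot])
            frames.append(frame)
            targets.append(base.targets[w])
            windows.append(w)
    n = len(frames)
    return ConformerSet(
        frames=np.array(frames),
        template_ids=[template.name] * n,
        window_indices=windows, targets=targets,
        provenance=["poses"] * n, seed=seed)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD (A) over proper rigid superpositions of ``b`` onto ``a``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ShapeMismatch(f"coordinate shapes {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    # recompute the residual from the superposed coordinates: the solver's
    # rssd loses precision to cancellation near zero
    diff = rot.apply(bc) - ac
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def cull_by_rmsd(conformers: ConformerSet, threshold: float = 1.0,
                 template: Optional[MolecularTemplate] = None,
                 heavy_only: bool = True) -> ConformerSet:
    """Greedy keep-first cull: a frame survives iff its RMSD to every
    previously kept frame is >= ``threshold``.  RMSD is computed over heavy
    atoms when a template is supplied and ``heavy_only`` is set."""
    if len(conformers) == 0:
        raise ValueError("cannot cull an empty conformer set")
    if heavy_only and template is not None:
        sel = template.heavy_atom_indices()
    else:
        sel = np.arange(conformers.frames.shape[1])
    kept: list[int] = []
    for i in range(len(conformers)):
        fi = conformers.frames[i][sel]
        if all(kabsch_rmsd(conformers.frames[k][sel], fi) >= threshold
               for k in kept):
            kept.append(i)
    return conformers.subset(kept)
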