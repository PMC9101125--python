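"""Sugar-pucker trajectory analysis.

Phase-angle series, probability histograms and the percent-North statistic
(%N, the fraction of frames with phase in the Northern hemicycle
-90 <= P < 90 of the signed phase convention), plus per-phase-window
energy-error statistics and the through-origin MM-vs-reference regression
used to judge force-field quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (BadBinWidth, DegenerateX, EmptySeries, LengthMismatch,
                     ZeroAmplitude)
from .geometry import RingAtomOrder, phase_from_ring_coords
from .io import ConformerSet


@dataclass
class PhaseSeries:
    """Per-frame signed phase (-180, 180] and amplitude (degrees)."""

    phase_deg: np.ndarray
    amplitude_deg: np.ndarray

    def __post_init__(self):
        self.phase_deg = np.asarray(self.phase_deg, float).ravel()
        self.amplitude_deg = np.asarray(self.amplitude_deg, float).ravel()
        if len(self.phase_deg) != len(self.amplitude_deg):
            raise LengthMismatch("phase/amplitude length mismatch")

    def __len__(self) -> int:
        return len(self.phase_deg)


def phase_series(frames: ConformerSet, order: RingAtomOrder) -> PhaseSeries:
    """Measure every frame's pucker; phases mapped to (-180, 180]."""
    phases, amps = [], []
    for i, frame in enumerate(frames.frames):
        try:
            ps = phase_from_ring_coords(frame, order)
        except ZeroAmplitude as exc:
            raise ZeroAmplitude(f"frame {i}: {exc}") from exc
        phases.append(ps.phase_signed)
        amps.append(ps.amplitude_deg)
    return PhaseSeries(phase_deg=np.array(phases),
                       amplitude_deg=np.array(amps))


def percent_north(series: PhaseSeries) -> float:
    """%N = 100 x fraction of frames with -90 <= P < 90 (signed phase).

    The boundary is half-open: a frame at exactly P = 90 counts South, so
    %N + %S = 100 exactly.
    """
    if len(series) == 0:
        raise EmptySeries("empty phase series")
    p = series.phase_deg
    return float(100.0 * np.count_nonzero((p >= -90.0) & (p < 90.0)) / len(p))


@dataclass
class PhaseHistogram:
    """Left-closed right-open probability bins over the signed phase."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    percent_north: float


def phase_histogram(series: PhaseSeries, bin_deg: float = 18.0
                    ) -> PhaseHistogram:
    """Probability of each phase window (counts / total).

    Bins are [edge, edge + bin_deg) from -180 to 180; the single point
    P = 180 is identified with -180 (the same angle).
    """
    if bin_deg <= 0 or 360.0 % bin_deg != 0:
        raise BadBinWidth(f"{bin_deg} does not divide 360")
    if len(series) == 0:
        raise EmptySeries("empty phase series")
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    p = series.phase_deg.copy()
    p[p == 180.0] = -180.0
    counts, _ = np.histogram(p, bins=edges)
    return PhaseHistogram(bin_edges=edges,
                          probabilities=counts / len(p),
                          percent_north=percent_north(series))


def window_error_stats(mm_energies, ref_energies, window_labels
                       ) -> pd.DataFrame:
    """Per-window statistics of the energy error EE = E_MM - E_ref.

    Returns one row per window label with the population mean and standard
    deviation (n divisor) plus the mu +/- sigma and mu +/- 2 sigma
    envelopes, and a final ``"all"`` row with the pooled statistics.
    """
    mm = np.asarray(mm_energies, float).ravel()
    ref = np.asarray(ref_energies, float).ravel()
    labels = np.asarray(window_labels).ravel()
    if not (len(mm) == len(ref) == len(labels)):
        raise LengthMismatch(
            f"lengths {len(mm)}, {len(ref)}, {len(labels)} differ")
    ee = mm - ref
    rows = []
    uniq = list(dict.fromkeys(labels.tolist()))    # first-appearance order
    for lab in uniq + ["all"]:
        sel = ee if lab == "all" else ee[labels == lab]
        mu = float(np.mean(sel))
        sigma = float(np.std(sel))                 # population (ddof=0)
        rows.append({"window": lab, "n": len(sel), "mu": mu, "sigma": sigma,
                     "mu_minus_sigma": mu - sigma,
                     "mu_plus_sigma": mu + sigma,
                     "mu_minus_2sigma": mu - 2 * sigma,
                     "mu_plus_2sigma": mu + 2 * sigma})
    return pd.DataFrame(rows)


@dataclass
class OriginRegression:
    """Through-origin least squares y = slope * x.

    ``r_squared`` uses the through-origin convention
    1 - SS_res / sum(y^2) (uncentered total sum of squares), matching
    zero-intercept regression reporting; it differs from the centered
    definition and is documented as such.
    """

    slope: float
    r_squared: float
    n: int


def origin_regression(x, y) -> OriginRegression:
    """slope = sum(xy)/sum(x^2); r^2 = 1 - sum((y - s x)^2)/sum(y^2)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise LengthMismatch(f"{len(x)} vs {len(y)}")
    if len(x) < 2 or float(x @ x) <= 0.0:
        raise DegenerateX("need n >= 2 and sum(x^2) > 0")
    slope = float(x @ y) / float(x @ x)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return OriginRegression(slope=slope, r_squared=r2, n=len(x))


def align_per_molecule(energies, molecule_ids) -> np.ndarray:
    """Subtract each molecule's minimum energy (reference and MM zeros are
    incommensurate; regression compares relative energies)."""
    e = np.asarray(energies, float).copy()
    ids = np.asarray(molecule_ids)
    for m in np.unique(ids):
        sel = ids == m
        e[sel] -= e[sel].min()
    return e
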