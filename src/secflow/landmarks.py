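"""Bend landmarking: splitting a centerline into branch sections.

A branch section (arterial bend) is a curvature peak flanked by a
proximal and a distal torsion peak; the torsion peaks are the borders
that partition the centerline into consecutive bends, starting from the
proximal end.  Torsion enters as |tau| so the handedness convention of
the Frenet frame cannot change the landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.ndimage import uniform_filter1d

from .centerline import FrenetFrameSet

__all__ = ["BranchSection", "find_peaks", "landmark", "assign_slices", "mark_aneurysmal"]

#: fraction of the signal range; low enough that a gentle bend is still
#: detected next to a sharply curved sibling (peak ratios of ~8 occur)
DEFAULT_MIN_PROMINENCE = 0.05
DEFAULT_MIN_SEPARATION_MM = 3.0
DEFAULT_SMOOTH_WINDOW = 5  # samples


@dataclass
class BranchSection:
    """One landmarked bend along the centerline."""

    index: int
    s_start: float
    s_end: float
    peak_abscissa: float
    peak_kappa: float
    tau_proximal: float | None  # flanking torsion-peak abscissa, None if endpoint fallback
    tau_distal: float | None
    endpoint_fallback: bool = False
    slice_indices: list[int] = field(default_factory=list)
    is_aneurysmal: bool = False

    def __post_init__(self) -> None:
        if not self.s_start < self.peak_abscissa < self.s_end:
            raise ValueError("bend peak must lie strictly inside its interval")


def find_peaks(
    abscissa: np.ndarray,
    signal: np.ndarray,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION_MM,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> np.ndarray:
    """Abscissae of strict local maxima after light pre-smoothing.

    Peaks must have prominence >= ``min_prominence`` times the signal
    range and be at least ``min_separation`` mm apart.  A constant
    signal has no peaks.
    """
    s = np.asarray(abscissa, float)
    y = np.asarray(signal, float)
    if y.shape != s.shape or len(y) < 3:
        raise ValueError("signal and abscissa must match and have length >= 3")
    y = np.nan_to_num(y, nan=0.0)
    if smooth_window > 1:
        y = uniform_filter1d(y, size=int(smooth_window), mode="nearest")
    rng = float(np.max(y) - np.min(y))
    if rng == 0.0:
        return np.empty(0)
    h = float(np.mean(np.diff(s)))
    dist = max(1, int(round(min_separation / h)))
    idx, _ = scipy.signal.find_peaks(y, prominence=min_prominence * rng, distance=dist)
    return s[idx]


def landmark(
    frames: FrenetFrameSet,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION_MM,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[BranchSection]:
    """Partition the centerline into bends from kappa and |tau| peaks.

    Each curvature peak is bracketed by the nearest torsion peaks on
    either side; where no torsion peak exists beyond the first/last
    curvature peak the domain endpoint is used and the bend is flagged
    (``endpoint_fallback``).  Curvature peaks falling inside an
    already-claimed interval are merged, keeping the higher peak.
    """
    s = frames.abscissa
    kappa = np.where(frames.valid, frames.kappa, 0.0)
    tau_abs = np.abs(np.nan_to_num(frames.tau, nan=0.0))

    k_peaks = find_peaks(s, kappa, min_prominence, min_separation, smooth_window)
    if len(k_peaks) == 0:
        raise ValueError("no curvature peaks found: cannot landmark")
    t_peaks = find_peaks(s, tau_abs, min_prominence, min_separation, smooth_window)

    # peak kappa values at the detected abscissae
    k_at = np.interp(k_peaks, s, kappa)

    bends: list[BranchSection] = []
    for pk, kv in zip(k_peaks, k_at):
        prox_candidates = t_peaks[t_peaks < pk]
        dist_candidates = t_peaks[t_peaks > pk]
        fallback = False
        if prox_candidates.size:
            s_start, tau_prox = float(prox_candidates.max()), float(prox_candidates.max())
        else:
            s_start, tau_prox, fallback = float(s[0]), None, True
        if dist_candidates.size:
            s_end, tau_dist = float(dist_candidates.min()), float(dist_candidates.min())
        else:
            s_end, tau_dist, fallback = float(s[-1]), None, True

        if bends and pk < bends[-1].s_end:
            # same interval as the previous bend: merge, keep higher peak
            prev = bends[-1]
            if kv > prev.peak_kappa:
                prev.peak_abscissa, prev.peak_kappa = float(pk), float(kv)
            continue
        bends.append(BranchSection(
            index=len(bends), s_start=s_start, s_end=s_end,
            peak_abscissa=float(pk), peak_kappa=float(kv),
            tau_proximal=tau_prox, tau_distal=tau_dist,
            endpoint_fallback=fallback))
    return bends


def assign_slices(bends: list[BranchSection], slice_abscissae: np.ndarray) -> list[BranchSection]:
    """Assign each slice to the bend whose interval [s_start, s_end) holds it.

    A slice exactly on a shared border belongs to the distal bend.
    Slices outside every bend stay unassigned.
    """
    sa = np.asarray(slice_abscissae, float)
    for b in bends:
        b.slice_indices = [int(i) for i in np.nonzero((sa >= b.s_start) & (sa < b.s_end))[0]]
    # the very last border is inclusive so the final point is not dropped
    if bends:
        last = bends[-1]
        extra = np.nonzero(sa == last.s_end)[0]
        for i in extra:
            if int(i) not in last.slice_indices:
                last.slice_indices.append(int(i))
    return bends


def mark_aneurysmal(
    bends: list[BranchSection],
    neck_start: float,
    neck_end: float,
) -> list[BranchSection]:
    """Flag the bend containing the aneurysm-neck midpoint (distal tie-break)."""
    if not neck_start < neck_end:
        raise ValueError("neck interval must have positive extent")
    mid = 0.5 * (neck_start + neck_end)
    for b in bends:
        b.is_aneurysmal = False
    for b in bends:
        if b.s_start <= mid < b.s_end or (b is bends[-1] and mid == b.s_end):
            b.is_aneurysmal = True
            return bends
    raise ValueError(f"neck midpoint {mid:.3f} mm lies outside every bend")
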