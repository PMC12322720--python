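"""Signal quantification: per-wire intensities, totals, blank normalization.

A localized bright wire ``i`` is scored by the dark-corrected mean pixel
intensity Ī_i in a small window around its position; the frame totals are

    I_tot = Σ_i Ī_i,        I_avg = I_tot / N,

with N the digital count of bright wires.  Relative readouts subtract blank
(pre-analyte) references:  N′ = N − N₀  and  I′_tot = I_tot − I_{0,tot}.
Two non-digital baseline readouts are also computed for comparison: the
whole-frame mean pixel intensity and the mean over pixels above a global
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .image_synthesis import CameraModel

__all__ = [
    "SignalSummary",
    "TimeSeriesSummary",
    "nanowire_intensity",
    "summarize_frame",
    "summarize_blanks",
    "tapering_factor",
    "cumulative_binding",
    "estimate_dark_offset",
]


@dataclass
class SignalSummary:
    """Per-frame signal metrics (counts; N is a digital wire count)."""

    n: int
    intensities: np.ndarray          # Ī_i per bright wire
    i_tot: float
    i_avg: float | None              # None when N = 0 (undefined, not zero)
    i_px: float                      # baseline: mean dark-corrected pixel
    i_thr: float                     # baseline: mean over above-threshold pixels
    n0: float | None = None
    i0_tot: float | None = None
    n_prime: float | None = None
    i_tot_prime: float | None = None
    i_px_prime: float | None = None
    i_thr_prime: float | None = None
    regime: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "intensities"}
        d["intensities"] = np.asarray(self.intensities).tolist()
        return d


def tapering_factor(d_top_nm: float, d_bot_nm: float) -> float:
    """Wire tapering (d_bot − d_top)/(d_bot + d_top); 0 for a cylinder."""
    if d_top_nm <= 0 or d_bot_nm <= 0:
        raise ValueError("diameters must be positive")
    return (d_bot_nm - d_top_nm) / (d_bot_nm + d_top_nm)


def estimate_dark_offset(blank_frames: list[np.ndarray] | np.ndarray) -> float:
    """Dark-current offset I_DC as the median of blank frames.

    Per-frame fallback (no blanks available): pass a single frame — the mode
    of its integer-rounded pixel histogram is returned, which is robust when
    most pixels are background.
    """
    if isinstance(blank_frames, np.ndarray) and blank_frames.ndim == 2:
        vals, counts = np.unique(np.rint(blank_frames).astype(int), return_counts=True)
        return float(vals[np.argmax(counts)])
    stack = np.asarray(blank_frames, float)
    return float(np.median(stack))


def nanowire_intensity(
    image: np.ndarray,
    location_px: tuple[float, float],
    i_dc: float,
    window: int = 3,
) -> float:
    """Ī_i: mean dark-corrected intensity in a K-pixel window around a wire.

    ``location_px`` is (x, y) in pixel-index coordinates.  The window (odd,
    default 3×3 → K = 9) is clipped at frame edges with K adjusted.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    c = int(round(location_px[0]))
    r = int(round(location_px[1]))
    r0, r1 = max(r - half, 0), min(r + half + 1, image.shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, image.shape[1])
    patch = np.asarray(image[r0:r1, c0:c1], float)
    if patch.size == 0:
        raise ValueError(f"window around {location_px} lies outside the frame")
    return float(patch.mean() - i_dc)


def summarize_frame(
    detections: pd.DataFrame,
    image: np.ndarray,
    camera: CameraModel,
    blank: SignalSummary | None = None,
    *,
    i_dc: float | None = None,
    window: int = 3,
    threshold: float | None = None,
    threshold_k: float = 3.0,
) -> SignalSummary:
    """Compute the frame's signal summary from its kept detections.

    ``threshold`` (counts) for the thresholded baseline defaults to
    blank mean + ``threshold_k``·sd of the blank pixel distribution when a
    blank frame statistic is available, else the same statistic of this
    frame.  When ``blank`` is given, blank-normalized N′ and I′ are filled.
    """
    img = np.asarray(image, float)
    if i_dc is None:
        i_dc = camera.dark_offset
    intensities = np.array(
        [
            nanowire_intensity(img, (row.x_px, row.y_px), i_dc, window)
            for row in detections.itertuples(index=False)
        ]
    )
    n = len(intensities)
    i_tot = float(intensities.sum())
    i_avg = (i_tot / n) if n > 0 else None
    i_px = float(img.mean() - i_dc)
    if threshold is None:
        threshold = i_dc + threshold_k * float(img.std())
    above = img > threshold
    i_thr = float(img[above].mean() - i_dc) if above.any() else 0.0

    s = SignalSummary(
        n=n, intensities=intensities, i_tot=i_tot, i_avg=i_avg,
        i_px=i_px, i_thr=i_thr,
    )
    if blank is not None:
        s.n0 = float(blank.n)
        s.i0_tot = float(blank.i_tot)
        s.n_prime = n - s.n0
        s.i_tot_prime = i_tot - s.i0_tot
        s.i_px_prime = i_px - blank.i_px
        s.i_thr_prime = i_thr - blank.i_thr
    return s


def summarize_blanks(
    blanks: list[tuple[pd.DataFrame, np.ndarray]],
    camera: CameraModel,
    **kw,
) -> SignalSummary:
    """Average reference statistics over several blank fields.

    N₀ and I_{0,tot} are the means over the blank regions, matching the
    practice of imaging several regions per condition.
    """
    summaries = [summarize_frame(d, img, camera, None, **kw) for d, img in blanks]
    n0 = float(np.mean([s.n for s in summaries]))
    i0 = float(np.mean([s.i_tot for s in summaries]))
    return SignalSummary(
        n=int(round(n0)),
        intensities=np.array([]),
        i_tot=i0,
        i_avg=None,
        i_px=float(np.mean([s.i_px for s in summaries])),
        i_thr=float(np.mean([s.i_thr for s in summaries])),
    )


@dataclass
class TimeSeriesSummary:
    """Time-resolved summaries plus the cumulative distinct-site count."""

    table: pd.DataFrame              # per time point: time_s, n, n_mol, ...
    sites_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_mol(self) -> np.ndarray:
        return self.table["n_mol"].to_numpy()


def cumulative_binding(
    frames: list[tuple[float, pd.DataFrame]],
    linking_radius_um: float,
) -> TimeSeriesSummary:
    """Cumulative count of distinct binding sites over a time series.

    Detections are linked across frames by nearest neighbor within
    ``linking_radius_um``; ``N_mol(t)`` counts distinct sites first seen at
    or before ``t`` and is monotone non-decreasing by construction.  This is
    a documented surrogate definition of the cumulative bound-molecule
    count; the linking radius is configurable.
    """
    times = [t for t, _ in frames]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frames must be ordered by non-decreasing time")
    sites: list[np.ndarray] = []
    rows = []
    for t, det in frames:
        xy = det[["x_um", "y_um"]].to_numpy(float) if len(det) else np.empty((0, 2))
        if sites:
            tree = cKDTree(np.vstack(sites))
            for p in xy:
                d, _ = tree.query(p)
                if d > linking_radius_um:
                    sites.append(p[None, :])
                    tree = cKDTree(np.vstack(sites))
        else:
            for p in xy:
                if not sites:
                    sites.append(p[None, :])
                else:
                    tree = cKDTree(np.vstack(sites))
                    if tree.query(p)[0] > linking_radius_um:
                        sites.append(p[None, :])
        rows.append({"time_s": t, "n": len(det), "n_mol": sum(len(s) for s in sites)})
    table = pd.DataFrame(rows)
    all_sites = np.vstack(sites) if sites else np.empty((0, 2))
    return TimeSeriesSummary(table=table, sites_um=all_sites)
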