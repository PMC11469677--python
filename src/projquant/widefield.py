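"""Wide-field optogenetic functional-connectivity mapping.

A grid of cortical sites is optogenetically stimulated while a genetically
encoded calcium indicator reports population activity across the dorsal
cortex.  The analysis chain: 2×2 spatial binning of the raw frames →
per-trial ΔF/F₀ against a 300 ms pre-stimulus baseline → average over an
evoked window (10–260 ms post-onset) and over the trials of each
stimulation site → trial-weighted population average across mice → center
of mass of supra-threshold (≥ 80% of max) ΔF/F inside a 40 × 25 pixel
frontal mask → linear regression of the response-center AP position on the
stimulation site's |ML|, the functional counterpart of the anatomical
mirror-map regression.

Frame timing is irregular by design (acquisition runs at 100 Hz around the
stimulus but 50 Hz during it, interleaved with the light pulses), so every
window here selects frames by timestamp, never by index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topography import TopographyFit, fit_topography

__all__ = [
    "WidefieldSession",
    "EvokedMap",
    "CoMResult",
    "preprocess_movie",
    "compute_dff",
    "evoked_map",
    "population_average",
    "frontal_center_of_mass",
    "fit_functional_topography",
    "save_session",
    "load_session",
]


@dataclass
class WidefieldSession:
    """Trials × frames × H × W fluorescence with stimulation metadata.

    ``frame_times_ms`` are relative to stimulus onset and shared across
    trials (trials are acquisition-aligned).  ``stim_log`` has one row per
    trial: ``trial, grid_point_id, stim_ml_mm, stim_ap_mm``.
    ``bregma_pixel`` is (row, col); rows increase posteriorly, columns
    increase rightward, mirroring the atlas axis conventions.
    """

    movie: np.ndarray
    frame_times_ms: np.ndarray
    stim_log: pd.DataFrame
    pixel_size_um: float
    bregma_pixel: tuple[float, float]
    mouse_id: str = "mouse0"
    cre_line: str = ""

    def __post_init__(self) -> None:
        self.movie = np.asarray(self.movie)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        if self.movie.ndim != 4:
            raise ValueError("movie must be trials × frames × H × W")
        if len(self.frame_times_ms) != self.movie.shape[1]:
            raise ValueError("frame_times_ms length must match the frame axis")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError("frame_times_ms must be strictly increasing")
        trials = set(self.stim_log["trial"].astype(int))
        if trials != set(range(self.movie.shape[0])):
            raise ValueError("stim_log must cover every trial exactly once")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_trials(self) -> int:
        return self.movie.shape[0]

    def pixel_to_mm(self, row: float, col: float) -> tuple[float, float]:
        """(AP_mm, ML_mm) of a pixel, anterior and right positive."""
        scale = self.pixel_size_um / 1000.0
        return (
            (self.bregma_pixel[0] - row) * scale,
            (col - self.bregma_pixel[1]) * scale,
        )


@dataclass
class EvokedMap:
    """Evoked-window ΔF/F map for one stimulation site (or a population)."""

    values: np.ndarray
    n_trials: int
    grid_point_id: int | str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("evoked map must be 2D")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class CoMResult:
    """Center of mass of the supra-threshold response within the mask."""

    ap_mm: float
    ml_mm: float
    row: float
    col: float
    threshold: float
    defined: bool = True
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #


def preprocess_movie(
    raw: np.ndarray,
    bin_factor: int = 2,
    pixel_size_um: float = 31.25,
    bregma_pixel: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Non-overlapping mean pooling of the camera frames.

    Accepts (frames, H, W) or (trials, frames, H, W).  Trailing rows and
    columns that do not fill a complete bin are dropped with a warning.
    Returns the binned movie, the rescaled pixel size and the rescaled
    bregma pixel.
    """
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    m = np.asarray(raw, dtype=float)
    if m.ndim not in (3, 4):
        raise ValueError("movie must be 3D or 4D")
    h, w = m.shape[-2], m.shape[-1]
    h2, w2 = (h // bin_factor) * bin_factor, (w // bin_factor) * bin_factor
    if (h2, w2) != (h, w):
        warnings.warn(
            f"dropping {h - h2} trailing row(s) and {w - w2} column(s) not filling a full bin",
            stacklevel=2,
        )
        m = m[..., :h2, :w2]
    lead = m.shape[:-2]
    m = m.reshape(*lead, h2 // bin_factor, bin_factor, w2 // bin_factor, bin_factor)
    binned = m.mean(axis=(-3, -1))
    return (
        binned,
        pixel_size_um * bin_factor,
        (bregma_pixel[0] / bin_factor, bregma_pixel[1] / bin_factor),
    )


def compute_dff(
    session: WidefieldSession,
    baseline_ms: float = 300.0,
) -> tuple[np.ndarray, dict]:
    """Per-trial ΔF/F₀ with F₀ the mean image over the pre-stimulus window.

    Baseline frames are those with timestamp in [−baseline_ms, 0).  Pixels
    whose F₀ is non-positive are set to NaN and tallied (they cannot carry
    a fractional change).
    """
    t = session.frame_times_ms
    baseline = (t >= -baseline_ms) & (t < 0)
    if not baseline.any():
        raise ValueError(f"no baseline frames in [-{baseline_ms}, 0) ms")
    f0 = session.movie[:, baseline].mean(axis=1)  # (trials, H, W)
    bad = f0 <= 0
    n_bad = int(bad.sum())
    f0_safe = np.where(bad, 1.0, f0)
    dff = (session.movie - f0_safe[:, np.newaxis]) / f0_safe[:, np.newaxis]
    if n_bad:
        dff[np.broadcast_to(bad[:, np.newaxis], dff.shape)] = np.nan
    info = {"n_baseline_frames": int(baseline.sum()), "n_nonpositive_f0_pixels": n_bad}
    return dff, info


def evoked_map(
    dff: np.ndarray,
    session: WidefieldSession,
    grid_point_id: int,
    window_ms: tuple[float, float] = (10.0, 260.0),
) -> EvokedMap:
    """Average ΔF/F over the evoked window and over a site's trials."""
    t = session.frame_times_ms
    lo, hi = window_ms
    in_window = (t >= lo) & (t <= hi)
    if not in_window.any():
        raise ValueError(f"no frames inside the evoked window [{lo}, {hi}] ms")
    trials = session.stim_log.loc[
        session.stim_log["grid_point_id"] == grid_point_id, "trial"
    ].astype(int)
    if trials.empty:
        raise ValueError(f"no trials for grid point {grid_point_id}")
    sub = dff[trials.to_numpy()][:, in_window]
    return EvokedMap(values=sub.mean(axis=(0, 1)), n_trials=len(trials), grid_point_id=grid_point_id)


def population_average(maps: Sequence[EvokedMap]) -> EvokedMap:
    """Trial-weighted mean of evoked maps across mice."""
    if not maps:
        raise ValueError("population_average requires at least one map")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"evoked maps have mismatched geometry: {sorted(shapes)}")
    weights = np.array([m.n_trials for m in maps], dtype=float)
    stacked = np.stack([m.values for m in maps])
    avg = np.tensordot(weights, stacked, axes=1) / weights.sum()
    return EvokedMap(values=avg, n_trials=int(weights.sum()), grid_point_id="population")


def frontal_center_of_mass(
    emap: EvokedMap,
    session: WidefieldSession,
    mask_origin: tuple[int, int],
    mask_shape: tuple[int, int] = (25, 40),
    frac: float = 0.8,
) -> CoMResult:
    """Value-weighted centroid of supra-threshold ΔF/F inside the frontal mask.

    The mask is a rectangle of ``mask_shape`` (rows, cols) binned pixels
    placed at ``mask_origin`` (top-left row, col).  The threshold is
    ``frac`` × the within-mask maximum; the center of mass weights the
    supra-threshold pixels by their ΔF/F value (positive by construction
    whenever the maximum is positive).  A mask with no positive pixel
    yields an undefined result, which downstream regressions drop.
    """
    r0, c0 = mask_origin
    nr, nc = mask_shape
    h, w = emap.values.shape
    if not (0 <= r0 and r0 + nr <= h and 0 <= c0 and c0 + nc <= w):
        raise ValueError(f"mask {mask_origin}+{mask_shape} not inside frame {(h, w)}")
    sub = emap.values[r0 : r0 + nr, c0 : c0 + nc]
    finite = np.isfinite(sub)
    if not finite.any() or np.nanmax(sub) <= 0:
        return CoMResult(
            ap_mm=float("nan"), ml_mm=float("nan"), row=float("nan"), col=float("nan"),
            threshold=float("nan"), defined=False,
            params={"mask_origin": mask_origin, "mask_shape": mask_shape, "frac": frac},
        )
    m = float(np.nanmax(sub))
    threshold = frac * m
    sel = finite & (sub >= threshold)
    rows, cols = np.nonzero(sel)
    wvals = sub[sel]
    row = float(np.average(rows, weights=wvals)) + r0
    col = float(np.average(cols, weights=wvals)) + c0
    ap_mm, ml_mm = session.pixel_to_mm(row, col)
    return CoMResult(
        ap_mm=ap_mm, ml_mm=ml_mm, row=row, col=col, threshold=threshold, defined=True,
        params={"mask_origin": mask_origin, "mask_shape": mask_shape, "frac": frac,
                "weighting": "value-weighted"},
    )


def save_session(session: WidefieldSession, path) -> None:
    """Write a session as HDF5: movie, timestamps, stim log, geometry attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("movie", data=session.movie, compression="gzip")
        f.create_dataset("frame_times_ms", data=session.frame_times_ms)
        log = f.create_group("stim_log")
        for col in ("trial", "grid_point_id", "stim_ml_mm", "stim_ap_mm"):
            log.create_dataset(col, data=session.stim_log[col].to_numpy())
        f.attrs["pixel_size_um"] = session.pixel_size_um
        f.attrs["bregma_pixel"] = list(session.bregma_pixel)
        f.attrs["mouse_id"] = session.mouse_id
        f.attrs["cre_line"] = session.cre_line


def load_session(path) -> WidefieldSession:
    """Read a session written by :func:`save_session`."""
    import h5py

    with h5py.File(path, "r") as f:
        stim_log = pd.DataFrame(
            {col: f["stim_log"][col][()] for col in ("trial", "grid_point_id",
                                                     "stim_ml_mm", "stim_ap_mm")}
        )
        return WidefieldSession(
            movie=f["movie"][()],
            frame_times_ms=f["frame_times_ms"][()],
            stim_log=stim_log,
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            bregma_pixel=tuple(f.attrs["bregma_pixel"]),
            mouse_id=str(f.attrs["mouse_id"]),
            cre_line=str(f.attrs["cre_line"]),
        )


def fit_functional_topography(
    points: pd.DataFrame,
) -> tuple[TopographyFit, dict[str, TopographyFit | None]]:
    """Population regression of response-center AP on stimulation |ML|.

    ``points`` needs columns ``mouse_id, stim_ml_mm, com_ap_mm``; rows with
    non-finite coordinates (undefined responses) are dropped.  Returns the
    pooled fit plus per-mouse fits (None for mice with fewer than two
    distinct stimulation positions, which still contribute to the pooled
    fit).
    """
    required = {"mouse_id", "stim_ml_mm", "com_ap_mm"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points missing column(s): {sorted(missing)}")
    work = points.copy()
    work["abs_ml"] = work["stim_ml_mm"].abs()
    finite = np.isfinite(work["abs_ml"]) & np.isfinite(work["com_ap_mm"])
    work = work[finite]
    pooled = fit_topography(list(zip(work["abs_ml"], work["com_ap_mm"])))
    per_mouse: dict[str, TopographyFit | None] = {}
    for mouse, sub in work.groupby("mouse_id"):
        x = sub["abs_ml"].to_numpy()
        y = sub["com_ap_mm"].to_numpy()
        if len(sub) < 2 or np.ptp(x) == 0:
            per_mouse[str(mouse)] = None
            continue
        res = stats.linregress(x, y)
        # per-mouse lines are for plotting; accept n=2 by bypassing the
        # n>=3 constraint of the population-level container
        fit = TopographyFit.__new__(TopographyFit)
        fit.slope = float(res.slope)
        fit.intercept = float(res.intercept)
        fit.r = float(res.rvalue)
        fit.p = float(res.pvalue)
        fit.n = len(sub)
        per_mouse[str(mouse)] = fit
    return pooled, per_mouse
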