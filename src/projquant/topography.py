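"""Motor-cortex hotspot topography and caudoputamen axis profiles.

Axons in layers 2/3 and 5 of the primary and secondary motor areas (MOp,
MOs) are sum-projected along the dorsoventral axis into a horizontal map,
Gaussian-filtered (σ = 4 pixels), and segmented at 75% and 95% of the
maximum.  The 75% contour area measures the horizontal spread of frontal
innervation; the unweighted centroid of the 95% set localizes the hotspot;
the mean filtered density in a 225 × 225 µm ROI around the peak measures
peak innervation density.  Regressing the hotspot's anteroposterior
position on the absolute mediolateral position of the injection center
tests the mirror-map organization: more lateral somatosensory injections
project to more anterior motor-cortex locations (positive slope under the
anterior-positive sign convention used throughout).

The caudoputamen analysis masks the density map to CP, filters (σ = 4
voxels) and extracts 1D profiles: anteroposterior and dorsoventral from the
ipsilateral hemisphere only, mediolateral bilaterally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .atlas import AP, DV, ML, AnnotationVolume, CoordinateFrame, StructureGraph
from .density import DensityMap

__all__ = [
    "HotspotResult",
    "TopographyFit",
    "AxisProfiles",
    "mo_axon_map",
    "hotspot_metrics",
    "fit_topography",
    "striatum_profiles",
]


@dataclass
class HotspotResult:
    """Hotspot contours, centroid, spread and peak density of a 2D map.

    ``defined`` is False for all-zero maps (samples without motor-cortex
    axons), in which case every metric is NaN and downstream regressions
    drop the sample.
    """

    filtered: np.ndarray
    contour_75: np.ndarray
    contour_95: np.ndarray
    area75_mm2: float
    centroid95_px: tuple[float, float]
    centroid95_mm: tuple[float, float]
    peak_pixel: tuple[int, int]
    peak_roi_density: float
    defined: bool = True
    params: dict = field(default_factory=dict)


@dataclass
class TopographyFit:
    """OLS fit AP = intercept + slope·|ML| with Pearson r and two-sided p."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise ValueError(f"fit requires n >= 3, got {self.n}")


@dataclass
class AxisProfiles:
    """1D caudoputamen density profiles with bregma-mm coordinates."""

    ap_mm: np.ndarray
    ap_curve: np.ndarray
    dv_mm: np.ndarray
    dv_curve: np.ndarray
    ml_mm: np.ndarray
    ml_curve: np.ndarray
    scopes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #


def _layer_ids(
    graph: StructureGraph, regions: Sequence[str], layers: Sequence[str]
) -> list[int]:
    """Resolve layer sub-structures like ``MOp2/3`` and their descendants."""
    ids: list[int] = []
    for region in regions:
        for layer in layers:
            acr = f"{region}{layer}"
            try:
                sid = graph.id_of(acr)
            except KeyError:
                raise ValueError(f"cannot resolve layer structure {acr!r} in graph") from None
            ids.extend(graph.self_and_descendants(sid))
    return sorted(set(ids))


def mo_axon_map(
    dmap: DensityMap,
    annotation: AnnotationVolume,
    graph: StructureGraph,
    regions: Sequence[str] = ("MOp", "MOs"),
    layers: Sequence[str] = ("2/3", "5"),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Horizontal (AP × ML) sum map of axons in selected motor-cortex layers.

    The mask is the union of the chosen layer structures of the chosen
    regions, both hemispheres; the masked density is sum-projected along
    DV, so the 2D total equals the 3D masked total.  A precomputed boolean
    ``mask`` may be supplied to amortize the structure lookup over a cohort.
    """
    if dmap.grid.shape != annotation.shape:
        raise ValueError("density map and annotation have mismatched geometry")
    if mask is None:
        ids = _layer_ids(graph, regions, layers)
        mask = np.isin(annotation.id_grid, ids)
    elif mask.shape != annotation.shape:
        raise ValueError("precomputed mask has mismatched geometry")
    out = np.zeros((annotation.shape[AP], annotation.shape[ML]))
    if not mask.any():
        return out
    # work inside the mask's bounding box; the full-frame product is wasted
    # arithmetic on a mostly-empty grid
    ap_idx, dv_idx, ml_idx = (np.flatnonzero(mask.any(axis=ax)) for ax in ((1, 2), (0, 2), (0, 1)))
    sl = (
        slice(ap_idx[0], ap_idx[-1] + 1),
        slice(dv_idx[0], dv_idx[-1] + 1),
        slice(ml_idx[0], ml_idx[-1] + 1),
    )
    out[sl[0], sl[2]] = (dmap.grid[sl] * mask[sl]).sum(axis=DV)
    return out


def hotspot_metrics(
    map2d: np.ndarray,
    frame: CoordinateFrame | None = None,
    pixel_size_um: float = 25.0,
    sigma_px: float = 4.0,
    levels: tuple[float, float] = (0.75, 0.95),
    roi_um: float = 225.0,
) -> HotspotResult:
    """Contour, centroid, spread and peak-density metrics of a horizontal map.

    The map is Gaussian-filtered (σ in pixels, reflect boundary); pixels at
    or above ``levels`` × max form the two contour sets (the 95% set is a
    subset of the 75% set by construction).  The centroid of the 95% set is
    unweighted over its pixels, even if disconnected.  ``peak_roi_density``
    is the mean of the *filtered* map over a square ROI (225 µm / 25 µm = 9
    pixels on a side) centered on the peak pixel, clipped at the borders,
    converted to axon voxels per mm² per neuron.  Ties at the maximum are
    resolved first-in-scan-order (row-major).

    An all-zero map yields a no-hotspot result with every metric NaN.
    """
    m2 = np.asarray(map2d, dtype=float)
    if m2.ndim != 2:
        raise ValueError("hotspot input must be a 2D map")
    lo_level, hi_level = levels
    if not (0.0 < lo_level < hi_level <= 1.0):
        raise ValueError(f"levels must satisfy 0 < lo < hi <= 1, got {levels}")

    if not np.any(m2 > 0):
        nanpair = (float("nan"), float("nan"))
        return HotspotResult(
            filtered=np.zeros_like(m2),
            contour_75=np.zeros_like(m2, dtype=bool),
            contour_95=np.zeros_like(m2, dtype=bool),
            area75_mm2=float("nan"),
            centroid95_px=nanpair,
            centroid95_mm=nanpair,
            peak_pixel=(-1, -1),
            peak_roi_density=float("nan"),
            defined=False,
            params={"sigma_px": sigma_px, "levels": levels, "roi_um": roi_um},
        )

    filt = ndimage.gaussian_filter(m2, sigma=sigma_px, mode="reflect") if sigma_px > 0 else m2
    peak_val = filt.max()
    contour_lo = filt >= lo_level * peak_val
    contour_hi = filt >= hi_level * peak_val
    assert not np.any(contour_hi & ~contour_lo)

    px_mm = pixel_size_um / 1000.0
    area75 = float(contour_lo.sum()) * px_mm**2

    hi_pixels = np.argwhere(contour_hi)
    centroid_px = tuple(float(c) for c in hi_pixels.mean(axis=0))
    if frame is not None:
        # horizontal map axes are (AP, ML); DV is the projection axis
        mm = frame.voxel_to_bregma_mm([centroid_px[0], 0.0, centroid_px[1]])
        centroid_mm = (float(mm[AP]), float(mm[ML]))
    else:
        centroid_mm = (float("nan"), float("nan"))

    peak_pixel = np.unravel_index(int(np.argmax(filt)), filt.shape)
    n_roi = int(round(roi_um / pixel_size_um))
    half = n_roi // 2
    r0 = max(0, peak_pixel[0] - half)
    r1 = min(filt.shape[0], peak_pixel[0] + half + 1)
    c0 = max(0, peak_pixel[1] - half)
    c1 = min(filt.shape[1], peak_pixel[1] + half + 1)
    peak_roi_density = float(filt[r0:r1, c0:c1].mean()) / px_mm**2

    return HotspotResult(
        filtered=filt,
        contour_75=contour_lo,
        contour_95=contour_hi,
        area75_mm2=area75,
        centroid95_px=centroid_px,  # type: ignore[arg-type]
        centroid95_mm=centroid_mm,
        peak_pixel=(int(peak_pixel[0]), int(peak_pixel[1])),
        peak_roi_density=peak_roi_density,
        defined=True,
        params={
            "sigma_px": float(sigma_px),
            "levels": tuple(levels),
            "roi_um": float(roi_um),
            "pixel_size_um": float(pixel_size_um),
            "roi_px": n_roi,
        },
    )


def fit_topography(points: Sequence[tuple[float, float]]) -> TopographyFit:
    """OLS regression of hotspot AP position on |ML| of the injection center.

    ``points`` are (|ML| mm, AP mm) pairs; non-finite pairs (samples without
    a hotspot) are dropped first.  Requires at least 3 finite points and
    nonzero variance in |ML|.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
    finite = np.all(np.isfinite(pts), axis=1)
    pts = pts[finite]
    n = len(pts)
    if n < 3:
        raise ValueError(f"topography fit requires >= 3 finite points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in |ML| positions; regression undefined")
    res = stats.linregress(x, y)
    return TopographyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
    )


def striatum_profiles(
    dmap: DensityMap,
    annotation: AnnotationVolume,
    graph: StructureGraph,
    frame: CoordinateFrame,
    injection_side: str,
    sigma_voxels: float = 4.0,
    cp_acronym: str = "CP",
) -> AxisProfiles:
    """1D caudoputamen innervation profiles along the three anatomical axes.

    The map is masked to CP (and descendants), Gaussian-filtered, and
    summed: the AP and DV curves use the ipsilateral hemisphere only, the
    ML curve both hemispheres.  Curves are cropped to the CP bounding box
    along their axis and reported against bregma-mm coordinates.
    """
    try:
        cp_id = graph.id_of(cp_acronym)
    except KeyError:
        raise ValueError(f"structure {cp_acronym!r} absent from atlas graph") from None
    if dmap.grid.shape != annotation.shape:
        raise ValueError("density map and annotation have mismatched geometry")
    cp_ids = graph.self_and_descendants(cp_id)
    cp_mask = np.isin(annotation.id_grid, cp_ids)
    if not cp_mask.any():
        raise ValueError(f"structure {cp_acronym!r} has no voxels in the annotation")

    masked = dmap.grid * cp_mask
    filt = ndimage.gaussian_filter(masked, sigma=sigma_voxels, mode="reflect") if sigma_voxels > 0 else masked

    hemi = frame.hemisphere_of(
        np.stack(
            [
                np.zeros(annotation.shape[ML]),
                np.zeros(annotation.shape[ML]),
                np.arange(annotation.shape[ML], dtype=float),
            ],
            axis=-1,
        ),
        injection_side,
    )
    ipsi_cols = np.asarray(hemi) == "ipsi"
    ipsi_vol = filt * ipsi_cols[np.newaxis, np.newaxis, :]

    ap_idx = np.flatnonzero(cp_mask.any(axis=(DV, ML)))
    dv_idx = np.flatnonzero(cp_mask.any(axis=(AP, ML)))
    ml_idx = np.flatnonzero(cp_mask.any(axis=(AP, DV)))
    ap_lo, ap_hi = ap_idx[0], ap_idx[-1] + 1
    dv_lo, dv_hi = dv_idx[0], dv_idx[-1] + 1
    ml_lo, ml_hi = ml_idx[0], ml_idx[-1] + 1

    ap_curve = ipsi_vol.sum(axis=(DV, ML))[ap_lo:ap_hi]
    dv_curve = ipsi_vol.sum(axis=(AP, ML))[dv_lo:dv_hi]
    ml_curve = filt.sum(axis=(AP, DV))[ml_lo:ml_hi]

    scale = frame.voxel_size_um / 1000.0
    ap_mm = (frame.bregma_voxel[AP] - np.arange(ap_lo, ap_hi, dtype=float)) * scale
    dv_mm = (np.arange(dv_lo, dv_hi, dtype=float) - frame.bregma_voxel[DV]) * scale
    ml_mm = (np.arange(ml_lo, ml_hi, dtype=float) - frame.midline_ml) * scale

    return AxisProfiles(
        ap_mm=ap_mm,
        ap_curve=ap_curve,
        dv_mm=dv_mm,
        dv_curve=dv_curve,
        ml_mm=ml_mm,
        ml_curve=ml_curve,
        scopes={
            "ap": "ipsilateral",
            "dv": "ipsilateral",
            "ml": "bilateral",
            "sigma_voxels": float(sigma_voxels),
            "injection_side": injection_side,
        },
    )
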