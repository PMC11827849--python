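"""Sarcomere filament metrology and flow-cytometry calibration.

Segments GFP-titin filaments from 2-D fluorescence images and computes the
per-filament geometry used to characterize sarcomere organization: primary
and secondary axis lengths (lambda1, lambda2, equivalent-ellipse convention),
area, orientation relative to the image vertical axis, and center-to-center
neighbor spacing d along the filament string.  Also fits the affine
AU -> MEFL conversion from rainbow-bead calibration tables so GFP
intensities are comparable across acquisition days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import filters, measure

from .stats import TestResult, bh_adjust, welch_t

__all__ = [
    "Filament",
    "FilamentSet",
    "MeflCalibration",
    "axis_vector_from_angle",
    "angle_from_vertical",
    "segment_filaments",
    "filament_metrics",
    "filament_spacing",
    "count_and_compare",
    "mefl_calibrate",
    "apply_mefl",
]

# Angle convention: degrees clockwise from the image vertical axis (screen
# "up"), reported in [-90, 90).  In array coordinates (x = column rightward,
# y = row downward) the major-axis unit vector of a filament at angle theta
# is (sin theta, -cos theta).


def axis_vector_from_angle(angle_deg: float) -> tuple[float, float]:
    """Unit (vx, vy) in array coordinates for an angle from vertical."""
    t = np.deg2rad(angle_deg)
    return (float(np.sin(t)), float(-np.cos(t)))


def angle_from_vertical(vx: float, vy: float) -> float:
    """Angle in degrees clockwise from vertical, normalized to [-90, 90)."""
    ang = np.rad2deg(np.arctan2(vx, -vy))
    return float(((ang + 90.0) % 180.0) - 90.0)


@dataclass
class Filament:
    """One segmented filament with equivalent-ellipse geometry.

    ``lambda1``/``lambda2`` are the full primary/secondary axis lengths of
    the ellipse with the same second central moments as the pixel set
    (4 * sqrt(eigenvalue) * um_per_px).  ``angle_deg`` is the major-axis
    orientation from the vertical axis in [-90, 90); NaN for isotropic
    components where orientation is undefined.
    """

    id: str
    centroid: tuple[float, float]  # (x, y) px
    pixels: np.ndarray  # (n, 2) array of (row, col)
    area_um2: float = np.nan
    lambda1_um: float = np.nan
    lambda2_um: float = np.nan
    angle_deg: float = np.nan


@dataclass
class FilamentSet:
    filaments: list[Filament]
    um_per_px: float
    threshold: float | None = None
    image_shape: tuple[int, int] | None = None
    spacing: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["i", "j", "d_um"]))

    def __len__(self) -> int:
        return len(self.filaments)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "id": f.id, "x": f.centroid[0], "y": f.centroid[1],
            "lambda1_um": f.lambda1_um, "lambda2_um": f.lambda2_um,
            "area_um2": f.area_um2, "angle_deg": f.angle_deg,
        } for f in self.filaments]
        return pd.DataFrame(rows, columns=["id", "x", "y", "lambda1_um",
                                           "lambda2_um", "area_um2", "angle_deg"])


def segment_filaments(
    image: np.ndarray,
    um_per_px: float,
    threshold_policy: str | float = "otsu",
    min_area_px: int = 5,
    background_sigma_px: float = 25.0,
    smooth_sigma_px: float = 1.0,
) -> FilamentSet:
    """Threshold-based filament segmentation with illumination correction.

    The background is estimated by a large-kernel Gaussian blur
    (``background_sigma_px`` much larger than a filament width) and
    subtracted; a light denoising blur (``smooth_sigma_px``, 0 to disable)
    suppresses shot noise below the filament scale; a global threshold
    (Otsu by default, or a fixed value) on the corrected image defines
    foreground, and connected components smaller than ``min_area_px`` are
    discarded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    smoothed = (filters.gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
                if smooth_sigma_px > 0 else img)
    corrected = smoothed - filters.gaussian(img, sigma=background_sigma_px,
                                            preserve_range=True)
    corrected = np.clip(corrected, 0.0, None)

    if isinstance(threshold_policy, str):
        if threshold_policy != "otsu":
            raise ValueError("threshold_policy must be 'otsu' or a fixed value")
        if np.ptp(corrected) == 0:
            warnings.warn("uniform image: no filaments segmented", stacklevel=2)
            return FilamentSet([], um_per_px, None, img.shape)
        thr = float(filters.threshold_otsu(corrected))
    else:
        thr = float(threshold_policy)

    binary = corrected > thr
    labels = measure.label(binary, connectivity=2)
    filaments: list[Filament] = []
    for i, region in enumerate(measure.regionprops(labels)):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        filaments.append(Filament(
            id=f"fil{len(filaments):04d}", centroid=(float(cx), float(cy)),
            pixels=region.coords.copy()))
    if not filaments and isinstance(threshold_policy, str):
        warnings.warn("no filaments above threshold", stacklevel=2)
    return FilamentSet(filaments, um_per_px, thr, img.shape)


#: eigenvalue floor so a single-pixel component reports a one-pixel axis
_EV_FLOOR = 1.0 / 16.0
#: relative anisotropy below which orientation is reported as undefined
_ISO_TOL = 1e-3


def filament_metrics(fs: FilamentSet) -> FilamentSet:
    """Fill lambda1, lambda2, area, and angle for every filament (in place).

    Axes come from the eigen-decomposition of the pixel-coordinate second
    central moments: lambda = 4 * sqrt(eigenvalue) * um_per_px, the full
    axis lengths of the equivalent ellipse.  Near-isotropic components
    (lambda1 ~ lambda2) get an undefined (NaN) angle.
    """
    s = fs.um_per_px
    for f in fs.filaments:
        if f.pixels.size == 0:
            raise ValueError(f"filament {f.id} has an empty pixel set")
        ys = f.pixels[:, 0].astype(float)
        xs = f.pixels[:, 1].astype(float)
        f.area_um2 = float(len(xs)) * s * s
        cov = np.cov(np.stack([xs, ys]), bias=True) if len(xs) > 1 else np.zeros((2, 2))
        evals, evecs = np.linalg.eigh(cov)  # ascending
        evals = np.maximum(evals, _EV_FLOOR)
        f.lambda1_um = 4.0 * float(np.sqrt(evals[1])) * s
        f.lambda2_um = 4.0 * float(np.sqrt(evals[0])) * s
        if (evals[1] - evals[0]) / evals[1] < _ISO_TOL:
            f.angle_deg = np.nan
        else:
            vx, vy = evecs[:, 1]
            f.angle_deg = angle_from_vertical(float(vx), float(vy))
    return fs


def filament_spacing(
    fs: FilamentSet,
    max_gap_um: float = 3.0,
    max_angle_diff_deg: float = 15.0,
) -> tuple[pd.DataFrame, float]:
    """Center-to-center spacing d between neighboring filaments in a string.

    For each filament, the nearest neighbor lying along its own major-axis
    direction (offset direction within ``max_angle_diff_deg`` of the axis,
    similarly oriented, and closer than ``max_gap_um``) contributes one
    spacing record; each unordered pair is recorded once.  Returns the
    records and the mean d (NaN when there are none).
    """
    if any(np.isnan(f.lambda1_um) for f in fs.filaments):
        filament_metrics(fs)
    records: set[tuple[int, int]] = set()
    dists: dict[tuple[int, int], float] = {}
    n = len(fs.filaments)
    for i, f in enumerate(fs.filaments):
        if np.isnan(f.angle_deg):
            continue
        u = np.array(axis_vector_from_angle(f.angle_deg))
        best, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            g = fs.filaments[j]
            if not np.isnan(g.angle_deg):
                dang = abs(f.angle_deg - g.angle_deg)
                dang = min(dang, 180.0 - dang)
                if dang > max_angle_diff_deg:
                    continue
            off = np.array([g.centroid[0] - f.centroid[0],
                            g.centroid[1] - f.centroid[1]])
            d_px = float(np.hypot(*off))
            if d_px == 0 or d_px * fs.um_per_px > max_gap_um:
                continue
            cosang = abs(float(off @ u)) / d_px
            if np.rad2deg(np.arccos(np.clip(cosang, -1, 1))) > max_angle_diff_deg:
                continue
            if d_px < best_d:
                best, best_d = j, d_px
        if best is not None:
            pair = (min(i, best), max(i, best))
            records.add(pair)
            dists[pair] = best_d * fs.um_per_px
    ids = [f.id for f in fs.filaments]
    table = pd.DataFrame(
        [{"i": ids[a], "j": ids[b], "d_um": dists[(a, b)]}
         for a, b in sorted(records)],
        columns=["i", "j", "d_um"])
    fs.spacing = table
    mean_d = float(table["d_um"].mean()) if len(table) else float("nan")
    return table, mean_d


def count_and_compare(
    groups: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype filament-count summaries and pairwise Welch comparisons.

    ``groups`` maps genotype -> per-well filament counts.  Groups with fewer
    than two wells are summarized but skipped in comparisons; BH adjustment
    spans all pairwise tests in this call.
    """
    summary_rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        summary_rows.append({
            "group": name, "n_wells": v.size, "mean": float(v.mean()) if v.size else np.nan,
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan})
    summary = pd.DataFrame(summary_rows)

    names = [n for n in groups if len(groups[n]) >= 2]
    skipped = [n for n in groups if len(groups[n]) < 2]
    if skipped:
        warnings.warn(f"groups with < 2 wells skipped in comparisons: {skipped}",
                      stacklevel=2)
    comp_rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            res = welch_t(groups[names[a]], groups[names[b]])
            comp_rows.append({"group_a": names[a], "group_b": names[b],
                              "mean_diff": res.estimate, "t": res.statistic,
                              "df": res.df, "p": res.p})
    comps = pd.DataFrame(comp_rows, columns=["group_a", "group_b", "mean_diff",
                                             "t", "df", "p"])
    comps["p_adj"] = bh_adjust(comps["p"].to_numpy()) if len(comps) else []
    return summary, comps


@dataclass
class MeflCalibration:
    """Affine AU -> MEFL map fitted from rainbow-bead peaks."""

    slope: float
    intercept: float
    residual_sd: float
    n_peaks: int


def mefl_calibrate(beads: pd.DataFrame | Sequence[tuple[float, float]]) -> MeflCalibration:
    """Least-squares affine fit of bead MEFL reference values against AU.

    ``beads`` is a table with ``au`` and ``mefl`` columns or a sequence of
    (AU, MEFL) pairs; at least two peaks with non-zero AU variance required.
    """
    if isinstance(beads, pd.DataFrame):
        au = beads["au"].to_numpy(dtype=float)
        mefl = beads["mefl"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(beads), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (AU, MEFL) pairs")
        au, mefl = arr[:, 0], arr[:, 1]
    if au.size < 2:
        raise ValueError("need at least 2 bead peaks")
    if np.ptp(au) == 0:
        raise ValueError("zero AU variance: calibration is underdetermined")
    fit = sps.linregress(au, mefl)
    resid = mefl - (fit.slope * au + fit.intercept)
    rsd = float(np.sqrt((resid ** 2).sum() / (au.size - 2))) if au.size > 2 else 0.0
    return MeflCalibration(float(fit.slope), float(fit.intercept), rsd, int(au.size))


def apply_mefl(calibration: MeflCalibration, au_values) -> np.ndarray:
    """Convert instrument AU values to MEFL with a fitted calibration."""
    au = np.asarray(au_values, dtype=float)
    return calibration.slope * au + calibration.intercept
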