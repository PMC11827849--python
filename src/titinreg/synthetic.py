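"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its downstream analysis
assumes — negative-binomial barcode counts over a libraries x wells MPRA
design, (beta-)binomial allele counts at a programmed allelic ratio,
time-lapse micropillar stacks with a programmed subpixel twitch, striated
filament fields with known axes/spacing/orientation, and affine bead
calibration tables — and returns a :class:`SimTruth` record holding every
generator argument plus the per-item latent quantity, so parameter-recovery
tests can compare pipeline estimates against exact truth.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
arguments and seed reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mpra import BarcodeCountMatrix, ConstructDesign
from .sarcomere import axis_vector_from_angle

__all__ = [
    "SimTruth",
    "gen_mpra_counts",
    "gen_ase_counts",
    "gen_pillar_stack",
    "gen_sarcomere_image",
    "gen_bead_table",
    "demo_scan_design",
]

STAGES = ("mpra", "ase", "pillar", "sarcomere", "beads")


@dataclass
class SimTruth:
    """Ground truth for one synthetic data set.

    ``parameters`` records every generator argument; ``per_item_truth`` is a
    table keyed by item id (construct, sample, frame, filament, or bead peak)
    holding the true latent quantity for that item.
    """

    stage: str
    parameters: dict
    per_item_truth: pd.DataFrame

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.per_item_truth.index.has_duplicates:
            raise ValueError("duplicate item ids in truth table")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + dispersion * mu^2.

    dispersion = 0 degrades to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# MPRA

def gen_mpra_counts(
    design: pd.DataFrame,
    n_libraries: int = 3,
    n_wells: int = 4,
    mean_depth: float = 1000.0,
    dispersion: float = 0.1,
    library_sigma: float = 0.25,
    seed: int = 0,
) -> tuple[BarcodeCountMatrix, BarcodeCountMatrix, SimTruth]:
    """Paired DNA/RNA barcode count matrices for a pooled reporter library.

    ``design`` needs columns ``construct_id`` and ``activity`` (true
    transcriptional activity, dimensionless; the wild-type element is 1).
    Each construct gets a library-specific plasmid abundance (log-normal
    around ``mean_depth`` with sd ``library_sigma`` on the log scale, shared
    by that library's wells).  DNA counts are negative-binomial around the
    abundance; RNA expected counts are abundance x activity.  The replicate
    axis is the n_libraries x n_wells grid, mirroring a design in which each
    construct enters several independent libraries each transfected into
    several wells.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    if n_libraries < 1 or n_wells < 1:
        raise ValueError("need n_libraries >= 1 and n_wells >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    activities = np.asarray(design["activity"], dtype=float)
    if np.any(activities < 0):
        raise ValueError("activities must be >= 0")
    ids = list(design["construct_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate construct_id in design")

    rng = np.random.default_rng(seed)
    n_c = len(ids)
    rep_ids = [f"L{l}W{w}" for l in range(1, n_libraries + 1)
               for w in range(1, n_wells + 1)]
    replicates = pd.DataFrame(
        {"library": np.repeat(np.arange(1, n_libraries + 1), n_wells),
         "well": np.tile(np.arange(1, n_wells + 1), n_libraries)},
        index=rep_ids)

    # construct x library plasmid abundances, shared across that library's wells
    abund = mean_depth * np.exp(rng.normal(0.0, library_sigma, size=(n_c, n_libraries)))
    dna = np.empty((n_c, n_libraries * n_wells), dtype=np.int64)
    rna = np.empty_like(dna)
    for l in range(n_libraries):
        for w in range(n_wells):
            j = l * n_wells + w
            dna[:, j] = _nb_draw(rng, abund[:, l], dispersion)
            rna[:, j] = _nb_draw(rng, abund[:, l] * activities, dispersion)

    truth = pd.DataFrame({"activity": activities}, index=pd.Index(ids, name="construct_id"))
    params = dict(n_libraries=n_libraries, n_wells=n_wells, mean_depth=mean_depth,
                  dispersion=dispersion, library_sigma=library_sigma, seed=seed)
    return (
        BarcodeCountMatrix("DNA", pd.DataFrame(dna, index=ids, columns=rep_ids),
                           replicates),
        BarcodeCountMatrix("RNA", pd.DataFrame(rna, index=ids, columns=rep_ids),
                           replicates),
        SimTruth("mpra", params, truth),
    )


def demo_scan_design(
    element_interval: tuple[int, int] = (1001, 1134),
    n_tf_sites: int = 6,
    site_width: int = 12,
    silenced_sites: Sequence[int] = (1, 3),
    silenced_activity: float = 0.4,
    barcodes_per_construct: int = 10,
) -> tuple[list[ConstructDesign], pd.DataFrame]:
    """A small saturation-mutagenesis design for demos and pipeline tests.

    Builds a wild-type element, a minimal-promoter control, one binding-site
    deletion plus one point-mutation construct per predicted site (sites
    tiled across the element), and 5'/3' end-deletion series.  Sites listed
    in ``silenced_sites`` carry true activity ``silenced_activity`` for both
    their deletion and point-mutation constructs; everything else is neutral
    (activity 1).  Returns the construct list and the activity table that
    :func:`gen_mpra_counts` consumes.
    """
    start, end = element_interval
    length = end - start + 1
    if n_tf_sites * site_width > length:
        raise ValueError("sites do not fit in the element")
    gap = (length - n_tf_sites * site_width) // max(n_tf_sites, 1)
    designs: list[ConstructDesign] = []
    acts: list[tuple[str, float, str]] = []
    bc_counter = 0

    def bcs() -> frozenset[str]:
        nonlocal bc_counter
        out = frozenset(f"BC{bc_counter + j:06d}" for j in range(barcodes_per_construct))
        bc_counter += barcodes_per_construct
        return out

    designs.append(ConstructDesign("WT", "wt", None, "", bcs()))
    acts.append(("WT", 1.0, "wt"))
    designs.append(ConstructDesign("minP", "control_minP", None, "", bcs()))
    acts.append(("minP", 0.2, "control_minP"))

    pos = start
    for i in range(1, n_tf_sites + 1):
        site = (pos, pos + site_width - 1)
        label = f"site_{i}"
        a = silenced_activity if i in silenced_sites else 1.0
        did, pid = f"del_{label}", f"pm_{label}"
        designs.append(ConstructDesign(did, "tf_deletion", site, label, bcs()))
        acts.append((did, a, "tf_deletion"))
        mid = (site[0] + site[1]) // 2
        designs.append(ConstructDesign(pid, "point_mutation", (mid, mid), label, bcs()))
        acts.append((pid, a, "point_mutation"))
        pos += site_width + gap

    for k, size in enumerate((10, 30, 50), start=1):
        c5 = f"del5p_{size}"
        designs.append(ConstructDesign(
            c5, "end_deletion_5p", (start, start + size - 1), "", bcs()))
        acts.append((c5, 1.0, "end_deletion_5p"))
        c3 = f"del3p_{size}"
        designs.append(ConstructDesign(
            c3, "end_deletion_3p", (end - size + 1, end), "", bcs()))
        acts.append((c3, 1.0, "end_deletion_3p"))

    table = pd.DataFrame(acts, columns=["construct_id", "activity", "category"])
    return designs, table


# ---------------------------------------------------------------------------
# Allele-specific expression

def gen_ase_counts(
    n_per_genotype: int = 5,
    true_ratio: float = 0.5,
    n_snps: int = 10,
    depth_per_snp: int = 10_000,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-SNP allele counts from hybrid-background RNA sequencing.

    For heterozygous-deletion samples the mutant-linked allele fraction is
    ``p = r / (1 + r)`` with ``r = true_ratio``; wild-type samples use r = 1.
    ``dispersion`` in [0, 1) adds beta-binomial overdispersion with
    intraclass correlation rho = dispersion (0 = pure binomial), emulating
    SNP-to-SNP variability in allelic capture.  SNPs with zero depth are
    emitted with zero counts and ``flag = "zero_depth"``.

    Returns a tidy table with columns (sample_id, genotype, snp_id, allele,
    count, flag) where genotype is ``wt`` or ``het`` (deletion carrier) and
    allele is ``mut_linked`` or ``wt_linked``.
    """
    if true_ratio < 0:
        raise ValueError("true_ratio must be >= 0")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if depth_per_snp < 0:
        raise ValueError("negative depth")
    if not 0 <= dispersion < 1:
        raise ValueError("dispersion must be in [0, 1)")

    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for geno, r in (("wt", 1.0), ("het", float(true_ratio))):
        p = r / (1.0 + r)
        for s in range(1, n_per_genotype + 1):
            sid = f"{geno}_{s}"
            truth_rows.append({"sample_id": sid, "genotype": geno, "true_ratio": r})
            for k in range(1, n_snps + 1):
                snp = f"snp{k:03d}"
                depth = depth_per_snp
                flag = ""
                if depth == 0:
                    mut = 0
                    flag = "zero_depth"
                else:
                    if dispersion > 0 and 0.0 < p < 1.0:
                        conc = (1.0 - dispersion) / dispersion
                        p_draw = rng.beta(p * conc, (1.0 - p) * conc)
                    else:
                        p_draw = p
                    mut = int(rng.binomial(depth, p_draw))
                rows.append((sid, geno, snp, "mut_linked", mut, flag))
                rows.append((sid, geno, snp, "wt_linked", depth - mut, flag))
    table = pd.DataFrame(rows, columns=["sample_id", "genotype", "snp_id",
                                        "allele", "count", "flag"])
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    params = dict(n_per_genotype=n_per_genotype, true_ratio=true_ratio,
                  n_snps=n_snps, depth_per_snp=depth_per_snp,
                  dispersion=dispersion, seed=seed)
    return table, SimTruth("ase", params, truth)


# ---------------------------------------------------------------------------
# Micropillar time-lapse

def _render_cap(shape: tuple[int, int], cx: float, cy: float,
                radius: float, edge_sigma: float) -> np.ndarray:
    """Radially symmetric disk with a smooth logistic edge, peak value 1."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    return 1.0 / (1.0 + np.exp((r - radius) / edge_sigma))


def gen_pillar_stack(
    frame_size: tuple[int, int] = (128, 256),
    pillar_centers: tuple[tuple[float, float], tuple[float, float]] = ((64.0, 64.0), (192.0, 64.0)),
    cap_radius: float = 10.0,
    amplitude_um: float = 1.0,
    period_frames: int = 30,
    n_frames: int = 60,
    um_per_px: float = 0.1625,
    noise_sd: float = 0.0,
    background: float = 200.0,
    cap_intensity: float = 3000.0,
    edge_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """Time-lapse stack of two pillar caps, one twitching periodically.

    The second pillar's cap translates toward the first along the
    inter-pillar axis by ``amplitude_um * waveform(t)`` where the waveform is
    a raised-cosine twitch with period ``period_frames`` (30 frames at
    30 fps = 1 Hz pacing).  ``frame_size`` is (height, width); centers are
    (x, y) in pixels.  Returns a uint16 stack of shape
    (n_frames, height, width) and per-frame truth with the exact subpixel
    moving-cap center and deflection in um.
    """
    if amplitude_um < 0:
        raise ValueError("amplitude_um must be >= 0")
    if n_frames < 1 or period_frames < 1:
        raise ValueError("need n_frames >= 1 and period_frames >= 1")
    h, w = frame_size
    (x0, y0), (x1, y1) = pillar_centers
    axis = np.array([x0 - x1, y0 - y1], dtype=float)
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("pillar centers coincide")
    axis /= norm
    amp_px = amplitude_um / um_per_px
    margin = cap_radius + 5.0 * edge_sigma
    for cx, cy in [(x0, y0), (x1, y1), (x1 + axis[0] * amp_px, y1 + axis[1] * amp_px)]:
        if not (margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin):
            raise ValueError("pillar cap leaves the frame at maximum deflection")

    rng = np.random.default_rng(seed)
    static = _render_cap((h, w), x0, y0, cap_radius, edge_sigma)
    t = np.arange(n_frames)
    wave = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t % period_frames) / period_frames))
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    truth_rows = []
    for i in range(n_frames):
        defl_um = amplitude_um * wave[i]
        cx = x1 + axis[0] * (defl_um / um_per_px)
        cy = y1 + axis[1] * (defl_um / um_per_px)
        frame = background + cap_intensity * (static + _render_cap((h, w), cx, cy,
                                                                   cap_radius, edge_sigma))
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        stack[i] = np.clip(frame, 0, 65535).astype(np.uint16)
        truth_rows.append({"frame": i, "x_static": x0, "y_static": y0,
                           "x_moving": cx, "y_moving": cy,
                           "deflection_um": defl_um})
    truth = pd.DataFrame(truth_rows).set_index("frame")
    params = dict(frame_size=list(frame_size),
                  pillar_centers=[list(pillar_centers[0]), list(pillar_centers[1])],
                  cap_radius=cap_radius, amplitude_um=amplitude_um,
                  period_frames=period_frames, n_frames=n_frames,
                  um_per_px=um_per_px, noise_sd=noise_sd, background=background,
                  cap_intensity=cap_intensity, edge_sigma=edge_sigma, seed=seed)
    return stack, SimTruth("pillar", params, truth)


# ---------------------------------------------------------------------------
# Sarcomere filament fields

def gen_sarcomere_image(
    n_strings: int = 6,
    filaments_per_string: int = 4,
    lambda1_um: float = 1.2,
    lambda2_um: float = 0.45,
    spacing_um: float = 1.8,
    angle_deg: float = 30.0,
    um_per_px: float = 0.1625,
    background: float = 100.0,
    noise_sd: float = 5.0,
    amplitude: float = 1000.0,
    image_size: tuple[int, int] = (360, 360),
    min_separation_um: float = 3.5,
    seed: int = 0,
    supersample: int = 4,
    max_tries: int = 2000,
) -> tuple[np.ndarray, SimTruth]:
    """Field of striated filament strings with known geometry.

    Each string is ``filaments_per_string`` solid ellipses (full axes
    lambda1 x lambda2, rendered with subpixel-accurate partial-volume edges)
    laid end-to-end along the string direction at center-to-center distance
    ``spacing_um``; the string direction — and therefore each filament's
    major axis — is rotated ``angle_deg`` clockwise from the image vertical
    axis.  Strings are placed by rejection sampling so filaments of
    different strings stay at least ``min_separation_um`` apart.

    Raises if ``spacing_um <= lambda1_um`` (consecutive filaments would
    overlap) or if the field cannot be placed without violating the
    separation constraint.
    """
    if spacing_um <= lambda2_um:
        raise ValueError("spacing_um must exceed lambda2_um")
    if spacing_um <= lambda1_um:
        raise ValueError("spacing_um <= lambda1_um: consecutive filaments overlap")
    if lambda1_um < lambda2_um:
        raise ValueError("lambda1_um must be >= lambda2_um")
    h, w = image_size
    rng = np.random.default_rng(seed)

    a_px = 0.5 * lambda1_um / um_per_px
    b_px = 0.5 * lambda2_um / um_per_px
    spacing_px = spacing_um / um_per_px
    min_sep_px = min_separation_um / um_per_px
    v = axis_vector_from_angle(angle_deg)  # (vx, vy) unit, array coords
    margin = a_px + 2.0

    centers: list[tuple[float, float]] = []
    string_of: list[int] = []
    string_len = (filaments_per_string - 1) * spacing_px
    placed = 0
    tries = 0
    while placed < n_strings:
        if tries >= max_tries:
            raise ValueError(
                "could not place strings without overlap; reduce n_strings "
                "or min_separation_um, or enlarge the image")
        tries += 1
        sx = rng.uniform(margin, w - 1 - margin)
        sy = rng.uniform(margin, h - 1 - margin)
        cand = [(sx + k * spacing_px * v[0], sy + k * spacing_px * v[1])
                for k in range(filaments_per_string)]
        if not all(margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin
                   for cx, cy in cand):
            continue
        if any(np.hypot(cx - ox, cy - oy) < min_sep_px
               for cx, cy in cand for ox, oy in centers):
            continue
        centers.extend(cand)
        string_of.extend([placed + 1] * filaments_per_string)
        placed += 1

    # supersampled binary rendering -> per-pixel area coverage
    ss = supersample
    cover = np.zeros((h, w), dtype=float)
    u_major = np.array(v)
    u_minor = np.array([-v[1], v[0]])
    patch_r = int(np.ceil(a_px)) + 2
    for cx, cy in centers:
        x_lo, x_hi = int(np.floor(cx)) - patch_r, int(np.ceil(cx)) + patch_r
        y_lo, y_hi = int(np.floor(cy)) - patch_r, int(np.ceil(cy)) + patch_r
        xs = (np.arange(x_lo * ss, (x_hi + 1) * ss) + 0.5) / ss - 0.5
        ys = (np.arange(y_lo * ss, (y_hi + 1) * ss) + 0.5) / ss - 0.5
        gx, gy = np.meshgrid(xs - cx, ys - cy)
        uu = gx * u_major[0] + gy * u_major[1]
        ww = gx * u_minor[0] + gy * u_minor[1]
        inside = (uu / a_px) ** 2 + (ww / b_px) ** 2 <= 1.0
        patch = inside.reshape(y_hi - y_lo + 1, ss, x_hi - x_lo + 1, ss).mean(axis=(1, 3))
        # clip the patch to the image bounds
        yc_lo, yc_hi = max(y_lo, 0), min(y_hi, h - 1)
        xc_lo, xc_hi = max(x_lo, 0), min(x_hi, w - 1)
        cover[yc_lo:yc_hi + 1, xc_lo:xc_hi + 1] += \
            patch[yc_lo - y_lo:yc_hi - y_lo + 1, xc_lo - x_lo:xc_hi - x_lo + 1]

    img = background + amplitude * cover
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    if centers:
        truth = pd.DataFrame({
            "x": [c[0] for c in centers], "y": [c[1] for c in centers],
            "lambda1_um": lambda1_um, "lambda2_um": lambda2_um,
            "angle_deg": ((angle_deg + 90.0) % 180.0) - 90.0,
            "string": string_of,
        }, index=pd.Index([f"fil{i:04d}" for i in range(len(centers))], name="filament_id"))
    else:
        truth = pd.DataFrame(columns=["x", "y", "lambda1_um", "lambda2_um",
                                      "angle_deg", "string"],
                             index=pd.Index([], name="filament_id"))
    params = dict(n_strings=n_strings, filaments_per_string=filaments_per_string,
                  lambda1_um=lambda1_um, lambda2_um=lambda2_um,
                  spacing_um=spacing_um, angle_deg=angle_deg,
                  um_per_px=um_per_px, background=background, noise_sd=noise_sd,
                  amplitude=amplitude, image_size=list(image_size),
                  min_separation_um=min_separation_um, seed=seed,
                  supersample=supersample)
    return img, SimTruth("sarcomere", params, truth)


# ---------------------------------------------------------------------------
# Flow-cytometry bead calibration

def gen_bead_table(
    slope: float = 10.0,
    intercept: float = 0.0,
    n_peaks: int = 8,
    noise_sd: float = 0.0,
    au_range: tuple[float, float] = (50.0, 50_000.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Rainbow-bead calibration table relating instrument AU to MEFL.

    Peak AU values are log-spaced over ``au_range`` (rainbow calibration
    particles span several decades); reference MEFL values follow the affine
    map ``MEFL = slope * AU + intercept`` plus Gaussian noise on the AU axis.
    """
    if n_peaks < 2:
        raise ValueError("need at least 2 bead peaks")
    rng = np.random.default_rng(seed)
    au_true = np.geomspace(au_range[0], au_range[1], n_peaks)
    au = au_true + (rng.normal(0.0, noise_sd, size=n_peaks) if noise_sd > 0 else 0.0)
    mefl = slope * au_true + intercept
    table = pd.DataFrame({"peak": np.arange(1, n_peaks + 1),
                          "au": au, "mefl": mefl})
    truth = pd.DataFrame({"au_true": au_true, "mefl": mefl},
                         index=pd.Index(table["peak"], name="peak"))
    params = dict(slope=slope, intercept=intercept, n_peaks=n_peaks,
                  noise_sd=noise_sd, au_range=list(au_range), seed=seed)
    return table, SimTruth("beads", params, truth)
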