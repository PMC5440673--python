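"""Synthetic force maps and fluorescence images with known ground truth.

Every downstream stage of the pipeline (curve fitting, map statistics,
focal-adhesion segmentation, nucleocytoplasmic ratio) is validated by
parameter recovery against the ground truth these generators emit.

Force curves are generated approach-only by inverting the Sneddon forward
model: at piezo height z past the contact point z0 the indentation solves
C*E*delta^2 = k*(z0 - z - delta), a quadratic with one positive root.
Noise is additive Gaussian on the deflection signal.

Images emulate confocal maximum-intensity projections of micropatterned
cells: a polygonal cell on a noisy background with a nuclear ellipse and a
known number of bright, anti-aliased elliptical focal-adhesion puncta in
the vinculin channel.  The "area" ground truth of each punctum is the
analytic ellipse area in um^2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import AcquisitionSettings, CantileverCalibration
from .curves import ForceDistanceCurve, ForceMap
from .sneddon import sneddon_prefactor

DEFAULT_SUBSTRATE_MODULUS_PA = 1.0e9   # glass-like stiff substrate
DEFAULT_CONTACT_FRACTION = 0.4         # contact point at 40% of the ramp


# ---------------------------------------------------------------------------
# force curves and maps
# ---------------------------------------------------------------------------

@dataclass
class ModulusField:
    """Ground-truth Young's modulus grid for a simulated force map."""
    modulus_Pa: np.ndarray
    cell_mask: np.ndarray   # True = cell, False = substrate / non-contact

    def __post_init__(self) -> None:
        self.modulus_Pa = np.asarray(self.modulus_Pa, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.modulus_Pa.shape != self.cell_mask.shape:
            raise ValueError("modulus grid and cell mask shapes differ")
        if np.any(self.modulus_Pa[self.cell_mask] <= 0):
            raise ValueError("moduli must be > 0 on cell pixels")

    @classmethod
    def uniform(cls, E_Pa: float, grid_points: int) -> "ModulusField":
        shape = (grid_points, grid_points)
        return cls(np.full(shape, float(E_Pa)), np.ones(shape, dtype=bool))

    @classmethod
    def cell_on_substrate(cls, E_cell_Pa: float, grid_points: int,
                          cell_radius_frac: float = 0.35) -> "ModulusField":
        """Circular cell of the given radius (fraction of the grid) centred
        on a substrate background."""
        n = grid_points
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2.0
        mask = (yy - c) ** 2 + (xx - c) ** 2 <= (cell_radius_frac * n) ** 2
        E = np.where(mask, float(E_cell_Pa), DEFAULT_SUBSTRATE_MODULUS_PA)
        return cls(E, mask)


@dataclass
class SyntheticGroundTruth:
    """What a simulation knows that the pipeline must recover."""
    modulus_field: Optional[ModulusField] = None
    nucleus_mask: Optional[np.ndarray] = None
    cytoplasm_mask: Optional[np.ndarray] = None
    cell_mask: Optional[np.ndarray] = None
    fa_spots: list = field(default_factory=list)  # dicts: centroid, area_um2, ...

    def to_json_dict(self) -> dict:
        out = {}
        if self.modulus_field is not None:
            out["modulus_Pa"] = self.modulus_field.modulus_Pa.tolist()
            out["cell_mask"] = self.modulus_field.cell_mask.astype(int).tolist()
        if self.fa_spots:
            out["fa_spots"] = self.fa_spots
        return out


def simulate_force_curve(E_Pa: float, calib: CantileverCalibration,
                         acq: Optional[AcquisitionSettings] = None,
                         noise_sd_N: float = 0.0,
                         seed: Optional[int] = None,
                         contact_fraction: float = DEFAULT_CONTACT_FRACTION,
                         prefactor_variant: str = "pyramid",
                         rng: Optional[np.random.Generator] = None
                         ) -> ForceDistanceCurve:
    """Simulate one Sneddon-shaped approach force-distance curve.

    The trace has a flat zero baseline until the ground-truth contact point,
    then the quadratic Sneddon response, truncated once the force reaches
    the acquisition setpoint.  Deflection is stored in volts via the
    calibration sensitivity; ``noise_sd_N`` is the Gaussian force-noise
    s.d. applied to the deflection signal.
    """
    if E_Pa <= 0:
        raise ValueError("Young's modulus must be > 0")
    if noise_sd_N < 0:
        raise ValueError("noise s.d. must be >= 0")
    acq = acq or AcquisitionSettings()
    n = acq.points_per_curve
    k = calib.spring_constant_N_per_m
    C = sneddon_prefactor(calib.alpha_deg, calib.nu, prefactor_variant) * E_Pa

    z_start = acq.z_length
    z = z_start - np.arange(n) * acq.z_step      # decreasing toward sample
    z0 = z_start * (1.0 - contact_fraction)

    travel = np.maximum(z0 - z, 0.0)             # piezo travel past contact
    # C*delta^2 + k*delta - k*travel = 0  ->  positive root
    delta = (-k + np.sqrt(k * k + 4.0 * C * k * travel)) / (2.0 * C)
    d = travel - delta                           # cantilever bending, m
    force = k * d

    reached = force >= acq.setpoint_force
    if not reached.any():
        raise ValueError(
            f"setpoint {acq.setpoint_force:.3g} N unreachable within "
            f"z_length {acq.z_length:.3g} m for E = {E_Pa:.4g} Pa")
    stop = int(np.argmax(reached)) + 1
    z, d = z[:stop], d[:stop]

    deflection_V = d / calib.sensitivity_m_per_V
    if noise_sd_N > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sigma_V = noise_sd_N / (k * calib.sensitivity_m_per_V)
        deflection_V = deflection_V + rng.normal(0.0, sigma_V, size=z.size)

    return ForceDistanceCurve(height_m=z, deflection_V=deflection_V,
                              calibration=calib, true_contact_m=z0)


def simulate_force_map(field_: ModulusField, calib: CantileverCalibration,
                       acq: Optional[AcquisitionSettings] = None,
                       noise_sd_N: float = 0.0, seed: int = 0,
                       substrate_mode: str = "stiff",
                       substrate_modulus_Pa: float = DEFAULT_SUBSTRATE_MODULUS_PA,
                       contact_fraction: float = DEFAULT_CONTACT_FRACTION
                       ) -> tuple[ForceMap, SyntheticGroundTruth]:
    """Simulate a full force map, one curve per pixel.

    Substrate pixels (cell mask False) emit either a near-vertical
    stiff-substrate response (``substrate_mode="stiff"``) or a flat
    no-contact trace (``"none"``).  Per-pixel seeds are spawned
    deterministically from the master seed, so identical inputs give
    bit-identical maps.
    """
    acq = acq or AcquisitionSettings()
    if field_.modulus_Pa.shape != (acq.grid_points, acq.grid_points):
        raise ValueError(
            f"modulus field shape {field_.modulus_Pa.shape} does not match "
            f"acquisition grid {(acq.grid_points,) * 2}")
    if substrate_mode not in ("stiff", "none"):
        raise ValueError("substrate_mode must be 'stiff' or 'none'")

    rows, cols = field_.modulus_Pa.shape
    children = np.random.SeedSequence(seed).spawn(rows * cols)
    curves = []
    for i in range(rows):
        for j in range(cols):
            rng = np.random.default_rng(children[i * cols + j])
            if field_.cell_mask[i, j]:
                c = simulate_force_curve(
                    field_.modulus_Pa[i, j], calib, acq, noise_sd_N,
                    contact_fraction=contact_fraction, rng=rng)
            elif substrate_mode == "stiff":
                c = simulate_force_curve(
                    substrate_modulus_Pa, calib, acq, noise_sd_N,
                    contact_fraction=contact_fraction, rng=rng)
            else:
                n = acq.points_per_curve
                z = acq.z_length - np.arange(n) * acq.z_step
                v = np.zeros(n)
                if noise_sd_N > 0:
                    sigma_V = noise_sd_N / (calib.spring_constant_N_per_m
                                            * calib.sensitivity_m_per_V)
                    v = rng.normal(0.0, sigma_V, size=n)
                c = ForceDistanceCurve(height_m=z, deflection_V=v,
                                       calibration=calib)
            c.pixel = (i, j)
            curves.append(c)
    fmap = ForceMap(curves=curves, shape=(rows, cols), acquisition=acq,
                    calibration=calib)
    return fmap, SyntheticGroundTruth(modulus_field=field_)


# ---------------------------------------------------------------------------
# fluorescence images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimImageSpec:
    """Specification of a synthetic micropatterned-cell image.

    Intensities are arbitrary fluorescence units; the defaults emulate a
    well-exposed confocal projection (bright puncta ~10x over the
    cytoplasmic signal, modest Gaussian read noise).  ``pixel_size_um``
    defaults to 0.1 um/px (63x oil objective at Nyquist sampling).
    """
    image_shape: tuple = (512, 512)          # (rows, cols), px
    pixel_size_um: float = 0.1
    cell_side_um: float = 45.0               # square micropattern side
    nucleus_axes_um: tuple = (9.0, 7.0)      # semi-axes of nuclear ellipse
    fa_count: int = 50
    fa_area_range_um2: tuple = (0.5, 5.0)
    fa_aspect_range: tuple = (1.8, 3.0)
    fa_intensity: float = 4000.0             # peak over local base
    nucleus_intensity: float = 1200.0        # YAP channel nuclear mean
    cytoplasm_intensity: float = 400.0       # both channels
    background: float = 200.0
    background_gradient: float = 0.0         # additive tilt across the image
    noise_sd: float = 20.0                   # Gaussian read noise
    poisson: bool = False
    min_gap_px: int = 2                      # clearance between FA supports
    max_place_tries: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.fa_count < 0:
            raise ValueError("fa_count must be >= 0")
        lo, hi = self.fa_area_range_um2
        if not 0 < lo <= hi:
            raise ValueError("invalid FA area range")
        side_px = self.cell_side_um / self.pixel_size_um
        if side_px > min(self.image_shape):
            raise ValueError("cell does not fit in the image")
        ax = max(self.nucleus_axes_um) / self.pixel_size_um
        if 2 * ax > side_px:
            raise ValueError("nucleus does not fit inside the cell")

    @classmethod
    def for_micropattern(cls, area_um2: float, **kw) -> "SimImageSpec":
        """Spec for a square micropattern of the given adhesive area.

        The image is sized to leave a ~15% margin around the pattern and the
        nucleus is scaled with the cell.
        """
        side = math.sqrt(area_um2)
        px = kw.pop("pixel_size_um", 0.1)
        side_px = side / px
        dim = int(np.ceil(side_px * 1.3 / 64.0)) * 64
        nuc = (0.22 * side, 0.17 * side)
        return cls(image_shape=(dim, dim), pixel_size_um=px,
                   cell_side_um=side, nucleus_axes_um=nuc, **kw)


def _ellipse_coverage(shape, cy, cx, a_px, b_px, theta, supersample=4):
    """Anti-aliased coverage raster of an ellipse (fractions in [0, 1]).

    Returns (coverage, (r0, r1, c0, c1)) restricted to the bounding box.
    """
    rmax = max(a_px, b_px)
    r0 = max(int(np.floor(cy - rmax - 1)), 0)
    r1 = min(int(np.ceil(cy + rmax + 2)), shape[0])
    c0 = max(int(np.floor(cx - rmax - 1)), 0)
    c1 = min(int(np.ceil(cx + rmax + 2)), shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 0)), (r0, r1, c0, c1)
    s = supersample
    off = (np.arange(s) + 0.5) / s
    ys = (r0 + np.add.outer(np.arange(r1 - r0), off).ravel())[:, None]
    xs = (c0 + np.add.outer(np.arange(c1 - c0), off).ravel())[None, :]
    dy, dx = ys - cy, xs - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    return cov, (r0, r1, c0, c1)


def simulate_cell_image(spec: SimImageSpec):
    """Render a two-channel synthetic cell image.

    Channels: ``"vinculin"`` (cell-body signal plus FA puncta) and ``"yap"``
    (nuclear and cytoplasmic signal at the configured means).  Returns
    ``(FluorImage, SyntheticGroundTruth)`` where the ground truth carries the
    nucleus/cytoplasm/cell masks and the list of seeded puncta with their
    analytic areas.

    Raises ``RuntimeError`` when the requested number of non-overlapping
    puncta cannot be placed within the retry budget.
    """
    from .imaging import FluorImage  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    ps = spec.pixel_size_um

    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    half = spec.cell_side_um / ps / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    cell = ((np.abs(yy - cy0) <= half) & (np.abs(xx - cx0) <= half))
    na, nb = (spec.nucleus_axes_um[0] / ps, spec.nucleus_axes_um[1] / ps)
    nucleus = (((xx - cx0) / na) ** 2 + ((yy - cy0) / nb) ** 2) <= 1.0
    nucleus &= cell
    cytoplasm = cell & ~nucleus

    # --- place FA puncta -------------------------------------------------
    occupied = np.zeros((rows, cols), dtype=bool)
    occupied[nucleus] = True          # keep puncta out of the nuclear region
    spots = []
    fa_layer = np.zeros((rows, cols))
    tries = 0
    lo_a, hi_a = spec.fa_area_range_um2
    gap = spec.min_gap_px
    while len(spots) < spec.fa_count:
        if tries >= spec.max_place_tries:
            raise RuntimeError(
                f"could not place {spec.fa_count} non-overlapping puncta in "
                f"{tries} tries; use a larger cell or fewer puncta")
        tries += 1
        area = rng.uniform(lo_a, hi_a)
        aspect = rng.uniform(*spec.fa_aspect_range)
        b_um = math.sqrt(area / (math.pi * aspect))
        a_um = aspect * b_um
        a_px, b_px = a_um / ps, b_um / ps
        theta = rng.uniform(0.0, math.pi)
        margin = a_px + gap + 1
        cy = rng.uniform(cy0 - half + margin, cy0 + half - margin)
        cx = rng.uniform(cx0 - half + margin, cx0 + half - margin)
        cov, (r0, r1, c0, c1) = _ellipse_coverage(
            (rows, cols), cy, cx, a_px, b_px, theta)
        if cov.size == 0 or cov.max() <= 0:
            continue
        support = cov > 0
        # clearance: no other support (or the nucleus) within min_gap_px
        g0 = max(r0 - gap, 0)
        g1 = min(r1 + gap, rows)
        h0 = max(c0 - gap, 0)
        h1 = min(c1 + gap, cols)
        neigh = occupied[g0:g1, h0:h1]
        if neigh.any():
            from scipy.ndimage import binary_dilation
            dil = binary_dilation(support, iterations=gap)
            pad = np.zeros_like(neigh)
            pad[r0 - g0:r0 - g0 + dil.shape[0],
                c0 - h0:c0 - h0 + dil.shape[1]] = dil
            if (pad & neigh).any():
                continue
        occupied[r0:r1, c0:c1] |= support
        fa_layer[r0:r1, c0:c1] += spec.fa_intensity * cov
        spots.append({"centroid_px": (float(cy), float(cx)),
                      "area_um2": float(area), "aspect": float(aspect),
                      "theta": float(theta)})

    # --- compose channels -------------------------------------------------
    base = spec.background + spec.background_gradient * (xx / max(cols - 1, 1))
    vinculin = base + spec.cytoplasm_intensity * cell + fa_layer
    yap = (base + spec.cytoplasm_intensity * cytoplasm
           + spec.nucleus_intensity * nucleus)
    if spec.poisson:
        vinculin = rng.poisson(np.maximum(vinculin, 0)).astype(float)
        yap = rng.poisson(np.maximum(yap, 0)).astype(float)
    if spec.noise_sd > 0:
        vinculin = vinculin + rng.normal(0, spec.noise_sd, vinculin.shape)
        yap = yap + rng.normal(0, spec.noise_sd, yap.shape)

    img = FluorImage(channels={"vinculin": vinculin, "yap": yap},
                     pixel_size_um=ps)
    truth = SyntheticGroundTruth(nucleus_mask=nucleus,
                                 cytoplasm_mask=cytoplasm,
                                 cell_mask=cell, fa_spots=spots)
    return img, truth
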