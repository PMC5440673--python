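"""Sneddon contact model for a pyramidal AFM tip, and batch force-map fitting.

For a rigid four-sided pyramid indenting an elastic half-space the load-
indentation relation is quadratic,

    F = (tan(alpha) / sqrt(2)) * E / (1 - nu^2) * delta^2,

with E the Young's modulus, nu the Poisson ratio, alpha the half-angle to
the pyramid face and delta the indentation.  The geometric prefactor is kept
as a single named constant so the Bilodeau variant (0.7453 * tan(alpha)) can
be selected by configuration.

The fit is exposed statsmodels-style: ``SneddonModel(curve, calib).fit()``
returns a :class:`SneddonResults` carrying the estimate, its standard error,
residual diagnostics and a ``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .calibration import CantileverCalibration
from .curves import ElasticityMap, ForceDistanceCurve, ForceMap
from .preprocess import (deflection_to_force, detect_contact_point,
                         estimate_baseline, tip_sample_separation)

PREFACTOR_VARIANTS = ("pyramid", "bilodeau")


def sneddon_prefactor(alpha_deg: float, nu: float,
                      variant: str = "pyramid") -> float:
    """Dimensionless prefactor C such that F [N] = C * E [Pa] * delta [m]^2."""
    if not 0.0 < alpha_deg < 90.0:
        raise ValueError("alpha must lie in (0, 90) degrees")
    if abs(1.0 - nu * nu) < 1e-12:
        raise ValueError("nu = +/-1 makes 1 - nu^2 vanish")
    tan_a = np.tan(np.deg2rad(alpha_deg))
    if variant == "pyramid":
        geom = tan_a / np.sqrt(2.0)
    elif variant == "bilodeau":
        geom = 0.7453 * tan_a
    else:
        raise ValueError(f"unknown prefactor variant {variant!r}; "
                         f"choose from {PREFACTOR_VARIANTS}")
    return geom / (1.0 - nu * nu)


def sneddon_force(delta_m, E_Pa: float, nu: float = 0.5,
                  alpha_deg: float = 18.0,
                  variant: str = "pyramid") -> np.ndarray:
    """Force (N) exerted by a pyramidal tip at indentation ``delta_m`` (m)."""
    delta = np.asarray(delta_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be >= 0")
    return sneddon_prefactor(alpha_deg, nu, variant) * E_Pa * delta ** 2


@dataclass(frozen=True)
class FitOptions:
    """Settings for the Sneddon least-squares fit."""
    refine_contact: bool = True        # jointly re-fit z0 with E
    min_contact_points: int = 20
    e_bounds_Pa: tuple = (1.0, 1.0e7)
    threshold_k: float = 3.0
    persistence: int = 5
    baseline_fraction: float = 0.3
    prefactor_variant: str = "pyramid"
    refine_window_samples: float = 5.0  # z0 search half-width, in z-steps

    def to_dict(self) -> dict:
        return {
            "refine_contact": self.refine_contact,
            "min_contact_points": self.min_contact_points,
            "e_bounds_Pa": list(self.e_bounds_Pa),
            "threshold_k": self.threshold_k,
            "persistence": self.persistence,
            "baseline_fraction": self.baseline_fraction,
            "prefactor_variant": self.prefactor_variant,
            "refine_window_samples": self.refine_window_samples,
        }


@dataclass
class SneddonResults:
    """Result of fitting one force-distance curve.

    Attributes
    ----------
    E_Pa : float
        Fitted Young's modulus (NaN when invalid).
    E_se_Pa : float
        Standard error of the modulus from the linearized fit.
    contact_point_m : float
        Fitted contact height z0.
    rms_residual_N : float
        Root-mean-square force residual over the in-contact region.
    n_points_used : int
        In-contact samples entering the fit.
    valid : bool
        False for non-contacting curves, fits with too few points, or
        estimates pinned at a modulus bound.
    at_bound : bool
        Fit converged onto a configured modulus bound.
    contacting : bool
        Whether a contact point was detected at all.
    """
    E_Pa: float
    E_se_Pa: float
    contact_point_m: float
    rms_residual_N: float
    n_points_used: int
    valid: bool
    at_bound: bool = False
    contacting: bool = True
    options: Optional[FitOptions] = None

    def summary(self) -> str:
        lines = [
            "Sneddon pyramidal-indenter fit",
            "=" * 46,
            f"{'valid':<28}{self.valid}",
            f"{'contacting':<28}{self.contacting}",
            f"{'Youngs modulus E (Pa)':<28}{self.E_Pa:.6g}",
            f"{'std. err. of E (Pa)':<28}{self.E_se_Pa:.3g}",
            f"{'contact point z0 (m)':<28}{self.contact_point_m:.6g}",
            f"{'rms force residual (N)':<28}{self.rms_residual_N:.3g}",
            f"{'in-contact samples':<28}{self.n_points_used}",
            f"{'pinned at bound':<28}{self.at_bound}",
        ]
        return "\n".join(lines)


def _invalid_result(opts: FitOptions, contacting: bool) -> SneddonResults:
    return SneddonResults(E_Pa=float("nan"), E_se_Pa=float("nan"),
                          contact_point_m=float("nan"),
                          rms_residual_N=float("nan"), n_points_used=0,
                          valid=False, contacting=contacting, options=opts)


class SneddonModel:
    """Sneddon elasticity model for one approach force-distance curve.

    The pipeline inside :meth:`fit` is: Hooke conversion of the photodiode
    signal to force, robust baseline (offset + tilt) subtraction,
    threshold-crossing contact-point detection, bending-corrected
    indentation, and least squares of F against delta^2 (linear in E),
    optionally re-fitting the contact point jointly with E.
    """

    def __init__(self, curve: ForceDistanceCurve,
                 calib: Optional[CantileverCalibration] = None,
                 options: Optional[FitOptions] = None):
        self.curve = curve
        self.calib = calib or curve.calibration
        if self.calib is None:
            raise ValueError("a cantilever calibration is required")
        self.options = options or FitOptions()

    # -- internals -------------------------------------------------------
    def _prepared(self):
        """Force in N, baseline-corrected, with the height series."""
        opts = self.options
        z = self.curve.height_m
        f_raw = deflection_to_force(self.curve, self.calib)
        offset, tilt = estimate_baseline(
            f_raw, z, baseline_fraction=opts.baseline_fraction)
        return f_raw - (offset + tilt * z), z

    def _E_given_z0(self, f: np.ndarray, z: np.ndarray, z0: float,
                    pref: float):
        """Closed-form least-squares E for a fixed contact point.

        F = (pref*E) * delta^2 is linear in E, so
        E_hat = sum(delta^2 F) / (pref * sum(delta^4)).
        Returns (E, sse, n, delta, mask).
        """
        delta, mask = tip_sample_separation(f, z, z0, self.calib)
        fc = f[mask]
        if delta.size == 0:
            return np.nan, np.inf, 0, delta, mask
        d2 = delta ** 2
        denom = np.dot(d2, d2)
        if denom <= 0:
            return np.nan, np.inf, delta.size, delta, mask
        amp = np.dot(d2, fc) / denom
        resid = fc - amp * d2
        return amp / pref, float(np.dot(resid, resid)), delta.size, delta, mask

    # -- public API ------------------------------------------------------
    def fit(self) -> SneddonResults:
        opts = self.options
        pref = sneddon_prefactor(self.calib.alpha_deg, self.calib.nu,
                                 opts.prefactor_variant)
        f, z = self._prepared()
        cp = detect_contact_point(
            f, z, threshold_k=opts.threshold_k, persistence=opts.persistence,
            baseline_fraction=opts.baseline_fraction)
        if not cp.contacting:
            return _invalid_result(opts, contacting=False)

        z0 = cp.z0_m
        step = abs(z[1] - z[0])
        if opts.refine_contact:
            # Threshold-crossing detection is systematically late for soft
            # samples: the quadratic response only exceeds k*sd at an
            # indentation delta_c = sqrt(thr / (C*E)).  Search upward (toward
            # the baseline) over a window scaled to that offset, then polish.
            big = 1e300

            def sse_of(z0c: float) -> float:
                _, sse, n, _, _ = self._E_given_z0(f, z, z0c, pref)
                return sse if (n >= opts.min_contact_points
                               and np.isfinite(sse)) else big

            E0, _, _, _, _ = self._E_given_z0(f, z, z0, pref)
            up = opts.refine_window_samples * step
            if np.isfinite(E0) and E0 > 0:
                thr = max(opts.threshold_k * cp.noise_sd_N, 1e-15)
                up = max(up, 3.0 * np.sqrt(thr / (pref * E0)))
            lo_b = z0 - opts.refine_window_samples * step
            hi_b = z0 + up
            grid = np.linspace(lo_b, hi_b, 61)
            sses = np.array([sse_of(g) for g in grid])
            k_best = int(np.argmin(sses))
            if sses[k_best] < big:
                spacing = grid[1] - grid[0]
                res = minimize_scalar(
                    sse_of,
                    bounds=(grid[k_best] - spacing, grid[k_best] + spacing),
                    method="bounded", options={"xatol": step * 1e-6})
                if res.fun <= sses[k_best]:
                    z0 = float(res.x)
                else:
                    z0 = float(grid[k_best])

        E, sse, n, delta, mask = self._E_given_z0(f, z, z0, pref)
        if n < opts.min_contact_points or not np.isfinite(E):
            return _invalid_result(opts, contacting=True)

        lo, hi = opts.e_bounds_Pa
        at_bound = not (lo < E < hi)
        E_clipped = float(np.clip(E, lo, hi))
        d2 = delta ** 2
        dof = max(n - 1, 1)
        sigma2 = sse / dof
        amp_se = np.sqrt(sigma2 / np.dot(d2, d2))
        return SneddonResults(
            E_Pa=E_clipped, E_se_Pa=float(amp_se / pref),
            contact_point_m=float(z0),
            rms_residual_N=float(np.sqrt(sse / n)), n_points_used=int(n),
            valid=(not at_bound) and E > 0, at_bound=at_bound,
            contacting=True, options=opts)


def fit_sneddon(curve: ForceDistanceCurve,
                calib: Optional[CantileverCalibration] = None,
                options: Optional[FitOptions] = None) -> SneddonResults:
    """Functional wrapper around :class:`SneddonModel`."""
    return SneddonModel(curve, calib, options).fit()


def process_force_map(fmap: ForceMap,
                      options: Optional[FitOptions] = None) -> ElasticityMap:
    """Fit every curve of a force map; pixel results are independent.

    Non-contacting curves, fits with too few in-contact points and fits
    pinned at a modulus bound are marked invalid and carry no modulus.
    """
    if len(fmap.curves) == 0:
        raise ValueError("empty force map")
    options = options or FitOptions()
    rows, cols = fmap.shape
    E = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            res = SneddonModel(fmap.curve_at(i, j), fmap.calibration,
                               options).fit()
            if res.valid:
                E[i, j] = res.E_Pa
                valid[i, j] = True
    prov = {"fit_options": options.to_dict(),
            "calibration": fmap.calibration.to_header(),
            "acquisition": fmap.acquisition.to_header()}
    import hashlib
    import json
    prov["settings_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True).encode()).hexdigest()[:16]
    return ElasticityMap(modulus_Pa=E, valid=valid, provenance=prov)
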