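"""Raw force-curve preprocessing: Hooke conversion, baseline, contact point,
tip-sample separation.

Sign conventions (documented and tested):

* the piezo height ``z`` decreases toward the sample during approach;
* indentation ``delta >= 0`` means the tip is pressing into the sample;
* forces are positive when the cantilever is deflected away from the sample.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import CantileverCalibration
from .curves import ForceDistanceCurve


def deflection_to_force(curve: ForceDistanceCurve,
                        calib: Optional[CantileverCalibration] = None
                        ) -> np.ndarray:
    """Convert raw photodiode volts to force in newtons.

    F = k * S * V with k the spring constant (N/m) and S the deflection
    sensitivity (m/V).  The baseline offset is *not* removed here.
    """
    calib = calib or curve.calibration
    if calib is None:
        raise ValueError("no cantilever calibration available for this curve")
    return (calib.spring_constant_N_per_m * calib.sensitivity_m_per_V
            * curve.deflection_V)


def estimate_baseline(force_N: np.ndarray, height_m: np.ndarray,
                      baseline_fraction: float = 0.3,
                      n_iter: int = 30) -> tuple[float, float]:
    """Robust linear baseline over the far-from-surface end of the approach.

    Fits ``F ~ offset + tilt * z`` by least absolute deviations (iteratively
    reweighted least squares) over the first ``baseline_fraction`` of the
    approach (the end farthest from the surface), and returns
    ``(offset_N, tilt_N_per_m)`` to subtract.
    """
    if not 0.0 < baseline_fraction <= 0.9:
        raise ValueError("baseline_fraction must lie in (0, 0.9]")
    n = int(np.floor(baseline_fraction * force_N.size))
    if n < 5:
        raise ValueError("baseline window has fewer than 5 points")
    f = np.asarray(force_N[:n], dtype=float)
    z = np.asarray(height_m[:n], dtype=float)
    # centre z for conditioning
    z0 = z.mean()
    zc = z - z0
    X = np.column_stack([np.ones(n), zc])
    beta, *_ = np.linalg.lstsq(X, f, rcond=None)
    scale = max(np.max(np.abs(f)), 1e-30)
    for _ in range(n_iter):
        r = f - X @ beta
        w = 1.0 / np.maximum(np.abs(r), 1e-9 * scale)
        Xw = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ f, rcond=None)
        if np.allclose(beta_new, beta, rtol=1e-12, atol=1e-30):
            beta = beta_new
            break
        beta = beta_new
    offset_c, tilt = beta
    offset = offset_c - tilt * z0
    return float(offset), float(tilt)


@dataclass(frozen=True)
class ContactPoint:
    """Result of contact-point detection."""
    contacting: bool
    z0_m: float = float("nan")
    index: int = -1            # first persistently in-contact sample
    noise_sd_N: float = 0.0


def detect_contact_point(force_N: np.ndarray, height_m: np.ndarray,
                         threshold_k: float = 3.0,
                         persistence: int = 5,
                         baseline_fraction: float = 0.3,
                         noise_floor_N: float = 1e-15) -> ContactPoint:
    """Detect the piezo height at which the tip first touches the sample.

    Works on a baseline-corrected force series.  The baseline noise s.d. is
    estimated robustly (1.4826 * MAD) over the far-end window; the contact
    index is the first sample where the force exceeds
    ``threshold_k * sd`` for ``persistence`` consecutive samples.  The contact
    height is then refined by a local quadratic fit of F(z) around the
    crossing (the Sneddon response is quadratic in ``z0 - z`` near contact).

    A curve with no persistent crossing is flagged non-contacting; this flag
    is the signal downstream outlier cleaning uses.
    """
    f = np.asarray(force_N, dtype=float)
    z = np.asarray(height_m, dtype=float)
    nb = max(int(np.floor(baseline_fraction * f.size)), 5)
    mad = np.median(np.abs(f[:nb] - np.median(f[:nb])))
    sd = 1.4826 * mad
    thr = max(threshold_k * sd, noise_floor_N)

    above = f > thr
    # first index where `persistence` consecutive samples are above threshold
    idx = -1
    if above.any():
        run = 0
        for i, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= persistence:
                idx = i - persistence + 1
                break
        else:
            # tolerate truncated runs at the very end of the ramp
            tail = min(persistence, f.size)
            if above[-tail:].all():
                idx = int(np.argmax(above[-tail:])) + f.size - tail
    if idx < 0:
        return ContactPoint(contacting=False, noise_sd_N=sd)

    z0 = float(z[idx])
    # Local refinement: profile fit of the kink model F = A * (z0 - z)_+^2
    # over a window spanning the crossing (baseline samples pin the kink).
    # For each candidate z0 the amplitude A is profiled out in closed form;
    # the SSE is minimized on a grid and polished by bounded search.
    hi = idx
    while hi < f.size and f[hi] < 100.0 * thr:
        hi += 1
    hi = int(min(max(hi, idx + 8), f.size, idx + 400))
    lo = max(idx - 100, 0)
    zz, ff = z[lo:hi], f[lo:hi]
    if hi - lo >= 8:
        def sse(z0c: float) -> float:
            d = np.maximum(z0c - zz, 0.0)
            d2 = d * d
            den = float(np.dot(d2, d2))
            if den <= 0:
                return float(np.dot(ff, ff))
            amp = float(np.dot(d2, ff)) / den
            r = ff - amp * d2
            return float(np.dot(r, r))

        step = abs(z[1] - z[0]) if z.size > 1 else 0.0
        cands = np.linspace(z[min(hi - 1, idx + 20)], z[lo], 81)
        vals = np.array([sse(c) for c in cands])
        k = int(np.argmin(vals))
        b_lo = cands[max(k - 1, 0)]
        b_hi = cands[min(k + 1, cands.size - 1)]
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(sse, bounds=(min(b_lo, b_hi), max(b_lo, b_hi)),
                              method="bounded",
                              options={"xatol": max(step * 1e-4, 1e-12)})
        z0 = float(res.x)
    return ContactPoint(contacting=True, z0_m=z0, index=int(idx),
                        noise_sd_N=sd)


def tip_sample_separation(force_N: np.ndarray, height_m: np.ndarray,
                          z0_m: float, calib: CantileverCalibration
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Indentation depth for the in-contact part of an approach curve.

    delta = (z0 - z) - d, with d = F / k the cantilever bending in metres.
    Only points past contact (z < z0) with delta >= 0 are returned.

    Returns ``(delta_m, mask)`` where ``mask`` selects the retained samples
    in the input arrays (so callers can pair forces with indentations).
    """
    f = np.asarray(force_N, dtype=float)
    z = np.asarray(height_m, dtype=float)
    d = f / calib.spring_constant_N_per_m
    delta = (z0_m - z) - d
    mask = (z < z0_m) & (delta >= 0)
    return delta[mask], mask
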