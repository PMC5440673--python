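"""Quick-look plots for fitted curves, elasticity maps and particle sets."""
from __future__ import annotations

import numpy as np

from .curves import ElasticityMap, ForceDistanceCurve
from .preprocess import deflection_to_force, estimate_baseline, \
    tip_sample_separation
from .sneddon import SneddonResults, sneddon_force


def plot_force_fit(curve: ForceDistanceCurve, result: SneddonResults,
                   ax=None):
    """Force versus indentation with the fitted Sneddon curve overlaid."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    calib = curve.calibration
    f = deflection_to_force(curve, calib)
    off, tilt = estimate_baseline(f, curve.height_m)
    f = f - off - tilt * curve.height_m
    delta, mask = tip_sample_separation(f, curve.height_m,
                                        result.contact_point_m, calib)
    ax.plot(delta * 1e6, f[mask] * 1e12, ".", ms=3, alpha=0.6,
            label="data")
    if result.valid:
        dd = np.linspace(0, delta.max(), 200)
        ax.plot(dd * 1e6,
                sneddon_force(dd, result.E_Pa, calib.nu,
                              calib.alpha_deg) * 1e12,
                "-", label=f"fit: E = {result.E_Pa:.0f} Pa")
    ax.set_xlabel("indentation (um)")
    ax.set_ylabel("force (pN)")
    ax.legend()
    return ax


def plot_elasticity_map(emap: ElasticityMap, ax=None, log=True):
    """Young's-modulus map with invalid pixels masked out."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm
    if ax is None:
        _, ax = plt.subplots()
    data = np.ma.masked_invalid(emap.modulus_Pa)
    norm = LogNorm(vmin=max(data.min(), 1.0), vmax=data.max()) if log \
        else None
    im = ax.imshow(data, norm=norm, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="E (Pa)")
    ax.set_xlabel("pixel")
    ax.set_ylabel("pixel")
    return ax
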