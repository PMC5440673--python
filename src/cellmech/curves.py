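"""Containers for force-distance curves, force maps and elasticity maps."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import AcquisitionSettings, CantileverCalibration


@dataclass
class ForceDistanceCurve:
    """One approach force-distance trace.

    ``height_m`` is the piezo Z position (m), strictly monotone decreasing
    during approach (z decreases toward the sample).  ``deflection_V`` is the
    raw photodiode signal (V); conversion to force requires a calibration.
    """

    height_m: np.ndarray
    deflection_V: np.ndarray
    calibration: Optional[CantileverCalibration] = None
    pixel: Optional[tuple] = None          # (i, j) in a map, if any
    true_contact_m: Optional[float] = None  # simulator ground truth

    def __post_init__(self) -> None:
        self.height_m = np.asarray(self.height_m, dtype=float)
        self.deflection_V = np.asarray(self.deflection_V, dtype=float)
        if self.height_m.shape != self.deflection_V.shape:
            raise ValueError("height and deflection series differ in length")
        if self.height_m.size < 10:
            raise ValueError("curve must contain at least 10 samples")
        dz = np.diff(self.height_m)
        if not (np.all(dz < 0) or np.all(dz > 0)):
            raise ValueError("height series must be strictly monotone")

    def __len__(self) -> int:
        return self.height_m.size

    @property
    def approaches_downward(self) -> bool:
        return self.height_m[-1] < self.height_m[0]


@dataclass
class ForceMap:
    """Grid of force-distance curves sharing one acquisition protocol."""

    curves: list                       # row-major list of ForceDistanceCurve
    shape: tuple                       # (rows, cols)
    acquisition: AcquisitionSettings
    calibration: CantileverCalibration

    def __post_init__(self) -> None:
        if len(self.curves) == 0:
            raise ValueError("force map contains no curves")
        if len(self.curves) != self.shape[0] * self.shape[1]:
            raise ValueError("curve count does not match map shape")

    def curve_at(self, i: int, j: int) -> ForceDistanceCurve:
        return self.curves[i * self.shape[1] + j]


@dataclass
class ElasticityMap:
    """Per-pixel Young's moduli with a validity mask.

    ``modulus_Pa`` is NaN wherever ``valid`` is False (non-contacting or
    failed fits carry no modulus).
    """

    modulus_Pa: np.ndarray
    valid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modulus_Pa = np.asarray(self.modulus_Pa, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.modulus_Pa.shape != self.valid.shape:
            raise ValueError("modulus grid and validity mask shapes differ")
        self.modulus_Pa = np.where(self.valid, self.modulus_Pa, np.nan)

    @property
    def shape(self) -> tuple:
        return self.modulus_Pa.shape

    def values(self) -> np.ndarray:
        """Moduli of valid pixels, flattened row-major."""
        return self.modulus_Pa[self.valid]
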