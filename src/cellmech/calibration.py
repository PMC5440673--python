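"""Cantilever calibration and force-mapping acquisition settings.

All mechanics are kept in SI internally (m, N, Pa).  The constructors accept
the units AFM software reports (nm/V sensitivity, pN/nm spring constant,
degrees for the tip half-angle) and expose SI properties.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CantileverCalibration:
    """Optical-lever and cantilever calibration for one experiment.

    Parameters
    ----------
    sensitivity_nm_per_V : float
        Deflection sensitivity of the photodiode, nm of tip deflection per
        volt of photodiode signal (typical soft-cantilever setups: ~15 nm/V).
    spring_constant_pN_per_nm : float
        Cantilever stiffness from a thermal-noise calibration, pN/nm
        (equivalently mN/m; typical soft probes ~18 pN/nm).
    alpha_deg : float
        Half-angle to the face of the pyramidal tip, degrees.
    nu : float
        Poisson ratio of the sample; 0.5 for incompressible soft matter.
    """

    sensitivity_nm_per_V: float
    spring_constant_pN_per_nm: float
    alpha_deg: float = 18.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.sensitivity_nm_per_V <= 0:
            raise ValueError("sensitivity must be > 0 nm/V")
        if self.spring_constant_pN_per_nm <= 0:
            raise ValueError("spring constant must be > 0 pN/nm")
        if not 0.0 < self.alpha_deg < 90.0:
            raise ValueError("tip half-angle must lie in (0, 90) degrees")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")

    @property
    def sensitivity_m_per_V(self) -> float:
        return self.sensitivity_nm_per_V * 1e-9

    @property
    def spring_constant_N_per_m(self) -> float:
        # pN/nm == mN/m == 1e-3 N/m
        return self.spring_constant_pN_per_nm * 1e-3

    def to_header(self) -> dict:
        return {
            "sensitivity_nm_per_V": self.sensitivity_nm_per_V,
            "spring_constant_pN_per_nm": self.spring_constant_pN_per_nm,
            "alpha_deg": self.alpha_deg,
            "nu": self.nu,
        }


@dataclass(frozen=True)
class AcquisitionSettings:
    """Force-mapping acquisition parameters.

    Defaults reproduce a soft-cell mapping protocol: relative setpoint
    1.0 nN, 15 um Z ramp at 30 um/s sampled at 2 kHz, 64 x 64 curves over
    a 100 x 100 um field.
    """

    setpoint_force: float = 1.0e-9   # N
    z_length: float = 15.0e-6        # m
    z_speed: float = 30.0e-6         # m/s
    sample_rate: float = 2000.0      # Hz
    grid_points: int = 64            # curves per axis
    scan_size: float = 100.0e-6      # m per axis

    def __post_init__(self) -> None:
        for name in ("setpoint_force", "z_length", "z_speed", "sample_rate",
                     "scan_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.grid_points < 1:
            raise ValueError("grid_points must be >= 1")
        if self.points_per_curve < 10:
            raise ValueError(
                "acquisition yields fewer than 10 samples per curve; "
                "increase z_length or sample_rate, or slow the ramp")

    @property
    def points_per_curve(self) -> int:
        return int(round(self.z_length / self.z_speed * self.sample_rate))

    @property
    def z_step(self) -> float:
        """Piezo travel between consecutive samples, m."""
        return self.z_speed / self.sample_rate

    def to_header(self) -> dict:
        return {
            "setpoint_N": self.setpoint_force,
            "z_length_m": self.z_length,
            "z_speed_m_per_s": self.z_speed,
            "sample_rate_Hz": self.sample_rate,
            "grid_points": self.grid_points,
            "scan_size_m": self.scan_size,
        }
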