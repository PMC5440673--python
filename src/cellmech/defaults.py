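"""Manifest of every numeric pipeline default and where it comes from.

Each entry maps a parameter name to ``(value, source)`` where source is
either the acquisition/analysis protocol the pipeline reproduces
("protocol") or a documented package design choice ("design", rationale in
docs/methods.md).  A unit test asserts the live defaults match this table.
"""

DEFAULTS = {
    # acquisition (protocol settings of the force-mapping experiment)
    "setpoint_force_N": (1.0e-9, "protocol"),
    "z_length_m": (15.0e-6, "protocol"),
    "z_speed_m_per_s": (30.0e-6, "protocol"),
    "sample_rate_Hz": (2000.0, "protocol"),
    "grid_points": (64, "protocol"),
    "scan_size_m": (100.0e-6, "protocol"),
    # cantilever / contact model
    "nu": (0.5, "protocol"),
    "alpha_deg": (18.0, "design: nominal pyramidal-probe half-angle"),
    # curve fitting
    "baseline_fraction": (0.3, "design"),
    "contact_threshold_k": (3.0, "design"),
    "contact_persistence": (5, "design"),
    "min_contact_points": (20, "design"),
    "e_bounds_Pa": ((1.0, 1.0e7), "design"),
    # map cleaning
    "clean_bounds_Pa": ((10.0, 1.0e5), "design"),
    # FA quantification chain (protocol settings of the ImageJ recipe)
    "bg_radius_px": (25, "protocol"),
    "bg_paraboloid": (True, "protocol: sliding-paraboloid option"),
    "clahe_block": (19, "protocol"),
    "clahe_bins": (256, "protocol"),
    "clahe_slope": (3.0, "protocol"),
    "saturated_percent": (0.35, "protocol"),
    "fa_size_range_um2": ((0.30, 15.0), "protocol"),
    "fa_circ_range": ((0.0, 0.99), "protocol"),
    "fa_connectivity": (2, "design: 8-connected labelling"),
    # statistics
    "alpha": (0.05, "protocol"),
    "lilliefors_reps": (10_000, "design"),
    # simulator (design choices; rationale in docs/methods.md)
    "substrate_modulus_Pa": (1.0e9, "design"),
    "contact_fraction": (0.4, "design"),
    "pixel_size_um": (0.1, "design: 63x oil confocal at Nyquist"),
    "fa_intensity": (4000.0, "design"),
    "cytoplasm_intensity": (400.0, "design"),
    "background": (200.0, "design"),
    "image_noise_sd": (20.0, "design"),
    "fa_aspect_range": ((1.8, 3.0), "design"),
    "min_gap_px": (2, "design"),
}
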