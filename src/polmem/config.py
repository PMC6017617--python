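"""Force-field wide configuration: anharmonic coefficients, buffering
constants, connectivity scale factors, Thole damping width and SCF
controls.

Defaults are the standard AMOEBA values.  Everything is overridable,
either programmatically or by merging a YAML file through
:func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml


@dataclass(frozen=True)
class ForceFieldConfig:
    # Electrostatics
    coulomb: float = 332.0637          # kcal·Å/(mol·e²)
    thole_a: float = 0.39              # dimensionless damping width
    scf_tolerance_debye: float = 1e-5  # max per-site change at convergence
    scf_max_iterations: int = 100
    scf_omega: float = 0.7             # successive over-relaxation factor

    # Connectivity scaling for permanent electrostatics (1-2, 1-3, 1-4, 1-5)
    mpole_scale: tuple[float, float, float, float] = (0.0, 0.0, 0.4, 0.8)
    # Connectivity scaling for vdW (1-2, 1-3, 1-4, 1-5)
    vdw_scale: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)

    # Buffered 14-7 constants
    vdw_delta: float = 0.07
    vdw_gamma: float = 0.12

    # Bond anharmonicity (quartic Morse expansion), Å⁻¹ and Å⁻²
    bond_cubic: float = -2.55
    bond_quartic: float = 3.793125

    # Angle / out-of-plane anharmonicity, per degree^n
    angle_cubic: float = -0.014
    angle_quartic: float = 5.6e-5
    angle_pentic: float = -7.0e-7
    angle_sextic: float = 2.2e-8

    # Membrane analysis
    n_slabs: int = 100

    def replace(self, **kw) -> "ForceFieldConfig":
        return replace(self, **kw)


DEFAULT_CONFIG = ForceFieldConfig()


def load_config(path: str | None = None) -> ForceFieldConfig:
    """Build a config, merging a YAML mapping over the defaults.

    Unknown keys raise ``KeyError`` so typos do not silently pass.
    """
    if path is None:
        return DEFAULT_CONFIG
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    valid = set(ForceFieldConfig.__dataclass_fields__)
    for key in overrides:
        if key not in valid:
            raise KeyError(f"unknown config key: {key!r}")
    for key in ("mpole_scale", "vdw_scale"):
        if key in overrides:
            overrides[key] = tuple(float(x) for x in overrides[key])
    return replace(DEFAULT_CONFIG, **overrides)
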