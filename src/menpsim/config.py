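"""Scenario configuration: materials, geometry, stimulation and I/O.

Every physical symbol used elsewhere in the package is declared here, with
SI units.  The default :class:`ScenarioConfig` reproduces the published
two-phase CoFe2O4 (core) / BaTiO3 (shell) nanoparticle in its two host
environments, culture medium ("CM", liquid) and blood-vessel wall ("BV",
solid).

Notes on the defaults
---------------------
* The magnetic constitutive parameters (Ms, chi0, lambda_s) belong to the
  magnetostrictive core; the dielectric/elastic set (eps_r = 10,
  E = 230 GPa, nu = 0.48, rho = 5.2e3 kg/m^3) to the piezoelectric shell.
* The shell electrical conductivity (5.2e6 S/m) is stored for completeness
  but deliberately ignored by the dielectric potential solve — see
  docs/methods.md; a warning is emitted when it is nonzero.
* The BaTiO3 stress-charge coupling coefficients are the standard
  tetragonal (4mm) literature values scaled by a single calibration factor
  ``piezo_scale`` fixed once against the 2 T baseline surface-potential
  difference (6.07 mV); see docs/methods.md.
* The Jiles-Atherton table is stored verbatim; the dynamic solver uses the
  documented effective coupling/demagnetization convention carried in
  ``alpha_effective`` and ``demag_n_effective`` (see docs/methods.md for
  why the verbatim inter-domain coupling cannot be used as-is).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .units import parse_field


class ConfigError(ValueError):
    """Raised when a configuration violates its schema or an invariant."""


# --------------------------------------------------------------------------
# material types
# --------------------------------------------------------------------------

@dataclass
class CoreMaterial:
    """Magnetostrictive core (cobalt ferrite).

    Attributes
    ----------
    Ms : saturation magnetization, A/m.
    chi0 : initial magnetic susceptibility (dimensionless).
    lambda_s : saturation magnetostriction (dimensionless strain; negative
        means contraction along the field).
    rho : density, kg/m^3.
    E, nu : isotropic elastic constants, Pa / dimensionless.
    eps_r : relative permittivity used in the electrostatic solve.
    """

    Ms: float = 3.69e5
    chi0: float = 3.0
    lambda_s: float = -200e-6
    rho: float = 5.29e3
    E: float = 173e9
    nu: float = 0.33
    eps_r: float = 1.0

    def validate(self) -> None:
        if not self.Ms > 0:
            raise ConfigError("core.Ms must be positive")
        if not self.chi0 > 0:
            raise ConfigError("core.chi0 must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ConfigError("core.poisson_ratio out of range (-1, 0.5)")
        if not self.rho > 0:
            raise ConfigError("core.rho must be positive")
        if not self.E > 0:
            raise ConfigError("core.youngs_modulus must be positive")
        if not self.eps_r >= 1:
            raise ConfigError("core.eps_r must be >= 1")


#: standard tetragonal BaTiO3 stress-charge coefficients, C/m^2
BTO_E31 = -4.4
BTO_E33 = 18.6
BTO_E15 = 11.6

#: one-time calibration factor applied to the BaTiO3 stress-charge matrix so
#: that the default BV scenario reproduces the 2 T baseline surface potential
#: difference of 6.07 mV on the default mesh (see docs/methods.md and
#: menpsim.coupled.calibrate_piezo_scale).
DEFAULT_PIEZO_SCALE = 1.199739011518915e-02


@dataclass
class ShellMaterial:
    """Piezoelectric shell (barium titanate), poled along +z.

    The stress-charge coupling respects tetragonal 4mm sparsity: only the
    e31, e33 and e15 families are nonzero.  ``piezo_scale`` multiplies the
    whole matrix (single documented calibration constant).
    """

    rho: float = 5.2e3
    eps_r: float = 10.0
    sigma: float = 5.2e6          # stored, not used by the potential solve
    E: float = 230e9
    nu: float = 0.48
    e31: float = BTO_E31
    e33: float = BTO_E33
    e15: float = BTO_E15
    piezo_scale: float = DEFAULT_PIEZO_SCALE

    def validate(self) -> None:
        if not self.eps_r >= 1:
            raise ConfigError("shell.eps_r must be >= 1")
        if not self.E > 0:
            raise ConfigError("shell.youngs_modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ConfigError("shell.poisson_ratio out of range (-1, 0.5)")
        if not self.piezo_scale > 0:
            raise ConfigError("shell.piezo_scale must be positive")


@dataclass
class EnvironmentMaterial:
    """Host medium surrounding the particle.

    ``CM`` is the liquid culture medium (no static mechanical response);
    ``BV`` is the solid blood-vessel wall with soft-tissue elasticity.
    """

    name: str = "BV"
    sigma: float = 0.232
    eps_r: float = 1.0
    mu_r: float = 1.0
    is_solid: bool = True
    E: float | None = 1e6
    nu: float | None = 0.49
    rho: float = 1102.0

    def validate(self) -> None:
        if self.name not in ("CM", "BV"):
            raise ConfigError("environment.name must be 'CM' or 'BV'")
        if self.sigma < 0:
            raise ConfigError("environment.sigma must be >= 0")
        if not self.eps_r >= 1:
            raise ConfigError("environment.eps_r must be >= 1")
        if self.is_solid:
            if self.E is None or self.nu is None:
                raise ConfigError(
                    "solid environment requires youngs_modulus and poisson_ratio"
                )
            if not -1.0 < self.nu < 0.5:
                raise ConfigError("environment.poisson_ratio out of range")


def culture_medium() -> EnvironmentMaterial:
    return EnvironmentMaterial(
        name="CM", sigma=1.5, eps_r=1.0, mu_r=1.0, is_solid=False,
        E=None, nu=None, rho=1007.0,
    )


def blood_vessel_wall() -> EnvironmentMaterial:
    return EnvironmentMaterial(
        name="BV", sigma=0.232, eps_r=1.0, mu_r=1.0, is_solid=True,
        E=1e6, nu=0.49, rho=1102.0,
    )


@dataclass
class JAParameters:
    """Jiles-Atherton hysteresis parameters.

    ``alpha`` stores the published table value verbatim.  The dynamic
    solver uses ``alpha_effective`` together with ``demag_n_effective``:
    the published inter-domain coupling (1.5) lies above the mean-field
    stability bound 3a/Ms ~ 1.22, for which the anhysteretic becomes
    multivalued and every trajectory snaps to a square loop — incompatible
    with the magnitudes the model is meant to reproduce.  The effective
    convention was fixed once by a discrete parameter study documented in
    docs/methods.md.
    """

    Ms: float = 3.69e5
    k_pinning: float = 2e5
    a_domain: float = 1.5e5
    alpha: float = 1.5
    c_reversibility: float = 0.3
    alpha_effective: float = 1.5e-3
    demag_n_effective: float = 1.0 / 3.0

    def validate(self) -> None:
        if not 0.0 <= self.c_reversibility <= 1.0:
            raise ConfigError("ja.c_reversibility must lie in [0, 1]")
        if not self.k_pinning > 0:
            raise ConfigError("ja.k_pinning must be positive")
        if not self.a_domain > 0:
            raise ConfigError("ja.a_domain must be positive")
        if not 0.0 <= self.demag_n_effective <= 1.0:
            raise ConfigError("ja.demag_n_effective must lie in [0, 1]")


@dataclass
class StimulationProtocol:
    """DC/AC stimulation protocol.

    All fields in tesla and seconds.  The DC sweep grid is the published
    three-sub-interval grid (2-50 mT, 100-800 mT, 1-4 T; fifteen linearly
    spaced values each).
    """

    dc_field: float = 0.3                 # T
    dc_duration: float = 5e-3             # s, nano-electroporation phase
    ac_amplitudes: tuple[float, ...] = (
        1e-3, 2e-3, 2.5e-3, 3e-3, 4.5e-3, 5e-3, 6.5e-3)  # T
    ac_frequency: float = 100.0           # Hz
    ac_duration: float = 30e-3            # s, drug-release phase
    sweep_grid: tuple[float, ...] | None = None  # T; None -> default grid

    def validate(self) -> None:
        if not self.ac_frequency > 0:
            raise ConfigError("stimulation.ac_frequency must be positive")
        if not (self.dc_duration > 0 and self.ac_duration > 0):
            raise ConfigError("stimulation durations must be positive")
        if self.dc_field < 0 or any(a < 0 for a in self.ac_amplitudes):
            raise ConfigError("stimulation amplitudes must be >= 0")


def default_sweep_grid() -> tuple[float, ...]:
    """The published DC sweep grid: 15 linearly spaced values in each of
    2-50 mT, 100-800 mT and 1-4 T (45 points; 0 T excluded)."""
    import numpy as np

    parts = [
        np.linspace(2e-3, 50e-3, 15),
        np.linspace(100e-3, 800e-3, 15),
        np.linspace(1.0, 4.0, 15),
    ]
    return tuple(float(h) for h in np.concatenate(parts))


@dataclass
class CoreShellGeometry:
    """Axisymmetric core-shell-box geometry (metres)."""

    core_radius: float = 45e-9
    shell_thickness: float = 25e-9
    box_half_side: float = 1000e-9

    @property
    def outer_radius(self) -> float:
        """Particle radius r_MENP = core radius + shell thickness."""
        return self.core_radius + self.shell_thickness

    @property
    def particle_diameter(self) -> float:
        """phi_MENP = 2 * r_MENP."""
        return 2.0 * self.outer_radius

    def validate(self) -> None:
        if not self.core_radius > 0:
            raise ConfigError("geometry.core_radius must be positive")
        if not self.shell_thickness > 0:
            raise ConfigError("geometry.shell_thickness must be positive")
        if not self.box_half_side > 5.0 * self.outer_radius:
            raise ConfigError(
                "geometry.box_half_side must exceed 5x the particle radius"
            )


# --------------------------------------------------------------------------
# scenario
# --------------------------------------------------------------------------

_RESOLUTIONS = ("coarse", "default", "fine")


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation."""

    core: CoreMaterial = field(default_factory=CoreMaterial)
    shell: ShellMaterial = field(default_factory=ShellMaterial)
    environment: EnvironmentMaterial = field(default_factory=blood_vessel_wall)
    geometry: CoreShellGeometry = field(default_factory=CoreShellGeometry)
    ja: JAParameters = field(default_factory=JAParameters)
    stimulation: StimulationProtocol = field(default_factory=StimulationProtocol)
    mesh_resolution: str = "default"
    random_seed: int = 0

    def validate(self) -> None:
        for section in (self.core, self.shell, self.environment,
                        self.geometry, self.ja, self.stimulation):
            section.validate()
        if self.mesh_resolution not in _RESOLUTIONS:
            raise ConfigError(
                f"mesh_resolution must be one of {_RESOLUTIONS}"
            )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        cfg = cls()
        sections = {
            "core": CoreMaterial,
            "shell": ShellMaterial,
            "environment": EnvironmentMaterial,
            "geometry": CoreShellGeometry,
            "ja": JAParameters,
            "stimulation": StimulationProtocol,
        }
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                base = getattr(cfg, key)
                known = {f.name for f in dataclasses.fields(base)}
                for name, v in value.items():
                    if name not in known:
                        raise ConfigError(f"unknown key {key}.{name}")
                    # magnetic fields may carry an explicit unit suffix
                    if key == "stimulation" and name in ("dc_field",):
                        v = parse_field(v)
                    if key == "stimulation" and name in ("ac_amplitudes",
                                                         "sweep_grid"):
                        if v is not None:
                            v = tuple(parse_field(x) for x in v)
                    if isinstance(getattr(base, name), tuple) and v is not None \
                            and not isinstance(v, tuple):
                        v = tuple(v)
                    setattr(base, name, v)
            elif key in ("mesh_resolution", "random_seed"):
                setattr(cfg, key, value)
            else:
                raise ConfigError(f"unknown top-level key {key!r}")
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        payload = self.to_dict()

        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [_clean(v) for v in obj]
            return obj

        Path(path).write_text(
            yaml.safe_dump(_clean(payload), sort_keys=True), encoding="utf-8"
        )


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario configuration from a YAML/JSON file.

    Unspecified fields take the published defaults; an empty mapping yields
    the full default BV scenario.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text(encoding="utf-8"))
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return ScenarioConfig.from_dict(data)


def default_scenario(environment: str = "BV") -> ScenarioConfig:
    """The published scenario in the requested host environment."""
    cfg = ScenarioConfig()
    if environment == "CM":
        cfg.environment = culture_medium()
    elif environment == "BV":
        cfg.environment = blood_vessel_wall()
    else:
        raise ConfigError("environment must be 'CM' or 'BV'")
    cfg.validate()
    return cfg
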