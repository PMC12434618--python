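"""Analytic oracle cases and scenario fixtures.

Closed-form reference solutions for the three verification problems every
pipeline stage is tested against:

* a linear magnetizable sphere in a uniform applied field (uniform
  interior magnetization with demagnetizing factor 1/3),
* a dielectric sphere in a uniform imposed field (uniform interior field
  3*eps_out*E0/(eps_in + 2*eps_out)),
* a uniform eigenstrain in a spherical inclusion of a homogeneous elastic
  medium (uniform interior stress — the classical inclusion property).

Every reference value here is produced by direct formula evaluation (or,
for the magnetic sphere, an independent fixed-point iteration on the
demagnetizing relation); this module imports no solver code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .config import ScenarioConfig, default_scenario
from .units import MU0

__all__ = [
    "OracleCase", "make_linear_sphere_case", "make_dielectric_sphere_case",
    "make_eigenstrain_inclusion_case", "generate_reference_scenarios",
    "linear_sphere_fixed_point",
]


@dataclass
class OracleCase:
    """A verification problem with an independent closed-form reference."""

    name: str
    params: dict
    reference: float | None
    formula: str
    tolerance: float
    check: Callable | None = None


def linear_sphere_fixed_point(chi: float, H_a: float,
                              tol: float = 1e-12) -> float:
    """Brute-force fixed point of M = chi*(H_a - M/3), cross-checking the
    closed form chi*H_a/(1 + chi/3)."""
    M = 0.0
    omega = 1.0 / (1.0 + chi / 3.0)     # contraction for any chi >= 0
    for _ in range(100000):
        M_new = chi * (H_a - M / 3.0)
        if abs(M_new - M) <= tol * max(abs(M), 1.0):
            return M_new
        M = M + omega * (M_new - M)
    return M


def make_linear_sphere_case(chi: float, H_ext_T: float) -> OracleCase:
    """Uniformly magnetized linear sphere: M = chi*H_a/(1 + chi/3)."""
    if chi < 0:
        raise ValueError("susceptibility must be >= 0")
    H_a = H_ext_T / MU0
    ref = chi * H_a / (1.0 + chi / 3.0)
    return OracleCase(
        name="linear_sphere",
        params={"chi": chi, "H_ext_T": H_ext_T},
        reference=ref,
        formula="chi*H_a/(1 + chi/3), demagnetizing factor 1/3",
        tolerance=0.02,
    )


def make_dielectric_sphere_case(eps_in: float, eps_out: float,
                                E0: float) -> OracleCase:
    """Dielectric sphere in a uniform field: E_in = 3*eps_out*E0/(eps_in+2*eps_out)."""
    if eps_in < 1 or eps_out < 1:
        raise ValueError("relative permittivities must be >= 1")
    ref = 3.0 * eps_out * E0 / (eps_in + 2.0 * eps_out)
    return OracleCase(
        name="dielectric_sphere",
        params={"eps_in": eps_in, "eps_out": eps_out, "E0": E0},
        reference=ref,
        formula="3*eps_out*E0/(eps_in + 2*eps_out)",
        tolerance=0.01,
    )


def make_eigenstrain_inclusion_case(lambda_eff: float) -> OracleCase:
    """Uniform eigenstrain in a spherical inclusion of a homogeneous
    medium: the interior stress field is uniform (qualitative reference;
    the check is a coefficient of variation below 3%)."""
    return OracleCase(
        name="eigenstrain_inclusion",
        params={"lambda_eff": lambda_eff},
        reference=None,
        formula="uniform interior stress for a uniform ellipsoidal eigenstrain",
        tolerance=0.03,
    )


def generate_reference_scenarios() -> list[ScenarioConfig]:
    """The two published scenarios (CM and BV) at default resolution plus
    coarse smoke-test variants with fixed seeds."""
    out = []
    for env in ("CM", "BV"):
        out.append(default_scenario(env))
    for env in ("CM", "BV"):
        cfg = default_scenario(env)
        cfg.mesh_resolution = "coarse"
        cfg.random_seed = 1234
        out.append(cfg)
    return out
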