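"""DC-sweep response curves, semi-corona field statistics and the
nano-electroporation operating map.

The magnetoelectric coefficient is the field's customary mixed-unit
efficiency metric

    alpha_ME = dV / (H * phi)   [mV Oe^-1 cm^-1],

with dV the pole-to-pole surface potential difference in mV, H the applied
field in oersted and phi the full particle diameter (core + shell) in cm.
Local electric-field distributions are summarized by the median and the
1st/99th percentiles over semi-corona annuli at 5/10/20 nm from the shell
surface, and classified against the reversible nano-electroporation window
2e4-5e4 V/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig, default_sweep_grid
from .coupled import FieldSolution, Model
from .mesh import CoronaRegion, corona_region
from .units import convert_field_units

__all__ = [
    "SweepRecord", "CoronaStats", "RegimeLabel", "delta_v", "alpha_me",
    "dc_sweep", "corona_statistics", "classify_regime",
    "select_operating_fields", "weighted_percentile",
    "E_REV_LOW", "E_REV_HIGH",
]

#: reversible nano-electroporation window, V/m
E_REV_LOW = 2.0e4
E_REV_HIGH = 5.0e4


def delta_v(solution: FieldSolution) -> float:
    """Surface potential difference max(V) - min(V) over the shell outer
    border, in mV (the two opposite poles)."""
    surf = solution.mesh.node_sets["shell_outer_surface"]
    if len(surf) == 0:
        raise ValueError("empty shell_outer_surface node set")
    Vs = solution.V[surf]
    return float((Vs.max() - Vs.min()) * 1e3)


def alpha_me(dv_mV: float, H_Oe: float, phi_cm: float) -> float:
    """Magnetoelectric coefficient dV/(H*phi), mV Oe^-1 cm^-1."""
    if H_Oe <= 0:
        raise ValueError("alpha_ME undefined for H <= 0")
    if phi_cm <= 0:
        raise ValueError("particle diameter must be positive")
    return dv_mV / (H_Oe * phi_cm)


@dataclass
class SweepRecord:
    """Per-field summary of the stationary response."""

    H_T: float
    H_Oe: float
    M: float                    # volume-averaged core magnetization, A/m
    dV_mV: float
    alpha: float                # mV Oe^-1 cm^-1
    environment: str

    def as_dict(self) -> dict:
        return {
            "H_mT": self.H_T * 1e3, "H_Oe": self.H_Oe, "M_Am": self.M,
            "dV_mV": self.dV_mV, "alpha_mV_per_Oe_cm": self.alpha,
            "environment": self.environment,
        }


def dc_sweep(config: ScenarioConfig, model: Model | None = None,
             grid=None) -> list[SweepRecord]:
    """Stationary solve over the DC field grid (default: the published
    three-sub-interval grid, 45 points).

    The mesh, the magnetostatic Laplacian and the electromechanical
    operator are factorized once and reused; each field value only changes
    right-hand sides.  The previous magnetization warm-starts the Picard
    iteration.
    """
    if model is None:
        model = Model(config)
    if grid is None:
        grid = config.stimulation.sweep_grid or default_sweep_grid()
    phi_cm = config.geometry.particle_diameter * 1e2
    records = []
    M_prev = None
    for H in grid:
        sol = model.stationary(H, M_init=M_prev)
        M_prev = sol.magnetostatics.M
        dv = delta_v(sol)
        H_Oe = convert_field_units(H, "T", "Oe")
        records.append(SweepRecord(
            H_T=H, H_Oe=H_Oe, M=sol.magnetostatics.core_mean_M(model.mesh),
            dV_mV=dv, alpha=alpha_me(dv, H_Oe, phi_cm),
            environment=config.environment.name,
        ))
    return records


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


# --------------------------------------------------------------------------
# corona statistics and regime classification
# --------------------------------------------------------------------------

def weighted_percentile(values: np.ndarray, weights: np.ndarray,
                        q) -> np.ndarray:
    """Weighted percentile with the linear-interpolation definition.

    Reduces to ``numpy.percentile(values, q)`` for equal weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.asarray(q, dtype=float) / 100.0, cw, v)


@dataclass
class CoronaStats:
    """Percentile summary of |E| over one semi-corona."""

    distance: float             # m
    H_T: float
    median: float
    p1: float
    p99: float
    n_samples: int
    mode: str
    environment: str = ""

    def validate(self) -> None:
        if not (0 <= self.p1 <= self.median <= self.p99):
            raise ValueError("corona percentiles out of order")


def corona_statistics(solution: FieldSolution, region: CoronaRegion,
                      environment: str = "") -> CoronaStats:
    """Weighted |E| percentiles over a sampled semi-corona region."""
    elems = solution.mesh.locate(region.points)
    Em = solution.E_mag[elems]
    med, p1, p99 = weighted_percentile(Em, region.weights, [50.0, 1.0, 99.0])
    H_T = (solution.magnetostatics.H_ext
           if solution.magnetostatics is not None else float("nan"))
    stats = CoronaStats(
        distance=region.distance, H_T=H_T, median=float(med),
        p1=float(p1), p99=float(p99), n_samples=len(region.points),
        mode=region.mode, environment=environment,
    )
    stats.validate()
    return stats


@dataclass
class RegimeLabel:
    """Nano-electroporation regime for one corona distribution.

    * ``irreversible``: p99 above the 5e4 V/m damage threshold.
    * ``sub_threshold``: p99 below the 2e4 V/m activation threshold.
    * ``reversible``: the whole 1st-99th percentile band inside the window.
    * ``mixed``: anything else (band straddles the lower threshold only).
    """

    label: str
    E_rev_low: float = E_REV_LOW
    E_rev_high: float = E_REV_HIGH


def classify_regime(stats: CoronaStats) -> RegimeLabel:
    if stats.p99 > E_REV_HIGH:
        lab = "irreversible"
    elif stats.p99 < E_REV_LOW:
        lab = "sub_threshold"
    elif stats.p1 >= E_REV_LOW:
        lab = "reversible"
    else:
        lab = "mixed"
    return RegimeLabel(label=lab)


# --------------------------------------------------------------------------
# operating-field selection
# --------------------------------------------------------------------------

def select_operating_fields(records: list[SweepRecord],
                            dv_increment_threshold: float = 0.15,
                            slope_tolerance: float = 0.20):
    """Select the three operating fields from a sorted DC sweep.

    * H2: grid point maximizing alpha_ME.
    * H3: first grid point past the steepest rise of dV(H) at which the
      increment of dV from the previous grid point falls below
      ``dv_increment_threshold`` (mV); ``None`` ("not reached") if the
      increments never drop below it.  (Restricting to the post-steepest
      region keeps the rule from firing trivially at low fields where dV
      itself is still small.)
    * H1: largest grid point below H2 whose local alpha-vs-H slope is
      within ``slope_tolerance`` of the initial slope (the operational
      reading of "linear dependence between alpha_ME and H").

    Returns (H1, H2, H3) in tesla (H1/H3 may be None).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 sweep points")
    H = np.array([r.H_T for r in records])
    if np.any(np.diff(H) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    dv = np.array([r.dV_mV for r in records])
    alpha = np.array([r.alpha for r in records])

    i2 = int(np.argmax(alpha))
    H2 = float(H[i2])

    H3 = None
    inc = np.diff(dv)
    for i in range(int(np.argmax(inc)) + 1, len(inc)):
        if inc[i] < dv_increment_threshold:
            H3 = float(H[i + 1])
            break

    slopes = np.diff(alpha) / (np.diff(H) * 1e3)   # per mT
    s0 = slopes[0]
    H1 = None
    for i in range(min(i2, len(slopes)) - 1, -1, -1):
        if abs(slopes[i] - s0) <= slope_tolerance * abs(s0):
            H1 = float(H[i + 1])
            break
    return H1, H2, H3
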