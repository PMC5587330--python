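"""Forward model of the in vitro lung model (IVLM) circuit.

The bench circuit is a closed extracorporeal loop: a pump feeds an upstream
("mixed venous") mixing chamber, which distributes perfusate over up to five
hollow-fiber membrane oxygenators in parallel plus optional shunt tubes; all
outlets recombine in a downstream ("arterial") mixing chamber.  Each
oxygenator is ventilated with inert-gas-free sweep gas at flow V and perfused
at flow Q.  Treating every oxygenator as a single perfectly equilibrating
compartment, the steady-state retention of a gas with partition coefficient
``lambda`` in one unit follows the Farhi relation

    r = lambda / (lambda + V/Q),

and the circuit retention is the perfusion-weighted mixture of unit
retentions plus the shunted fraction (which retains everything).  True
("preset") shunt is the shunted flow divided by total flow.

Only flow ratios and ``lambda`` enter the retentions; pressures are carried
in arbitrary-but-consistent units so that measured data can be ingested
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .gases import GasPanel

#: relative tolerance above 1.0 beyond which a measured retention is suspect
RETENTION_TOLERANCE = 0.05


@dataclass(frozen=True)
class ExchangeUnit:
    """One membrane oxygenator: sweep-gas flow V and perfusate flow Q (ml/min).

    A unit with ``sweep_flow == 0`` exchanges nothing and acts as shunt; a
    unit with ``perfusate_flow == 0`` carries no perfusate and contributes
    nothing to the downstream mixture.
    """

    sweep_flow: float
    perfusate_flow: float

    def __post_init__(self) -> None:
        if self.sweep_flow < 0 or self.perfusate_flow < 0:
            raise ConfigurationError(
                f"flows must be >= 0, got V={self.sweep_flow}, Q={self.perfusate_flow}"
            )

    @property
    def vq_ratio(self) -> float:
        if self.perfusate_flow == 0:
            return np.nan
        return self.sweep_flow / self.perfusate_flow


@dataclass(frozen=True)
class CircuitConfig:
    """Circuit layout: parallel exchange units plus explicit shunt-tube flow.

    ``total_flow`` defaults to ``shunt_flow + sum(unit perfusate flows)``;
    if given explicitly it must agree within ``flow_tolerance`` (relative),
    which admits flow-meter error in measured configurations.
    """

    units: tuple[ExchangeUnit, ...]
    shunt_flow: float = 0.0
    total_flow: float | None = None
    flow_tolerance: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if not 1 <= len(self.units) <= 5:
            raise ConfigurationError("circuit needs 1-5 exchange units")
        if self.shunt_flow < 0:
            raise ConfigurationError("shunt_flow must be >= 0")
        summed = self.shunt_flow + sum(u.perfusate_flow for u in self.units)
        if self.total_flow is None:
            object.__setattr__(self, "total_flow", summed)
        else:
            if self.total_flow <= 0:
                raise ConfigurationError("total_flow must be > 0")
            tol = max(self.flow_tolerance, 1e-9) * max(self.total_flow, summed)
            if abs(self.total_flow - summed) > tol:
                raise ConfigurationError(
                    f"total_flow {self.total_flow} inconsistent with branch sum "
                    f"{summed} (tolerance {tol})"
                )
        if self.total_flow <= 0:
            raise ConfigurationError("circuit needs at least one positive flow path")

    @property
    def n_units(self) -> int:
        return len(self.units)


def five_unit_circuit(unit_flow: float = 500.0, sweep_flow: float = 500.0) -> CircuitConfig:
    """Nominal five-oxygenator circuit: equal V and Q per unit, zero shunt.

    The bench default is 500 ml/min sweep gas and 500 ml/min perfusate per
    unit (V/Q = 1 in every unit, 2500 ml/min total pump flow).
    """
    return CircuitConfig(
        tuple(ExchangeUnit(sweep_flow, unit_flow) for _ in range(5)), shunt_flow=0.0
    )


def unit_retention(lam: float, sweep_flow: float, perfusate_flow: float) -> float:
    """Farhi retention ``lambda / (lambda + V/Q)`` of one equilibrating unit.

    Equals 1 for an unventilated (V = 0) unit.  ``perfusate_flow`` must be
    positive: a unit without perfusate has no defined retention.
    """
    if perfusate_flow <= 0:
        raise ConfigurationError("unit_retention requires perfusate_flow > 0")
    if lam <= 0:
        raise ConfigurationError("partition coefficient must be > 0")
    if sweep_flow < 0:
        raise ConfigurationError("sweep_flow must be >= 0")
    return lam / (lam + sweep_flow / perfusate_flow)


def preset_shunt_fraction(config: CircuitConfig) -> float:
    """Reference (preset) shunt: shunted flow over total flow.

    Shunted flow is the shunt-tube flow plus the perfusate flow of any unit
    with zero sweep-gas flow (such a unit exchanges nothing).
    """
    if config.total_flow is None or config.total_flow <= 0:
        raise ConfigurationError("total_flow must be > 0")
    shunted = config.shunt_flow + sum(
        u.perfusate_flow for u in config.units if u.sweep_flow == 0
    )
    return shunted / config.total_flow


def bypass_units(config: CircuitConfig, k: int) -> CircuitConfig:
    """Reroute the perfusate of ``k`` units through shunt tubes.

    Requires an equal-flow circuit (every unit at the same perfusate flow);
    this mirrors the bench maneuver of bypassing 1-4 of the 5 oxygenators
    while keeping total pump flow unchanged, so the preset shunt becomes
    ``k / n_units`` exactly.  ``k`` may be at most ``n_units - 1``: with every
    unit bypassed the circuit has no ventilated path.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ConfigurationError(f"k must be an integer, got {k!r}")
    if not 0 <= k <= config.n_units - 1:
        raise ConfigurationError(
            f"k must be in [0, {config.n_units - 1}] "
            "(a fully bypassed circuit has no ventilated path)"
        )
    flows = {u.perfusate_flow for u in config.units}
    if len(flows) != 1:
        raise ConfigurationError("bypass_units requires equal-flow units")
    if config.shunt_flow != 0:
        raise ConfigurationError("bypass_units starts from a zero-shunt circuit")
    per_unit = flows.pop()
    kept = config.units[: config.n_units - k]
    bypassed_flow = k * per_unit
    return CircuitConfig(kept, shunt_flow=bypassed_flow, total_flow=config.total_flow)


@dataclass(frozen=True)
class RetentionRecord:
    """One MMIMS sample: paired up/downstream partial pressures per gas.

    Pressures are in arbitrary consistent units; only the ratio (retention)
    matters downstream.  ``retentions`` is downstream / upstream per gas.
    """

    gas_names: tuple[str, ...]
    upstream_pressures: np.ndarray
    downstream_pressures: np.ndarray
    sample_id: str = "sample"
    setting_id: str = "setting"
    perfusate: str = "blood"

    def __post_init__(self) -> None:
        up = np.asarray(self.upstream_pressures, dtype=float)
        dn = np.asarray(self.downstream_pressures, dtype=float)
        object.__setattr__(self, "gas_names", tuple(self.gas_names))
        object.__setattr__(self, "upstream_pressures", up)
        object.__setattr__(self, "downstream_pressures", dn)
        if not (len(self.gas_names) == up.size == dn.size):
            raise DataError("gas names and pressure arrays must align")
        if np.any(up <= 0):
            raise DataError("upstream pressures must be > 0")
        if np.any(dn < 0):
            raise DataError("downstream pressures must be >= 0")

    @property
    def retentions(self) -> np.ndarray:
        return self.downstream_pressures / self.upstream_pressures

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "setting_id": self.setting_id,
                "perfusate": self.perfusate,
                "gas": list(self.gas_names),
                "upstream_pressure": self.upstream_pressures,
                "downstream_pressure": self.downstream_pressures,
                "retention": self.retentions,
            }
        )


def retention_from_pressures(upstream: float, downstream: float) -> float:
    """Retention as the downstream/upstream partial-pressure ratio.

    Values above ``1 + RETENTION_TOLERANCE`` are physically suspect
    (measurement artefact); they are kept but flagged with a warning.
    """
    if upstream <= 0:
        raise DataError(f"upstream pressure must be > 0, got {upstream}")
    if downstream < 0:
        raise DataError(f"downstream pressure must be >= 0, got {downstream}")
    r = downstream / upstream
    if r > 1.0 + RETENTION_TOLERANCE:
        warnings.warn(
            f"retention {r:.4g} exceeds 1 beyond tolerance; suspect measurement",
            stacklevel=2,
        )
    return r


def predict_retentions(
    config: CircuitConfig,
    panel: GasPanel,
    upstream_pressures: np.ndarray | float = 1.0,
    sample_id: str = "forward",
    setting_id: str = "forward",
) -> RetentionRecord:
    """Noiseless circuit retentions: perfusion-weighted mixture of unit outlets.

    For gas j,  ``R_j = q_s + sum_i q_i * lambda_j / (lambda_j + V_i/Q_i)``
    where ``q_s`` is the shunted flow fraction and ``q_i`` the perfusate-flow
    fraction of unit i (units with no perfusate flow drop out).  Downstream
    pressures are ``R * upstream``.
    """
    lams = panel.partition_coefficients
    q_total = config.total_flow
    r = np.full_like(lams, config.shunt_flow / q_total)
    for u in config.units:
        if u.perfusate_flow == 0:
            continue
        q_i = u.perfusate_flow / q_total
        if u.sweep_flow == 0:
            r += q_i  # unventilated unit retains everything
        else:
            r += q_i * lams / (lams + u.vq_ratio)
    up = np.broadcast_to(np.asarray(upstream_pressures, dtype=float), lams.shape).copy()
    return RetentionRecord(
        tuple(panel.names),
        up,
        r * up,
        sample_id=sample_id,
        setting_id=setting_id,
        perfusate=panel.perfusate_label,
    )


def steady_state_upstream_level(
    config: CircuitConfig, panel: GasPanel, infusion_rate: float
) -> np.ndarray:
    """Per-gas upstream level at closed-circuit steady state.

    With continuous infusion into a closed loop, each gas accumulates until
    elimination through the ventilated units balances the infusion; the
    upstream (mixed-venous side) level then scales as

        c_j = infusion_rate / (total_flow * (1 - R_j)).

    Retention itself is independent of the infusion rate; this is used only
    to give synthetic samples realistic absolute pressures.  A gas with
    R_j = 1 (full shunt) never reaches steady state.
    """
    if infusion_rate <= 0:
        raise ConfigurationError("infusion_rate must be > 0")
    r = predict_retentions(config, panel).retentions
    if np.any(r >= 1.0 - 1e-12):
        raise ConfigurationError(
            "no steady state: retention is 1 for at least one gas (full shunt); "
            "inert gas would accumulate without bound in a closed circuit"
        )
    return infusion_rate / (config.total_flow * (1.0 - r))
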