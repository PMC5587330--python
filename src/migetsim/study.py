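"""Synthetic bench studies with the structure of the validation experiment.

A study visits a set of preset shunt settings (k of 5 equal-flow oxygenators
bypassed, so targets are multiples of 0.2) in seeded-random order, for one or
both perfusates, drawing duplicate retention samples at each setting.  Two
error sources are modelled:

* flow-meter error — every "measured" flow is the true flow times a
  ``Normal(1, flow_error_rel)`` factor (the meters are rated at about 1%);
  the reference shunt IVLM-S is computed from these measured flows, as on
  the bench, while the physics uses the true flows;
* retention measurement noise — multiplicative ``Normal(1,
  retention_noise_rel)`` per gas and duplicate, clipped to [0, 1].

Everything is reproducible from the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import (
    CircuitConfig,
    RetentionRecord,
    bypass_units,
    five_unit_circuit,
    predict_retentions,
    preset_shunt_fraction,
    steady_state_upstream_level,
)
from .exceptions import ConfigurationError
from .gases import GasPanel, default_panel
from .inversion import CompartmentGrid, VQDistributionModel

N_UNITS = 5


@dataclass(frozen=True)
class StudyDesign:
    """Design of one synthetic bench study.

    Defaults reproduce the experiment's layout: shunt settings 0-0.8 in
    steps of 0.2 (bypassing 0-4 of 5 units), duplicate samples per setting,
    both perfusates, 1% flow-meter error, 2% multiplicative retention noise,
    500 ml/min sweep and perfusate flow per unit, and an inert-gas infusion
    of about 1/1000 of total pump flow.
    """

    settings: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    duplicates_per_setting: int = 2
    perfusates: tuple[str, ...] = ("blood", "saline")
    seed: int = 0
    flow_error_rel: float = 0.01
    retention_noise_rel: float = 0.02
    unit_flow: float = 500.0
    sweep_flow: float = 500.0
    infusion_rate: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "settings", tuple(self.settings))
        object.__setattr__(self, "perfusates", tuple(self.perfusates))
        if self.duplicates_per_setting < 1:
            raise ConfigurationError("duplicates_per_setting must be >= 1")
        if self.flow_error_rel < 0 or self.retention_noise_rel < 0:
            raise ConfigurationError("noise levels must be >= 0")
        if not self.perfusates or any(
            p not in ("blood", "saline") for p in self.perfusates
        ):
            raise ConfigurationError(f"invalid perfusates {self.perfusates}")
        for s in self.settings:
            self.bypass_count(s)

    @staticmethod
    def bypass_count(setting: float) -> int:
        """Map a target shunt fraction to the number of bypassed units."""
        k = setting * N_UNITS
        if abs(k - round(k)) > 1e-9 or not 0 <= round(k) <= N_UNITS - 1:
            raise ConfigurationError(
                f"setting {setting} is not achievable: targets must be k/{N_UNITS} "
                f"with k in 0..{N_UNITS - 1}"
            )
        return int(round(k))


def _measured_flows(
    config: CircuitConfig, rel_err: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Simulate the shunt-tube and main flow meters; returns (shunt, total)."""
    jitter = lambda x: x * rng.normal(1.0, rel_err) if rel_err > 0 else x
    return jitter(config.shunt_flow), jitter(config.total_flow)


def generate_study(
    design: StudyDesign,
    panels: dict[str, GasPanel] | None = None,
) -> tuple[list[RetentionRecord], pd.DataFrame]:
    """Simulate the full study.

    Returns the retention records (``duplicates_per_setting`` per setting and
    perfusate, with noise applied) and a truth table with one row per record:
    ``perfusate, setting_id, duplicate, target_shunt, ivlm_shunt, seed``.
    ``ivlm_shunt`` is the flow-meter-derived reference shunt; ``target_shunt``
    is the exact k/5 design value.
    """
    rng = np.random.default_rng(design.seed)
    panels = panels or {p: default_panel(p) for p in design.perfusates}
    records: list[RetentionRecord] = []
    truth_rows = []
    for perfusate in design.perfusates:
        panel = panels[perfusate]
        order = rng.permutation(len(design.settings))  # randomized setting order
        for pos in order:
            target = design.settings[pos]
            k = design.bypass_count(target)
            config = bypass_units(
                five_unit_circuit(design.unit_flow, design.sweep_flow), k
            )
            shunt_meas, total_meas = _measured_flows(
                config, design.flow_error_rel, rng
            )
            ivlm_shunt = shunt_meas / total_meas
            clean = predict_retentions(config, panel)
            upstream = steady_state_upstream_level(
                config, panel, design.infusion_rate
            )
            setting_id = f"k{k}"
            for dup in range(design.duplicates_per_setting):
                r = clean.retentions
                if design.retention_noise_rel > 0:
                    r = r * rng.normal(1.0, design.retention_noise_rel, r.size)
                r = np.clip(r, 0.0, 1.0)
                rec = RetentionRecord(
                    tuple(panel.names),
                    upstream,
                    r * upstream,
                    sample_id=f"{perfusate}_{setting_id}_d{dup}",
                    setting_id=setting_id,
                    perfusate=perfusate,
                )
                records.append(rec)
                truth_rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "perfusate": perfusate,
                        "setting_id": setting_id,
                        "duplicate": dup,
                        "target_shunt": target,
                        "ivlm_shunt": ivlm_shunt,
                        "seed": design.seed,
                    }
                )
    return records, pd.DataFrame(truth_rows)


def invert_records(
    records: list[RetentionRecord],
    panels: dict[str, GasPanel] | None = None,
    grid: CompartmentGrid | None = None,
    smoothing_weight: float | None = None,
) -> pd.DataFrame:
    """Run the MIGET inversion on every record.

    Returns a summary frame ``sample_id, mm_shunt, rss, converged``.
    """
    panels = panels or {}
    kwargs = {}
    if smoothing_weight is not None:
        kwargs["smoothing_weight"] = smoothing_weight
    rows = []
    for rec in records:
        panel = panels.get(rec.perfusate) or default_panel(rec.perfusate)
        dist = VQDistributionModel(rec, panel, grid=grid, **kwargs).fit()
        rows.append(
            {
                "sample_id": rec.sample_id,
                "mm_shunt": dist.shunt,
                "rss": dist.rss,
                "converged": dist.converged,
            }
        )
    return pd.DataFrame(rows)


def emulate_s1_table(
    design: StudyDesign,
    panels: dict[str, GasPanel] | None = None,
    grid: CompartmentGrid | None = None,
    smoothing_weight: float | None = None,
) -> pd.DataFrame:
    """Full pipeline: simulate, invert, and pair reference with derived shunt.

    Produces the experiment table consumed by the agreement statistics, in
    the same schema used for the deposited bench data: one row per sample
    with ``perfusate, setting_id, duplicate, ivlm_shunt, mm_shunt, rss``.
    """
    records, truth = generate_study(design, panels)
    summary = invert_records(records, panels, grid, smoothing_weight)
    table = truth.merge(summary, on="sample_id", validate="one_to_one")
    return table[
        [
            "sample_id",
            "perfusate",
            "setting_id",
            "duplicate",
            "target_shunt",
            "ivlm_shunt",
            "mm_shunt",
            "rss",
            "converged",
            "seed",
        ]
    ]
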