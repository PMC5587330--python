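"""Inert gas panels for MIGET.

MIGET infers the ventilation-perfusion distribution from the simultaneous
retention of several inert gases whose solubilities span the physiological
V/Q range.  A gas is characterised by its Ostwald perfusate-gas partition
coefficient ``lambda`` (dimensionless); a panel is an ordered set of gases
with strictly increasing ``lambda``.  The classic six-gas panel runs from
sulfur hexafluoride (nearly insoluble, sensitive to shunt) to acetone
(highly soluble, sensitive to high V/Q and deadspace).

Default coefficients for blood and saline perfusates are literature-typical
values shipped in a versioned data file (``data/gas_panels.yaml``); they can
be overridden per experiment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

#: canonical gas order of the default six-gas panel
GAS_NAMES = ("SF6", "KR", "DES", "ENF", "DEE", "AC")

PERFUSATE_LABELS = ("blood", "saline")


@dataclass(frozen=True)
class InertGas:
    """One inert tracer gas.

    Parameters
    ----------
    name : str
        Short identifier (e.g. ``"SF6"``).
    partition_coefficient : float
        Ostwald perfusate-gas partition coefficient ``lambda`` at circuit
        temperature; dimensionless, strictly positive.
    """

    name: str
    partition_coefficient: float

    def __post_init__(self) -> None:
        lam = self.partition_coefficient
        if not np.isfinite(lam) or lam <= 0:
            raise ConfigurationError(
                f"partition coefficient of {self.name!r} must be finite and > 0, "
                f"got {lam!r}"
            )


@dataclass(frozen=True)
class GasPanel:
    """Ordered panel of inert gases for one perfusate.

    Gases must be unique by name and strictly increasing in
    ``partition_coefficient``; panel order therefore encodes solubility order.
    """

    gases: tuple[InertGas, ...]
    perfusate_label: str = "blood"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gases", tuple(self.gases))
        if len(self.gases) < 2:
            raise ConfigurationError("a gas panel needs at least 2 gases")
        names = [g.name for g in self.gases]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate gas names in panel: {names}")
        lams = self.partition_coefficients
        if not np.all(np.diff(lams) > 0):
            raise ConfigurationError(
                "panel gases must be strictly increasing in partition "
                f"coefficient, got {dict(zip(names, lams))}"
            )

    def __len__(self) -> int:
        return len(self.gases)

    def __iter__(self):
        return iter(self.gases)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.gases]

    @property
    def partition_coefficients(self) -> np.ndarray:
        """``lambda`` values in panel order, shape ``(n_gases,)``."""
        return np.array([g.partition_coefficient for g in self.gases], dtype=float)

    @classmethod
    def from_mapping(
        cls, coefficients: Mapping[str, float], perfusate_label: str = "blood"
    ) -> "GasPanel":
        """Build a panel from ``{name: lambda}``, sorted by ``lambda``."""
        gases = sorted(
            (InertGas(n, float(v)) for n, v in coefficients.items()),
            key=lambda g: g.partition_coefficient,
        )
        return cls(tuple(gases), perfusate_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gas": self.names,
                "partition_coefficient": self.partition_coefficients,
                "perfusate": self.perfusate_label,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "GasPanel":
        df = pd.read_csv(path_or_buf)
        labels = df["perfusate"].unique()
        if len(labels) != 1:
            raise ConfigurationError(f"panel CSV mixes perfusates: {labels}")
        gases = tuple(
            InertGas(str(r.gas), float(r.partition_coefficient))
            for r in df.itertuples()
        )
        return cls(gases, str(labels[0]))


def _load_default_coefficients() -> dict[str, dict[str, float]]:
    text = resources.files("migetsim.data").joinpath("gas_panels.yaml").read_text()
    return yaml.safe_load(io.StringIO(text))["panels"]


def default_panel(
    perfusate_label: str, overrides: Mapping[str, float] | None = None
) -> GasPanel:
    """Return the default six-gas panel for ``"blood"`` or ``"saline"``.

    ``overrides`` replaces individual coefficients (the result must still be
    strictly ordered).  The shipped values are literature defaults; the
    source experiment reports only the gas identities.
    """
    if perfusate_label not in PERFUSATE_LABELS:
        raise ConfigurationError(
            f"unknown perfusate {perfusate_label!r}; expected one of {PERFUSATE_LABELS}"
        )
    coefs = dict(_load_default_coefficients()[perfusate_label])
    if overrides:
        unknown = set(overrides) - set(coefs)
        if unknown:
            raise ConfigurationError(f"overrides for unknown gases: {sorted(unknown)}")
        coefs.update({k: float(v) for k, v in overrides.items()})
    gases = tuple(InertGas(n, coefs[n]) for n in GAS_NAMES)
    return GasPanel(gases, perfusate_label)
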