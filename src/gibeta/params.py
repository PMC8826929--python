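"""Model parameters for the glucose–insulin–β-cell (GIβ) system.

Units are fixed package-wide: glucose in mM, insulin in nM, β-cell mass in
arbitrary mass units, time in minutes.  Rate constants carry per-minute
units; the classical human parametrization of the Topp model (mg/dl,
μU/ml, days) can be converted with the helpers below.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Union

__all__ = [
    "ModelParams",
    "default_params",
    "topp_human_params",
    "load_params",
    "save_params",
    "MGDL_PER_MM",
    "NM_PER_UU_ML",
    "MIN_PER_DAY",
]

#: mg/dl of glucose per mM (molar mass of glucose 180.16 g/mol).
MGDL_PER_MM = 18.016
#: nM of insulin per μU/ml (1 IU insulin = 6.00 nmol).
NM_PER_UU_ML = 0.006
#: minutes per day, for converting per-day rate constants.
MIN_PER_DAY = 1440.0


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's constraints."""


@dataclass(frozen=True)
class ModelParams:
    """The ten constants of the GIβ system.

    Attributes
    ----------
    R0 : float
        Hepatic glucose production rate (mM·min⁻¹).
    EG0 : float
        Insulin-independent glucose clearance rate (min⁻¹).
    SP : float
        Peripheral insulin sensitivity (nM⁻¹·min⁻¹): rate constant
        coupling insulin to glucose disposal.
    sigma0 : float
        Maximal insulin secretion rate per unit β mass (nM·min⁻¹·mass⁻¹).
    alpha : float
        Square of the glucose half-saturation constant of secretion (mM²).
    k : float
        First-order insulin clearance rate (min⁻¹).
    d0 : float
        β-cell death rate (min⁻¹).
    r1 : float
        First-order β-cell replication coefficient (mM⁻¹·min⁻¹).
    r2 : float
        Second-order β-cell replication coefficient (mM⁻²·min⁻¹).
    Sbeta : float
        β-cell insulin sensitivity (nM⁻¹), scaling the autocrine
        inhibition factor 1/(1 + Sbeta·I) on secretion.  Sbeta = 0
        recovers the unmodified Topp secretion term.
    """

    R0: float
    EG0: float
    SP: float
    sigma0: float
    alpha: float
    k: float
    d0: float
    r1: float
    r2: float
    Sbeta: float

    def __post_init__(self) -> None:
        for name in ("R0", "EG0", "SP", "sigma0", "k", "d0", "r1", "r2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if not math.isfinite(self.alpha) or self.alpha <= 0:
            # alpha = 0 would make secretion a step at G=0 and the
            # half-saturation constant meaningless.
            raise ParameterError(f"alpha must be finite and > 0, got {self.alpha}")
        if not math.isfinite(self.Sbeta) or self.Sbeta < 0:
            raise ParameterError(
                f"Sbeta must be finite and >= 0 for simulation use, got {self.Sbeta}"
            )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(changes)
        return ModelParams(**d)

    def has_interior_steady_state(self) -> bool:
        """Whether the β-cell net-growth quadratic has a real positive root."""
        return self.r1 * self.r1 >= 4.0 * self.r2 * self.d0

    def to_dict(self) -> dict:
        return asdict(self)


_PARAM_NAMES = tuple(f.name for f in fields(ModelParams))


def default_params() -> ModelParams:
    """Default wildtype-female parameter set (mM / nM / min units).

    Derived from the human Topp parametrization converted to these units,
    then adjusted so that (a) the full-model steady state sits at a typical
    6-h-fasted mouse glycemia of 8 mM with plasma insulin ≈ 0.15 nM and a
    reference β mass near 1, and (b) a simulated +20 mM glucose tolerance
    test clears over roughly an hour, as in wildtype female mice on a
    low-fat diet.  Sbeta defaults to 3.4 nM⁻¹, the clamp-estimated
    wildtype-female β-cell insulin sensitivity; SP defaults to
    70 nM⁻¹·day⁻¹ expressed per minute.
    """
    return ModelParams(
        R0=0.07,
        EG0=0.0015,
        SP=70.0 / MIN_PER_DAY,
        sigma0=0.136,
        alpha=64.0,
        k=0.3,
        d0=1.0e-4,
        r1=1.65e-5,
        r2=5.0e-7,
        Sbeta=3.4,
    )


def topp_human_params(Sbeta: float = 0.0) -> ModelParams:
    """Classical human Topp parameter set converted to mM / nM / min.

    The original values are R0=864 mg·dl⁻¹·d⁻¹, EG0=1.44 d⁻¹,
    SI=0.72 ml·μU⁻¹·d⁻¹, σ=43.2 μU·ml⁻¹·d⁻¹, α=20000 mg²·dl⁻²,
    k=432 d⁻¹, d0=0.06 d⁻¹, r1=0.84e-3 dl·mg⁻¹·d⁻¹,
    r2=0.24e-5 dl²·mg⁻²·d⁻¹ (β mass in mg).
    """
    return ModelParams(
        R0=864.0 / MGDL_PER_MM / MIN_PER_DAY,
        EG0=1.44 / MIN_PER_DAY,
        SP=0.72 / NM_PER_UU_ML / MIN_PER_DAY,
        sigma0=43.2 * NM_PER_UU_ML / MIN_PER_DAY,
        alpha=20000.0 / MGDL_PER_MM**2,
        k=432.0 / MIN_PER_DAY,
        d0=0.06 / MIN_PER_DAY,
        r1=0.84e-3 * MGDL_PER_MM / MIN_PER_DAY,
        r2=0.24e-5 * MGDL_PER_MM**2 / MIN_PER_DAY,
        Sbeta=Sbeta,
    )


def load_params(path: Union[str, Path]) -> ModelParams:
    """Read a flat-JSON parameter file (strict: unknown keys rejected).

    The file must contain exactly the ten parameter keys plus
    ``"time_unit": "min"``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must contain a JSON object")
    time_unit = raw.pop("time_unit", None)
    if time_unit != "min":
        raise ParameterError(f'parameter file must declare "time_unit": "min", got {time_unit!r}')
    unknown = set(raw) - set(_PARAM_NAMES)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(_PARAM_NAMES) - set(raw)
    if missing:
        raise ParameterError(f"missing parameter keys: {sorted(missing)}")
    return ModelParams(**{k: float(v) for k, v in raw.items()})


def save_params(params: ModelParams, path: Union[str, Path]) -> None:
    """Write a parameter file in the schema accepted by :func:`load_params`."""
    payload = {"time_unit": "min", **params.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
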