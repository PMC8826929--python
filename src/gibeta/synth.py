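"""Synthetic clamp, GTT and calcium data with known ground truth.

Every generator is a deterministic function of (seed, config) and embeds
the generating parameters in its output, so each downstream estimator can
be scored against truth.  The default conditions emulate the study
design: hyperglycemic clamps at 19 mM sampled every 10 min for 2 h with
the first sample excluded, control (Sβ = 3.4 nM⁻¹) versus β-cell
insulin-receptor knockout (Sβ = 0) groups with identical β-cell mass,
+20 mM glucose tolerance tests, and perifusion calcium traces with a
3 mM baseline phase and a 15 mM stimulation phase.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .clamp import ClampSeries
from .gtt import GTTCurve, augc, simulate_gtt
from .model import clamp_steady_insulin, steady_state_full
from .params import ModelParams, default_params

__all__ = [
    "ClampConfig",
    "GTTConfig",
    "CalciumConfig",
    "ClampDataset",
    "GTTDataset",
    "gen_clamp_dataset",
    "gen_gtt_dataset",
    "gen_calcium_traces",
    "write_manifest",
]

#: Measurement noise, as a fraction of the group-mean signal.  The upper
#: end of the 5–10% range typical of insulin immunoassay plus sampling
#: variability; glucose meters are comparable.
DEFAULT_NOISE_FRAC = 0.10
#: Generated measurements are truncated below at this fraction of the
#: group mean, keeping them positive.
POSITIVITY_FLOOR_FRAC = 0.01


def _noisy(
    rng: np.random.Generator, values: np.ndarray, sd: float, floor: float
) -> np.ndarray:
    out = values + rng.normal(0.0, sd, size=values.shape)
    return np.maximum(out, floor)


# ---------------------------------------------------------------------------
# Hyperglycemic clamps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClampConfig:
    """Study design for a synthetic control/knockout clamp experiment."""

    seed: int = 0
    n_animals: int = 14
    clamp_glucose: float = 19.0
    t_start: float = 0.0
    t_end: float = 120.0
    t_step: float = 10.0
    noise_frac: float = DEFAULT_NOISE_FRAC
    sbeta_control: float = 3.4
    sex: str = "female"
    params: ModelParams = field(default_factory=default_params)
    beta_mass: Optional[float] = None  # default: full-model β* of control params

    def __post_init__(self) -> None:
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.sbeta_control < 0:
            raise ValueError("control Sbeta must be >= 0")
        if self.n_animals < 1:
            raise ValueError("need at least one animal per group")


@dataclass(frozen=True)
class ClampDataset:
    control: ClampSeries
    knockout: ClampSeries
    truth: Dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for series in (self.control, self.knockout):
            for a in range(series.n_animals):
                parts.append(
                    pd.DataFrame(
                        {
                            "animal_id": f"{series.group}_{a:02d}",
                            "group": series.group,
                            "sex": series.sex,
                            "time_min": series.timepoints,
                            "insulin_nM": series.measurements[a],
                            "clamp_glucose_mM": series.clamp_glucose,
                        }
                    )
                )
        return pd.concat(parts, ignore_index=True)


def gen_clamp_dataset(cfg: ClampConfig) -> ClampDataset:
    """Generate paired control/knockout clamp insulin series.

    Each measurement is the group's closed-form clamp steady-state
    insulin plus Gaussian noise (SD = ``noise_frac`` × group mean),
    truncated at a small positive floor.  The knockout group is forced to
    Sβ = 0; both groups share the same β-cell mass.
    """
    rng = np.random.default_rng(cfg.seed)
    p_wt = cfg.params.replace(Sbeta=cfg.sbeta_control)
    p_ko = cfg.params.replace(Sbeta=0.0)
    beta = cfg.beta_mass
    if beta is None:
        beta = steady_state_full(p_wt)[2]
    timepoints = np.arange(cfg.t_start, cfg.t_end + 0.5 * cfg.t_step, cfg.t_step)
    series = {}
    levels = {}
    for label, p in (("control", p_wt), ("knockout", p_ko)):
        I_ss = clamp_steady_insulin(p, cfg.clamp_glucose, beta)
        levels[label] = I_ss
        flat = np.full((cfg.n_animals, len(timepoints)), I_ss)
        meas = _noisy(rng, flat, cfg.noise_frac * I_ss, POSITIVITY_FLOOR_FRAC * I_ss)
        series[label] = ClampSeries(
            group=label,
            sex=cfg.sex,
            timepoints=timepoints,
            measurements=meas,
            clamp_glucose=cfg.clamp_glucose,
        )
    truth = {
        "sbeta_true": cfg.sbeta_control,
        "I_ss_control": levels["control"],
        "I_ss_knockout": levels["knockout"],
        "beta_mass": beta,
        "seed": cfg.seed,
    }
    return ClampDataset(control=series["control"], knockout=series["knockout"], truth=truth)


# ---------------------------------------------------------------------------
# Glucose tolerance tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTTConfig:
    """Study design for a synthetic per-group GTT cohort."""

    seed: int = 0
    n_animals: int = 14
    bolus: float = 20.0
    duration: float = 60.0
    t_step: float = 1.0
    noise_frac: float = DEFAULT_NOISE_FRAC
    params: ModelParams = field(default_factory=default_params)
    beta_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_frac < 0 or self.bolus < 0:
            raise ValueError("noise_frac and bolus must be >= 0")


@dataclass(frozen=True)
class GTTDataset:
    curves: List[GTTCurve]
    true_curve: GTTCurve
    truth: Dict[str, float]

    @property
    def augc_values(self) -> np.ndarray:
        return np.array([augc(c) for c in self.curves])

    def augc_band(self) -> Tuple[float, float]:
        """(mean, SEM) of per-animal glucose AUCs."""
        a = self.augc_values
        return float(a.mean()), float(a.std(ddof=1) / np.sqrt(len(a)))

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for i, c in enumerate(self.curves):
            parts.append(
                pd.DataFrame(
                    {
                        "animal_id": f"animal_{i:02d}",
                        "time_min": c.times,
                        "glucose_mM": c.glucose,
                        "insulin_nM": c.insulin,
                        "bolus_mM": c.bolus,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def gen_gtt_dataset(cfg: GTTConfig) -> GTTDataset:
    """Generate a cohort of noisy GTT curves from one parameter set.

    The noiseless model curve is simulated once; each animal's glucose
    (and insulin) samples add Gaussian noise with SD = ``noise_frac`` ×
    the true value at that time, floored at 1% of the curve mean.
    """
    rng = np.random.default_rng(cfg.seed)
    beta = cfg.beta_mass
    if beta is None:
        beta = steady_state_full(cfg.params)[2]
    t_grid = np.arange(0.0, cfg.duration + 0.5 * cfg.t_step, cfg.t_step)
    base = simulate_gtt(cfg.params, beta, bolus=cfg.bolus, duration=cfg.duration, t_grid=t_grid)
    g_floor = POSITIVITY_FLOOR_FRAC * base.glucose.mean()
    i_floor = POSITIVITY_FLOOR_FRAC * base.insulin.mean()
    curves = []
    for _ in range(cfg.n_animals):
        g = np.maximum(base.glucose + rng.normal(0, cfg.noise_frac * base.glucose), g_floor)
        i = np.maximum(base.insulin + rng.normal(0, cfg.noise_frac * base.insulin), i_floor)
        curves.append(GTTCurve(times=t_grid, glucose=g, insulin=i, bolus=cfg.bolus))
    truth = {
        "sbeta_true": cfg.params.Sbeta,
        "sp_true": cfg.params.SP,
        "beta_mass": beta,
        "augc_true": augc(base),
        "seed": cfg.seed,
    }
    return GTTDataset(curves=curves, true_curve=base, truth=truth)


# ---------------------------------------------------------------------------
# Calcium traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalciumConfig:
    """Design of a synthetic perifusion recording.

    The stimulation phase carries ``n_bumps`` Gaussian-shaped calcium
    transients (shape arbitrary; only the counting rule matters) of
    amplitude ``amplitude_pct`` percent over the baseline level.
    """

    seed: int = 0
    n_cells: int = 12
    baseline_label: str = "3mM"
    stim_label: str = "15mM"
    baseline_s: float = 300.0
    stim_s: float = 600.0
    sample_dt_s: float = 5.0
    baseline_level: float = 1.0
    n_bumps: int = 5
    amplitude_pct: float = 40.0
    bump_width_s: float = 6.0
    noise_sd_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.n_bumps < 0 or self.noise_sd_frac < 0:
            raise ValueError("n_bumps and noise_sd_frac must be >= 0")
        # bumps are spaced with 4-sigma margins; they must fit the phase
        if self.n_bumps and self.stim_s < (self.n_bumps + 1) * 4.0 * self.bump_width_s:
            raise ValueError("bump width exceeds stimulation-phase capacity")

    @property
    def phase_glucose(self) -> Dict[str, float]:
        return {self.baseline_label: 3.0, self.stim_label: 15.0}


def gen_calcium_traces(cfg: CalciumConfig) -> Tuple[List[CalciumTrace], Dict[str, float]]:
    """Generate phase-structured ratio traces with a known peak count.

    Bump centres are evenly spaced through the stimulation phase with
    4-sigma margins, so each bump is an isolated suprathreshold local
    maximum; additive Gaussian noise (SD = ``noise_sd_frac`` × baseline)
    perturbs every sample.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sample_dt_s
    t = np.arange(0.0, cfg.baseline_s + cfg.stim_s, dt)
    n_base = int(round(cfg.baseline_s / dt))
    phases = np.array(
        [cfg.baseline_label] * n_base + [cfg.stim_label] * (len(t) - n_base)
    )
    amp = cfg.baseline_level * cfg.amplitude_pct / 100.0
    margin = 4.0 * cfg.bump_width_s
    if cfg.n_bumps:
        centres = np.linspace(
            cfg.baseline_s + margin, cfg.baseline_s + cfg.stim_s - margin, cfg.n_bumps
        )
    else:
        centres = np.array([])
    traces = []
    for c in range(cfg.n_cells):
        clean = np.full_like(t, cfg.baseline_level)
        for mu in centres:
            clean = clean + amp * np.exp(-0.5 * ((t - mu) / cfg.bump_width_s) ** 2)
        noisy = clean + rng.normal(0, cfg.noise_sd_frac * cfg.baseline_level, size=len(t))
        noisy = np.maximum(noisy, 0.05 * cfg.baseline_level)
        traces.append(
            CalciumTrace(
                times=t,
                ratio=noisy,
                phases=phases,
                cell_id=f"cell_{c:03d}",
                mouse_id="mouse_00",
            )
        )
    truth = {
        "n_bumps": cfg.n_bumps,
        "amplitude_pct": cfg.amplitude_pct,
        "baseline_level": cfg.baseline_level,
        "seed": cfg.seed,
    }
    return traces, truth


def write_manifest(path, seed: int, config, truth: Dict[str, float]) -> None:
    """Write a JSON manifest recording seed, config and ground truth."""
    cfg = asdict(config)
    if "params" in cfg and not isinstance(cfg["params"], dict):
        cfg["params"] = cfg["params"].to_dict()
    payload = {"seed": seed, "config": cfg, "ground_truth": truth}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")
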