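"""β-cell insulin sensitivity (Sβ) estimation from hyperglycemic-clamp data.

During a hyperglycemic clamp, glucose is held constant (~19 mM) and plasma
insulin hovers around its secretion–clearance steady state.  Writing the
insulin steady-state equation for a control animal (with autocrine
feedback, sensitivity Sβ) and for a β-cell insulin-receptor knockout
(Sβ = 0) with all other parameters shared, and solving the pair for Sβ,
every model parameter cancels:

    derivation variant:  Sβ = (I_m − I_wt) / I_wt²
    printed variant:     Sβ = (I_m − I_wt) / I_m²

where I_wt and I_m are the steady-state insulin levels of the control and
knockout group.  The two variants coincide to first order in Sβ·I and are
related exactly by printed = derivation / (1 + Sβ·I_wt)² on noiseless
data; both are provided because the published formula (the "printed"
form) differs from the form the steady-state algebra yields (the
"derivation" form).  The estimator is parameter-free: it needs no rate
constants and no β-cell mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClampSeries",
    "SbetaEstimate",
    "sbeta_point_estimate",
    "estimate_sbeta",
    "compare_sbeta",
    "read_clamp_csv",
    "write_clamp_csv",
]

Variant = Literal["printed", "derivation"]

CLAMP_CSV_COLUMNS = (
    "animal_id",
    "group",
    "sex",
    "time_min",
    "insulin_nM",
    "clamp_glucose_mM",
)


class ClampSchemaError(ValueError):
    """A clamp CSV violates the declared schema."""


@dataclass(frozen=True)
class ClampSeries:
    """Per-group clamp insulin measurements assumed at steady state.

    ``measurements`` has shape (n_animals, n_timepoints), one row per
    animal, aligned to ``timepoints`` (minutes since clamp start).  The
    first timepoint is excluded from estimation: insulin has not yet
    settled to steady state there.
    """

    group: str
    sex: str
    timepoints: np.ndarray
    measurements: np.ndarray
    clamp_glucose: float

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        m = np.asarray(self.measurements, dtype=float)
        if tp.ndim != 1 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if m.ndim != 2 or m.shape[1] != len(tp):
            raise ValueError("measurements must be (n_animals, n_timepoints)")
        if m.shape[0] < 1:
            raise ValueError("at least one animal required")
        if np.any(~np.isfinite(m)) or np.any(m <= 0):
            raise ValueError("all insulin measurements must be finite and > 0")
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "measurements", m)

    @property
    def n_animals(self) -> int:
        return self.measurements.shape[0]

    def retained_means(self) -> Tuple[np.ndarray, np.ndarray]:
        """(timepoints, per-timepoint group-mean insulin), first point dropped."""
        return self.timepoints[1:], self.measurements[:, 1:].mean(axis=0)


@dataclass(frozen=True)
class SbetaEstimate:
    """Sβ estimate with per-timepoint values and a test against zero."""

    point_estimates: np.ndarray
    mean: float
    sem: float
    n: int
    p_vs_zero: float
    variant: Variant

    def __post_init__(self) -> None:
        pe = np.asarray(self.point_estimates, dtype=float)
        if len(pe) != self.n:
            raise ValueError("n must equal the number of point estimates")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        object.__setattr__(self, "point_estimates", pe)

    def to_dict(self) -> dict:
        return {
            "mean_nM_inv": self.mean,
            "sem_nM_inv": self.sem,
            "n_timepoints": self.n,
            "p_vs_zero": self.p_vs_zero,
            "variant": self.variant,
            "point_estimates": list(map(float, self.point_estimates)),
        }


def sbeta_point_estimate(I_wt: float, I_m: float, variant: Variant = "printed") -> float:
    """Single-timepoint Sβ (nM⁻¹) from control/knockout steady insulin.

    ``printed`` uses the published closed form (I_m − I_wt)/I_m²;
    ``derivation`` uses (I_m − I_wt)/I_wt², the form obtained by solving
    the paired steady-state equations.  Negative values (knockout insulin
    below control) are reported as-is, never clipped.
    """
    if not (I_wt > 0 and I_m > 0):
        raise ValueError(f"insulin levels must be > 0, got I_wt={I_wt}, I_m={I_m}")
    if variant == "printed":
        return (I_m - I_wt) / (I_m * I_m)
    if variant == "derivation":
        return (I_m - I_wt) / (I_wt * I_wt)
    raise ValueError(f"unknown variant {variant!r}")


def estimate_sbeta(
    wt: ClampSeries,
    ko: ClampSeries,
    variant: Variant = "printed",
    bootstrap: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SbetaEstimate:
    """Estimate Sβ from paired control/knockout clamp series.

    At each shared timepoint after the first, group-mean insulins are
    formed and converted into a point estimate; the result carries their
    mean, SEM across timepoints, and a one-sample two-sided t-test of
    mean ≠ 0.  If ``bootstrap`` is given, the SEM is instead computed by
    resampling animals within each group that many times (the
    per-animal-bootstrap alternative).
    """
    t_wt, m_wt = wt.retained_means()
    t_ko, m_ko = ko.retained_means()
    if len(t_wt) != len(t_ko) or not np.allclose(t_wt, t_ko):
        raise ValueError("series must share timepoints after the first")
    if len(t_wt) < 2:
        raise ValueError("insufficient matched timepoints (< 2 after excluding the first)")
    pe = np.array(
        [sbeta_point_estimate(iw, im, variant) for iw, im in zip(m_wt, m_ko)]
    )
    mean = float(pe.mean())
    n = len(pe)
    if bootstrap:
        rng = rng or np.random.default_rng(0)
        reps = np.empty(bootstrap)
        W = wt.measurements[:, 1:]
        K = ko.measurements[:, 1:]
        for b in range(bootstrap):
            iw = W[rng.integers(0, W.shape[0], W.shape[0])].mean(axis=0)
            im = K[rng.integers(0, K.shape[0], K.shape[0])].mean(axis=0)
            reps[b] = np.mean(
                [sbeta_point_estimate(a, c, variant) for a, c in zip(iw, im)]
            )
        sem = float(reps.std(ddof=1))
    else:
        sem = float(pe.std(ddof=1) / np.sqrt(n))
    if np.ptp(pe) == 0.0:
        # degenerate (noiseless) collections: the t statistic is 0/0
        p_val = 1.0 if mean == 0.0 else 0.0
    else:
        p_val = float(stats.ttest_1samp(pe, 0.0).pvalue)
    return SbetaEstimate(
        point_estimates=pe,
        mean=mean,
        sem=sem,
        n=n,
        p_vs_zero=p_val,
        variant=variant,
    )


def compare_sbeta(
    a: SbetaEstimate,
    b: SbetaEstimate,
    test: Literal["welch", "student", "paired"] = "welch",
) -> float:
    """Two-sample p-value comparing the point-estimate collections.

    Welch's t-test by default; ``paired`` requires equal length and
    returns 1.0 when the two collections are identical.
    """
    x, y = a.point_estimates, b.point_estimates
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 point estimates per group")
    if test == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if test == "student":
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    if test == "paired":
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length collections")
        d = x - y
        if np.allclose(d, 0.0):
            return 1.0
        return float(stats.ttest_rel(x, y).pvalue)
    raise ValueError(f"unknown test {test!r}")


def read_clamp_csv(path) -> pd.DataFrame:
    """Read and validate a long-format clamp CSV.

    Required columns: animal_id, group, sex, time_min, insulin_nM,
    clamp_glucose_mM.
    """
    df = pd.read_csv(path)
    missing = set(CLAMP_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ClampSchemaError(f"clamp CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ClampSchemaError("clamp CSV contains no rows")
    if (df["insulin_nM"] <= 0).any():
        raise ClampSchemaError("clamp CSV contains nonpositive insulin values")
    return df


def series_from_frame(df: pd.DataFrame, group: str) -> ClampSeries:
    """Assemble one group's ClampSeries from a validated long-format frame."""
    sub = df[df["group"] == group]
    if sub.empty:
        raise ClampSchemaError(f"no rows for group {group!r}")
    wide = sub.pivot_table(index="animal_id", columns="time_min", values="insulin_nM")
    if wide.isna().any().any():
        raise ClampSchemaError(f"group {group!r} has missing animal/timepoint cells")
    return ClampSeries(
        group=group,
        sex=str(sub["sex"].iloc[0]),
        timepoints=wide.columns.to_numpy(dtype=float),
        measurements=wide.to_numpy(dtype=float),
        clamp_glucose=float(sub["clamp_glucose_mM"].iloc[0]),
    )


def write_clamp_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(CLAMP_CSV_COLUMNS))
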