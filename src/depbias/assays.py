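"""Assay-level normalizations: competition proliferation, drug
sensitization, and DNA-fiber fork-restart ratios.

Competition assays track the percentage of fluorescence-positive (sgRNA+)
cells over time; the analysis quantity is each day's percentage relative
to a baseline day (day 3 post-infection by default), optionally further
normalized to a co-cultured negative-control guide. Drug sensitization
divides the treated relative proportion by the vehicle one day-by-day.
Fiber restart efficiency is the per-fork ratio of the post-stall (IdU)
tract length to its matched pre-stall (CldU) tract, compared between
conditions with a two-tailed Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeCourse",
    "FiberRestartResult",
    "relative_proportion",
    "drug_sensitization",
    "fiber_restart",
]


@dataclass
class TimeCourse:
    """Days (strictly increasing) vs percent fluorescence-positive cells."""

    days: Sequence[int]
    percent_positive: Sequence[float]
    label: str = ""

    def __post_init__(self) -> None:
        days = list(self.days)
        vals = list(self.percent_positive)
        if len(days) != len(vals):
            raise ValueError("days and percent_positive lengths differ")
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(not (0 <= v <= 100) for v in vals):
            raise ValueError("percent_positive must lie in [0, 100]")

    def as_series(self) -> pd.Series:
        return pd.Series(list(self.percent_positive), index=list(self.days), dtype=float)


def relative_proportion(
    tc: TimeCourse, baseline_day: int = 3, control: TimeCourse | None = None
) -> pd.Series:
    """Each day's sgRNA+ percentage relative to the baseline day.

    With a control time course, each day is further divided by the
    control's own baseline-relative value for that day (a flat control
    leaves the series unchanged). The result at the baseline day is 1.0 by
    construction.
    """
    s = tc.as_series()
    if baseline_day not in s.index:
        raise ValueError(f"baseline day {baseline_day} absent from time course {tc.label!r}")
    base = s[baseline_day]
    if base <= 0:
        raise ValueError(f"baseline value must be > 0, got {base}")
    rel = s / base
    if control is not None:
        c = control.as_series()
        missing = [d for d in s.index if d not in c.index]
        if missing:
            raise ValueError(f"control time course lacks days {missing}")
        cbase = c[baseline_day]
        if cbase <= 0 or (c[s.index] <= 0).any():
            raise ValueError("control values must be > 0 on all aligned days")
        rel = rel / (c[s.index] / cbase)
    return rel


def drug_sensitization(treated: TimeCourse, vehicle: TimeCourse) -> pd.Series:
    """Day-matched treated/vehicle ratio of sgRNA+ proportions.

    Ratio < 1 means the drug depletes guide-carrying cells beyond the
    vehicle baseline (drug-specific sensitization).
    """
    t = treated.as_series()
    v = vehicle.as_series()
    if list(t.index) != list(v.index):
        raise ValueError(f"day mismatch: {list(t.index)} vs {list(v.index)}")
    if (v <= 0).any():
        bad = list(v.index[v <= 0])
        raise ValueError(f"vehicle proportion is zero on day(s) {bad}")
    return t / v


@dataclass
class FiberRestartResult:
    ratios_a: np.ndarray
    ratios_b: np.ndarray
    median_a: float
    median_b: float
    pvalue: float
    n_excluded_a: int = 0
    n_excluded_b: int = 0


def _fiber_ratios(
    fibers: pd.DataFrame | Sequence[tuple[float, float]],
    zero_idu: str,
    arm: str,
) -> tuple[np.ndarray, int]:
    if isinstance(fibers, pd.DataFrame):
        pairs = fibers[["cldu_len", "idu_len"]].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(fibers), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("fiber input must be (cldu_len, idu_len) pairs")
    cldu, idu = pairs[:, 0], pairs[:, 1]
    bad = cldu <= 0
    if bad.any():
        warnings.warn(
            f"arm {arm}: excluded {int(bad.sum())} fiber(s) with non-positive CldU tract",
            stacklevel=2,
        )
    keep = ~bad
    if zero_idu == "exclude":
        keep &= idu > 0
    elif zero_idu != "include":
        raise ValueError("zero_idu must be 'include' or 'exclude'")
    ratios = idu[keep] / cldu[keep]
    return ratios, int((~keep).sum())


def fiber_restart(
    cond_a,
    cond_b,
    zero_idu: str = "include",
    exact_max_n: int = 20,
) -> FiberRestartResult:
    """Per-fork IdU/CldU restart ratios and a two-tailed rank-sum comparison.

    Fibers with a zero IdU tract (no restart) are kept with ratio 0 by
    default (``zero_idu="exclude"`` drops them). The Mann-Whitney p-value
    uses exact enumeration when both arms have <=``exact_max_n`` tie-free
    ratios and the tie-corrected normal approximation otherwise.
    """
    ratios_a, excl_a = _fiber_ratios(cond_a, zero_idu, "a")
    ratios_b, excl_b = _fiber_ratios(cond_b, zero_idu, "b")
    if len(ratios_a) == 0 or len(ratios_b) == 0:
        raise ValueError("each condition needs >=1 usable fiber")
    if len(ratios_a) < 3 or len(ratios_b) < 3:
        pvalue = float("nan")
    else:
        has_ties = len(np.unique(np.concatenate([ratios_a, ratios_b]))) < len(ratios_a) + len(ratios_b)
        small = max(len(ratios_a), len(ratios_b)) <= exact_max_n
        method = "exact" if (small and not has_ties) else "asymptotic"
        pvalue = float(
            stats.mannwhitneyu(ratios_a, ratios_b, alternative="two-sided", method=method).pvalue
        )
    return FiberRestartResult(
        ratios_a=ratios_a,
        ratios_b=ratios_b,
        median_a=float(np.median(ratios_a)),
        median_b=float(np.median(ratios_b)),
        pvalue=pvalue,
        n_excluded_a=excl_a,
        n_excluded_b=excl_b,
    )
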