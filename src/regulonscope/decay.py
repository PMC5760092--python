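"""Protein half-life estimation from translation-shutoff chase courses.

Band intensities after blocking translation (e.g. with chloramphenicol)
are modelled as first-order decay, I(t) = I0 * 2^(-t / t_half).  The fit
is a log-linear ordinary least squares with a shared decay rate across
replicates and a free intercept per replicate (each lane has its own
loading); this keeps the estimator deterministic and closed-form.
Proteins whose apparent half-life exceeds the observation window — or
that show no decay at all — are reported censored, as "t1/2 > t_max".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))


@dataclass
class DecayCourse:
    """Chase time course: columns ``replicate``, ``time_min``, ``intensity``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"replicate", "time_min", "intensity"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"decay course missing columns: {sorted(missing)}")
        if (self.data["intensity"] <= 0).any():
            raise ValueError("intensities must be positive (log-linear fit)")
        for _, rep in self.data.groupby("replicate"):
            if rep["time_min"].min() != 0:
                raise ValueError("every replicate must start at t = 0")

    @classmethod
    def from_tsv(cls, path: str) -> "DecayCourse":
        return cls(data=pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def t_max(self) -> float:
        return float(self.data["time_min"].max())


@dataclass
class HalfLifeEstimate:
    decay_rate: float          # k, per minute (ln-scale rate)
    t_half: float              # minutes; may be inf when k <= 0
    censored: bool = False
    censor_bound: float = float("nan")
    fit_r_squared: float = float("nan")

    def __str__(self) -> str:
        if self.censored:
            return f"t1/2 > {self.censor_bound:g} min"
        return f"t1/2 = {self.t_half:.1f} min"


def fit_decay(course: DecayCourse) -> HalfLifeEstimate:
    """Joint log-linear OLS: shared slope, per-replicate intercept.

    k = -slope of ln(intensity) vs time; t_half = ln2 / k.  Intensities
    are normalized to each replicate's t = 0 value first, which only
    shifts the intercepts.  Requires >= 3 distinct time points.
    """
    df = course.data
    if df["time_min"].nunique() < 3:
        raise ValueError("need at least 3 time points to fit a decay rate")
    reps = df["replicate"].unique()
    t = df["time_min"].to_numpy(float)
    y = np.log(df["intensity"].to_numpy(float))
    # normalize to t=0 per replicate (shifts intercepts only, but keeps
    # the reported intercepts interpretable)
    for r in reps:
        m = (df["replicate"] == r).to_numpy()
        y0 = y[m & (t == 0)].mean()
        y[m] -= y0
    # design: [time | replicate dummies]
    X = np.zeros((len(df), 1 + len(reps)))
    X[:, 0] = t
    for j, r in enumerate(reps):
        X[:, 1 + j] = (df["replicate"] == r).to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(beta[0])
    k = -slope
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    t_half = LN2 / k if k > 0 else float("inf")
    return HalfLifeEstimate(decay_rate=k, t_half=t_half, fit_r_squared=r2)


def censor_estimate(estimate: HalfLifeEstimate, t_max: float) -> HalfLifeEstimate:
    """Apply the observation-window bound: estimates slower than t_max
    (or non-decaying, k <= 0) are reported as 't1/2 > t_max'."""
    if estimate.decay_rate <= 0 or estimate.t_half > t_max:
        return HalfLifeEstimate(
            decay_rate=estimate.decay_rate,
            t_half=estimate.t_half,
            censored=True,
            censor_bound=float(t_max),
            fit_r_squared=estimate.fit_r_squared,
        )
    return estimate


def estimate_half_life(course: DecayCourse, t_max: float | None = None) -> HalfLifeEstimate:
    """Fit and censor in one step (t_max defaults to the last time point)."""
    est = fit_decay(course)
    return censor_estimate(est, course.t_max if t_max is None else t_max)
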