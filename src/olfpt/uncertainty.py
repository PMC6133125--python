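"""Recovery statistics and reproducibility / uncertainty analysis.

Recoveries (measured over assigned odor concentration) describe the raw
dispersion of results; the variance-component analysis decomposes the
log10 implied odor thresholds into a within-laboratory part s_w
(repeatability, including sampling) and a between-laboratory part s_L,
by one-way ANOVA with laboratory as the grouping factor (ISO 5725-2,
unbalanced correction).  The reproducibility standard deviation
s_R = sqrt(s_w² + s_L²) then yields the expanded (k = 2) uncertainty of
a single olfactometric measurement, expressed either in decibel odor
level (10·2·s_R) or as the multiplicative interval
100·10^(∓2·s_R) percent around the assigned value.

EN 13725's quality requirement caps the within-lab log10 standard
deviation for the reference substance at s_r ≤ 0.1721, i.e. an expanded
uncertainty of at most 0.3442 log10 units (3.44 dB), roughly a 45–220 %
band — the yardstick the observed reproducibility is compared against.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusThreshold

__all__ = [
    "EN13725_SR_LIMIT",
    "VarianceComponents",
    "RecoverySummary",
    "recoveries",
    "recovery_summary",
    "estimate_variance_components",
    "expanded_uncertainty",
    "reproducibility_factor",
    "within_margin_fraction",
]

#: EN 13725 limit on the within-lab log10 standard deviation for n-butanol.
EN13725_SR_LIMIT = 0.1721

LAB_KEY = ["test_id", "participant_id"]


class ExpandedUncertainty(NamedTuple):
    U95_db: float
    rel_low_pct: float
    rel_high_pct: float


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    """Log10-scale variance decomposition for one component.

    s_w: within-laboratory (repeatability incl. sampling) standard
    deviation; s_L: between-laboratory standard deviation; both in
    log10(µg/m³).  Derived quantities follow from
    s_R = sqrt(s_w² + s_L²).
    """

    component: str
    s_w: float
    s_L: float
    n_labs: int = 0
    n_results: int = 0

    @property
    def s_R(self) -> float:
        return float(np.hypot(self.s_w, self.s_L))

    @property
    def U95_log(self) -> float:
        return 2.0 * self.s_R

    @property
    def U95_db(self) -> float:
        return 10.0 * self.U95_log

    @property
    def rel_low_pct(self) -> float:
        return 100.0 * 10.0 ** (-self.U95_log)

    @property
    def rel_high_pct(self) -> float:
        return 100.0 * 10.0 ** self.U95_log

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "component": self.component,
            "n_labs": self.n_labs,
            "n_results": self.n_results,
            "s_w": self.s_w,
            "s_L": self.s_L,
            "s_R": self.s_R,
            "U95_db": self.U95_db,
            "rel_low_pct": self.rel_low_pct,
            "rel_high_pct": self.rel_high_pct,
        }


@dataclasses.dataclass(frozen=True)
class RecoverySummary:
    """Per-(test, component) recovery descriptives."""

    test_id: str
    component: str
    n: int
    X_mean_assigned: float
    X_mean_measured: float
    rel_sd_pct: float
    log_recovery_quartiles: tuple[float, float, float]


def _threshold_value(thresholds: Mapping[str, object], comp: str) -> float:
    if comp not in thresholds:
        raise KeyError(f"no threshold available for component {comp!r}")
    th = thresholds[comp]
    if isinstance(th, ConsensusThreshold):
        return th.c0
    return float(th)  # plain µg/m³ value


def recoveries(
    measurements: pd.DataFrame, thresholds: Mapping[str, object]
) -> pd.DataFrame:
    """Per-measurement recovery table.

    ``thresholds`` maps component → odor threshold (a plain µg/m³ value
    or a :class:`ConsensusThreshold`).  Adds the assigned odor
    concentration X_ik = c_ik/c0_k, recovery = x_ik/X_ik and its log10
    to a copy of the measurement table.
    """
    out = measurements.copy()
    c0 = measurements["component"].map(
        {c: _threshold_value(thresholds, c) for c in pd.unique(out["component"])}
    )
    out["assigned_oue_m3"] = out["dosed_mass_conc_ug_m3"] / c0
    out["recovery"] = out["measured_odor_conc_oue_m3"] / out["assigned_oue_m3"]
    out["log10_recovery"] = np.log10(out["recovery"])
    return out


def recovery_summary(
    measurements: pd.DataFrame,
    thresholds: Mapping[str, object],
    by: Sequence[str] = ("test_id", "component"),
) -> list[RecoverySummary]:
    """Grouped recovery descriptives (assigned/measured means, rel. SD, quartiles).

    The relative standard deviation is 100 × sample SD / mean of the
    measured odor concentrations; quartiles of the log10 recoveries use
    the linear-interpolation (type-7) definition.
    """
    rec = recoveries(measurements, thresholds)
    out: list[RecoverySummary] = []
    for keys, sub in rec.groupby(list(by), sort=True):
        if len(sub) < 2:
            raise ValueError(
                f"group {keys} has a single measurement; SD undefined"
            )
        x = sub["measured_odor_conc_oue_m3"].to_numpy()
        q1, q2, q3 = np.quantile(sub["log10_recovery"].to_numpy(), [0.25, 0.5, 0.75])
        keys = keys if isinstance(keys, tuple) else (keys,)
        info = dict(zip(by, keys))
        out.append(
            RecoverySummary(
                test_id=str(info.get("test_id", "")),
                component=str(info.get("component", "")),
                n=len(sub),
                X_mean_assigned=float(sub["assigned_oue_m3"].mean()),
                X_mean_measured=float(x.mean()),
                rel_sd_pct=100.0 * float(np.std(x, ddof=1)) / float(x.mean()),
                log_recovery_quartiles=(float(q1), float(q2), float(q3)),
            )
        )
    return out


def estimate_variance_components(
    measurements: pd.DataFrame, component: str
) -> VarianceComponents:
    """One-way ANOVA variance decomposition of log10 implied thresholds.

    Laboratory = (test, participant); the analysed response is
    log10(c_ik/x_ik), whose within/between-lab spread is independent of
    any threshold convention.  Unbalanced designs use the standard
    correction n̄ = (N − Σn_i²/N)/(p − 1):

        s_w² = pooled within-lab mean square
        s_L² = max(0, (MS_between − s_w²) / n̄)

    Laboratories contributing a single replicate are excluded (they
    carry no within-lab information).
    """
    sub = measurements.loc[measurements["component"] == component]
    if sub.empty:
        raise ValueError(f"no measurements for component {component!r}")
    logt = np.log10(
        sub["dosed_mass_conc_ug_m3"] / sub["measured_odor_conc_oue_m3"]
    )
    groups = [
        g.to_numpy()
        for _, g in logt.groupby([sub[k] for k in LAB_KEY], sort=True)
        if len(g) >= 2
    ]
    p = len(groups)
    if p < 2:
        raise ValueError(
            f"need >= 2 laboratories with >= 2 replicates for {component!r}"
        )
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    s_w2 = ss_within / (N - p)
    ms_between = float((n_i * (means - grand) ** 2).sum() / (p - 1))
    n_bar = (N - (n_i**2).sum() / N) / (p - 1)
    s_L2 = max(0.0, (ms_between - s_w2) / n_bar)
    return VarianceComponents(
        component=component,
        s_w=float(np.sqrt(s_w2)),
        s_L=float(np.sqrt(s_L2)),
        n_labs=p,
        n_results=N,
    )


def expanded_uncertainty(s_R: float, *, rounded: bool = False) -> ExpandedUncertainty:
    """Expanded (k = 2) uncertainty of a single measurement from s_R.

    Returns the dB odor level 10·(2·s_R) and the multiplicative percent
    interval 100·10^(∓2·s_R).  With ``rounded=True`` applies report
    rounding: dB to 2 decimals, bounds to integer percent.
    """
    if s_R < 0:
        raise ValueError("s_R must be >= 0")
    u_log = 2.0 * s_R
    db = 10.0 * u_log
    low = 100.0 * 10.0 ** (-u_log)
    high = 100.0 * 10.0**u_log
    if rounded:
        return ExpandedUncertainty(round(db, 2), float(round(low)), float(round(high)))
    return ExpandedUncertainty(db, low, high)


def reproducibility_factor(s_R: float) -> float:
    """95 % bound on the ratio of two independent single measurements.

    The difference of two i.i.d. log10 results has standard deviation
    sqrt(2)·s_R, so in 95 % of cases the ratio stays below
    10^(2·sqrt(2)·s_R).
    """
    if s_R < 0:
        raise ValueError("s_R must be >= 0")
    return 10.0 ** (2.0 * np.sqrt(2.0) * s_R)


def within_margin_fraction(
    recovery_table: pd.DataFrame, low: float = 0.5, high: float = 2.0
) -> pd.Series:
    """Share of recoveries inside [low, high], per component."""
    if recovery_table.empty:
        raise ValueError("empty recovery table")
    r = recovery_table["recovery"]
    inside = (r >= low) & (r <= high)
    return inside.groupby(recovery_table["component"], sort=True).mean()
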