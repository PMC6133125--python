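"""Assigned values, adaptive criteria, z-scores, and verdicts.

Each single result is scored on the log10 scale:

    z_ik = (1 / σ_k) · log10(x_ik / X_ik),   X_ik = c_ik / c0_k  [ou_E/m³]

where c_ik is the dosed mass concentration, c0_k the odor threshold of
component k (the conventional EN 13725 value of 123 µg/m³ for n-butanol,
a robust consensus estimate otherwise), and σ_k the criterion for
proficiency assessment.  σ_k is 0.10 log10 units unless the relative
uncertainty u_k of the assigned value is too large to be ignored, in
which case the criterion is adapted to σ_k = (1/0.3)·log10(1 + u_k)
(ISO 13528 fitness-for-purpose condition).

A participant passes a component when the mean of its three absolute
z-scores is strictly below 3, and passes overall when all components
pass.  With σ_k = 0.10 the per-result |z| < 3 band corresponds to
recoveries strictly inside 10^(±0.3), roughly 50–200 % of the assigned
value.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusThreshold
from .datamodel import ComponentConfig

__all__ = [
    "SigmaCriterion",
    "Verdict",
    "VerdictReport",
    "assigned_value",
    "combined_uncertainty",
    "adapt_sigma",
    "z_score",
    "score_study",
    "verdicts",
    "nbu_correlation",
    "default_component_configs",
]

UConvention = Literal["linear", "log"]

#: EN 13725 odor threshold of n-butanol [µg/m³].
NBU_FIXED_THRESHOLD = 123.0


def default_component_configs(
    components=("AAC", "ETX", "NBU", "PIG", "RLI", "THT"),
) -> dict[str, ComponentConfig]:
    """Default scoring configuration: σ base 0.10, u(c_k) = 1.01 %, NBU fixed."""
    return {
        comp: ComponentConfig(
            component=comp,
            fixed_threshold=NBU_FIXED_THRESHOLD if comp == "NBU" else None,
        )
        for comp in components
    }


@dataclasses.dataclass(frozen=True)
class SigmaCriterion:
    """Proficiency-assessment criterion for one component.

    ``sigma_k`` [log10 units] is the base criterion, widened when the
    assigned-value uncertainty ``u_k`` (relative fraction) violates the
    fitness-for-purpose condition; ``adapted`` records whether widening
    occurred.
    """

    component: str
    u_k: float
    sigma_k: float
    adapted: bool


@dataclasses.dataclass(frozen=True)
class Verdict:
    """Per-participant outcome: mean |z| and pass flag per component."""

    test_id: str
    participant_id: str
    per_component: dict[str, tuple[float, bool]]

    @property
    def overall_passed(self) -> bool:
        return all(passed for _, passed in self.per_component.values())


@dataclasses.dataclass(frozen=True)
class VerdictReport:
    verdicts: list[Verdict]
    pass_rate: float

    @property
    def n_passed(self) -> int:
        return sum(v.overall_passed for v in self.verdicts)


def assigned_value(c_ik: float, c0_k: float) -> float:
    """Assigned odor concentration X_ik = c_ik / c0_k [ou_E/m³]."""
    if not (c_ik > 0 and c0_k > 0):
        raise ValueError("concentrations and thresholds must be > 0")
    return c_ik / c0_k


def combined_uncertainty(u_ck: float, u_c0_rel: float) -> float:
    """Relative uncertainty of the assigned value: sqrt(u(c_k)² + u(c0_k)²)."""
    if not (0 <= u_ck < 1 and 0 <= u_c0_rel < 1):
        raise ValueError("relative uncertainties must lie in [0, 1)")
    return math.hypot(u_ck, u_c0_rel)


def adapt_sigma(
    u_k: float, base_sigma: float = 0.10, component: str = ""
) -> SigmaCriterion:
    """Widen the criterion when the assigned value is too uncertain.

    The fitness-for-purpose condition requires
    σ_k ≥ (1/0.3)·log10(1 + u_k); when the base criterion violates it,
    σ_k is raised to that threshold.
    """
    if u_k < 0:
        raise ValueError("u_k must be >= 0")
    t = math.log10(1.0 + u_k) / 0.3
    return SigmaCriterion(
        component=component,
        u_k=u_k,
        sigma_k=max(base_sigma, t),
        adapted=t > base_sigma,
    )


def z_score(x_ik: float, X_ik: float, sigma_k: float):
    """z_ik = (1/σ_k) · log10(x_ik / X_ik); accepts scalars or arrays."""
    x = np.asarray(x_ik, dtype=float)
    X = np.asarray(X_ik, dtype=float)
    if np.any(x <= 0) or np.any(X <= 0) or not sigma_k > 0:
        raise ValueError("x, X and sigma_k must be > 0")
    z = np.log10(x / X) / sigma_k
    return float(z) if z.ndim == 0 else z


def score_study(
    measurements: pd.DataFrame,
    thresholds: Mapping[str, ConsensusThreshold],
    configs: Mapping[str, ComponentConfig] | None = None,
    u_convention: UConvention = "linear",
) -> tuple[pd.DataFrame, dict[str, SigmaCriterion]]:
    """Score every measurement of a campaign.

    For each component the assigned values use the fixed conventional
    threshold when the configuration defines one (the consensus estimate
    otherwise), and the criterion σ_k is adapted from the combined
    relative uncertainty of dosing and threshold.  A fixed threshold is
    exact by convention, so only the dosing uncertainty enters u_k.

    ``u_convention`` selects how the consensus uncertainty is expressed
    as a relative fraction: ``"linear"`` uses (c0_high/c0 − 1)/2,
    ``"log"`` uses 10**u_log − 1.

    Returns the z-score table (one row per measurement, with assigned
    value, z, and σ_k) and the per-component criteria.
    """
    if configs is None:
        configs = default_component_configs(sorted(thresholds))
    criteria: dict[str, SigmaCriterion] = {}
    pieces: list[pd.DataFrame] = []
    for comp in pd.unique(measurements["component"]):
        cfg = configs.get(comp, ComponentConfig(component=comp))
        if cfg.fixed_threshold is not None:
            c0 = cfg.fixed_threshold
            u_c0 = 0.0
        else:
            if comp not in thresholds:
                raise KeyError(f"no threshold available for component {comp!r}")
            th = thresholds[comp]
            c0 = th.c0
            u_c0 = th.u_c0_rel if u_convention == "linear" else th.u_c0_rel_logscale
        crit = adapt_sigma(
            combined_uncertainty(cfg.u_ck, u_c0), cfg.base_sigma, component=comp
        )
        criteria[comp] = crit
        sub = measurements.loc[measurements["component"] == comp].copy()
        sub["assigned_oue_m3"] = sub["dosed_mass_conc_ug_m3"] / c0
        sub["sigma_k"] = crit.sigma_k
        sub["z"] = z_score(
            sub["measured_odor_conc_oue_m3"].to_numpy(),
            sub["assigned_oue_m3"].to_numpy(),
            crit.sigma_k,
        )
        pieces.append(sub)
    z_records = pd.concat(pieces).loc[measurements.index]
    return z_records, criteria


def verdicts(z_records: pd.DataFrame) -> VerdictReport:
    """Per-participant verdicts from a z-score table.

    The mean of the absolute z-scores per (participant, component) must
    be strictly below 3 for a component pass; ties at exactly 3 fail.
    A participant passes overall when every component passes.
    """
    if z_records.empty:
        raise ValueError("empty z-score table")
    mean_abs = (
        z_records.assign(abs_z=z_records["z"].abs())
        .groupby(["test_id", "participant_id", "component"], sort=True)["abs_z"]
        .mean()
    )
    out: list[Verdict] = []
    for (test_id, participant_id), sub in mean_abs.groupby(
        level=["test_id", "participant_id"], sort=True
    ):
        per_component = {
            comp: (float(val), bool(val < 3.0))
            for (_, _, comp), val in sub.items()
        }
        out.append(Verdict(test_id, participant_id, per_component))
    rate = sum(v.overall_passed for v in out) / len(out)
    return VerdictReport(verdicts=out, pass_rate=rate)


def mean_abs_z_table(z_records: pd.DataFrame) -> pd.DataFrame:
    """Tidy (test, participant, component, mean |z|) table."""
    return (
        z_records.assign(abs_z=z_records["z"].abs())
        .groupby(["test_id", "participant_id", "component"], as_index=False)["abs_z"]
        .mean()
        .rename(columns={"abs_z": "mean_abs_z"})
    )


def nbu_correlation(
    mean_z: pd.DataFrame, component: str, reference: str = "NBU"
) -> float:
    """Pearson correlation of per-participant mean z-scores vs the reference.

    ``mean_z`` is the tidy table from :func:`mean_abs_z_table`; pairs are
    formed within tests on (test_id, participant_id).  Quantifies whether
    performance on the reference substance predicts performance on
    another odorant.
    """
    ref = mean_z.loc[mean_z["component"] == reference]
    other = mean_z.loc[mean_z["component"] == component]
    merged = ref.merge(
        other, on=["test_id", "participant_id"], suffixes=("_ref", "_cmp")
    )
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 participants measuring both {reference!r} and "
            f"{component!r}, got {len(merged)}"
        )
    r, _ = stats.pearsonr(merged["mean_abs_z_ref"], merged["mean_abs_z_cmp"])
    return float(r)
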