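"""Robust consensus odor thresholds.

When no reference value exists for an odorant, the best available
estimate of its odor threshold is a robust consensus over all
participants' results.  Each single determination implies a threshold
estimate log10(c_ik / x_ik) — dosed mass concentration over measured
odor concentration — and the consensus is the robust mean of those
logarithmic values (ISO 13528 Algorithm A), which resists gross
outliers by iterative winsorization at m* ± 1.5 s*.

The standard uncertainty of the consensus is u = 1.25 · s* / sqrt(n);
the k = 2 interval is geometrically symmetric after back-transformation
to µg/m³, and the (skewed) linear-scale relative standard uncertainty is
conventionally taken from the upper limit.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusThreshold",
    "implied_thresholds",
    "robust_mean_sd",
    "consensus",
    "consensus_all",
]

NBasis = Literal["measurements", "participant_means"]


@dataclasses.dataclass(frozen=True)
class ConsensusThreshold:
    """Robust consensus odor threshold for one component.

    ``m_star``/``s_star`` are the robust mean and robust standard
    deviation of the log10 implied thresholds; ``u_log`` the standard
    uncertainty of the consensus on the log10 scale; ``c0`` and its k = 2
    limits are back-transformed to µg/m³.  ``u_c0_rel`` is the relative
    standard uncertainty derived from the upper limit,
    (c0_high/c0 − 1)/2.
    """

    component: str
    n_results: int
    m_star: float
    s_star: float
    u_log: float

    @property
    def c0(self) -> float:
        return 10.0 ** self.m_star

    @property
    def c0_low(self) -> float:
        return 10.0 ** (self.m_star - 2.0 * self.u_log)

    @property
    def c0_high(self) -> float:
        return 10.0 ** (self.m_star + 2.0 * self.u_log)

    @property
    def u_c0_rel(self) -> float:
        """Linear-scale relative standard uncertainty (upper-limit based)."""
        return (self.c0_high / self.c0 - 1.0) / 2.0

    @property
    def u_c0_rel_logscale(self) -> float:
        """Alternative convention: 10**u_log − 1 (half the log-scale k=2 span)."""
        return 10.0 ** self.u_log - 1.0

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "component": self.component,
            "n_results": self.n_results,
            "m_star": self.m_star,
            "s_star": self.s_star,
            "u_log": self.u_log,
            "c0": self.c0,
            "c0_low": self.c0_low,
            "c0_high": self.c0_high,
            "u_c0_rel": self.u_c0_rel,
        }


def implied_thresholds(measurements: pd.DataFrame, component: str) -> np.ndarray:
    """Per-measurement threshold estimates log10(c_ik / x_ik) for a component.

    Units: log10(µg/m³ per ou_E/m³), i.e. the log10 mass concentration
    corresponding to one odour unit.
    """
    sub = measurements.loc[measurements["component"] == component]
    if sub.empty:
        raise ValueError(f"no measurements for component {component!r}")
    return np.log10(
        sub["dosed_mass_conc_ug_m3"].to_numpy()
        / sub["measured_odor_conc_oue_m3"].to_numpy()
    )


def _relative_change(new: float, old: float) -> float:
    return abs(new - old) / max(abs(new), abs(old), 1e-12)


def robust_mean_sd(
    values: Iterable[float],
    *,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Robust mean and standard deviation by ISO 13528 Algorithm A.

    Initialization: m* = median, s* = 1.483 × median|v − m*|.  Each
    iteration winsorizes the data to m* ± 1.5 s*, then updates m* to the
    mean and s* to 1.134 × the sample standard deviation of the
    winsorized values, until both change by less than ``tol`` in relative
    terms (or ``max_iter`` iterations).

    If the initial MAD is zero while the values are not all identical
    (more than half the sample tied at the median), iteration starts from
    the classical standard deviation instead.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise ValueError(f"robust_mean_sd needs at least 3 values, got {v.size}")
    m = float(np.median(v))
    if np.all(v == v[0]):
        return m, 0.0
    s = 1.483 * float(np.median(np.abs(v - m)))
    if s == 0.0:
        s = float(np.std(v, ddof=1))
    for _ in range(max_iter):
        delta = 1.5 * s
        w = np.clip(v, m - delta, m + delta)
        m_new = float(np.mean(w))
        s_new = 1.134 * float(np.std(w, ddof=1))
        converged = (
            _relative_change(m_new, m) < tol and _relative_change(s_new, s) < tol
        )
        m, s = m_new, s_new
        if converged or s == 0.0:
            break
    return m, s


def consensus(
    measurements: pd.DataFrame,
    component: str,
    n_basis: NBasis = "measurements",
) -> ConsensusThreshold:
    """Robust consensus threshold for one component.

    ``n_basis`` selects the n entering u = 1.25 · s* / sqrt(n): either
    the number of individual measurements pooled over all tests (the
    convention when every single result is treated as one proficiency
    result) or the number of participating laboratories (appropriate
    when between-lab bias dominates, since replicates within a lab are
    then not independent results).
    """
    logs = implied_thresholds(measurements, component)
    m_star, s_star = robust_mean_sd(logs)
    if n_basis == "measurements":
        n = int(logs.size)
    elif n_basis == "participant_means":
        sub = measurements.loc[measurements["component"] == component]
        n = int(sub.groupby(["test_id", "participant_id"]).ngroups)
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown n_basis {n_basis!r}")
    u_log = 1.25 * s_star / math.sqrt(n)
    return ConsensusThreshold(
        component=component,
        n_results=n,
        m_star=m_star,
        s_star=s_star,
        u_log=u_log,
    )


def consensus_all(
    measurements: pd.DataFrame,
    components: Iterable[str] | None = None,
    n_basis: NBasis = "measurements",
) -> dict[str, ConsensusThreshold]:
    """Consensus thresholds for every (or the given) components."""
    if components is None:
        components = pd.unique(measurements["component"])
    return {
        comp: consensus(measurements, comp, n_basis=n_basis) for comp in components
    }
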