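"""Nonparametric group comparisons and multiplicity adjustment.

Two-group comparisons of pulse amplitude/frequency use the Mann-Whitney U
test: exact two-sided p by full enumeration when both groups have at most
8 values and there are no ties, otherwise the tie-corrected normal
approximation.  Families of comparisons are adjusted with the Holm-Sidak
step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "AdjustedPValues", "mann_whitney_u", "holm_sidak"]

EXACT_MAX_N = 8  # full enumeration is at most C(16, 8) = 12870 splits


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of two value sequences.

    ``statistic_u`` is U for group A; ``method`` records whether the exact
    enumeration or the tie-corrected normal approximation produced the p.
    """

    group_a: np.ndarray
    group_b: np.ndarray
    statistic_u: float
    p_two_sided: float
    method: str

    def to_dict(self) -> dict:
        return {"n_a": len(self.group_a), "n_b": len(self.group_b),
                "U": self.statistic_u, "p_two_sided": self.p_two_sided,
                "method": self.method}


@dataclass
class AdjustedPValues:
    """Holm-Sidak adjusted p-values, in the input order."""

    raw: np.ndarray
    adjusted: np.ndarray
    procedure: str = "holm_sidak"


def mann_whitney_u(a, b, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode`` is ``"auto"`` (exact when both n <= 8 and no ties),
    ``"exact"`` or ``"normal_approx"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        use_exact = (len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N
                     and not has_ties)
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact method is undefined with ties")
        use_exact = True
    elif mode == "normal_approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if use_exact else "asymptotic")
    return GroupComparison(group_a=a, group_b=b,
                           statistic_u=float(res.statistic),
                           p_two_sided=float(min(res.pvalue, 1.0)),
                           method="exact" if use_exact else "normal_approx")


def holm_sidak(raw_p, m: int | None = None) -> AdjustedPValues:
    """Holm-Sidak step-down adjustment.

    With p-values sorted ascending, the i-th adjusted value is the running
    maximum of 1 - (1 - p_(j))^(m - j + 1) for j <= i (1-based), capped at
    1; the input order is restored on return.  ``m`` defaults to the
    number of p-values but may be larger when the family includes
    comparisons not passed in.
    """
    raw = np.asarray(raw_p, dtype=float)
    if raw.size == 0:
        return AdjustedPValues(raw=raw, adjusted=raw.copy())
    if np.any(raw <= 0) or np.any(raw > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = raw.size
    if m < raw.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(raw, kind="stable")
    sorted_p = raw[order]
    exponents = m - np.arange(raw.size)
    stepwise = 1.0 - (1.0 - sorted_p) ** exponents
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    adjusted = np.empty_like(raw)
    adjusted[order] = adjusted_sorted
    return AdjustedPValues(raw=raw, adjusted=adjusted)
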