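"""Cohort statistics: rank-sum VAF comparisons and CH prevalence by age.

The rank-sum test is implemented with both an exact branch (full enumeration
of the permutation distribution, used for small groups) and a
normal-approximation branch (tie-corrected variance with continuity
correction).  Tests cross-check the two branches and scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .triage import OriginLabel, PatientTriage

ALPHA = 0.05
#: exact enumeration is used when the smaller group has at most this many values
EXACT_MAX_N = 8


@dataclass
class VafGroupComparison:
    group_a_label: str
    group_b_label: str
    values_a: list[float]
    values_b: list[float]
    u_statistic: float
    p_value: float
    alpha: float = ALPHA
    method: str = "exact"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a_label,
            "group_b": self.group_b_label,
            "n_a": len(self.values_a),
            "n_b": len(self.values_b),
            "mean_a": float(np.mean(self.values_a)),
            "mean_b": float(np.mean(self.values_b)),
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "method": self.method,
            "significant": self.significant,
        }


@dataclass
class AgeBin:
    low: float
    high: float
    n_patients: int
    n_with_pbc_variant: int

    @property
    def prevalence_pct(self) -> float | None:
        if self.n_patients == 0:
            return None
        return 100.0 * self.n_with_pbc_variant / self.n_patients


def _u_statistic(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Mann-Whitney U for group a, with midranks for ties."""
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    n_a = len(values_a)
    rank_sum_a = ranks[:n_a].sum()
    return float(rank_sum_a - n_a * (n_a + 1) / 2.0)


def _exact_two_sided_p(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided p by enumerating every assignment of pooled values to group a.

    Ties are handled through midranks, so the null distribution is built on
    the same rank scale as the observed statistic.  Two-sided p is the
    probability of a U at least as far from the null mean n_a*n_b/2 as the
    observed one.
    """
    n_a, n_b = len(values_a), len(values_b)
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    center = n_a * n_b / 2.0
    u_obs = _u_statistic(values_a, values_b)
    dev_obs = abs(u_obs - center)
    total = math.comb(n_a + n_b, n_a)
    hits = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def _normal_two_sided_p(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    n_a, n_b = len(values_a), len(values_b)
    n = n_a + n_b
    pooled = np.concatenate([values_a, values_b])
    u = _u_statistic(values_a, values_b)
    mean = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all values identical
        return 1.0
    dev = abs(u - mean) - 0.5
    z = max(dev, 0.0) / math.sqrt(var)
    return math.erfc(z / math.sqrt(2.0))


def rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U for group a, p).

    Exact permutation enumeration when min(n_a, n_b) <= 8, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    u = _u_statistic(values_a, values_b)
    if min(len(values_a), len(values_b)) <= EXACT_MAX_N:
        p = _exact_two_sided_p(values_a, values_b)
    else:
        p = _normal_two_sided_p(values_a, values_b)
    return u, min(p, 1.0)


def compare_vaf_by_origin(
    cohort: Sequence[PatientTriage], compartment: str, alpha: float = ALPHA
) -> VafGroupComparison:
    """Tumor-derived vs CH-related VAFs within one compartment.

    For plasma, unknown-origin (plasma-exclusive) variants are excluded; for
    tumor tissue, tumor-only and concordant variants together form the
    tumor-derived group.
    """
    if compartment not in ("tumor", "plasma"):
        raise ValueError(f"compartment must be tumor or plasma, got {compartment!r}")
    tumor_derived: list[float] = []
    ch_related: list[float] = []
    for patient in cohort:
        for lv in patient.variants.values():
            vaf = lv.vafs.get(compartment)
            if vaf is None:
                continue
            if lv.origin is OriginLabel.CH_RELATED:
                ch_related.append(vaf)
            elif lv.origin is OriginLabel.UNKNOWN_PLASMA_ONLY:
                continue
            else:
                tumor_derived.append(vaf)
    if not tumor_derived or not ch_related:
        raise ValueError(
            f"{compartment}: need both groups non-empty "
            f"(tumor-derived {len(tumor_derived)}, CH-related {len(ch_related)})"
        )
    u, p = rank_sum_test(tumor_derived, ch_related)
    method = "exact" if min(len(tumor_derived), len(ch_related)) <= EXACT_MAX_N else "normal"
    return VafGroupComparison(
        group_a_label=f"tumor_derived_{compartment}",
        group_b_label=f"ch_related_{compartment}",
        values_a=tumor_derived,
        values_b=ch_related,
        u_statistic=u,
        p_value=p,
        alpha=alpha,
        method=method,
    )


def ch_prevalence_by_age(
    cohort: Sequence[PatientTriage], bin_width_years: float = 10.0
) -> list[AgeBin]:
    """Per-decade fraction of patients with >= 1 PBC-detected (CH) variant.

    Patients with unknown age are dropped from all denominators.
    """
    aged = [p for p in cohort if p.age is not None]
    if not aged:
        raise ValueError("no patients with known age")
    lo = math.floor(min(p.age for p in aged) / bin_width_years) * bin_width_years
    hi = math.floor(max(p.age for p in aged) / bin_width_years) * bin_width_years
    bins = []
    edge = lo
    while edge <= hi:
        members = [p for p in aged if edge <= p.age < edge + bin_width_years]
        with_ch = sum(
            1
            for p in members
            if any(lv.origin is OriginLabel.CH_RELATED for lv in p.variants.values())
        )
        bins.append(
            AgeBin(
                low=edge,
                high=edge + bin_width_years,
                n_patients=len(members),
                n_with_pbc_variant=with_ch,
            )
        )
        edge += bin_width_years
    return bins
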