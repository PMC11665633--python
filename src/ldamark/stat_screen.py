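"""Nonparametric screening stages and multiple-testing correction.

Stage one is a per-feature Kruskal–Wallis test between the two classes
(chi-squared p-value, df = 1, tie correction). Stage two, applied only when
subclass labels are present, is a strict sign-consistency screen: every
cross-class stratum pair must yield a significant rank-sum z-score AND all
z-scores must share one sign for the feature to survive.

Both tests use asymptotic (normal / chi-squared) p-values with tie
correction rather than exact permutation, matching the defaults of the
standard implementations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    ADJUST_METHODS,
    AbundanceTable,
    ComparisonRecord,
    SampleGroups,
    ScreenResult,
    ValidationError,
)

__all__ = [
    "rank_sum_z",
    "kruskal_wallis_screen",
    "wilcoxon_subclass_screen",
    "adjust_pvalues",
]

_STATSMODELS_METHOD = {
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "bonferroni": "bonferroni",
    "BH": "fdr_bh",
    "fdr": "fdr_bh",
    "BY": "fdr_by",
}


def adjust_pvalues(p_values: Sequence[float], method: str = "none") -> np.ndarray:
    """Adjust a family of p-values; ``"none"`` is the identity.

    Supported methods: none, holm, hochberg, hommel, bonferroni, BH, BY and
    fdr (alias of BH), mirroring the conventional adjustment family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in _STATSMODELS_METHOD:
        raise ValidationError(
            f"unknown adjustment method {method!r}; expected one of {ADJUST_METHODS}"
        )
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_STATSMODELS_METHOD[method])[1]


def rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected standardized rank-sum of ``x`` against ``y``.

    Returns ``(z, p)`` where z is the normal-approximation standardization
    of the rank sum of ``x`` (W) within the pooled sample: positive z means
    ``x`` tends to be larger. Degenerate pooled samples (all values tied)
    give ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("rank-sum comparison requires nonempty groups")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    expected = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    if n < 2:
        return 0.0, 1.0
    variance = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    if variance <= 0:
        return 0.0, 1.0
    z = (w - expected) / np.sqrt(variance)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return float(z), p


def kruskal_wallis_screen(
    table: AbundanceTable,
    groups: SampleGroups,
    alpha: float = 0.05,
    adjust_method: str = "none",
) -> list[ScreenResult]:
    """Kruskal–Wallis class screen over every feature.

    Constant features carry no rank information and short-circuit to p = 1.
    The adjustment is applied across all features; a feature is retained iff
    its adjusted p-value is strictly below ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    ref, other = groups.class_levels
    mask_ref = groups.class_mask(ref)
    mask_other = groups.class_mask(other)
    if mask_ref.sum() < 2 or mask_other.sum() < 2:
        raise ValidationError("each class needs at least 2 samples for the class screen")

    raw_p = np.empty(table.n_features)
    for i in range(table.n_features):
        row = table.values[i]
        a, b = row[mask_ref], row[mask_other]
        if np.all(row == row[0]):
            raw_p[i] = 1.0
            continue
        try:
            _, p = stats.kruskal(a, b)
        except ValueError:  # all values identical within the tie structure
            p = 1.0
        raw_p[i] = min(1.0, float(p)) if np.isfinite(p) else 1.0

    adjusted = adjust_pvalues(raw_p, adjust_method)
    return [
        ScreenResult(
            feature_id=table.feature_ids[i],
            p_value=float(raw_p[i]),
            p_adjusted=float(adjusted[i]),
            retained=bool(adjusted[i] < alpha),
        )
        for i in range(table.n_features)
    ]


def _strata(labels: Sequence[str], mask: np.ndarray) -> list[str]:
    """Stratum names present in a class, in first-appearance order."""
    return list(dict.fromkeys(s for s, m in zip(labels, mask) if m))


def wilcoxon_subclass_screen(
    table: AbundanceTable,
    groups: SampleGroups,
    retained_features: Iterable[str],
    alpha: float = 0.05,
    adjust_method: str = "none",
) -> tuple[list[str], list[ComparisonRecord]]:
    """Strict sign-consistent rank-sum screen across subclass strata.

    For each feature retained by the class screen and each (reference-class
    stratum, non-reference-class stratum) pair, the tie-corrected rank-sum
    z and p are computed. A feature survives iff every pairwise comparison
    has adjusted p < ``alpha`` AND all z-scores share one strict sign.
    Adjustment is applied within each feature's set of comparisons.

    With no subclass labels the screen is an identity pass-through. A
    feature with no valid stratum pair falls back to the class-level
    decision (it survives).
    """
    retained = list(retained_features)
    if not groups.has_subclass:
        return retained, []
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    ref, other = groups.class_levels
    mask_ref = groups.class_mask(ref)
    mask_other = groups.class_mask(other)
    sub = groups.subclass_labels
    assert sub is not None
    strata_ref = _strata(sub, mask_ref)
    strata_other = _strata(sub, mask_other)
    sub_arr = np.array(sub)
    pair_masks = [
        (
            (u, v),
            mask_ref & (sub_arr == u),
            mask_other & (sub_arr == v),
        )
        for u in strata_ref
        for v in strata_other
    ]

    survivors: list[str] = []
    records: list[ComparisonRecord] = []
    for fid in retained:
        row = table.feature_values(fid)
        feat_records: list[ComparisonRecord] = []
        for pair, m_u, m_v in pair_masks:
            if not m_u.any() or not m_v.any():
                continue  # stratum absent from this class: skipped
            z, p = rank_sum_z(row[m_u], row[m_v])
            feat_records.append(ComparisonRecord(fid, pair, z, p))
        records.extend(feat_records)
        if not feat_records:
            survivors.append(fid)  # no valid pair: class-level decision stands
            continue
        adj = adjust_pvalues([r.p_value for r in feat_records], adjust_method)
        signs = np.sign([r.z_score for r in feat_records])
        all_significant = bool(np.all(adj < alpha))
        sign_consistent = bool(np.all(signs == signs[0]) and signs[0] != 0)
        if all_significant and sign_consistent:
            survivors.append(fid)
    return survivors, records
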