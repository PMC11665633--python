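"""Scaling, degenerate-feature filtering, direct two-class LDA, effect
sizes, the score transform, and the end-to-end discovery pipeline.

The discriminant direction is the classic two-class solution
``w proportional to S_w^{-1} (mu1 - mu0)`` with pooled within-class scatter
and a tolerance-guarded solve: rank deficiency is reported (with candidate
collinear features) rather than masked by noise injection, and the main
path contains no random number generation at all — identical inputs give
identical outputs without any seed.

The reported statistic per feature is ``sign(raw) * log10(|raw|)`` where the
raw effect combines the between-class separation of discriminant scores
with the feature's unit-normalized coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import (
    AbundanceTable,
    EffectRecord,
    LDAFit,
    MarkerRecord,
    MarkerResult,
    PipelineConfig,
    SampleGroups,
    ValidationError,
    validate_inputs,
)
from .stat_screen import kruskal_wallis_screen, wilcoxon_subclass_screen

__all__ = [
    "SingularScatterError",
    "normalize_per_million",
    "filter_degenerate",
    "fit_two_class_lda",
    "fit_from_direction",
    "compute_effect_sizes",
    "score_and_threshold",
    "find_markers",
    "BootstrapLDA",
    "bootstrap_lda_reference",
]

#: Relative eigenvalue tolerance below which the within-class scatter is
#: treated as singular.
SCATTER_RTOL = 1e-10


class SingularScatterError(ValidationError):
    """Within-class scatter is numerically singular after filtering."""

    def __init__(self, message: str, features: Sequence[str] = ()):
        super().__init__(message)
        self.features = list(features)


def normalize_per_million(
    table: AbundanceTable, scale_constant: float = 1e6
) -> AbundanceTable:
    """Rescale every sample column to sum to ``scale_constant``.

    Proportions and raw counts alike map onto a common per-sample scale, so
    the default reporting threshold of 2.0 corresponds to an absolute raw
    effect of 100 scaled-abundance units when ``scale_constant`` is 1e6.
    """
    if scale_constant <= 0:
        raise ValidationError("scale_constant must be positive")
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = table.sample_ids[int(np.argmin(sums))]
        raise ValidationError(f"sample {bad!r} has zero total abundance; cannot rescale")
    return AbundanceTable(
        table.values * (scale_constant / sums),
        list(table.feature_ids),
        list(table.sample_ids),
    )


def filter_degenerate(table: AbundanceTable) -> tuple[AbundanceTable, list[str]]:
    """Drop features that cannot inform the discriminant.

    Removes all-zero features, zero-variance (constant) features, and exact
    duplicate rows (keeping the first in input order). Returns the filtered
    table and the dropped feature ids for reporting.
    """
    keep: list[int] = []
    dropped: list[str] = []
    seen_rows: set[bytes] = set()
    for i in range(table.n_features):
        row = table.values[i]
        if np.all(row == 0) or np.all(row == row[0]):
            dropped.append(table.feature_ids[i])
            continue
        key = row.tobytes()
        if key in seen_rows:
            dropped.append(table.feature_ids[i])
            continue
        seen_rows.add(key)
        keep.append(i)
    if not keep:
        raise ValidationError("all features were dropped as degenerate")
    filtered = AbundanceTable(
        table.values[keep],
        [table.feature_ids[i] for i in keep],
        list(table.sample_ids),
    )
    return filtered, dropped


def _class_split(
    table: AbundanceTable, groups: SampleGroups
) -> tuple[np.ndarray, np.ndarray]:
    ref, other = groups.class_levels
    x = table.values.T  # samples x features
    x0 = x[groups.class_mask(ref)]
    x1 = x[groups.class_mask(other)]
    return x0, x1


def fit_two_class_lda(table: AbundanceTable, groups: SampleGroups) -> LDAFit:
    """Direct two-class LDA on the full data.

    ``w`` solves ``S_w w = mu1 - mu0`` with pooled within-class scatter
    ``S_w`` (sum of the two class scatter matrices). The returned
    coefficients are unit-normalized; ``delta_ld`` is the absolute
    difference of the class-mean discriminant scores under those unit
    coefficients, which is invariant to the scatter normalization.
    """
    x0, x1 = _class_split(table, groups)
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise ValidationError("two-class LDA requires at least 2 samples per class")
    mu0 = x0.mean(axis=0)
    mu1 = x1.mean(axis=0)
    c0 = x0 - mu0
    c1 = x1 - mu1
    sw = c0.T @ c0 + c1.T @ c1

    evals, evecs = np.linalg.eigh(sw)
    tol = float(evals.max()) * SCATTER_RTOL if evals.size else 0.0
    if evals.size == 0 or evals.min() <= tol:
        null_vecs = evecs[:, evals <= tol]
        loading = np.abs(null_vecs).max(axis=1) if null_vecs.size else np.zeros(len(evals))
        offenders = [
            table.feature_ids[i] for i in np.argsort(loading)[::-1] if loading[i] > 0.1
        ]
        raise SingularScatterError(
            "within-class scatter is numerically singular; candidate collinear "
            f"features: {offenders[:10]}",
            offenders,
        )
    diff = mu1 - mu0
    w = evecs @ ((evecs.T @ diff) / evals)
    nrm = float(np.linalg.norm(w))
    if nrm == 0.0:
        raise ValidationError("class means are identical; discriminant direction undefined")
    w_unit = w / nrm
    delta_ld = float(abs(w_unit @ diff))
    return LDAFit(
        w_unit=w_unit,
        delta_ld=delta_ld,
        class_feature_means=np.vstack([mu0, mu1]),
        feature_ids=list(table.feature_ids),
        class_levels=groups.class_levels,
    )


def fit_from_direction(
    w: np.ndarray,
    class_feature_means: np.ndarray,
    feature_ids: Sequence[str],
    class_levels: tuple[str, str],
) -> LDAFit:
    """Build an :class:`LDAFit` from an externally supplied direction.

    Used to substitute bootstrap-averaged coefficients for the direct fit
    in comparison experiments; the direction is unit-normalized here and
    ``delta_ld`` recomputed against the supplied class means.
    """
    w = np.asarray(w, dtype=float)
    nrm = float(np.linalg.norm(w))
    if nrm == 0.0:
        raise ValidationError("zero direction vector")
    w_unit = w / nrm
    means = np.asarray(class_feature_means, dtype=float)
    delta_ld = float(abs(w_unit @ (means[1] - means[0])))
    return LDAFit(
        w_unit=w_unit,
        delta_ld=delta_ld,
        class_feature_means=means,
        feature_ids=list(feature_ids),
        class_levels=class_levels,
    )


def compute_effect_sizes(fit: LDAFit, mode: str = "projection") -> list[EffectRecord]:
    """Per-feature signed raw effect sizes from a discriminant fit.

    ``projection`` (default): |raw_i| = delta_ld * |w_unit_i|.
    ``averaged`` (compatibility variant): |raw_i| is the mean of the
    feature's absolute class-mean difference and its discriminant
    contribution. In both modes the sign is that of the non-reference minus
    reference class mean, so positive scores mark enrichment in the
    non-reference class.
    """
    if mode not in ("projection", "averaged"):
        raise ValidationError(f"unknown effect mode {mode!r}")
    diff = fit.class_feature_means[1] - fit.class_feature_means[0]
    contribution = fit.delta_ld * np.abs(fit.w_unit)
    if mode == "projection":
        magnitude = contribution
    else:
        magnitude = (np.abs(diff) + contribution) / 2.0
    raw = np.sign(diff) * magnitude
    return [EffectRecord(fid, float(r)) for fid, r in zip(fit.feature_ids, raw)]


def score_and_threshold(
    effects: Iterable[EffectRecord], lda_threshold: float = 2.0
) -> MarkerResult:
    """Log-transform raw effects and keep |score| >= threshold.

    Records with a raw effect of exactly zero are excluded before the
    transform. Ordering is descending score with feature-id ties broken
    lexicographically, so output order is deterministic.
    """
    if lda_threshold < 0:
        raise ValidationError("lda_threshold must be >= 0")
    records = []
    for eff in effects:
        score = eff.score
        if score is None:
            continue
        if abs(score) >= lda_threshold:
            records.append(MarkerRecord(eff.feature_id, score))
    records.sort(key=lambda r: (-r.score, r.feature_id))
    return MarkerResult(records)


def find_markers(
    table: AbundanceTable,
    groups: SampleGroups,
    config: Optional[PipelineConfig] = None,
) -> MarkerResult:
    """Run the full discovery pipeline.

    Composition: per-sample rescale -> degenerate-feature filter ->
    Kruskal–Wallis class screen -> (if subclasses present) strict
    sign-consistent rank-sum subclass screen -> direct LDA restricted to the
    surviving features -> effect sizes -> score transform and threshold.

    The pipeline is fully deterministic — it draws no random numbers — and
    invariant to a global rescaling of the input abundances. Zero surviving
    features yield an empty result, not an error.
    """
    config = config if config is not None else PipelineConfig()
    table, groups = validate_inputs(table, groups)
    scaled = normalize_per_million(table, config.scale_constant)
    filtered, _dropped = filter_degenerate(scaled)

    screen = kruskal_wallis_screen(
        filtered, groups, config.kruskal_threshold, config.adjust_method
    )
    retained = [r.feature_id for r in screen if r.retained]
    if not retained:
        return MarkerResult([])

    survivors, _records = wilcoxon_subclass_screen(
        filtered, groups, retained, config.wilcox_threshold, config.adjust_method
    )
    if not survivors:
        return MarkerResult([])

    fit = fit_two_class_lda(filtered.select_features(survivors), groups)
    effects = compute_effect_sizes(fit, config.effect_mode)
    return score_and_threshold(effects, config.lda_threshold)


@dataclass
class BootstrapLDA:
    """Bootstrap-averaged discriminant coefficients next to the direct fit.

    Provided only for comparison experiments: the main pipeline never uses
    it. ``coefficients`` holds one sign-aligned unit coefficient vector per
    replicate; ``mean_coefficients`` is their elementwise mean.
    """

    direct: LDAFit
    coefficients: np.ndarray  # (n_boot, n_features)
    mean_coefficients: np.ndarray
    n_boot: int
    fraction: float


def bootstrap_lda_reference(
    table: AbundanceTable,
    groups: SampleGroups,
    n_boot: int = 30,
    fraction: float = 2.0 / 3.0,
    seed: Optional[int] = None,
    max_retries: int = 100,
) -> BootstrapLDA:
    """Subsample-averaged LDA coefficients (the legacy estimation scheme).

    Each replicate fits LDA on a random ``fraction`` of the samples drawn
    without replacement (re-drawn, up to ``max_retries`` times, until both
    classes keep at least 2 samples and the subsample scatter is regular).
    Replicate coefficients are sign-aligned to the direct full-data fit
    before averaging. Randomness comes only from the explicit ``seed``;
    global RNG state is never touched.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    direct = fit_two_class_lda(table, groups)
    n = table.n_samples
    k = n if fraction == 1.0 else max(4, int(np.floor(fraction * n)))
    k = min(k, n)
    ref, other = groups.class_levels
    class_arr = np.array(groups.class_labels)

    coeffs = np.empty((n_boot, table.n_features))
    for b in range(n_boot):
        fit = None
        for _ in range(max_retries):
            idx = np.sort(rng.choice(n, size=k, replace=False))
            sub_classes = class_arr[idx]
            if (sub_classes == ref).sum() < 2 or (sub_classes == other).sum() < 2:
                continue
            sub_ids = [table.sample_ids[j] for j in idx]
            try:
                fit = fit_two_class_lda(
                    table.select_samples(sub_ids), groups.reorder(sub_ids)
                )
            except SingularScatterError:
                continue
            break
        if fit is None:
            raise ValidationError(
                f"bootstrap replicate {b}: no valid subsample within "
                f"{max_retries} retries"
            )
        w = fit.w_unit
        if float(w @ direct.w_unit) < 0:
            w = -w
        coeffs[b] = w

    return BootstrapLDA(
        direct=direct,
        coefficients=coeffs,
        mean_coefficients=coeffs.mean(axis=0),
        n_boot=n_boot,
        fraction=fraction,
    )
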