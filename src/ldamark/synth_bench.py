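"""Synthetic compositional data with known ground truth, plus the
stability and ranking-evaluation experiments.

The generator draws log-normal latent abundances, multiplies spiked
features by a fold change in their designated class, injects structural
zeros (sparing spiked features so ground truth stays well-defined), and
closes each sample to proportions. Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AbundanceTable,
    PipelineConfig,
    SampleGroups,
    ValidationError,
)
from .lda_effect import (
    bootstrap_lda_reference,
    compute_effect_sizes,
    fit_from_direction,
    fit_two_class_lda,
    filter_degenerate,
    normalize_per_million,
    score_and_threshold,
)
from .stat_screen import kruskal_wallis_screen, wilcoxon_subclass_screen

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "enrichment_difference",
    "StabilityResult",
    "stability_experiment",
    "read_config",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic compositional generator.

    ``fold_change`` multiplies each spiked feature in its enriched class.
    Spike directions alternate: even-numbered spiked features are enriched
    in the second (non-reference) class and therefore carry positive truth
    direction (+1, matching a positive pipeline score); odd-numbered ones
    are enriched in the reference class (-1). ``subclass_count`` strata per
    class are created by even splitting with a small multiplicative shift
    shared across classes, so the sign-consistency screen is exercised
    without breaking it for spiked features.
    """

    n_features: int = 100
    n_samples_per_class: tuple[int, int] = (30, 30)
    n_spiked: int = 5
    fold_change: float = 4.0
    subclass_count: int = 0
    sparsity: float = 0.0
    log_mean: float = 0.0
    log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if self.n_spiked > self.n_features:
            raise ValidationError("n_spiked cannot exceed n_features")
        if self.fold_change < 1.0:
            raise ValidationError("fold_change must be >= 1")
        if not (0.0 <= self.sparsity < 1.0):
            raise ValidationError("sparsity must be in [0, 1)")
        if min(self.n_samples_per_class) < 2:
            raise ValidationError("need at least 2 samples per class")
        if self.subclass_count < 0:
            raise ValidationError("subclass_count must be >= 0")
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be positive")


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[AbundanceTable, SampleGroups, dict[str, int]]:
    """Generate a compositional table, labels, and the spike ground truth.

    Returns ``(table, groups, truth)`` where ``truth`` maps each spiked
    feature id to +1 (enriched in the non-reference class ``B``; expected
    positive score) or -1 (enriched in the reference class ``A``).
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_samples_per_class
    n = n0 + n1
    nf = spec.n_features

    latent = rng.lognormal(spec.log_mean, spec.log_sd, size=(nf, n))
    class_labels = ["A"] * n0 + ["B"] * n1
    mask_b = np.array([c == "B" for c in class_labels])

    feature_ids = [f"feat_{i:04d}" for i in range(nf)]
    truth: dict[str, int] = {}
    for i in range(spec.n_spiked):
        direction = 1 if i % 2 == 0 else -1
        truth[feature_ids[i]] = direction
        target = mask_b if direction > 0 else ~mask_b
        latent[i, target] *= spec.fold_change

    subclass_labels: Optional[list[str]] = None
    if spec.subclass_count > 0:
        subclass_labels = []
        for start, count in ((0, n0), (n0, n1)):
            subclass_labels.extend(
                f"sub{(j % spec.subclass_count) + 1}" for j in range(count)
            )
        # small multiplicative shift common to both classes, on a random
        # fifth of the features, so strata differ without flipping signs
        shifted = rng.random(nf) < 0.2
        sub_arr = np.array(subclass_labels)
        for stratum in dict.fromkeys(subclass_labels):
            factor = float(np.exp(rng.normal(0.0, 0.3)))
            cols = sub_arr == stratum
            latent[np.ix_(shifted, cols)] *= factor

    if spec.sparsity > 0:
        zero_mask = rng.random((nf, n)) < spec.sparsity
        zero_mask[: spec.n_spiked, :] = False  # spiked features are protected
        latent[zero_mask] = 0.0
        dead = latent.sum(axis=0) <= 0
        if np.any(dead):  # keep every sample column positive
            latent[nf - 1, dead] = 1.0

    values = latent / latent.sum(axis=0)
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    table = AbundanceTable(values, feature_ids, sample_ids)
    groups = SampleGroups(
        sample_ids=sample_ids,
        class_labels=class_labels,
        subclass_labels=subclass_labels,
        reference_level="A",
    )
    return table, groups, truth


def enrichment_difference(
    ranked_features: Sequence[str],
    truth_positive_set: set[str],
    truth_negative_set: set[str],
    cutoffs: Sequence[int],
) -> dict[int, int]:
    """Putative-TP minus putative-FP counts among the top-k features.

    At each cutoff k the difference is the number of truth-positives minus
    the number of truth-negatives in the top k of the ranked list; features
    in neither truth set are ignored for the counts but still occupy rank
    positions. Cutoffs beyond the list length are errors.
    """
    overlap = truth_positive_set & truth_negative_set
    if overlap:
        raise ValidationError(f"truth sets overlap: {sorted(overlap)[:5]}")
    out: dict[int, int] = {}
    for k in cutoffs:
        if k < 0 or k > len(ranked_features):
            raise ValidationError(
                f"cutoff {k} out of range for a list of {len(ranked_features)}"
            )
        top = ranked_features[:k]
        tp = sum(1 for f in top if f in truth_positive_set)
        fp = sum(1 for f in top if f in truth_negative_set)
        out[k] = tp - fp
    return out


@dataclass
class StabilityResult:
    """Selected-feature sets per (repeat, bootstrap-count) run plus summaries."""

    boot_grid: list[int]
    n_repeats: int
    direct_selected: tuple[str, ...]
    direct_selections: list[tuple[str, ...]]  # one per repeat (control runs)
    selections: dict[tuple[int, int], tuple[str, ...]]  # (repeat, n_boot) -> features
    coefficient_variance: dict[int, float]  # n_boot -> mean across-repeat variance
    feature_ids: list[str]

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for sel in self.selections.values():
            out.update(sel)
        return out

    @property
    def intersection(self) -> set[str]:
        sels = list(self.selections.values())
        out = set(sels[0])
        for sel in sels[1:]:
            out &= set(sel)
        return out

    def jaccard(self, a: tuple[str, ...], b: tuple[str, ...]) -> float:
        sa, sb = set(a), set(b)
        if not sa and not sb:
            return 1.0
        return len(sa & sb) / len(sa | sb)

    def mean_pairwise_jaccard(self, mode: str = "bootstrap") -> float:
        sels = (
            list(self.selections.values())
            if mode == "bootstrap"
            else list(self.direct_selections)
        )
        if len(sels) < 2:
            return 1.0
        vals = [
            self.jaccard(sels[i], sels[j])
            for i in range(len(sels))
            for j in range(i + 1, len(sels))
        ]
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "repeat": r,
                "n_boot": b,
                "n_selected": len(sel),
                "features": ",".join(sel),
            }
            for (r, b), sel in sorted(self.selections.items())
        ]
        return pd.DataFrame(rows, columns=["repeat", "n_boot", "n_selected", "features"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _select_with_direction(w, fit, config) -> tuple[str, ...]:
    sub_fit = fit_from_direction(
        w, fit.class_feature_means, fit.feature_ids, fit.class_levels
    )
    result = score_and_threshold(
        compute_effect_sizes(sub_fit, config.effect_mode), config.lda_threshold
    )
    return tuple(result.features)


def stability_experiment(
    table: AbundanceTable,
    groups: SampleGroups,
    config: Optional[PipelineConfig] = None,
    boot_grid: Optional[Sequence[int]] = None,
    n_repeats: int = 20,
    fraction: float = 2.0 / 3.0,
    seed: Optional[int] = None,
) -> StabilityResult:
    """Run-to-run stability of selection under bootstrap-averaged coefficients.

    For every repeat and every bootstrap-count grid point the pipeline is
    re-run with the direct discriminant direction replaced by the
    sign-aligned bootstrap mean; the deterministic direct fit is recomputed
    per repeat as a control. Screens are deterministic and shared by all
    runs. Reports selected sets, union/intersection, pairwise Jaccard
    overlaps, and per-grid-point across-repeat coefficient variance.
    """
    config = config if config is not None else PipelineConfig()
    grid = list(boot_grid) if boot_grid is not None else list(range(5, 101, 5))
    if not grid or min(grid) < 1:
        raise ValidationError("boot_grid must contain positive iteration counts")

    scaled = normalize_per_million(table, config.scale_constant)
    filtered, _ = filter_degenerate(scaled)
    screen = kruskal_wallis_screen(
        filtered, groups, config.kruskal_threshold, config.adjust_method
    )
    retained = [r.feature_id for r in screen if r.retained]
    survivors, _ = wilcoxon_subclass_screen(
        filtered, groups, retained, config.wilcox_threshold, config.adjust_method
    )
    if not survivors:
        raise ValidationError("no features survive the screens; nothing to perturb")
    sub_table = filtered.select_features(survivors)

    direct_selections: list[tuple[str, ...]] = []
    selections: dict[tuple[int, int], tuple[str, ...]] = {}
    mean_coeffs: dict[int, list[np.ndarray]] = {b: [] for b in grid}

    children = np.random.SeedSequence(seed).spawn(n_repeats)
    for r in range(n_repeats):
        run_seeds = children[r].generate_state(len(grid))
        direct_fit = fit_two_class_lda(sub_table, groups)
        direct_selections.append(
            _select_with_direction(direct_fit.w_unit, direct_fit, config)
        )
        for b, run_seed in zip(grid, run_seeds):
            boot = bootstrap_lda_reference(
                sub_table, groups, n_boot=b, fraction=fraction, seed=int(run_seed)
            )
            mean_coeffs[b].append(boot.mean_coefficients)
            selections[(r, b)] = _select_with_direction(
                boot.mean_coefficients, boot.direct, config
            )

    coefficient_variance = {
        b: float(np.mean(np.var(np.vstack(ws), axis=0))) for b, ws in mean_coeffs.items()
    }
    return StabilityResult(
        boot_grid=grid,
        n_repeats=n_repeats,
        direct_selected=direct_selections[0],
        direct_selections=direct_selections,
        selections=selections,
        coefficient_variance=coefficient_variance,
        feature_ids=list(sub_table.feature_ids),
    )


def read_config(path) -> dict[str, object]:
    """Read a plain ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; values are coerced to int
    or float when possible, otherwise kept as strings.
    """
    out: dict[str, object] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            value: object = raw
            for cast in (int, float):
                try:
                    value = cast(raw)
                    break
                except ValueError:
                    continue
            out[key] = value
    return out
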