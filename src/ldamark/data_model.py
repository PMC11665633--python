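"""Core domain types, validation, and pipeline configuration.

All downstream modules operate on the in-memory types defined here:

* :class:`AbundanceTable` — nonnegative feature-by-sample matrix with ids.
* :class:`SampleGroups` — per-sample two-level class labels plus optional
  subclass labels; the *reference* level is the one mapped to negative scores.
* :class:`PipelineConfig` — thresholds and options of the discovery pipeline.
* Result records (:class:`ScreenResult`, :class:`ComparisonRecord`,
  :class:`LDAFit`, :class:`MarkerResult`) and the :class:`LineageTree` used
  for cladogram rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ADJUST_METHODS",
    "ValidationError",
    "AbundanceTable",
    "SampleGroups",
    "PipelineConfig",
    "ScreenResult",
    "ComparisonRecord",
    "LDAFit",
    "EffectRecord",
    "MarkerRecord",
    "MarkerResult",
    "LineageNode",
    "LineageTree",
    "validate_inputs",
]

#: p-value adjustment methods accepted by the pipeline; ``fdr`` is an alias
#: for Benjamini–Hochberg.
ADJUST_METHODS = ("none", "holm", "hochberg", "hommel", "bonferroni", "BH", "BY", "fdr")


class ValidationError(ValueError):
    """An input violates a structural invariant of the domain types."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {kind} id: {dup!r}")


@dataclass
class AbundanceTable:
    """Feature-by-sample matrix of nonnegative (relative) abundances.

    Parameters
    ----------
    values
        ``(n_features, n_samples)`` array; unitless relative abundances or
        scaled counts. Must be finite and nonnegative.
    feature_ids
        Unique feature identifiers (rows); may be pipe-delimited lineages.
    sample_ids
        Unique sample identifiers (columns).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError(
                f"abundance values must be 2-dimensional, got shape {self.values.shape}"
            )
        nf, ns = self.values.shape
        if nf != len(self.feature_ids):
            raise ValidationError(
                f"{nf} rows but {len(self.feature_ids)} feature ids"
            )
        if ns != len(self.sample_ids):
            raise ValidationError(
                f"{ns} columns but {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("abundance values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            f, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance for feature {self.feature_ids[f]!r} "
                f"in sample {self.sample_ids[s]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index(feature_id)]

    def select_features(self, feature_ids: Iterable[str]) -> "AbundanceTable":
        """Subset (and reorder) rows by feature id."""
        ids = list(feature_ids)
        idx = [self.feature_index(f) for f in ids]
        return AbundanceTable(self.values[idx], ids, list(self.sample_ids))

    def select_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        """Subset (and reorder) columns by sample id."""
        ids = list(sample_ids)
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [lookup[s] for s in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id: {exc.args[0]!r}") from None
        return AbundanceTable(self.values[:, idx], list(self.feature_ids), ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class SampleGroups:
    """Per-sample class (two ordered levels) and optional subclass labels.

    ``reference_level`` is the class mapped to *negative* scores; by default
    it is the first class level in order of first appearance, which keeps the
    sign convention deterministic without locale-dependent sorting.
    """

    sample_ids: list[str]
    class_labels: list[str]
    subclass_labels: Optional[list[str]] = None
    reference_level: Optional[str] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        _check_unique(self.sample_ids, "sample")
        if len(self.class_labels) != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.class_labels)} class labels for {len(self.sample_ids)} samples"
            )
        levels = list(dict.fromkeys(self.class_labels))  # first-appearance order
        if len(levels) != 2:
            raise ValidationError(
                f"exactly two classes required, found {len(levels)}: {levels}"
            )
        if self.reference_level is None:
            self.reference_level = levels[0]
        elif self.reference_level not in levels:
            raise ValidationError(
                f"reference level {self.reference_level!r} not among class levels {levels}"
            )
        if self.subclass_labels is not None:
            self.subclass_labels = [str(s) for s in self.subclass_labels]
            if len(self.subclass_labels) != len(self.sample_ids):
                raise ValidationError(
                    f"{len(self.subclass_labels)} subclass labels for "
                    f"{len(self.sample_ids)} samples"
                )
            if any(s == "" for s in self.subclass_labels):
                raise ValidationError("empty subclass label; missing subclasses are an error")

    @property
    def has_subclass(self) -> bool:
        return self.subclass_labels is not None

    @property
    def class_levels(self) -> tuple[str, str]:
        """``(reference, non-reference)`` level pair."""
        levels = list(dict.fromkeys(self.class_labels))
        other = levels[1] if levels[0] == self.reference_level else levels[0]
        return (self.reference_level, other)  # type: ignore[return-value]

    @property
    def nonreference_level(self) -> str:
        return self.class_levels[1]

    def class_mask(self, level: str) -> np.ndarray:
        return np.array([c == level for c in self.class_labels], dtype=bool)

    def reorder(self, sample_ids: Sequence[str]) -> "SampleGroups":
        """Return labels aligned to ``sample_ids``; unknown ids are an error."""
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [lookup[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(
                f"sample {exc.args[0]!r} has no class label"
            ) from None
        return SampleGroups(
            sample_ids=[self.sample_ids[j] for j in idx],
            class_labels=[self.class_labels[j] for j in idx],
            subclass_labels=(
                [self.subclass_labels[j] for j in idx] if self.subclass_labels else None
            ),
            reference_level=self.reference_level,
        )


@dataclass
class PipelineConfig:
    """Thresholds and options controlling the discovery pipeline.

    Defaults follow the conventional settings: alpha 0.05 for both rank-test
    screens, minimum absolute score 2.0, no multiplicity adjustment, and a
    per-sample scale of one million (so a score of 2.0 corresponds to an
    absolute raw effect of 100 in scaled relative-abundance units).
    """

    kruskal_threshold: float = 0.05
    wilcox_threshold: float = 0.05
    lda_threshold: float = 2.0
    adjust_method: str = "none"
    effect_mode: str = "projection"
    scale_constant: float = 1e6

    def __post_init__(self) -> None:
        for name in ("kruskal_threshold", "wilcox_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.lda_threshold < 0:
            raise ValidationError(f"lda_threshold must be >= 0, got {self.lda_threshold}")
        if self.adjust_method not in ADJUST_METHODS:
            raise ValidationError(
                f"unknown adjust_method {self.adjust_method!r}; "
                f"expected one of {ADJUST_METHODS}"
            )
        if self.effect_mode not in ("projection", "averaged"):
            raise ValidationError(
                f"effect_mode must be 'projection' or 'averaged', got {self.effect_mode!r}"
            )
        if self.scale_constant <= 0:
            raise ValidationError("scale_constant must be positive")


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature outcome of the class-level rank test."""

    feature_id: str
    p_value: float
    p_adjusted: float
    retained: bool


@dataclass(frozen=True)
class ComparisonRecord:
    """One cross-class stratum comparison of the subclass screen.

    ``z_score`` is the standardized rank-sum of the reference-class stratum:
    negative z means the feature is higher in the non-reference stratum.
    """

    feature_id: str
    stratum_pair: tuple[str, str]
    z_score: float
    p_value: float


@dataclass
class LDAFit:
    """Two-class discriminant fit on the full data.

    Attributes
    ----------
    w_unit
        Unit-normalized discriminant coefficients (one per feature).
    delta_ld
        Absolute difference of the class means of the discriminant scores.
    class_feature_means
        ``(2, n_features)``: row 0 is the reference class, row 1 the other.
    feature_ids, class_levels
        Identifiers for the coefficient axis and the mean rows.
    """

    w_unit: np.ndarray
    delta_ld: float
    class_feature_means: np.ndarray
    feature_ids: list[str]
    class_levels: tuple[str, str]

    def __post_init__(self) -> None:
        self.w_unit = np.asarray(self.w_unit, dtype=float)
        self.class_feature_means = np.asarray(self.class_feature_means, dtype=float)
        nrm = float(np.linalg.norm(self.w_unit))
        if abs(nrm - 1.0) > 1e-10:
            raise ValidationError(f"discriminant coefficients not unit-normalized (norm {nrm})")
        if self.delta_ld < 0:
            raise ValidationError("delta_ld must be nonnegative")
        if self.class_feature_means.shape != (2, self.w_unit.size):
            raise ValidationError("class_feature_means must be 2 x n_features")


@dataclass(frozen=True)
class EffectRecord:
    """Signed raw effect size of one feature, in scaled-abundance units."""

    feature_id: str
    raw_effect: float

    @property
    def score(self) -> Optional[float]:
        """sign(raw) * log10(|raw|); undefined (None) for a zero raw effect."""
        if self.raw_effect == 0.0:
            return None
        return float(np.sign(self.raw_effect) * np.log10(abs(self.raw_effect)))


@dataclass(frozen=True)
class MarkerRecord:
    feature_id: str
    score: float


@dataclass
class MarkerResult:
    """Ordered ``(feature, score)`` records surviving all filters."""

    records: list[MarkerRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MarkerRecord]:
        return iter(self.records)

    @property
    def features(self) -> list[str]:
        return [r.feature_id for r in self.records]

    @property
    def scores(self) -> list[float]:
        return [r.score for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"features": self.features, "scores": self.scores})


class LineageNode:
    """Node of a rooted taxon tree; children keyed by rank-prefixed name."""

    __slots__ = ("name", "parent", "children", "score", "enriched_class")

    def __init__(self, name: str, parent: Optional["LineageNode"] = None):
        self.name = name
        self.parent = parent
        self.children: dict[str, LineageNode] = {}
        self.score: Optional[float] = None
        self.enriched_class: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def path(self) -> tuple[str, ...]:
        parts: list[str] = []
        node = self
        while node.parent is not None:
            parts.append(node.name)
            node = node.parent
        return tuple(reversed(parts))

    def leaf_count(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.leaf_count() for c in self.children.values())


class LineageTree:
    """Rooted tree built from root-to-leaf lineage paths.

    Shared prefixes share nodes, so the structure is a proper tree rather
    than a forest of duplicated paths.
    """

    def __init__(self) -> None:
        self.root = LineageNode("<root>")

    @classmethod
    def from_paths(cls, paths: Iterable[Sequence[str]]) -> "LineageTree":
        tree = cls()
        for path in paths:
            tree.add_path(path)
        return tree

    @classmethod
    def from_lineages(
        cls, lineages: Iterable[str], separator: str = "|"
    ) -> "LineageTree":
        from .io_formats import parse_lineage  # deferred: io_formats imports us

        return cls.from_paths(parse_lineage(l, separator) for l in lineages)

    def add_path(self, path: Sequence[str]) -> LineageNode:
        if not path:
            raise ValidationError("empty lineage path")
        node = self.root
        for name in path:
            if name not in node.children:
                node.children[name] = LineageNode(name, parent=node)
            node = node.children[name]
        return node

    def find(self, path: Sequence[str]) -> Optional[LineageNode]:
        node = self.root
        for name in path:
            if name not in node.children:
                return None
            node = node.children[name]
        return node

    def iter_nodes(self, include_root: bool = False) -> Iterator[LineageNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node is not self.root or include_root:
                yield node
            stack.extend(reversed(list(node.children.values())))

    def annotate(
        self, path: Sequence[str], score: float, enriched_class: Optional[str] = None
    ) -> LineageNode:
        node = self.find(path)
        if node is None:
            node = self.add_path(path)
        node.score = score
        node.enriched_class = enriched_class
        return node


def validate_inputs(
    table: AbundanceTable, groups: SampleGroups
) -> tuple[AbundanceTable, SampleGroups]:
    """Validate a table/labels pair and align the labels to the table.

    Idempotent: validating an already-validated pair returns an equal pair.
    Samples present in ``groups`` but absent from ``table`` are dropped;
    table samples without labels raise :class:`ValidationError`.
    """
    aligned = groups.reorder(table.sample_ids)
    col_sums = table.values.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = table.sample_ids[int(np.argmin(col_sums))]
        raise ValidationError(f"sample {bad!r} has non-positive total abundance")
    for level in aligned.class_levels:
        if int(aligned.class_mask(level).sum()) < 1:
            raise ValidationError(f"class {level!r} has no samples")
    return table, aligned
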