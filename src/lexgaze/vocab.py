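"""Checklist vocabularies and category-level structure.

A child's productive vocabulary is recorded on a CDI-style parental
checklist.  Category-level semantic density is a within-child, rank-based
classification: the proportion of each of the six experimental categories
that the child produces is ranked, the top three categories are that child's
High-density categories and the bottom three the Low-density ones, with ties
straddling the 3/4 boundary all going High.  Vocabulary groups are a median
split of total productive vocabulary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: The six experimental semantic categories with their checklist item counts.
EXPERIMENTAL_CATEGORIES = {
    "ANIMALS": 43,
    "CLOTHING": 28,
    "VEHICLES": 14,
    "BODY-PARTS": 27,
    "FRUIT": 7,
    "DRINKS": 7,
}


@dataclass(frozen=True)
class ChecklistDefinition:
    """Maps checklist word ids to category labels.

    The checklist may contain filler categories beyond the six experimental
    ones; every item belongs to exactly one category.
    """

    items: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in EXPERIMENTAL_CATEGORIES if c not in set(self.items.values())]
        if missing:
            raise ValueError(f"checklist missing experimental categories: {missing}")

    def category_size(self, category: str) -> int:
        return sum(1 for c in self.items.values() if c == category)

    def category_items(self, category: str) -> set[str]:
        return {w for w, c in self.items.items() if c == category}

    @property
    def words(self) -> set[str]:
        return set(self.items)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChecklistDefinition":
        """Build from a table with columns ``word_id`` and ``category``."""
        dup = df["word_id"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate word ids: {sorted(df.loc[dup, 'word_id'])}")
        return cls(items=dict(zip(df["word_id"], df["category"])))

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "ChecklistDefinition":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"word_id": list(self.items), "category": list(self.items.values())}
        )


@dataclass(frozen=True)
class ChildVocabulary:
    """One child's reported produced words against a checklist."""

    child_id: str
    produced: frozenset[str]
    total_produced: int = -1  # -1 means |produced|

    def __post_init__(self) -> None:
        if self.total_produced < 0:
            object.__setattr__(self, "total_produced", len(self.produced))
        if self.total_produced < len(self.produced) and self.total_produced >= 0:
            # total may exceed |produced| if the full checklist is longer than
            # the portion we track, but never be smaller
            raise ValueError(
                f"{self.child_id}: total_produced {self.total_produced} "
                f"< |produced| {len(self.produced)}"
            )

    def validate_against(self, checklist: ChecklistDefinition) -> None:
        unknown = self.produced - checklist.words
        if unknown:
            raise ValueError(
                f"{self.child_id}: words not on checklist: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class DensityAssignment:
    """Per-child High/Low semantic-density condition for each category."""

    child_id: str
    condition: dict[str, str]  # category -> "High" | "Low"
    proportion: dict[str, float]

    def __post_init__(self) -> None:
        highs = sum(1 for v in self.condition.values() if v == "High")
        if not 3 <= highs <= 6:
            raise ValueError(f"{self.child_id}: {highs} High categories")


@dataclass(frozen=True)
class VocabGroupAssignment:
    """Median-split vocabulary group for each child."""

    group: dict[str, str]  # child_id -> "High" | "Low"
    split_value: float


def category_proportions(
    child: ChildVocabulary,
    checklist: ChecklistDefinition,
    mode: str = "per-category-size",
) -> dict[str, float]:
    """Proportion of each experimental category the child produces.

    Parameters
    ----------
    mode
        ``"per-category-size"`` divides the number of produced words in a
        category by that category's checklist size (the default);
        ``"per-total-produced"`` divides by the child's total productive
        vocabulary (0 if the child produces nothing).
    """
    if mode not in ("per-category-size", "per-total-produced"):
        raise ValueError(f"unknown mode {mode!r}")
    child.validate_against(checklist)
    out: dict[str, float] = {}
    for cat in EXPERIMENTAL_CATEGORIES:
        in_cat = sum(1 for w in child.produced if checklist.items[w] == cat)
        if mode == "per-category-size":
            out[cat] = in_cat / checklist.category_size(cat)
        else:
            out[cat] = in_cat / child.total_produced if child.total_produced else 0.0
    return out


def assign_density(child_id: str, proportions: dict[str, float]) -> DensityAssignment:
    """Rank the six category proportions and split High/Low.

    The top three ranks are High and the bottom three Low; if the rank-3 and
    rank-4 proportions tie, every category at that value goes High, so High
    may hold more than three categories.  Equivalently: a category is High
    iff its proportion is at least the third-highest value.
    """
    if len(proportions) != 6:
        raise ValueError(f"expected 6 categories, got {len(proportions)}")
    # stable order by category name, then by value, for deterministic ranking
    ordered = sorted(sorted(proportions), key=lambda c: -proportions[c])
    third = proportions[ordered[2]]
    condition = {c: ("High" if proportions[c] >= third else "Low") for c in proportions}
    n_high = sum(1 for v in condition.values() if v == "High")
    if n_high == 6:
        warnings.warn(
            f"{child_id}: all six category proportions tied at "
            f"{third:.4g}; all assigned High",
            stacklevel=2,
        )
    return DensityAssignment(
        child_id=child_id, condition=condition, proportion=dict(proportions)
    )


def split_vocab_groups(
    children: list[ChildVocabulary], ties_high: bool = True
) -> VocabGroupAssignment:
    """Median split of total productive vocabulary into High/Low groups.

    Children at or above the sample median are High by default
    (``ties_high=True``); with ``ties_high=False`` only strictly-above-median
    children are High.
    """
    if len(children) < 2:
        raise ValueError("need at least 2 children for a median split")
    totals = pd.Series(
        {c.child_id: c.total_produced for c in children}, dtype=float
    )
    med = float(totals.median())
    if ties_high:
        high = totals >= med
    else:
        high = totals > med
    if high.all():
        warnings.warn("all children in the High vocabulary group", stacklevel=2)
    return VocabGroupAssignment(
        group={cid: ("High" if h else "Low") for cid, h in high.items()},
        split_value=med,
    )


def read_vocabulary_reports(path, checklist: ChecklistDefinition, sep: str = ","):
    """Read per-child produced-word reports.

    Accepts long format (columns ``child_id``, ``word_id``) or a wide 0/1
    matrix with ``child_id`` as the first column and word ids as the
    remaining column names.
    """
    df = pd.read_csv(path, sep=sep)
    if set(df.columns) >= {"child_id", "word_id"}:
        grouped = df.groupby("child_id")["word_id"].apply(set)
    else:
        wide = df.set_index("child_id")
        grouped = wide.apply(lambda row: set(wide.columns[row.astype(bool)]), axis=1)
    children = [
        ChildVocabulary(child_id=str(cid), produced=frozenset(words))
        for cid, words in grouped.items()
    ]
    for c in children:
        c.validate_against(checklist)
    return children


def density_table(assignments: list[DensityAssignment]) -> pd.DataFrame:
    """Long table: child_id, category, proportion, condition."""
    rows = [
        {
            "child_id": a.child_id,
            "category": cat,
            "proportion": a.proportion[cat],
            "condition": a.condition[cat],
        }
        for a in assignments
        for cat in a.condition
    ]
    return pd.DataFrame(rows)


def group_table(groups: VocabGroupAssignment, children: list[ChildVocabulary]) -> pd.DataFrame:
    totals = {c.child_id: c.total_produced for c in children}
    return pd.DataFrame(
        {
            "child_id": list(groups.group),
            "total_produced": [totals[c] for c in groups.group],
            "group": list(groups.group.values()),
        }
    )
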