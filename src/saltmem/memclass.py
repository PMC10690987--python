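"""Classification of stress-memory genes from two successive-stress contrasts.

A gene is a stress-memory gene (SMG) when it is differentially expressed in
BOTH the first-stress contrast (3 h of the first event vs its untreated
baseline) and the second-stress contrast (3 h of the second event vs 3 h of
the first).  The sign pattern over the two contrasts gives four classes:

=====  ==========  ===========
class  contrast 1  contrast 2
=====  ==========  ===========
PP     up          up
MM     down        down
PM     up          down
MP     down        up
=====  ==========  ===========

Genes significant in only one contrast (or neither) are NON_MEMORY.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .decore import ContrastResult


class MemoryClass(str, enum.Enum):
    PP = "PP"   # [+/+]
    MM = "MM"   # [-/-]
    PM = "PM"   # [+/-]
    MP = "MP"   # [-/+]
    NON_MEMORY = "NON_MEMORY"


MEMORY_CLASSES = (MemoryClass.PP, MemoryClass.MM, MemoryClass.PM, MemoryClass.MP)

_PATTERN = {
    ("UP", "UP"): MemoryClass.PP,
    ("DOWN", "DOWN"): MemoryClass.MM,
    ("UP", "DOWN"): MemoryClass.PM,
    ("DOWN", "UP"): MemoryClass.MP,
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed percentages conventionally are."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class MemoryCatalog:
    """Per-gene memory class plus per-class counts and SMG proportions."""

    classes: pd.Series                       # gene -> class label (str)
    table: pd.DataFrame = field(repr=False)  # gene, class, log2fc1, padj1, log2fc2, padj2

    @property
    def counts(self) -> dict[str, int]:
        return {c.value: int((self.classes == c.value).sum()) for c in MEMORY_CLASSES}

    @property
    def smg_total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        total = self.smg_total
        if total == 0:
            return {}
        return {c: round_half_up(100.0 * n / total, 1) for c, n in self.counts.items()}

    def smg_genes(self) -> set:
        return set(self.classes.index[self.classes != MemoryClass.NON_MEMORY.value])

    def genes_of(self, cls: MemoryClass | str) -> set:
        label = cls.value if isinstance(cls, MemoryClass) else cls
        return set(self.classes.index[self.classes == label])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def classify_memory(contrast1: ContrastResult, contrast2: ContrastResult) -> MemoryCatalog:
    """Assign one memory class per gene from the two defining contrasts.

    Raises if the two contrasts do not cover the same gene universe.
    """
    g1, g2 = set(contrast1.genes), set(contrast2.genes)
    if g1 != g2:
        diff = sorted(g1 ^ g2)
        raise ValueError(f"contrast gene universes differ; symmetric difference: {diff[:10]}")

    t1 = contrast1.table
    t2 = contrast2.table.reindex(t1.index)
    labels = [
        _PATTERN.get((s1, s2), MemoryClass.NON_MEMORY).value
        for s1, s2 in zip(t1["status"], t2["status"])
    ]
    classes = pd.Series(labels, index=t1.index, name="class")
    table = pd.DataFrame(
        {
            "class": classes,
            "log2fc1": t1["log2fc"],
            "padj1": t1["padj"],
            "log2fc2": t2["log2fc"],
            "padj2": t2["padj"],
        },
        index=t1.index,
    )
    return MemoryCatalog(classes=classes, table=table)


def summarize_classes(catalog: MemoryCatalog) -> pd.DataFrame:
    """Per-class count and percent-of-SMGs table (empty if no SMGs)."""
    total = catalog.smg_total
    if total == 0:
        return pd.DataFrame(columns=["class", "count", "percent"])
    rows = [
        {"class": c, "count": n, "percent": round_half_up(100.0 * n / total, 1)}
        for c, n in catalog.counts.items()
    ]
    return pd.DataFrame(rows)


def deg_reduction(n_first: int, n_second: int) -> float:
    """Percent decrease in DEG count from a first-event to a second-event
    contrast, one decimal."""
    if n_first <= 0:
        raise ValueError("n_first must be positive")
    return round_half_up(100.0 * (n_first - n_second) / n_first, 1)
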