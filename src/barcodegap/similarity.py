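"""Incidence-based faunal similarity between regional checklists.

Two classical indices over species (or genus) sets A and B:

* Czekanowski–Sørensen  S = 2|A∩B| / (|A| + |B|)
* Jaccard               J = |A∩B| / |A∪B|

linked by the identity J = S / (2 − S).  Values are kept as full-precision
fractions internally; percentages for reporting are rounded half-up (the
convention of the printed tables this tool reproduces), so 0.077064 prints
as 7.71%.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxa import Checklist, genera_of

__all__ = [
    "UndefinedSimilarityError",
    "sorensen",
    "jaccard",
    "jaccard_from_sorensen",
    "percent",
    "SimilarityMatrix",
    "pairwise_matrix",
    "pairwise_table",
]


class UndefinedSimilarityError(ValueError):
    """Similarity of two empty sets is 0/0 and has no faunistic meaning."""


def sorensen(a: Iterable, b: Iterable) -> float:
    """Czekanowski–Sørensen index 2|A∩B|/(|A|+|B|) as a fraction in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise UndefinedSimilarityError("Sørensen index of two empty sets is undefined")
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |A∩B|/|A∪B| as a fraction in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise UndefinedSimilarityError("Jaccard index of two empty sets is undefined")
    return len(sa & sb) / len(sa | sb)


def jaccard_from_sorensen(s: float) -> float:
    """Convert a Sørensen fraction to the Jaccard fraction via J = S/(2−S)."""
    if not 0 <= s <= 1:
        raise ValueError(f"Sørensen fraction out of [0, 1]: {s}")
    return s / (2 - s)


def percent(fraction: float, decimals: int = 2) -> float:
    """Express a fraction as a percentage rounded half-up to ``decimals``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


_INDEX_FUNCS = {"jaccard": jaccard, "sorensen": sorensen}


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with unit diagonal.

    ``values`` holds full-precision fractions; :meth:`to_percent_frame`
    renders the half-up-rounded percentages used in reports.
    """

    labels: Sequence[str]
    level: str  # "species" | "genus"
    index: str  # "jaccard" | "sorensen"
    values: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = list(self.labels).index(pair[0])
        j = list(self.labels).index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_percent_frame(self, decimals: int = 2) -> pd.DataFrame:
        return self.to_frame().map(lambda v: percent(v, decimals))


def _level_sets(
    checklists: Sequence[Checklist],
    level: str,
    unions: Mapping[str, Sequence[str]] | None,
) -> dict[str, set[str]]:
    if level not in {"species", "genus"}:
        raise ValueError(f"unknown level: {level!r}")
    sets: dict[str, set[str]] = {}
    for c in checklists:
        if c.region_label in sets:
            raise ValueError(f"duplicate checklist label: {c.region_label!r}")
        sets[c.region_label] = c.keys if level == "species" else genera_of(c)
    for label, members in (unions or {}).items():
        if label in sets:
            raise ValueError(f"union label collides with a checklist label: {label!r}")
        merged: set[str] = set()
        for m in members:
            if m not in sets:
                raise ValueError(f"union {label!r} references unknown checklist {m!r}")
            merged |= sets[m]
        sets[label] = merged
    return sets


def pairwise_matrix(
    checklists: Sequence[Checklist],
    level: str = "species",
    index: str = "sorensen",
    unions: Mapping[str, Sequence[str]] | None = None,
) -> SimilarityMatrix:
    """All-pairs similarity among checklists (plus optional union faunas).

    ``unions`` maps a new label to member checklist labels whose taxa are
    pooled before indexing — the continent-versus-continent comparison is a
    union of member regions against another region.
    """
    if len(checklists) < 2 and not unions:
        raise ValueError("need at least two checklists")
    func = _INDEX_FUNCS.get(index)
    if func is None:
        raise ValueError(f"unknown index: {index!r}")
    sets = _level_sets(checklists, level, unions)
    labels = list(sets)
    n = len(labels)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = func(sets[labels[i]], sets[labels[j]])
    return SimilarityMatrix(labels=labels, level=level, index=index, values=values)


def pairwise_table(
    checklists: Sequence[Checklist],
    level: str = "species",
    unions: Mapping[str, Sequence[str]] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Long-form report: one row per pair, Jaccard % and Sørensen % columns."""
    sets = _level_sets(checklists, level, unions)
    labels = list(sets)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "level": level,
                    "jaccard_pct": percent(jaccard(sets[a], sets[b]), decimals),
                    "sorensen_pct": percent(sorensen(sets[a], sets[b]), decimals),
                }
            )
    return pd.DataFrame(rows)
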