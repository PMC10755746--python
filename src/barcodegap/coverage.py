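"""Geographic attribution and checklist coverage statistics.

Given a deduplicated corpus and a regional checklist, this module counts,
for every species of the fauna, how many unique barcodes exist at all and
how many originate from specimens collected inside the region, then
summarizes the fauna-level picture: how many species have at least one
barcode, how many are deeply covered (more than ``k`` barcodes), and what
share of the barcoded species could actually be sequenced from local
material.  Species with barcodes that are absent from the checklist are
reported separately as extralimital taxa, never inside coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Pattern

import pandas as pd
import yaml

from .harmonize import MergedCorpus
from .records_io import BarcodeRecord
from .similarity import percent
from .taxa import Checklist, SynonymTable

__all__ = [
    "RegionScheme",
    "RegionSchemeError",
    "default_scheme",
    "assign_region",
    "count_per_species",
    "extralimital_taxa",
    "summarize",
    "CoverageReport",
    "top_barcoded",
]


class RegionSchemeError(ValueError):
    """Raised when a region definition is ambiguous or malformed."""


@dataclass
class RegionScheme:
    """Mapping from collection country (plus admin-unit overrides) to region.

    ``regions`` maps a region label to its set of bare countries; a bare
    country may belong to at most one region.  ``overrides`` are
    ``(country, compiled admin-unit pattern, region label)`` triples checked
    before the bare-country mapping, which is how sub-country regions (West
    Siberia within Russia, Alaska within the United States) are expressed.
    """

    regions: dict[str, set[str]]
    overrides: list[tuple[str, Pattern[str], str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, countries in self.regions.items():
            for c in countries:
                if c in seen and seen[c] != label:
                    raise RegionSchemeError(
                        f"country {c!r} assigned to both {seen[c]!r} and {label!r}"
                    )
                seen[c] = label
        for country, _, label in self.overrides:
            if label not in self.regions:
                raise RegionSchemeError(f"override region {label!r} not defined")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionScheme":
        with Path(path).open(encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RegionScheme":
        regions = {
            label: set(body.get("countries") or [])
            for label, body in (doc.get("regions") or {}).items()
        }
        overrides = [
            (
                o["country"],
                re.compile(o["admin_pattern"], re.IGNORECASE),
                o["region"],
            )
            for o in doc.get("overrides") or []
        ]
        return cls(regions=regions, overrides=overrides)


def default_scheme() -> RegionScheme:
    """The shipped three-region scheme (West Siberia / Fennoscandia / Canada and Alaska)."""
    ref = resources.files("barcodegap").joinpath("data/regions.yaml")
    with resources.as_file(ref) as path:
        return RegionScheme.from_yaml(path)


def assign_region(record: BarcodeRecord, scheme: RegionScheme) -> str | None:
    """Region label for a record's collection locality, or None.

    Overrides (country + admin-unit pattern) win over the bare-country map;
    records with no country resolve to None.
    """
    if not record.country:
        return None
    for country, pattern, label in scheme.overrides:
        if record.country == country and record.admin_unit and pattern.search(record.admin_unit):
            return label
    for label, countries in scheme.regions.items():
        if record.country in countries:
            return label
    return None


def _resolved_key(record: BarcodeRecord, synonyms: SynonymTable) -> str | None:
    if record.taxon is None:
        return None
    return synonyms.resolve_key(record.taxon.canonical_key)


def count_per_species(
    corpus: MergedCorpus,
    checklist: Checklist,
    scheme: RegionScheme,
    region_label: str,
    synonyms: SynonymTable | None = None,
) -> pd.DataFrame:
    """Per-species barcode tallies for one regional checklist.

    One row per checklist species (zero-count species included), columns
    ``canonical_key``, ``total_barcodes``, ``within_region_barcodes``.
    Records identified under a junior synonym count toward the valid name.
    Only unique (deduplicated) records are counted.
    """
    table = synonyms or SynonymTable()
    totals: dict[str, int] = {k: 0 for k in checklist.taxa}
    within: dict[str, int] = {k: 0 for k in checklist.taxa}
    for mr in corpus.unique_records:
        key = _resolved_key(mr.record, table)
        if key is None or key not in totals:
            continue
        totals[key] += 1
        if assign_region(mr.record, scheme) == region_label:
            within[key] += 1
    rows = [
        {
            "canonical_key": k,
            "total_barcodes": totals[k],
            "within_region_barcodes": within[k],
        }
        for k in sorted(totals)
    ]
    return pd.DataFrame(rows, columns=["canonical_key", "total_barcodes", "within_region_barcodes"])


def extralimital_taxa(
    corpus: MergedCorpus,
    checklist: Checklist,
    synonyms: SynonymTable | None = None,
) -> pd.DataFrame:
    """Barcoded species NOT on the checklist — an appendix, outside coverage."""
    table = synonyms or SynonymTable()
    counts: dict[str, int] = {}
    for mr in corpus.unique_records:
        key = _resolved_key(mr.record, table)
        if key is None or key in checklist.taxa:
            continue
        counts[key] = counts.get(key, 0) + 1
    rows = [{"canonical_key": k, "total_barcodes": counts[k]} for k in sorted(counts)]
    return pd.DataFrame(rows, columns=["canonical_key", "total_barcodes"])


@dataclass
class CoverageReport:
    """Fauna-level coverage summary; percentages recompute from the integers."""

    region_label: str
    fauna_size: int
    k: int
    n_with_ge_1: int
    n_with_gt_k: int
    n_with_within_region_ge_1: int
    decimals: int = 0

    @property
    def pct_ge_1_of_fauna(self) -> float:
        return percent(self.n_with_ge_1 / self.fauna_size, self.decimals) if self.fauna_size else 0.0

    @property
    def pct_gt_k_of_fauna(self) -> float:
        return percent(self.n_with_gt_k / self.fauna_size, self.decimals) if self.fauna_size else 0.0

    @property
    def pct_within_of_fauna(self) -> float:
        return (
            percent(self.n_with_within_region_ge_1 / self.fauna_size, self.decimals)
            if self.fauna_size
            else 0.0
        )

    @property
    def pct_within_of_barcoded(self) -> float:
        return (
            percent(self.n_with_within_region_ge_1 / self.n_with_ge_1, self.decimals)
            if self.n_with_ge_1
            else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "region": self.region_label,
            "fauna_size": self.fauna_size,
            "k": self.k,
            "n_with_ge_1": self.n_with_ge_1,
            "n_with_gt_k": self.n_with_gt_k,
            "n_with_within_region_ge_1": self.n_with_within_region_ge_1,
            "pct_ge_1_of_fauna": self.pct_ge_1_of_fauna,
            "pct_gt_k_of_fauna": self.pct_gt_k_of_fauna,
            "pct_within_of_fauna": self.pct_within_of_fauna,
            "pct_within_of_barcoded": self.pct_within_of_barcoded,
        }


def summarize(
    rows: pd.DataFrame,
    fauna_size: int,
    k: int = 10,
    region_label: str = "",
    decimals: int = 0,
) -> CoverageReport:
    """Tally a per-species table into a :class:`CoverageReport`.

    Deep coverage is strict: a species counts toward the ``k`` threshold
    only with MORE than ``k`` barcodes.  Percentages round half-up to
    ``decimals`` places (whole numbers by default, bar-chart style).
    """
    if fauna_size < len(rows):
        raise ValueError(f"fauna_size {fauna_size} < number of species rows {len(rows)}")
    totals = rows["total_barcodes"]
    within = rows["within_region_barcodes"] if "within_region_barcodes" in rows else None
    report = CoverageReport(
        region_label=region_label,
        fauna_size=fauna_size,
        k=k,
        n_with_ge_1=int((totals >= 1).sum()),
        n_with_gt_k=int((totals > k).sum()),
        n_with_within_region_ge_1=int((within >= 1).sum()) if within is not None else 0,
        decimals=decimals,
    )
    assert 0 <= report.n_with_within_region_ge_1 <= report.n_with_ge_1 <= fauna_size
    return report


def top_barcoded(rows: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` most-barcoded species: totals descending, ties alphabetical."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = rows.sort_values(
        ["total_barcodes", "canonical_key"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ordered.head(n)
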