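"""Restrict corpora to the COI-5P barcode fragment and collapse cross-deposits.

The same physical barcode often exists as a record in both BOLD and GenBank,
linked by mutual ID references (a GenBank ``db_xref`` naming the BOLD
process ID, or a BOLD row citing the GenBank accession).  Such pairs must be
counted once.  Before deduplication the corpora are restricted to the 5'
barcode fragment of COI: the 3' fragment (amplified with the Jerry/Pat
primer pair, mainly for phylogenetics) has almost no overlap with the
barcode region, and records with no gene-region information at all cannot be
assumed to cover it.  Filtering runs first so that a duplicate of a removed
record cannot resurrect it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records_io import BarcodeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BOLD_ONLY",
    "GENBANK_ONLY",
    "BOTH",
    "COI5P_COMPATIBLE_MARKERS",
    "MergedRecord",
    "MergedCorpus",
    "filter_barcode_region",
    "match_duplicates",
    "merge",
    "dedupe_corpora",
]

BOLD_ONLY = "BOLD_ONLY"
GENBANK_ONLY = "GENBANK_ONLY"
BOTH = "BOTH"

# Marker codes taken as naming the COI gene without contrary evidence of the
# 3' fragment; GenBank rarely states the exact region, so a bare COI/COX1
# code counts as barcode-compatible and the primer rule catches 3' products.
COI5P_COMPATIBLE_MARKERS = {"COI-5P", "COX1", "CO1", "COI"}

_COI3P_RE = re.compile(r"^\s*COI[-_ ]?3P\s*$", re.IGNORECASE)
# Jerry (C1-J-2183, often misprinted Cl-J-2183) and Pat (TL2-N-3014).
_3P_PRIMER_RE = re.compile(r"\bpat\b|TL2[-_ ]?N[-_ ]?3014|\bjerry\b|C[1l][-_ ]?J[-_ ]?2183", re.IGNORECASE)
# Evidence that an unlabelled record nevertheless covers the 5' fragment
# (Folmer or Lep barcode primers).
_5P_EVIDENCE_RE = re.compile(r"LCO[-_ ]?1490|HCO[-_ ]?2198|LepF|LepR|COI[-_ ]?5P|barcode", re.IGNORECASE)


def filter_barcode_region(
    records: Iterable[BarcodeRecord],
) -> tuple[list[BarcodeRecord], dict[str, int]]:
    """Keep COI-5P-compatible records; log removals per rule.

    Rules, applied in order per record:

    1. marker code explicitly COI-3P -> ``coi3p_removed``;
    2. primer notes naming the Jerry/Pat 3' pair -> ``primer_removed``;
    3. no marker and no recognizable COI-5P evidence (or a marker naming a
       different region) -> ``no_region_removed``.
    """
    kept: list[BarcodeRecord] = []
    log = {"coi3p_removed": 0, "primer_removed": 0, "no_region_removed": 0}
    for rec in records:
        marker = rec.marker.strip().upper()
        if _COI3P_RE.match(rec.marker):
            log["coi3p_removed"] += 1
            continue
        if rec.primer_notes and _3P_PRIMER_RE.search(rec.primer_notes):
            log["primer_removed"] += 1
            continue
        if marker in COI5P_COMPATIBLE_MARKERS:
            kept.append(rec)
            continue
        if not marker and _5P_EVIDENCE_RE.search(rec.primer_notes or ""):
            kept.append(rec)
            continue
        log["no_region_removed"] += 1
    return kept, log


def _accession_stem(identifier: str) -> str:
    return identifier.split(".", 1)[0]


def match_duplicates(
    bold: Sequence[BarcodeRecord], genbank: Sequence[BarcodeRecord]
) -> list[tuple[str, str]]:
    """Pair cross-deposited records by their mutual ID references.

    Rule (a): a GenBank record whose cross-references contain a BOLD process
    ID present in the corpus.  Rule (b): a BOLD record citing a GenBank
    accession (matched on the stem before the version dot).  Matching is
    greedy — rule (a) first, then (b), both in input order — and each record
    joins at most one pair; extra candidate matches are logged, first wins.
    """
    bold_by_id = {r.primary_id: r for r in bold}
    gb_by_stem = {_accession_stem(r.primary_id): r for r in genbank}
    pairs: list[tuple[str, str]] = []
    matched_bold: set[str] = set()
    matched_gb: set[str] = set()

    for gb in genbank:
        if gb.primary_id in matched_gb:
            continue
        for xref in sorted(gb.xref_ids):
            if xref in bold_by_id:
                if xref in matched_bold:
                    logger.warning(
                        "BOLD record %s already paired; extra match from %s ignored",
                        xref,
                        gb.primary_id,
                    )
                    continue
                pairs.append((xref, gb.primary_id))
                matched_bold.add(xref)
                matched_gb.add(gb.primary_id)
                break
    for br in bold:
        if br.primary_id in matched_bold:
            continue
        for xref in sorted(br.xref_ids):
            stem = _accession_stem(xref)
            gb = gb_by_stem.get(stem)
            if gb is None:
                continue
            if gb.primary_id in matched_gb:
                logger.warning(
                    "GenBank record %s already paired; extra match from %s ignored",
                    gb.primary_id,
                    br.primary_id,
                )
                continue
            pairs.append((br.primary_id, gb.primary_id))
            matched_bold.add(br.primary_id)
            matched_gb.add(gb.primary_id)
            break
    return pairs


@dataclass
class MergedRecord:
    """A unique barcode with its library provenance flag."""

    record: BarcodeRecord
    provenance: str  # BOLD_ONLY | GENBANK_ONLY | BOTH


@dataclass
class MergedCorpus:
    """Deduplicated corpus: |unique| = |bold kept| + |genbank kept| − |pairs|."""

    unique_records: list[MergedRecord]
    match_pairs: list[tuple[str, str]]
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.unique_records)

    def records(self) -> list[BarcodeRecord]:
        return [m.record for m in self.unique_records]


def merge(
    bold: Sequence[BarcodeRecord],
    genbank: Sequence[BarcodeRecord],
    pairs: Sequence[tuple[str, str]],
) -> MergedCorpus:
    """Collapse matched pairs into single records.

    A pair yields ONE record flagged ``BOTH``, taking its fields from the
    BOLD copy (BOLD taxonomy is curated more actively) and retaining the
    GenBank ID among the cross-references.  Taxonomic disagreements inside a
    pair are logged; downstream synonym resolution reconciles true synonyms.
    """
    bold_by_id = {r.primary_id: r for r in bold}
    gb_by_id = {r.primary_id: r for r in genbank}
    paired_bold: set[str] = set()
    paired_gb: set[str] = set()
    merged: list[MergedRecord] = []
    for bid, gid in pairs:
        if bid not in bold_by_id or gid not in gb_by_id:
            raise ValueError(f"pair ({bid!r}, {gid!r}) references an unknown record")
        if bid in paired_bold or gid in paired_gb:
            raise ValueError(f"record appears in two pairs: ({bid!r}, {gid!r})")
        paired_bold.add(bid)
        paired_gb.add(gid)
    for br in bold:
        if br.primary_id in paired_bold:
            continue
        merged.append(MergedRecord(br, BOLD_ONLY))
    for gb in genbank:
        if gb.primary_id in paired_gb:
            continue
        merged.append(MergedRecord(gb, GENBANK_ONLY))
    for bid, gid in pairs:
        br, gb = bold_by_id[bid], gb_by_id[gid]
        if br.taxon and gb.taxon and br.taxon.canonical_key != gb.taxon.canonical_key:
            logger.warning(
                "pair (%s, %s): identifications differ (%s vs %s); keeping BOLD's",
                bid,
                gid,
                br.taxon.canonical_key,
                gb.taxon.canonical_key,
            )
        rec = BarcodeRecord(
            source=br.source,
            primary_id=br.primary_id,
            taxon=br.taxon,
            xref_ids=set(br.xref_ids) | {gb.primary_id},
            marker=br.marker,
            primer_notes=br.primer_notes,
            country=br.country,
            admin_unit=br.admin_unit,
            sequence=br.sequence,
        )
        merged.append(MergedRecord(rec, BOTH))
    assert len(merged) == len(bold) + len(genbank) - len(pairs)
    return MergedCorpus(unique_records=merged, match_pairs=list(pairs))


def dedupe_corpora(
    bold: Sequence[BarcodeRecord], genbank: Sequence[BarcodeRecord]
) -> MergedCorpus:
    """Full pipeline: filter both corpora to COI-5P, then match and merge."""
    bold_kept, bold_log = filter_barcode_region(bold)
    gb_kept, gb_log = filter_barcode_region(genbank)
    pairs = match_duplicates(bold_kept, gb_kept)
    corpus = merge(bold_kept, gb_kept, pairs)
    corpus.filter_log = {k: bold_log[k] + gb_log[k] for k in bold_log}
    corpus.filter_log["pairs_matched"] = len(pairs)
    return corpus
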