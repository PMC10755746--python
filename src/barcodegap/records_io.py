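"""Readers and writers for barcode-record corpora.

Two source formats are supported offline:

* BOLD-style combined specimen+sequence TSV dumps (one row per record,
  header names vary between export vintages — a built-in alias map accepts
  the common dialects);
* GenBank flat files (``.gb``), parsed with Biopython; the record identity
  is the ``VERSION`` token (accession.version), the collection country comes
  from the source feature (both the historical ``country`` qualifier and its
  successor ``geo_loc_name`` are accepted), and BOLD process IDs cited in
  ``db_xref`` become cross-references.

Every statistic downstream is metadata-driven; sequences are carried along
but never interpreted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .taxa import MalformedNameError, TaxonName, parse_binomial

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeRecord",
    "BoldFormatError",
    "read_bold_tsv",
    "read_genbank_flatfile",
    "write_counts_csv",
]


class BoldFormatError(ValueError):
    """Raised when a BOLD TSV lacks mandatory columns."""


@dataclass
class BarcodeRecord:
    """One barcode record from either library.

    ``primary_id`` is the BOLD process ID (e.g. ``UAMIC2628-15``) or the
    GenBank accession.version.  ``xref_ids`` holds IDs pointing at the other
    library.  ``taxon`` is the name as identified by the source (None when
    unparseable).  ``admin_unit`` keeps sub-country locality text (the part
    after the colon in GenBank country qualifiers, or the BOLD
    province/state column) for region-scheme overrides.
    """

    source: str  # "BOLD" | "GENBANK"
    primary_id: str
    taxon: TaxonName | None = None
    xref_ids: set[str] = field(default_factory=set)
    marker: str = ""
    primer_notes: str = ""
    country: str = ""
    admin_unit: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.source not in {"BOLD", "GENBANK"}:
            raise ValueError(f"unknown source: {self.source!r}")
        if not self.primary_id:
            raise ValueError("primary_id must be non-empty")


# Header dialects shipped by BOLD over the years, canonical name -> aliases.
_BOLD_ALIASES: dict[str, tuple[str, ...]] = {
    "processid": ("processid", "process_id", "process id", "sampleid_process"),
    "species_name": ("species_name", "species", "identification_species", "identification"),
    "markercode": ("markercode", "marker_code", "marker_codes", "marker"),
    "country": ("country", "country/ocean", "country_ocean"),
    "province_state": ("province_state", "province/state", "province"),
    "genbank_accession": ("genbank_accession", "accession", "insdc_acc", "genbank accession"),
    "nucleotides": ("nucleotides", "nuc", "sequence"),
    "seq_primers": ("seq_primers", "primers", "primer_notes", "sequencing_primers"),
}

_MANDATORY_BOLD = ("processid", "species_name")


def _map_bold_header(fieldnames: Sequence[str]) -> dict[str, str]:
    lowered = {f.lower().strip(): f for f in fieldnames}
    mapping: dict[str, str] = {}
    for canonical, aliases in _BOLD_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canonical] = lowered[alias]
                break
    missing = [c for c in _MANDATORY_BOLD if c not in mapping]
    if missing:
        raise BoldFormatError(f"BOLD TSV missing mandatory columns: {missing}")
    return mapping


def _split_country(text: str) -> tuple[str, str]:
    """Split ``"Canada: Yukon"`` into country and admin-unit detail."""
    if ":" in text:
        country, admin = text.split(":", 1)
        return country.strip(), admin.strip()
    return text.strip(), ""


def read_bold_tsv(path: str | Path) -> list[BarcodeRecord]:
    """Read a BOLD combined TSV dump; one :class:`BarcodeRecord` per row.

    Missing optional cells become empty fields.  A populated
    ``genbank_accession`` cell is recorded as a cross-reference.  Rows whose
    species name cannot be parsed keep ``taxon=None`` (they still count as
    records but match no checklist species).
    """
    path = Path(path)
    records: list[BarcodeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise BoldFormatError(f"{path}: empty file")
        colmap = _map_bold_header(reader.fieldnames)

        def cell(row: dict, canonical: str) -> str:
            col = colmap.get(canonical)
            return (row.get(col) or "").strip() if col else ""

        for row in reader:
            pid = cell(row, "processid")
            if not pid:
                continue
            raw_name = cell(row, "species_name")
            try:
                taxon: TaxonName | None = parse_binomial(raw_name) if raw_name else None
            except MalformedNameError:
                logger.warning("%s: unparseable species name %r (record %s)", path, raw_name, pid)
                taxon = None
            xrefs: set[str] = set()
            acc = cell(row, "genbank_accession")
            if acc:
                xrefs.add(acc)
            records.append(
                BarcodeRecord(
                    source="BOLD",
                    primary_id=pid,
                    taxon=taxon,
                    xref_ids=xrefs,
                    marker=cell(row, "markercode"),
                    primer_notes=cell(row, "seq_primers"),
                    country=cell(row, "country"),
                    admin_unit=cell(row, "province_state"),
                    sequence=cell(row, "nucleotides"),
                )
            )
    ids = [r.primary_id for r in records]
    if len(ids) != len(set(ids)):
        raise BoldFormatError(f"{path}: duplicate process IDs within one dump")
    return records


# Qualifier text that identifies the COI gene at all, and the 5' barcode
# fragment specifically.
_COI_HINTS = ("cox1", "coxi", "coi", "co1", "cytochrome c oxidase subunit i", "cytochrome oxidase subunit i", "cytochrome oxidase subunit 1")


def _infer_marker(seqrec) -> tuple[str, str]:
    """Infer (marker, primer_notes) from gene/product/note qualifiers."""
    marker = ""
    notes: list[str] = []
    for feat in seqrec.features:
        for q in ("gene", "product", "note", "standard_name"):
            for val in feat.qualifiers.get(q, []):
                low = val.lower()
                if "coi-5p" in low or "coi 5p" in low or "barcode" in low:
                    marker = "COI-5P"
                elif "coi-3p" in low or "coi 3p" in low:
                    if marker != "COI-5P":
                        marker = "COI-3P"
                elif any(h in low for h in _COI_HINTS) and not marker:
                    marker = "COI"
        for q in ("PCR_primers", "primer_bind", "note"):
            for val in feat.qualifiers.get(q, []):
                if "primer" in val.lower() or q == "PCR_primers":
                    notes.append(val)
    return marker, "; ".join(dict.fromkeys(notes))


def read_genbank_flatfile(path: str | Path) -> list[BarcodeRecord]:
    """Read GenBank flat-file records from a ``.gb`` file or a directory.

    ``primary_id`` is the accession.version; records without a version are
    skipped with a logged warning.  The source feature's country-style
    qualifier (``country`` or ``geo_loc_name``) is split at the first colon
    into country and admin-unit detail.  ``db_xref`` values of the form
    ``BOLD:<process id>`` populate the cross-references.
    """
    path = Path(path)
    files: list[Path]
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".gb", ".gbk", ".genbank"}
        )
    else:
        files = [path]
    records: list[BarcodeRecord] = []
    n_skipped = 0
    for fp in files:
        for seqrec in SeqIO.parse(str(fp), "genbank"):
            version = seqrec.annotations.get("sequence_version")
            if not version or "." not in seqrec.id:
                n_skipped += 1
                logger.warning("%s: record %r has no VERSION; skipped", fp, seqrec.name)
                continue
            organism = seqrec.annotations.get("organism", "")
            country = admin = ""
            xrefs: set[str] = set()
            for feat in seqrec.features:
                if feat.type == "source":
                    for q in ("geo_loc_name", "country"):
                        vals = feat.qualifiers.get(q, [])
                        if vals:
                            country, admin = _split_country(vals[0])
                            break
                for val in feat.qualifiers.get("db_xref", []):
                    if val.upper().startswith("BOLD:"):
                        xrefs.add(val.split(":", 1)[1])
            marker, primer_notes = _infer_marker(seqrec)
            try:
                taxon: TaxonName | None = parse_binomial(organism) if organism else None
            except MalformedNameError:
                logger.warning("%s: unparseable organism %r (%s)", fp, organism, seqrec.id)
                taxon = None
            records.append(
                BarcodeRecord(
                    source="GENBANK",
                    primary_id=seqrec.id,
                    taxon=taxon,
                    xref_ids=xrefs,
                    marker=marker,
                    primer_notes=primer_notes,
                    country=country,
                    admin_unit=admin,
                    sequence=str(seqrec.seq) if seqrec.seq is not None else "",
                )
            )
    if n_skipped:
        logger.info("skipped %d GenBank record(s) without VERSION", n_skipped)
    return records


def write_counts_csv(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-species count rows deterministically.

    Column order is fixed (``canonical_key`` first, remaining columns in
    first-seen order) and rows are sorted by species key, so shuffled input
    produces a byte-identical file.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if "canonical_key" not in df.columns:
        raise ValueError("rows must carry a 'canonical_key' column")
    cols = ["canonical_key"] + [c for c in df.columns if c != "canonical_key"]
    df = df[cols].sort_values("canonical_key", kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\n")
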