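"""BOLD TSV and GenBank flat-file parsing, and deterministic CSV reports."""

import textwrap

import pandas as pd
import pytest

from barcodegap.records_io import (
    BarcodeRecord,
    BoldFormatError,
    read_bold_tsv,
    read_genbank_flatfile,
    write_counts_csv,
)

BOLD_HEADER = "processid\tspecies_name\tmarkercode\tseq_primers\tcountry\tprovince_state\tgenbank_accession\tnucleotides\n"


def write_bold(tmp_path, body, header=BOLD_HEADER):
    p = tmp_path / "bold.tsv"
    p.write_text(header + body)
    return p


def test_read_bold_row(tmp_path):
    p = write_bold(
        tmp_path,
        "UAMIC2628-15\tAtheta allocera\tCOI-5P\tLepF1/LepR1\tCanada\tYukon\tKX123456\tACGT\n",
    )
    (rec,) = read_bold_tsv(p)
    assert rec.source == "BOLD"
    assert rec.primary_id == "UAMIC2628-15"
    assert rec.taxon.canonical_key == "Atheta allocera"
    assert rec.marker == "COI-5P"
    assert rec.country == "Canada"
    assert rec.admin_unit == "Yukon"
    assert rec.xref_ids == {"KX123456"}
    assert rec.sequence == "ACGT"


def test_read_bold_header_only(tmp_path):
    assert read_bold_tsv(write_bold(tmp_path, "")) == []


def test_read_bold_header_aliases(tmp_path):
    p = write_bold(
        tmp_path,
        "X1-20\tQuedius fuliginosus\tCOI-5P\tFinland\n",
        header="process_id\tspecies\tmarker_code\tcountry/ocean\n",
    )
    (rec,) = read_bold_tsv(p)
    assert rec.primary_id == "X1-20"
    assert rec.country == "Finland"


def test_read_bold_missing_mandatory_columns(tmp_path):
    p = write_bold(tmp_path, "", header="markercode\tcountry\n")
    with pytest.raises(BoldFormatError, match="processid"):
        read_bold_tsv(p)


def test_read_bold_missing_optional_cells_and_unparseable_names(tmp_path):
    p = write_bold(
        tmp_path,
        "A1-20\tAtheta sp.\t\t\t\t\t\t\nB2-20\tAtheta allocera\tCOI-5P\t\t\t\t\t\n",
    )
    recs = read_bold_tsv(p)
    assert len(recs) == 2
    assert recs[0].taxon is None and recs[0].marker == ""
    assert recs[1].taxon is not None


def test_read_bold_duplicate_ids_rejected(tmp_path):
    p = write_bold(tmp_path, "A1-20\tAtheta allocera\n" * 2, header="processid\tspecies_name\n")
    with pytest.raises(BoldFormatError, match="duplicate"):
        read_bold_tsv(p)


GB_RECORD = textwrap.dedent("""\
    LOCUS       XX000001                  60 bp    DNA     linear   INV 01-JAN-2023
    DEFINITION  Atheta campbelli cytochrome c oxidase subunit I, partial cds.
    ACCESSION   XX000001
    VERSION     XX000001.1
    KEYWORDS    .
    SOURCE      mitochondrion Atheta campbelli
      ORGANISM  Atheta campbelli
                Eukaryota; Arthropoda; Insecta.
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="Atheta campbelli"
                         /country="Canada: Yukon"
                         /db_xref="BOLD:UAMIC2628-15"
         gene            1..60
                         /gene="COX1"
    ORIGIN
            1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
    //
    """)

GB_NEW_QUALIFIER = textwrap.dedent("""\
    LOCUS       XX000002                  60 bp    DNA     linear   INV 01-JAN-2023
    DEFINITION  Quedius fuliginosus cytochrome c oxidase subunit I, partial cds.
    ACCESSION   XX000002
    VERSION     XX000002.2
    KEYWORDS    .
    SOURCE      mitochondrion Quedius fuliginosus
      ORGANISM  Quedius fuliginosus
                Eukaryota; Arthropoda; Insecta.
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="Quedius fuliginosus"
                         /geo_loc_name="Finland"
         gene            1..60
                         /gene="COX1"
                         /note="COI-5P barcode region"
    ORIGIN
            1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
    //
    """)

GB_NO_VERSION = textwrap.dedent("""\
    LOCUS       XX000003                  60 bp    DNA     linear   INV 01-JAN-2023
    DEFINITION  Stenus clavicornis, no version.
    ACCESSION   XX000003
    KEYWORDS    .
    SOURCE      mitochondrion Stenus clavicornis
      ORGANISM  Stenus clavicornis
                Eukaryota; Arthropoda; Insecta.
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="Stenus clavicornis"
    ORIGIN
            1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
    //
    """)


def test_read_genbank_country_colon_truncation_and_xref(tmp_path):
    p = tmp_path / "a.gb"
    p.write_text(GB_RECORD)
    (rec,) = read_genbank_flatfile(p)
    assert rec.source == "GENBANK"
    assert rec.primary_id == "XX000001.1"
    assert rec.taxon.canonical_key == "Atheta campbelli"
    assert rec.country == "Canada"
    assert rec.admin_unit == "Yukon"
    assert "UAMIC2628-15" in rec.xref_ids
    assert rec.marker == "COI"


def test_read_genbank_new_geo_qualifier_and_5p_note(tmp_path):
    p = tmp_path / "b.gb"
    p.write_text(GB_NEW_QUALIFIER)
    (rec,) = read_genbank_flatfile(p)
    assert rec.primary_id == "XX000002.2"
    assert rec.country == "Finland"
    assert rec.admin_unit == ""
    assert rec.marker == "COI-5P"


def test_read_genbank_record_without_version_is_skipped(tmp_path):
    p = tmp_path / "c.gb"
    p.write_text(GB_RECORD + GB_NO_VERSION)
    recs = read_genbank_flatfile(p)
    assert [r.primary_id for r in recs] == ["XX000001.1"]


def test_read_genbank_directory_and_empty(tmp_path):
    assert read_genbank_flatfile(tmp_path) == []
    (tmp_path / "a.gb").write_text(GB_RECORD)
    (tmp_path / "b.gb").write_text(GB_NEW_QUALIFIER)
    assert len(read_genbank_flatfile(tmp_path)) == 2


def test_write_counts_csv_round_trip_and_sort_stability(tmp_path):
    rows = [
        {"canonical_key": "Quedius fuliginosus", "total_barcodes": 3, "within_region_barcodes": 1},
        {"canonical_key": "Atheta allocera", "total_barcodes": 5, "within_region_barcodes": 2},
    ]
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_counts_csv(rows, p1)
    write_counts_csv(list(reversed(rows)), p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert len(p1.read_text().splitlines()) == 3
    back = pd.read_csv(p1)
    assert back.iloc[0]["canonical_key"] == "Atheta allocera"
    assert set(back["total_barcodes"]) == {3, 5}


def test_barcode_record_validation():
    with pytest.raises(ValueError):
        BarcodeRecord(source="EMBL", primary_id="x")
    with pytest.raises(ValueError):
        BarcodeRecord(source="BOLD", primary_id="")
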