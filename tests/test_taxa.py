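"""Name parsing, synonym resolution and checklist loading."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodegap.taxa import (
    Checklist,
    ChecklistFormatError,
    MalformedNameError,
    SynonymConfigError,
    SynonymTable,
    TaxonName,
    genera_of,
    load_checklist,
    parse_binomial,
    resolve,
    write_checklist_csv,
)

SYNONYMS = SynonymTable(
    {
        "Atheta campbelli": "Atheta allocera",
        "Gnypeta minuta": "Dasygnypeta velata",
        "Oxypoda grandipennis": "Oxypoda sylvia",
        "Lathrobium simplex": "Lathrobium fauveli",
    }
)


@pytest.mark.parametrize(
    "raw, genus, epithet, author",
    [
        ("Atheta allocera Eppelsheim, 1893", "Atheta", "allocera", "Eppelsheim, 1893"),
        ("Atheta campbelli (Lohse, 1990)", "Atheta", "campbelli", "(Lohse, 1990)"),
        ("Lathrobium fauveli Duvivier, 1883", "Lathrobium", "fauveli", "Duvivier, 1883"),
        ("Ontholestes cingulatus", "Ontholestes", "cingulatus", ""),
        ("  Quedius   fuliginosus  ", "Quedius", "fuliginosus", ""),
    ],
)
def test_parse_binomial(raw, genus, epithet, author):
    name = parse_binomial(raw)
    assert (name.genus, name.epithet, name.author_year) == (genus, epithet, author)
    assert name.canonical_key == f"{genus} {epithet}"


def test_parse_round_trip():
    name = parse_binomial("Lathrobium fauveli Duvivier, 1883")
    assert parse_binomial(name.canonical_key).canonical_key == "Lathrobium fauveli"


def test_trinomial_collapses_to_binomial():
    name = parse_binomial("Quedius fuliginosus borealis Gravenhorst, 1802")
    assert name.canonical_key == "Quedius fuliginosus"
    assert name.rank_note == "trinomial"
    assert name.author_year == "Gravenhorst, 1802"


@pytest.mark.parametrize(
    "raw",
    ["", "   ", "Quedius", "Quedius sp.", "Athetacampbelli", "12345 678", "Quedius 17"],
)
def test_malformed_names_rejected(raw):
    with pytest.raises(MalformedNameError):
        parse_binomial(raw)


def test_resolve_paper_synonym_pairs():
    assert resolve(parse_binomial("Atheta campbelli"), SYNONYMS).canonical_key == "Atheta allocera"
    assert resolve(parse_binomial("Gnypeta minuta"), SYNONYMS).canonical_key == "Dasygnypeta velata"


def test_resolve_identity_on_empty_table():
    name = parse_binomial("Ontholestes cingulatus")
    assert resolve(name, SynonymTable()) is name


def test_resolve_chain_and_idempotence():
    table = SynonymTable({"Aus bus": "Aus cus", "Aus cus": "Aus dus"})
    once = resolve(parse_binomial("Aus bus"), table)
    assert once.canonical_key == "Aus dus"
    assert resolve(once, table).canonical_key == once.canonical_key


def test_synonym_cycle_rejected():
    with pytest.raises(SynonymConfigError):
        SynonymTable({"Aus bus": "Aus cus", "Aus cus": "Aus bus"})


def test_synonym_table_from_csv(tmp_path):
    p = tmp_path / "syn.csv"
    p.write_text("junior,valid\nAtheta campbelli,Atheta allocera\n")
    table = SynonymTable.from_csv(p)
    assert table.resolve_key("Atheta campbelli") == "Atheta allocera"
    assert table.resolve_key("Atheta allocera") == "Atheta allocera"


def _write(tmp_path, rows, header="species"):
    p = tmp_path / "list.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


def test_load_checklist_collapses_synonym_duplicates(tmp_path, caplog):
    p = _write(
        tmp_path,
        ["Atheta campbelli (Lohse, 1990)", "Atheta allocera Eppelsheim, 1893", "Quedius fuliginosus"],
    )
    with caplog.at_level(logging.WARNING):
        checklist = load_checklist(p, "test", synonyms=SYNONYMS)
    assert len(checklist) == 2
    assert "Atheta allocera" in checklist
    assert any("duplicate" in r.message for r in caplog.records)


def test_load_checklist_single_row(tmp_path):
    checklist = load_checklist(_write(tmp_path, ["Quedius fuliginosus"]), "t")
    assert len(checklist) == 1


def test_load_checklist_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(ChecklistFormatError):
        load_checklist(empty, "t")
    wrong = _write(tmp_path, ["Quedius fuliginosus"], header="taxon_name")
    with pytest.raises(ChecklistFormatError, match="species"):
        load_checklist(wrong, "t")


@given(st.permutations(list(range(6))), st.integers(1, 3))
def test_load_checklist_order_and_duplication_invariant(tmp_path_factory, order, repeats):
    """Cardinality is invariant under row order and duplicated rows."""
    base = [
        "Atheta allocera",
        "Atheta campbelli",
        "Quedius fuliginosus",
        "Gnypeta minuta",
        "Dasygnypeta velata",
        "Lathrobium fauveli",
    ]
    rows = [base[i] for i in order for _ in range(repeats)]
    tmp = tmp_path_factory.mktemp("cl")
    p = tmp / "list.csv"
    p.write_text("\n".join(["species"] + rows) + "\n")
    checklist = load_checklist(p, "t", synonyms=SYNONYMS)
    assert len(checklist) == 4  # two pairs collapse


def test_genera_of():
    names = [parse_binomial(s) for s in ["Atheta allocera", "Atheta campbelli", "Quedius fuliginosus"]]
    assert genera_of(names) == {"Atheta", "Quedius"}
    assert genera_of(Checklist("x")) == set()
    congeners = [TaxonName("Stenus", e) for e in ["a" + c for c in "bcdef"]]
    assert genera_of(congeners) == {"Stenus"}


@given(
    st.sets(st.sampled_from([f"Gen{c} sp{i}" for c in "ABC" for i in range(4)]), max_size=8),
    st.sets(st.sampled_from([f"Gen{c} sp{i}" for c in "ABC" for i in range(4)]), max_size=8),
)
def test_genera_union_monotone(keys_a, keys_b):
    """genera_of distributes over checklist union."""

    def to_names(keys):
        return [TaxonName(*k.split()) for k in keys]

    union = genera_of(to_names(keys_a | keys_b))
    assert union == genera_of(to_names(keys_a)) | genera_of(to_names(keys_b))


def test_write_checklist_csv(tmp_path):
    checklist = Checklist("R")
    checklist.add(parse_binomial("Quedius fuliginosus"))
    checklist.add(parse_binomial("Atheta allocera"))
    out = tmp_path / "out.csv"
    write_checklist_csv(checklist, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "region,genus,epithet,canonical_key"
    assert lines[1].startswith("R,Atheta,allocera")
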