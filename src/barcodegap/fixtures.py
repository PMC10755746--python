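"""Synthetic test data: paired BOLD/GenBank corpora and regional checklists.

Everything here is generated, never downloaded, so the whole pipeline is
testable offline against known ground truth.

:func:`generate_corpus` emulates the record population the pipeline is built
for: per-species barcode counts follow a zero-inflated geometric law (most
species have few barcodes, a heavy tail has hundreds), a controlled fraction
of barcodes is cross-deposited in both libraries with consistent mutual ID
references, contamination (COI-3P records, Jerry/Pat primer products,
records with no gene-region information) is planted at stated rates, and
synonym conflicts are planted on cross-deposited pairs.  A ``truth.json``
records exactly what was planted.

:func:`synthetic_checklists` builds three SYNTHETIC regional rove-beetle
checklists (West Siberia, Fennoscandia, Canada and Alaska).  The species
names are invented, but the cardinalities (726 / 1399 / 1858 species) and
the species- and genus-level overlap structure are solved from the published
three-region similarity figures, as far as those figures are mutually
consistent (see docs/methods.md), so the similarity module can be exercised
at the published fauna sizes.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .coverage import RegionScheme, assign_region, default_scheme
from .records_io import BarcodeRecord
from .taxa import Checklist, TaxonName

__all__ = [
    "FixtureSpec",
    "generate_corpus",
    "synthetic_checklists",
    "write_synthetic_checklists",
    "SPECIES_CELLS",
    "GENUS_CELLS",
]


# ---------------------------------------------------------------------------
# Deterministic pseudo-Latin name machinery

_GENUS_ONSETS = [
    "Staphylo", "Athero", "Quedo", "Tachy", "Philo", "Steno", "Oxy", "Lathro",
    "Bledio", "Gyro", "Myceto", "Omalo", "Alevo", "Euplecto", "Paedero",
    "Scopaeo", "Xantho", "Carpelo", "Ocypo", "Bryo", "Acido", "Platy",
    "Micro", "Zyro",
]
_GENUS_SUFFIXES = [
    "bius", "derus", "soma", "porus", "linus", "charis", "theta", "notus",
    "gnathus", "cephalus", "trichus", "merus", "phloeus", "pinus",
    "stilicus", "onthus", "mura", "glossa", "cantha", "dytes", "phaena",
]
_EPITHET_STEMS = [
    "nigr", "ruf", "later", "sibir", "bore", "mont", "palustr", "silv",
    "arct", "fenn", "canad", "alasc", "lute", "obscur", "punctat", "striat",
    "vernal", "campestr", "rugos", "laevigat", "pallid", "fusc", "gracil",
    "robust",
]
_EPITHET_ENDINGS = [
    "a", "us", "um", "ellus", "icollis", "ipennis", "iventris", "icornis",
    "ifrons", "oides", "ianus", "inus", "ator", "ensis",
]


def _genus_name(i: int) -> str:
    a, b = divmod(i, len(_GENUS_SUFFIXES))
    if a >= len(_GENUS_ONSETS):
        raise ValueError(f"genus index {i} out of range")
    return _GENUS_ONSETS[a] + _GENUS_SUFFIXES[b]


def _epithet(j: int) -> str:
    a, b = divmod(j, len(_EPITHET_ENDINGS))
    if a >= len(_EPITHET_STEMS):
        raise ValueError(f"epithet index {j} out of range")
    return _EPITHET_STEMS[a] + _EPITHET_ENDINGS[b]


# ---------------------------------------------------------------------------
# Synthetic regional checklists

W, F, C = "West Siberia", "Fennoscandia", "Canada and Alaska"

# Venn-cell sizes (exclusive cells) for species and genera across the three
# regions.  Solved so that |W|=726, |F|=1399, |C|=1858 and the pairwise /
# union similarity fractions reproduce as many of the published percentage
# cells as integer set arithmetic permits: species overlaps W∩F=616,
# W∩C=185, F∩C=287, triple=175; genus totals 213/300/385 with overlaps
# 191/159/207, triple=149.
SPECIES_CELLS: dict[str, int] = {
    "W": 100, "F": 671, "C": 1561, "WF": 441, "WC": 10, "FC": 112, "WFC": 175,
}
GENUS_CELLS: dict[str, int] = {
    "W": 12, "F": 51, "C": 168, "WF": 42, "WC": 10, "FC": 58, "WFC": 149,
}

_CELL_ORDER = ["W", "F", "C", "WF", "WC", "FC", "WFC"]
_CELL_REGIONS = {
    "W": (W,), "F": (F,), "C": (C,),
    "WF": (W, F), "WC": (W, C), "FC": (F, C), "WFC": (W, F, C),
}
# Genus cells able to host a species of a given cell (superset region-sets).
_COMPATIBLE = {
    "W": ("W", "WF", "WC", "WFC"),
    "F": ("F", "WF", "FC", "WFC"),
    "C": ("C", "WC", "FC", "WFC"),
    "WF": ("WF", "WFC"),
    "WC": ("WC", "WFC"),
    "FC": ("FC", "WFC"),
    "WFC": ("WFC",),
}


def synthetic_checklists() -> dict[str, Checklist]:
    """Build the three synthetic regional checklists (deterministic).

    Genera are laid out cell by cell; every genus is seeded with one species
    occupying exactly the genus's region set (so genus-level presence equals
    the design), and the remaining species of each cell are dealt
    round-robin to compatible genera.
    """
    genus_cells: list[tuple[str, str]] = []  # (genus name, cell)
    gi = 0
    for cell in _CELL_ORDER:
        for _ in range(GENUS_CELLS[cell]):
            genus_cells.append((_genus_name(gi), cell))
            gi += 1

    remaining = dict(SPECIES_CELLS)
    species: list[tuple[str, str, str]] = []  # (genus, cell, epithet)
    per_genus_counter: dict[str, int] = {}

    def add_species(genus: str, cell: str) -> None:
        j = per_genus_counter.get(genus, 0)
        per_genus_counter[genus] = j + 1
        species.append((genus, cell, _epithet(j)))

    for genus, cell in genus_cells:
        add_species(genus, cell)
        remaining[cell] -= 1
        if remaining[cell] < 0:
            raise AssertionError(f"species cell {cell} exhausted by genus seeding")

    for cell in _CELL_ORDER:
        hosts = [g for g, gc in genus_cells if gc in _COMPATIBLE[cell]]
        for idx in range(remaining[cell]):
            add_species(hosts[idx % len(hosts)], cell)

    checklists = {label: Checklist(region_label=label) for label in (W, F, C)}
    for i, (genus, cell, epithet) in enumerate(species):
        name = TaxonName(genus=genus, epithet=epithet, author_year=f"Auctor, {1850 + i % 150}")
        for label in _CELL_REGIONS[cell]:
            if not checklists[label].add(name):
                raise AssertionError(f"duplicate synthetic species {name.canonical_key}")
    return checklists


def write_synthetic_checklists(out_dir: str | Path) -> dict[str, Path]:
    """Write the synthetic checklists as CSVs (column ``species``) and return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = {W: "west_siberia_synthetic", F: "fennoscandia_synthetic", C: "canada_alaska_synthetic"}
    paths: dict[str, Path] = {}
    for label, checklist in synthetic_checklists().items():
        path = out_dir / f"{stems[label]}.csv"
        with path.open("w", newline="", encoding="utf-8") as fh:
            fh.write("species\n")
            for key in sorted(checklist.taxa):
                name = checklist.taxa[key]
                full = f"{name.canonical_key} {name.author_year}".strip()
                fh.write(full + "\n")
        paths[label] = path
    return paths


# ---------------------------------------------------------------------------
# Paired corpus generator

_DEFAULT_COUNTRIES: dict[str, float] = {
    "Finland": 3.0,
    "Sweden": 2.0,
    "Norway": 1.0,
    "Canada": 3.0,
    "Canada: Yukon": 1.0,
    "USA: Alaska": 1.0,
    "Germany": 2.0,
    "Russia: Tyumen Oblast": 1.0,
    "": 1.0,
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic paired corpus.

    ``zero_inflation`` is the probability a species has no barcode at all;
    otherwise its count is geometric with mean ``mean_count`` (support >=1).
    ``p_dup`` is the fraction of barcodes deposited in BOTH libraries;
    ``p_coi3p`` / ``p_primer_note`` / ``p_no_region`` are contamination
    rates relative to the number of genuine barcodes.  ``synonym_pairs``
    species get a junior synonym used by their GenBank copies.
    """

    n_species: int = 20
    zero_inflation: float = 0.3
    mean_count: float = 8.0
    p_dup: float = 0.25
    p_coi3p: float = 0.0
    p_primer_note: float = 0.0
    p_no_region: float = 0.0
    synonym_pairs: int = 0
    seed: int = 0
    country_weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COUNTRIES))

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name in ("zero_inflation", "p_dup", "p_coi3p", "p_primer_note", "p_no_region"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_count < 1:
            raise ValueError("mean_count must be >= 1")


def _species_names(spec: FixtureSpec) -> list[TaxonName]:
    # ~3 congeneric species per genus so genus-level code paths get exercised
    names = []
    for i in range(spec.n_species):
        names.append(TaxonName(genus=_genus_name(i // 3), epithet=_epithet(3 * (i % 3) + 1)))
    return names


def _junior_synonym(valid: TaxonName, i: int) -> TaxonName:
    return TaxonName(genus=valid.genus, epithet=_epithet(100 + i))


def _geometric(rng: random.Random, mean: float) -> int:
    p = 1.0 / mean
    return 1 + int(math.log(1.0 - rng.random()) / math.log(1.0 - p))


def _locality(rng: random.Random, spec: FixtureSpec) -> tuple[str, str, str]:
    """Draw a locality; returns (full string, country, admin_unit)."""
    choices = list(spec.country_weights)
    weights = [spec.country_weights[c] for c in choices]
    full = rng.choices(choices, weights=weights, k=1)[0]
    if ":" in full:
        country, admin = (s.strip() for s in full.split(":", 1))
    else:
        country, admin = full, ""
    return full, country, admin


def _sequence(rng: random.Random, length: int = 658) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _bold_row(pid, name, marker, primers, country, admin, accession, seq):
    return [pid, name, marker, primers, country, admin, accession, seq]


def _genbank_seqrecord(
    accession: str,
    organism: str,
    locality_full: str,
    seq: str,
    bold_xref: str = "",
    marker_note: str = "COI-5P",
    primer_note: str = "",
    use_new_qualifier: bool = False,
    with_gene: bool = True,
) -> SeqRecord:
    stem = accession.split(".", 1)[0]
    rec = SeqRecord(
        Seq(seq),
        id=accession,
        name=stem,
        description=f"{organism} cytochrome c oxidase subunit I (COX1) gene, partial cds; mitochondrial",
    )
    rec.annotations.update(
        {
            "molecule_type": "DNA",
            "topology": "linear",
            "data_file_division": "INV",
            "date": "01-JAN-2023",
            "accessions": [stem],
            "sequence_version": int(accession.rsplit(".", 1)[1]),
            "organism": organism,
            "source": f"mitochondrion {organism}",
            "taxonomy": ["Eukaryota", "Arthropoda", "Insecta", "Coleoptera", "Staphylinidae"],
        }
    )
    src_quals: dict[str, list[str]] = {
        "organism": [organism],
        "organelle": ["mitochondrion"],
        "mol_type": ["genomic DNA"],
    }
    if locality_full:
        qual = "geo_loc_name" if use_new_qualifier else "country"
        src_quals[qual] = [locality_full]
    if bold_xref:
        src_quals["db_xref"] = [f"BOLD:{bold_xref}"]
    rec.features.append(SeqFeature(SimpleLocation(0, len(seq)), type="source", qualifiers=src_quals))
    if with_gene:
        quals: dict[str, list[str]] = {"gene": ["COX1"]}
        if marker_note:
            quals["note"] = [marker_note]
        if primer_note:
            quals["PCR_primers"] = [primer_note]
        rec.features.append(SeqFeature(SimpleLocation(0, len(seq)), type="gene", qualifiers=quals))
    return rec


def generate_corpus(
    spec: FixtureSpec,
    out_dir: str | Path,
    scheme: RegionScheme | None = None,
) -> dict[str, Path]:
    """Generate a paired corpus with ground truth; returns written paths.

    Writes ``bold.tsv``, ``genbank.gb``, ``checklist.csv``, ``synonyms.csv``
    and ``truth.json`` into ``out_dir``.  The same spec and seed yield
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = scheme or default_scheme()
    rng = random.Random(spec.seed)

    names = _species_names(spec)
    juniors: dict[str, TaxonName] = {}
    for i in range(min(spec.synonym_pairs, spec.n_species)):
        juniors[names[i].canonical_key] = _junior_synonym(names[i], i)

    bold_rows: list[list[str]] = []
    gb_records: list[SeqRecord] = []
    serial = 0

    def next_ids() -> tuple[str, str]:
        nonlocal serial
        serial += 1
        return f"FIX{serial:05d}-21", f"FX{serial:06d}.1"

    per_species: dict[str, dict] = {}
    n_pairs = 0
    n_good = 0
    for name in names:
        key = name.canonical_key
        count = 0 if rng.random() < spec.zero_inflation else _geometric(rng, spec.mean_count)
        entry = {"total": count, "within": {}}
        for _ in range(count):
            n_good += 1
            pid, acc = next_ids()
            full, country, admin = _locality(rng, spec)
            seq = _sequence(rng)
            region = assign_region(
                BarcodeRecord(source="BOLD", primary_id=pid, country=country, admin_unit=admin),
                scheme,
            )
            if region:
                entry["within"][region] = entry["within"].get(region, 0) + 1
            u = rng.random()
            deposition = "BOTH" if u < spec.p_dup else ("BOLD" if u < spec.p_dup + (1 - spec.p_dup) / 2 else "GENBANK")
            gb_name = key
            if deposition == "BOTH" and key in juniors:
                gb_name = juniors[key].canonical_key  # planted synonym conflict
            if deposition in ("BOLD", "BOTH"):
                accession_cell = acc.split(".", 1)[0] if deposition == "BOTH" else ""
                bold_rows.append(
                    _bold_row(pid, key, "COI-5P", "LepF1/LepR1", country, admin, accession_cell, seq)
                )
            if deposition in ("GENBANK", "BOTH"):
                gb_records.append(
                    _genbank_seqrecord(
                        acc,
                        gb_name,
                        full,
                        seq,
                        bold_xref=pid if deposition == "BOTH" else "",
                        use_new_qualifier=serial % 2 == 0,
                    )
                )
            if deposition == "BOTH":
                n_pairs += 1
        per_species[key] = entry

    # contamination: planted at stated rates relative to the genuine pool
    contamination = {
        "coi3p_removed": round(spec.p_coi3p * n_good),
        "primer_removed": round(spec.p_primer_note * n_good),
        "no_region_removed": round(spec.p_no_region * n_good),
    }
    jerry_pat = "fwd_name: Jerry (Cl-J-2183), rev_name: Pat (TL2-N-3014)"
    for rule, n_bad in contamination.items():
        for _ in range(n_bad):
            pid, acc = next_ids()
            name = rng.choice(names)
            full, country, admin = _locality(rng, spec)
            seq = _sequence(rng)
            in_bold = rng.random() < 0.5
            if rule == "coi3p_removed":
                if in_bold:
                    bold_rows.append(_bold_row(pid, name.canonical_key, "COI-3P", "", country, admin, "", seq))
                else:
                    gb_records.append(
                        _genbank_seqrecord(acc, name.canonical_key, full, seq, marker_note="COI-3P")
                    )
            elif rule == "primer_removed":
                if in_bold:
                    bold_rows.append(_bold_row(pid, name.canonical_key, "COI", jerry_pat, country, admin, "", seq))
                else:
                    gb_records.append(
                        _genbank_seqrecord(acc, name.canonical_key, full, seq, marker_note="", primer_note=jerry_pat)
                    )
            else:  # no gene-region information at all
                if in_bold:
                    bold_rows.append(_bold_row(pid, name.canonical_key, "", "", country, admin, "", seq))
                else:
                    gb_records.append(
                        _genbank_seqrecord(acc, name.canonical_key, full, seq, with_gene=False)
                    )

    paths = {
        "bold": out_dir / "bold.tsv",
        "genbank": out_dir / "genbank.gb",
        "checklist": out_dir / "checklist.csv",
        "synonyms": out_dir / "synonyms.csv",
        "truth": out_dir / "truth.json",
    }
    with paths["bold"].open("w", newline="", encoding="utf-8") as fh:
        fh.write(
            "processid\tspecies_name\tmarkercode\tseq_primers\tcountry\tprovince_state\tgenbank_accession\tnucleotides\n"
        )
        for row in bold_rows:
            fh.write("\t".join(row) + "\n")
    with paths["genbank"].open("w", encoding="utf-8") as fh:
        SeqIO.write(gb_records, fh, "genbank")
    with paths["checklist"].open("w", newline="", encoding="utf-8") as fh:
        fh.write("species\n")
        for name in names:
            fh.write(name.canonical_key + "\n")
    with paths["synonyms"].open("w", newline="", encoding="utf-8") as fh:
        fh.write("junior,valid\n")
        for valid_key, junior in juniors.items():
            fh.write(f"{junior.canonical_key},{valid_key}\n")
    truth = {
        "spec": {k: v for k, v in asdict(spec).items() if k != "country_weights"},
        "n_bold_rows": len(bold_rows),
        "n_genbank_records": len(gb_records),
        "unique_good_barcodes": n_good,
        "pairs": n_pairs,
        "filter_log": {**contamination, "pairs_matched": n_pairs},
        "per_species": per_species,
    }
    with paths["truth"].open("w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
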