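"""Scientific-name handling: parsing, normalization, synonym resolution, checklists.

Regional faunal checklists arrive as delimited text with one taxon per row,
printed in a mix of styles: with or without author/year, sometimes as
trinomials.  Everything downstream (similarity indices, barcode coverage)
compares taxa by an authorship-free canonical key ``"Genus epithet"``, with
junior synonyms resolved to the valid name first.  Matching is exact on that
key; no fuzzy or phonetic matching is attempted, because a near-miss that is
silently merged would change species counts without trace.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonName",
    "SynonymTable",
    "Checklist",
    "MalformedNameError",
    "SynonymConfigError",
    "ChecklistFormatError",
    "parse_binomial",
    "resolve",
    "load_checklist",
    "genera_of",
    "write_checklist_csv",
]


class MalformedNameError(ValueError):
    """Raised when a raw string cannot be interpreted as a species binomial."""


class SynonymConfigError(ValueError):
    """Raised when a synonym table is structurally invalid (e.g. cyclic)."""


class ChecklistFormatError(ValueError):
    """Raised when a checklist file is empty or lacks the declared name column."""


# Epithet placeholders that mark an undetermined species, not a real name.
_PLACEHOLDER_EPITHETS = {"sp", "spp", "cf", "aff", "nr", "indet", "gen"}

_WORD_RE = re.compile(r"^[A-Za-z][a-z-]*$")


@dataclass(frozen=True)
class TaxonName:
    """A normalized species binomial.

    ``genus`` is capitalized, ``epithet`` fully lower-case.  ``author_year``
    keeps whatever authorship text followed the name (parentheses included)
    and never participates in comparison.  ``rank_note`` flags names that
    arrived as trinomials and were collapsed to the binomial.
    """

    genus: str
    epithet: str
    author_year: str = ""
    rank_note: str = ""

    def __post_init__(self) -> None:
        if not self.genus or not self.genus[0].isupper():
            raise MalformedNameError(f"genus must be capitalized: {self.genus!r}")
        if not self.epithet or self.epithet != self.epithet.lower():
            raise MalformedNameError(f"epithet must be lower-case: {self.epithet!r}")

    @property
    def canonical_key(self) -> str:
        return f"{self.genus} {self.epithet}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_key


def parse_binomial(raw: str) -> TaxonName:
    """Parse a printed species name into a :class:`TaxonName`.

    Accepts ``"Genus epithet"`` optionally followed by a subspecific epithet
    (collapsed, with ``rank_note="trinomial"``) and/or author-year text such
    as ``"Eppelsheim, 1893"`` or ``"(Lohse, 1990)"``.  Names must contain a
    separator between genus and epithet: fused renderings cannot be split
    without a genus dictionary and are rejected.
    """
    text = raw.strip()
    if not text:
        raise MalformedNameError("empty name string")
    tokens = text.split()
    if len(tokens) < 2:
        raise MalformedNameError(f"not a binomial (single token): {raw!r}")

    genus_tok, epithet_tok = tokens[0], tokens[1]
    if not _WORD_RE.match(genus_tok):
        raise MalformedNameError(f"unparseable genus token in {raw!r}: {genus_tok!r}")
    epithet = epithet_tok.lower().rstrip(".")
    if not _WORD_RE.match(epithet) or epithet != epithet_tok.rstrip("."):
        # reject capitalized/odd epithets outright rather than guess
        if not _WORD_RE.match(epithet):
            raise MalformedNameError(f"unparseable epithet in {raw!r}: {epithet_tok!r}")
    if epithet in _PLACEHOLDER_EPITHETS:
        raise MalformedNameError(f"placeholder epithet (no determinable species) in {raw!r}")

    rest = tokens[2:]
    rank_note = ""
    # A further all-lower-case alphabetic token is a subspecific epithet.
    if rest and _WORD_RE.match(rest[0]) and rest[0] == rest[0].lower():
        rank_note = "trinomial"
        rest = rest[1:]
    author_year = " ".join(rest)

    genus = genus_tok[0].upper() + genus_tok[1:].lower()
    return TaxonName(genus=genus, epithet=epithet, author_year=author_year, rank_note=rank_note)


class SynonymTable:
    """Mapping from junior-synonym canonical keys to valid-name keys.

    Chains (A -> B -> C) resolve fully; cycles are rejected at construction.
    Resolving a key with no entry returns the key unchanged, so resolution
    is idempotent.
    """

    def __init__(self, entries: Mapping[str, str] | None = None) -> None:
        self._entries: dict[str, str] = dict(entries or {})
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for start in self._entries:
            seen = {start}
            cur = start
            while cur in self._entries:
                cur = self._entries[cur]
                if cur in seen:
                    raise SynonymConfigError(f"synonym cycle involving {start!r}")
                seen.add(cur)

    def __len__(self) -> int:
        return len(self._entries)

    def resolve_key(self, key: str) -> str:
        cur = key
        while cur in self._entries:
            cur = self._entries[cur]
        return cur

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        """Load a two-column delimited file (junior name, valid name).

        A header row is detected by the presence of non-name words such as
        ``junior``/``synonym``/``valid`` and skipped.  Both columns are parsed
        as binomials and stored by canonical key.
        """
        path = Path(path)
        entries: dict[str, str] = {}
        with path.open(newline="", encoding="utf-8") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            delim = "\t" if "\t" in sample.splitlines()[0] else "," if sample else ","
            reader = csv.reader(fh, delimiter=delim)
            for i, row in enumerate(reader):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 2:
                    raise SynonymConfigError(f"{path}: row {i + 1} has fewer than 2 columns")
                a, b = row[0].strip(), row[1].strip()
                if i == 0 and any(
                    w in (a + " " + b).lower() for w in ("junior", "synonym", "valid")
                ):
                    continue
                junior = parse_binomial(a).canonical_key
                valid = parse_binomial(b).canonical_key
                entries[junior] = valid
        return cls(entries)


def resolve(name: TaxonName, table: SynonymTable) -> TaxonName:
    """Return the valid name for ``name``, or ``name`` itself if not a synonym.

    Only the canonical key is rewritten; authorship of a rewritten name is
    dropped (it belonged to the junior synonym).
    """
    key = table.resolve_key(name.canonical_key)
    if key == name.canonical_key:
        return name
    genus, epithet = key.split(" ", 1)
    return TaxonName(genus=genus, epithet=epithet)


@dataclass
class Checklist:
    """A named regional fauna: a set of synonym-resolved :class:`TaxonName`.

    Cardinality (``len``) is the fauna size.  ``source_notes`` carries
    per-taxon provenance text keyed by canonical key.
    """

    region_label: str
    taxa: dict[str, TaxonName] = field(default_factory=dict)
    source_notes: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.taxa)

    def __contains__(self, key: str) -> bool:
        return key in self.taxa

    def add(self, name: TaxonName, note: str = "") -> bool:
        """Add a (resolved) taxon; returns False if the key was already present."""
        key = name.canonical_key
        if key in self.taxa:
            return False
        self.taxa[key] = name
        if note:
            self.source_notes[key] = note
        return True

    @property
    def keys(self) -> set[str]:
        return set(self.taxa)

    @property
    def genera(self) -> set[str]:
        return genera_of(self)


def load_checklist(
    path: str | Path,
    region_label: str,
    name_column: str = "species",
    synonyms: SynonymTable | None = None,
    note_column: str | None = None,
    errors: str = "raise",
) -> Checklist:
    """Load a delimited checklist (one taxon per row) into a :class:`Checklist`.

    Every row is parsed with :func:`parse_binomial` and synonym-resolved;
    rows that collapse onto an already-present key are dropped with a logged
    warning.  ``errors="skip"`` logs and skips malformed rows instead of
    raising.  The delimiter is inferred from the file extension (``.tsv`` ->
    tab, else comma).
    """
    path = Path(path)
    table = synonyms or SynonymTable()
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    checklist = Checklist(region_label=region_label)
    n_rows = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ChecklistFormatError(f"{path}: empty file")
        if name_column not in reader.fieldnames:
            raise ChecklistFormatError(
                f"{path}: name column {name_column!r} not in header {reader.fieldnames}"
            )
        for row in reader:
            raw = (row.get(name_column) or "").strip()
            if not raw:
                continue
            n_rows += 1
            try:
                name = parse_binomial(raw)
            except MalformedNameError as exc:
                if errors == "skip":
                    logger.warning("%s: skipping malformed name: %s", path, exc)
                    continue
                raise
            name = resolve(name, table)
            note = (row.get(note_column) or "") if note_column else ""
            if not checklist.add(name, note):
                logger.warning(
                    "%s: duplicate after synonym resolution collapsed: %r -> %s",
                    path,
                    raw,
                    name.canonical_key,
                )
    if n_rows == 0:
        raise ChecklistFormatError(f"{path}: no data rows")
    logger.info("%s: loaded %d taxa for %s", path, len(checklist), region_label)
    return checklist


def genera_of(checklist: Checklist | Iterable[TaxonName]) -> set[str]:
    """The set of distinct genus names in a checklist (or iterable of names)."""
    if isinstance(checklist, Checklist):
        names: Iterable[TaxonName] = checklist.taxa.values()
    else:
        names = checklist
    return {n.genus for n in names}


def write_checklist_csv(checklist: Checklist, path: str | Path) -> None:
    """Write ``region,genus,epithet,canonical_key`` rows, sorted by key."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "genus", "epithet", "canonical_key"])
        for key in sorted(checklist.taxa):
            name = checklist.taxa[key]
            writer.writerow([checklist.region_label, name.genus, name.epithet, key])
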