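"""Lexical cognate data: curation, binarization, and matrix I/O.

A cognate dataset records, for each (language, concept) pair, the set of
cognate classes the language attests for that concept — possibly more than
one (synonyms), possibly none (missing datum) — with loanwords flagged.
Binarization turns every (concept, cognate class) into one presence/absence
character: 1 if the language attests the class, 0 if it attests the concept
through other classes, and '?' if the concept is missing altogether.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import dendropy

__all__ = [
    "CognateDataset", "BinaryMatrix", "SitePatterns",
    "read_cognate_table", "write_cognate_table", "exclude_taxa",
    "remove_loans", "multistate_to_binary", "compress_patterns",
    "write_binary_nexus", "read_binary_nexus",
]

MISSING = 2  # integer code for '?' in binary matrices


@dataclass(frozen=True)
class ClassLabel:
    """One attested cognate class, scoped to its concept."""
    label: str
    is_loan: bool = False


@dataclass
class CognateDataset:
    """Multistate lexical matrix with loan/synonym/missing annotation."""

    languages: list[str]
    concepts: list[str]
    #: (language, concept) -> set of attested classes; absent pair = missing.
    entries: dict[tuple[str, str], frozenset[ClassLabel]]
    #: language -> age in ka BP (0 for extant); default 0.
    tip_dates: dict[str, float] = field(default_factory=dict)
    excluded_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        langs, cons = set(self.languages), set(self.concepts)
        for (lang, con) in self.entries:
            if lang not in langs:
                raise ValueError(f"entry references unknown language {lang!r}")
            if con not in cons:
                raise ValueError(f"entry references unknown concept {con!r}")
        for lang, age in self.tip_dates.items():
            if age < 0:
                raise ValueError(f"negative tip date for {lang!r}")

    def classes(self, language: str, concept: str) -> frozenset[ClassLabel]:
        return self.entries.get((language, concept), frozenset())

    @property
    def n_loans(self) -> int:
        return sum(1 for labels in self.entries.values()
                   for c in labels if c.is_loan)

    def __eq__(self, other: object) -> bool:
        """Content equality: axis *order* is presentation, not data."""
        if not isinstance(other, CognateDataset):
            return NotImplemented
        return (set(self.languages) == set(other.languages)
                and set(self.concepts) == set(other.concepts)
                and self.entries == other.entries
                and {l: self.tip_dates.get(l, 0.0) for l in self.languages}
                == {l: other.tip_dates.get(l, 0.0) for l in other.languages})


@dataclass
class BinaryMatrix:
    """Languages x cognate-set presence/absence matrix over {0, 1, ?}."""

    languages: list[str]
    columns: list[tuple[str, str]]            # (concept, class label)
    values: np.ndarray                        # int8, codes {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.languages), len(self.columns)):
            raise ValueError("matrix shape does not match labels")

    @property
    def n_cognate_sets(self) -> int:
        return len(self.columns)

    def column(self, concept: str, label: str) -> np.ndarray:
        j = self.columns.index((concept, label))
        return self.values[:, j]


@dataclass
class SitePatterns:
    """Unique binary columns and their multiplicities (likelihood speed-up)."""

    languages: list[str]
    patterns: np.ndarray    # (n_patterns, n_languages) int8
    weights: np.ndarray     # (n_patterns,) ints

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        self.weights = np.asarray(self.weights)
        if self.patterns.shape[0] != self.weights.shape[0]:
            raise ValueError("pattern/weight length mismatch")

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


# ----------------------------------------------------------------------
# reading and writing the CSV cognate dialect
# ----------------------------------------------------------------------
CSV_FIELDS = ["language", "concept", "cognate_class", "is_loan"]
_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def read_cognate_table(path, format: str = "csv",
                       tip_dates: Optional[dict[str, float]] = None
                       ) -> CognateDataset:
    """Read a multistate cognate table.

    ``csv``: one row per attested word, columns
    ``language, concept, cognate_class, is_loan``.  ``nexus-multistate``:
    a NEXUS standard-datatype matrix, one character per concept, one state
    symbol per cognate class (no loan flags — NEXUS has nowhere to put them).
    """
    if format == "csv":
        return _read_csv(path, tip_dates or {})
    if format == "nexus-multistate":
        return _read_nexus_multistate(path, tip_dates or {})
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path, tip_dates: dict[str, float]) -> CognateDataset:
    languages: list[str] = []
    concepts: list[str] = []
    cells: dict[tuple[str, str], set[ClassLabel]] = {}
    seen_rows: set[tuple[str, str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        if [f.strip() for f in reader.fieldnames] != CSV_FIELDS:
            raise ValueError(
                f"{path}: header must be {','.join(CSV_FIELDS)}; "
                f"got {','.join(reader.fieldnames)}")
        for lineno, row in enumerate(reader, start=2):
            lang = (row["language"] or "").strip()
            con = (row["concept"] or "").strip()
            cls = (row["cognate_class"] or "").strip()
            loan_raw = (row["is_loan"] or "").strip().lower()
            if not lang or not con or not cls:
                raise ValueError(f"{path}:{lineno}: empty field")
            if loan_raw in _TRUE:
                loan = True
            elif loan_raw in _FALSE:
                loan = False
            else:
                raise ValueError(
                    f"{path}:{lineno}: unparseable is_loan value {loan_raw!r}")
            key = (lang, con, cls)
            if key in seen_rows:
                raise ValueError(
                    f"{path}:{lineno}: duplicate row for {key}")
            seen_rows.add(key)
            if lang not in languages:
                languages.append(lang)
            if con not in concepts:
                concepts.append(con)
            cells.setdefault((lang, con), set()).add(ClassLabel(cls, loan))
    if not languages:
        raise ValueError(f"{path}: no data rows")
    entries = {k: frozenset(v) for k, v in cells.items()}
    dates = {l: float(tip_dates.get(l, 0.0)) for l in languages}
    return CognateDataset(languages, concepts, entries, dates)


def write_cognate_table(ds: CognateDataset, path) -> None:
    """Write the CSV cognate dialect (row order: language, then concept)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_FIELDS)
        for lang in ds.languages:
            for con in ds.concepts:
                for cl in sorted(ds.classes(lang, con),
                                 key=lambda c: c.label):
                    writer.writerow([lang, con, cl.label,
                                     "1" if cl.is_loan else "0"])


def _read_nexus_multistate(path, tip_dates: dict[str, float]) -> CognateDataset:
    dataset = dendropy.DataSet.get(path=str(path), schema="nexus")
    if not dataset.char_matrices:
        raise ValueError(f"{path}: no character matrix found")
    mat = dataset.char_matrices[0]
    languages = [t.label for t in mat.taxon_namespace]
    n_chars = max(len(mat[t]) for t in mat.taxon_namespace)
    concepts = [f"concept_{i+1}" for i in range(n_chars)]
    entries: dict[tuple[str, str], frozenset[ClassLabel]] = {}
    for taxon in mat.taxon_namespace:
        seq = mat[taxon]
        for i, ch in enumerate(seq):
            sym = str(ch.symbol)
            if sym in ("?", "-"):
                continue
            entries[(taxon.label, concepts[i])] = frozenset(
                [ClassLabel(sym, False)])
    dates = {l: float(tip_dates.get(l, 0.0)) for l in languages}
    return CognateDataset(languages, concepts, entries, dates)


# ----------------------------------------------------------------------
# curation
# ----------------------------------------------------------------------
def exclude_taxa(ds: CognateDataset, names: Iterable[str]) -> CognateDataset:
    """Drop the named languages, recording them in ``excluded_taxa``."""
    names = list(names)
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate names in exclude list: {sorted(dupes)}")
    unknown = [n for n in names if n not in ds.languages]
    if unknown:
        raise ValueError(f"cannot exclude unknown taxa: {unknown}")
    keep = [l for l in ds.languages if l not in names]
    entries = {k: v for k, v in ds.entries.items() if k[0] not in names}
    dates = {l: ds.tip_dates.get(l, 0.0) for l in keep}
    return CognateDataset(keep, list(ds.concepts), entries, dates,
                          excluded_taxa=list(ds.excluded_taxa) + names)


def remove_loans(ds: CognateDataset) -> CognateDataset:
    """Delete loan-flagged classes; loan-only cells become missing data.

    A cell whose every class was a loan is dropped entirely: the native
    word is unknown, so the concept becomes a missing datum rather than an
    asserted absence.
    """
    entries: dict[tuple[str, str], frozenset[ClassLabel]] = {}
    for key, labels in ds.entries.items():
        kept = frozenset(c for c in labels if not c.is_loan)
        if kept:
            entries[key] = kept
    return replace(ds, entries=entries)


# ----------------------------------------------------------------------
# binarization
# ----------------------------------------------------------------------
def multistate_to_binary(ds: CognateDataset) -> BinaryMatrix:
    """One presence/absence column per (concept, class) attested anywhere.

    Loans are removed first (idempotent).  Column order is deterministic:
    concepts in dataset order, classes within a concept in order of first
    attestation (scanning languages in dataset order).
    """
    ds = remove_loans(ds)
    if not ds.languages or not ds.concepts:
        raise ValueError("cannot binarize an empty dataset")
    columns: list[tuple[str, str]] = []
    for con in ds.concepts:
        seen: list[str] = []
        for lang in ds.languages:
            for cl in sorted(ds.classes(lang, con), key=lambda c: c.label):
                if cl.label not in seen:
                    seen.append(cl.label)
        columns.extend((con, lbl) for lbl in seen)
    if not columns:
        raise ValueError("dataset has no attested cognate classes")
    values = np.full((len(ds.languages), len(columns)), MISSING, dtype=np.int8)
    col_index = {pair: j for j, pair in enumerate(columns)}
    cols_of_concept: dict[str, list[int]] = {}
    for (con, lbl), j in col_index.items():
        cols_of_concept.setdefault(con, []).append(j)
    for i, lang in enumerate(ds.languages):
        for con in ds.concepts:
            labels = ds.classes(lang, con)
            if not labels:
                continue  # missing concept -> '?' across its columns
            for j in cols_of_concept.get(con, []):
                values[i, j] = 0
            for cl in labels:
                values[i, col_index[(con, cl.label)]] = 1
    return BinaryMatrix(list(ds.languages), columns, values)


def compress_patterns(bm: BinaryMatrix) -> SitePatterns:
    """Collapse identical columns into weighted site patterns."""
    cols = bm.values.T  # (n_sets, n_languages)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return SitePatterns(list(bm.languages), patterns, counts)


# ----------------------------------------------------------------------
# NEXUS interchange for the binary matrix
# ----------------------------------------------------------------------
_SYMBOL = {0: "0", 1: "1", MISSING: "?"}


def write_binary_nexus(bm: BinaryMatrix, path) -> None:
    """Write a standard-datatype NEXUS DATA block (symbols 01, missing ?)."""
    from dendropy.datamodel.charstatemodel import new_standard_state_alphabet
    taxa = dendropy.TaxonNamespace(bm.languages)
    rows = {lang: "".join(_SYMBOL[v] for v in bm.values[i])
            for i, lang in enumerate(bm.languages)}
    mat = dendropy.StandardCharacterMatrix.from_dict(
        rows, taxon_namespace=taxa,
        default_state_alphabet=new_standard_state_alphabet("01"))
    mat.write(path=str(path), schema="nexus")


def read_binary_nexus(path) -> BinaryMatrix:
    """Read a binary NEXUS matrix back (column identity is positional)."""
    dataset = dendropy.DataSet.get(path=str(path), schema="nexus")
    if not dataset.char_matrices:
        raise ValueError(f"{path}: no character matrix found")
    mat = dataset.char_matrices[0]
    languages = [t.label for t in mat.taxon_namespace]
    n_chars = max(len(mat[t]) for t in mat.taxon_namespace)
    values = np.full((len(languages), n_chars), MISSING, dtype=np.int8)
    for i, taxon in enumerate(mat.taxon_namespace):
        for j, ch in enumerate(mat[taxon]):
            sym = str(ch.symbol)
            if sym in ("?", "-"):
                values[i, j] = MISSING
            elif sym in ("0", "1"):
                values[i, j] = int(sym)
            else:
                raise ValueError(f"{path}: unexpected symbol {sym!r}")
    columns = [(f"site_{j+1}", "1") for j in range(n_chars)]
    return BinaryMatrix(languages, columns, values)
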