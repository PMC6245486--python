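"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`Proteome`, :class:`DomainAnnotation`,
:class:`DDITable`, :class:`InteractionRecord` and :class:`FeatureRow`.

Formats:

* protein FASTA (one file per organism);
* domain hits, either HMMER per-domain tabular output (``domtblout``) or a
  plain TSV with ``protein_id`` / ``domain_accession`` columns;
* DDI score tables as TSV (``domain_a``, ``domain_b``, ``score``);
* interaction pair tables as TSV
  (``phage_id``, ``bacterium_id``, ``species``, ``family``[, ``label``]);
* feature matrices as CSV (``pair_id``, ``label``, ``f0`` .. ``f{n-1}``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

PHAGE = "phage"
BACTERIUM = "bacterium"
POSITIVE = "positive"
NEGATIVE = "negative"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence belonging to one organism."""

    protein_id: str
    organism_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(
                f"protein {self.protein_id!r} of {self.organism_id!r} has an "
                "empty sequence"
            )
        if not self.sequence.isalpha():
            raise ValueError(
                f"protein {self.protein_id!r} sequence contains non-letter "
                "characters"
            )


@dataclass
class Proteome:
    """An organism identifier plus its protein complement."""

    organism_id: str
    kind: str  # PHAGE or BACTERIUM
    proteins: list[ProteinRecord]

    def __post_init__(self) -> None:
        if self.kind not in (PHAGE, BACTERIUM):
            raise ValueError(f"unknown organism kind {self.kind!r}")
        if not self.proteins:
            raise ValueError(f"proteome {self.organism_id!r} has no proteins")
        seen: set[str] = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise ValueError(
                    f"duplicate protein id {p.protein_id!r} in proteome "
                    f"{self.organism_id!r}"
                )
            seen.add(p.protein_id)

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on a protein (accession version suffix stripped)."""

    protein_id: str
    domain_accession: str
    hit_score: float | None = None

    def __post_init__(self) -> None:
        if not self.domain_accession:
            raise ValueError(
                f"empty domain accession for protein {self.protein_id!r}"
            )


class DDITable:
    """Symmetric mapping from an unordered domain-accession pair to a score.

    Absent pairs score 0. Duplicate rows for the same unordered pair are
    collapsed by taking the maximum score.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"negative DDI score {score} for ({a}, {b})")
        k = self._key(a, b)
        prev = self._entries.get(k)
        self._entries[k] = score if prev is None else max(prev, score)

    def lookup(self, a: str, b: str) -> float:
        return self._entries.get(self._key(a, b), 0.0)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self._entries.items()

    def max_score(self) -> float:
        return max(self._entries.values(), default=0.0)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DDITable) and self._entries == other._entries


@dataclass(frozen=True)
class InteractionRecord:
    """One labelled phage-bacterium pair with host taxonomy metadata."""

    phage_id: str
    bacterium_id: str
    species: str
    family: str
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == POSITIVE and (not self.species or not self.family):
            raise ValueError(
                f"positive pair ({self.phage_id}, {self.bacterium_id}) must "
                "carry species and family"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.phage_id, self.bacterium_id)


@dataclass
class FeatureRow:
    """A fixed-length numeric feature vector for one labelled pair."""

    pair_id: str
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# accession helpers
# ---------------------------------------------------------------------------

def strip_accession_version(accession: str) -> str:
    """Remove a trailing version suffix: ``PF00069.23`` -> ``PF00069``."""
    return accession.split(".", 1)[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path, organism_id: str, kind: str) -> Proteome:
    """Read an organism's protein FASTA file into a :class:`Proteome`.

    The header token before the first whitespace is the protein id;
    sequences are uppercased and a trailing stop ``*`` is dropped.
    """
    path = Path(path)
    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        proteins.append(ProteinRecord(pid, organism_id, seq))
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(organism_id, kind, proteins)


def write_protein_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for p in proteome.proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------

#: minimum field count of a HMMER per-domain table row
_DOMTBL_MIN_FIELDS = 22


def read_domain_hits(path: str | Path, dialect: str = "tsv") -> list[DomainAnnotation]:
    """Read per-protein domain hits.

    ``dialect="hmmer_domtbl"`` parses the space-aligned per-domain tabular
    output of hmmscan (``--domtblout``): the target accession (column 2)
    is the domain, the query name (column 4) is the protein. ``dialect="tsv"``
    expects columns ``protein_id`` and ``domain_accession`` (header optional).
    """
    path = Path(path)
    if dialect == "hmmer_domtbl":
        hits = _read_domtbl(path)
    elif dialect == "tsv":
        hits = _read_hits_tsv(path)
    else:
        raise ValueError(f"unknown domain-hit dialect {dialect!r}")
    if not hits:
        logger.warning("no domain annotations parsed from %s", path)
    return hits


def _read_domtbl(path: Path) -> list[DomainAnnotation]:
    hits: list[DomainAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: expected at least "
                    f"{_DOMTBL_MIN_FIELDS} fields, got {len(fields)}"
                )
            target_name, target_acc, _tlen, query_name = fields[:4]
            acc = target_acc if target_acc != "-" else target_name
            try:
                score = float(fields[13])  # this-domain bit score
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable domain score "
                    f"{fields[13]!r}"
                ) from exc
            hits.append(
                DomainAnnotation(query_name, strip_accession_version(acc), score)
            )
    return hits


def _read_hits_tsv(path: Path) -> list[DomainAnnotation]:
    hits: list[DomainAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "protein_id":
                continue  # header
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected protein_id<TAB>domain_accession"
                )
            score = None
            if len(fields) >= 3 and fields[2]:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable hit score {fields[2]!r}"
                    ) from exc
            hits.append(
                DomainAnnotation(fields[0], strip_accession_version(fields[1]), score)
            )
    return hits


def write_domain_hits(hits: Sequence[DomainAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_id\tdomain_accession\thit_score\n")
        for h in hits:
            score = "" if h.hit_score is None else repr(h.hit_score)
            fh.write(f"{h.protein_id}\t{h.domain_accession}\t{score}\n")


def annotations_by_protein(
    hits: Iterable[DomainAnnotation],
) -> dict[str, list[str]]:
    """Group hit accessions per protein, preserving multiplicity and order."""
    out: dict[str, list[str]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h.domain_accession)
    return out


# ---------------------------------------------------------------------------
# DDI tables
# ---------------------------------------------------------------------------

def read_ddi_table(path: str | Path) -> DDITable:
    """Read a DDI score TSV (``domain_a``, ``domain_b``, ``score``).

    The table is symmetrized; duplicate unordered pairs collapse by max.
    """
    path = Path(path)
    table = DDITable()
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"domain_a", "domain_b", "score"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                score = float(row["score"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {row['score']!r}"
                ) from exc
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative score {score}")
            table.add(
                strip_accession_version(row["domain_a"]),
                strip_accession_version(row["domain_b"]),
                score,
            )
    return table


def write_ddi_table(table: DDITable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("domain_a\tdomain_b\tscore\n")
        for (a, b), score in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{score!r}\n")


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = ("phage_id", "bacterium_id", "species", "family")


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a pair TSV; ``label`` column is optional (default positive)."""
    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PAIR_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        for row in reader:
            records.append(
                InteractionRecord(
                    phage_id=row["phage_id"],
                    bacterium_id=row["bacterium_id"],
                    species=row["species"] or "",
                    family=row["family"] or "",
                    label=row.get("label") or POSITIVE,
                )
            )
    return records


def write_interaction_table(
    records: Sequence[InteractionRecord], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("phage_id\tbacterium_id\tspecies\tfamily\tlabel\n")
        for r in records:
            fh.write(
                f"{r.phage_id}\t{r.bacterium_id}\t{r.species}\t{r.family}\t{r.label}\n"
            )


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(rows: Sequence[FeatureRow], path: str | Path) -> None:
    """Write rows as CSV: ``pair_id, label, f0 .. f{n-1}``.

    Values are written with full float repr so the reader round-trips
    losslessly. An empty row list yields a header-only file.
    """
    path = Path(path)
    if rows:
        n = len(rows[0].values)
        for r in rows:
            if len(r.values) != n:
                raise ValueError(
                    f"ragged feature rows: {r.pair_id!r} has {len(r.values)} "
                    f"values, expected {n}"
                )
    else:
        n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "label"] + [f"f{i}" for i in range(n)])
        for r in rows:
            writer.writerow([r.pair_id, r.label] + [repr(float(v)) for v in r.values])


def read_feature_matrix(path: str | Path) -> list[FeatureRow]:
    path = Path(path)
    rows: list[FeatureRow] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["pair_id", "label"]:
            raise ValueError(f"{path}: not a feature-matrix CSV")
        for rec in reader:
            rows.append(
                FeatureRow(rec[0], rec[1], np.array([float(v) for v in rec[2:]]))
            )
    return rows


def matrix_to_xy(rows: Sequence[FeatureRow]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack feature rows into ``(X, y, pair_ids)`` with positive -> 1."""
    if not rows:
        raise ValueError("empty feature matrix")
    X = np.vstack([r.values for r in rows])
    y = np.array([1 if r.label == POSITIVE else 0 for r in rows])
    return X, y, [r.pair_id for r in rows]
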