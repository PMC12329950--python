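"""Readers, writers and the shared data model.

Dominant-marker fingerprinting data (ISSR/RAPD) are binary band-presence
matrices: rows are taxa (or population replicates of a taxon, labelled
``species/replicate``), columns are scored bands ("loci") that carry the
identity of the primer that produced them.  Sequence data (DNA barcodes,
cloned fragments, PCR templates) travel as FASTA.  Primer panels are small
delimited tables.

The band-matrix file dialect is: first column = taxon label, header row =
locus identifiers of the form ``<primer>:<band-id>`` (a bare identifier is
treated as a single-band primer), cells strictly ``0``/``1``.  The delimiter
is auto-detected among tab and comma unless given explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MergeError, ParseError, ValidationError

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
GAP = "-"

__all__ = [
    "Locus",
    "BandMatrix",
    "PrimerEntry",
    "PrimerPanel",
    "SequenceSet",
    "read_band_matrix",
    "write_band_matrix",
    "merge_band_matrices",
    "read_fasta",
    "write_fasta",
    "read_primer_panel",
]


@dataclass(frozen=True)
class Locus:
    """A scored band: the primer that produced it plus a band label."""

    primer: str
    band: str = ""

    @property
    def label(self) -> str:
        return f"{self.primer}:{self.band}" if self.band else self.primer


@dataclass
class BandMatrix:
    """Taxa x loci binary presence/absence table with primer provenance.

    ``taxa`` may be plain species labels or ``species/replicate`` labels;
    :attr:`replicate_group` maps each row to its grouping label (the part
    before ``/``, or the full label when there is no ``/``).
    """

    taxa: list[str]
    loci: list[Locus]
    values: np.ndarray  # shape (n_taxa, n_loci), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        if len(self.taxa) < 2:
            raise ValidationError("a band matrix needs at least 2 taxa")
        if len(self.loci) < 1:
            raise ValidationError("a band matrix needs at least 1 locus")
        if self.values.shape != (len(self.taxa), len(self.loci)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.loci)} loci"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        seen: set[tuple[str, str]] = set()
        for loc in self.loci:
            key = (loc.primer, loc.band)
            if key in seen:
                raise ValidationError(
                    f"duplicate locus {loc.label!r} within primer {loc.primer!r}"
                )
            seen.add(key)
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"cell ({r + 1},{c + 1}) is {self.values[r, c]}, not 0/1"
            )
        zero = ~self.values.any(axis=0)
        if zero.any():
            j = int(np.argmax(zero))
            raise ValidationError(
                f"locus {self.loci[j].label!r} is absent from every taxon; "
                "a never-observed band cannot be scored"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def replicate_group(self) -> list[str]:
        return [t.split("/", 1)[0] for t in self.taxa]

    @property
    def primers(self) -> list[str]:
        out: list[str] = []
        for loc in self.loci:
            if loc.primer not in out:
                out.append(loc.primer)
        return out

    def by_primer(self) -> dict[str, "BandMatrix"]:
        """Split into one matrix per primer, preserving locus order."""
        out: dict[str, BandMatrix] = {}
        for primer in self.primers:
            idx = [j for j, loc in enumerate(self.loci) if loc.primer == primer]
            out[primer] = BandMatrix(
                taxa=list(self.taxa),
                loci=[self.loci[j] for j in idx],
                values=self.values[:, idx].copy(),
            )
        return out

    def collapse(self) -> "BandMatrix":
        """Collapse replicate rows to one consensus row per group.

        A band is called present in a group when it is present in at least
        half of the group's replicate rows (majority vote, ties -> present),
        mirroring how a scorer reads a consistent band across replicate gel
        lanes.  A matrix without replicate labels is returned unchanged.
        """
        groups: list[str] = []
        for g in self.replicate_group:
            if g not in groups:
                groups.append(g)
        if len(groups) == len(self.taxa):
            return self
        rows = []
        for g in groups:
            idx = [i for i, gg in enumerate(self.replicate_group) if gg == g]
            sub = self.values[idx]
            rows.append((sub.sum(axis=0) * 2 >= len(idx)).astype(np.int8))
        return BandMatrix(taxa=groups, loci=list(self.loci), values=np.array(rows))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=self.taxa,
            columns=[loc.label for loc in self.loci],
        )


@dataclass(frozen=True)
class PrimerEntry:
    """One primer: name, 5'->3' IUPAC sequence, marker system, optional Tm."""

    name: str
    sequence: str
    system: str = "RAPD"  # ISSR | RAPD | SCAR
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValidationError(f"primer {self.name!r} has an empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"primer {self.name!r} contains non-IUPAC characters {sorted(bad)}"
            )


@dataclass
class PrimerPanel:
    entries: list[PrimerEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> PrimerEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class SequenceSet:
    """Ordered DNA records; ``aligned`` means equal lengths (gaps allowed)."""

    ids: list[str]
    seqs: list[str]
    descriptions: list[str] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.descriptions:
            self.descriptions = [""] * len(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids")
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        self.seqs = [s.upper() for s in self.seqs]
        if self.aligned:
            lengths = {len(s) for s in self.seqs}
            if len(lengths) > 1:
                raise ValidationError(
                    f"aligned set has unequal lengths {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    @property
    def n_sites(self) -> int:
        if not self.aligned:
            raise ValidationError("n_sites requires an aligned set")
        return len(self.seqs[0]) if self.seqs else 0


# ---------------------------------------------------------------------------
# band-matrix files
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _parse_locus(token: str) -> Locus:
    token = token.strip()
    if ":" in token:
        primer, band = token.split(":", 1)
        return Locus(primer.strip(), band.strip())
    return Locus(token)


def read_band_matrix(path: str | Path, delimiter: str | None = None) -> BandMatrix:
    """Read a delimited 0/1 band matrix (header = loci, first column = taxa)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty file")
    lines = text.splitlines()
    delim = _sniff_delimiter(lines[0], delimiter)
    rows = list(csv.reader(lines, delimiter=delim))
    header = rows[0]
    loci = [_parse_locus(tok) for tok in header[1:]]
    taxa: list[str] = []
    values: list[list[int]] = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {len(header)}"
            )
        taxon = row[0].strip()
        if taxon in taxa:
            raise ValidationError(f"{path}: duplicate taxon {taxon!r}")
        taxa.append(taxon)
        cells: list[int] = []
        for j, tok in enumerate(row[1:], start=1):
            tok = tok.strip()
            if tok not in ("0", "1"):
                raise ParseError(
                    f"{path}: cell at row {i}, column {j} is {tok!r}, expected 0 or 1"
                )
            cells.append(int(tok))
        values.append(cells)
    return BandMatrix(taxa=taxa, loci=loci, values=np.array(values, dtype=np.int8))


def write_band_matrix(matrix: BandMatrix, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["taxon"] + [loc.label for loc in matrix.loci])
        for taxon, row in zip(matrix.taxa, matrix.values):
            writer.writerow([taxon] + [str(int(v)) for v in row])


def merge_band_matrices(matrices: Sequence[BandMatrix]) -> BandMatrix:
    """Concatenate loci of matrices sharing an identical taxon list/order."""
    if not matrices:
        raise MergeError("no matrices to merge")
    first = matrices[0]
    for m in matrices[1:]:
        if m.taxa != first.taxa:
            extra = sorted(set(m.taxa) ^ set(first.taxa))
            detail = f"symmetric difference {extra}" if extra else "row order differs"
            raise MergeError(f"taxon lists do not match: {detail}")
    loci = [loc for m in matrices for loc in m.loci]
    values = np.hstack([m.values for m in matrices])
    return BandMatrix(taxa=list(first.taxa), loci=loci, values=values)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA; residues uppercased; aligned flag set on equal lengths."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate record ids")
    seqs = [str(r.seq).upper() for r in records]
    descs = [r.description[len(r.id):].strip() for r in records]
    aligned = len({len(s) for s in seqs}) == 1 and len(seqs) > 1
    return SequenceSet(ids=ids, seqs=seqs, descriptions=descs, aligned=aligned)


def write_fasta(sset: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description=d)
        for i, s, d in zip(sset.ids, sset.seqs, sset.descriptions)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# primer panels
# ---------------------------------------------------------------------------

def read_primer_panel(path: str | Path, delimiter: str | None = None) -> PrimerPanel:
    """Read a primer table: name, sequence[, system[, annealing_temp]]."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty file")
    lines = text.splitlines()
    delim = _sniff_delimiter(lines[0], delimiter)
    rows = list(csv.reader(lines, delimiter=delim))
    if rows and rows[0] and rows[0][0].lower() in ("name", "primer", "primer_name"):
        rows = rows[1:]
    entries = []
    for row in rows:
        if not row or not row[0].strip():
            continue
        name, seq = row[0].strip(), row[1].strip()
        system = row[2].strip() if len(row) > 2 and row[2].strip() else "RAPD"
        tm = float(row[3]) if len(row) > 3 and row[3].strip() else None
        entries.append(PrimerEntry(name, seq, system, tm))
    return PrimerPanel(entries)
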