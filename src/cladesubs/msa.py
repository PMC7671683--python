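"""Validated multiple sequence alignments, coordinate maps, and sequence weights.

The alignment is the coordinate system for every downstream call: columns
are 0-based internally, residue positions are reported 1-based in each
species' ungapped (precursor) sequence.  Position-based sequence weights
(Henikoff & Henikoff style) down-weight redundant sequences so that column
statistics are not dominated by over-represented lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .records import GAP, OrthologFamily

AMBIGUOUS = frozenset("XBZ")


class MsaValidationError(ValueError):
    """Raised for ragged alignments or rows inconsistent with family records."""


class UndefinedPositionError(ValueError):
    """Raised when a residue number is requested at a gap position."""


@dataclass
class Msa:
    """Equal-length gapped rows keyed by species."""

    gene_symbol: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaValidationError("alignment has no rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise MsaValidationError(
                f"ragged alignment for {self.gene_symbol!r}: row lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise MsaValidationError("alignment has zero columns")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def column(self, index: int) -> dict[str, str]:
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} out of range [0, {self.length})")
        return {sp: row[index] for sp, row in self.rows.items()}

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")


@dataclass(frozen=True)
class ColumnView:
    """One alignment column with its weighted gap fraction."""

    column_index: int
    residues: Mapping[str, str]
    gap_fraction: float


def load_msa(path: str | Path, family: OrthologFamily) -> Msa:
    """Read an aligned FASTA and validate it against the family's records.

    Every row's ungapped sequence must reproduce the resolved record for
    that species exactly; mismatches indicate the alignment was built from
    different inputs and are treated as errors, not warnings.
    """
    rows: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        species_id = entry.id.split("|")[0]
        rows[species_id] = str(entry.seq).upper()
    if not rows:
        raise MsaValidationError(f"{path}: no alignment rows")
    msa = Msa(family.gene_symbol, rows)
    for sp, row in msa.rows.items():
        rec = family.records.get(sp)
        if rec is None:
            raise MsaValidationError(
                f"{path}: alignment row for {sp!r} has no family record"
            )
        if row.replace(GAP, "") != rec.sequence:
            raise MsaValidationError(
                f"{path}: ungapped alignment row for {sp!r} does not match "
                f"the resolved record {rec.accession!r}"
            )
    return msa


def write_msa(msa: Msa, family: OrthologFamily, path: str | Path) -> None:
    """Write aligned FASTA using the ``species|accession|gene`` header dialect."""
    with open(path, "w") as fh:
        for sp in sorted(msa.rows):
            rec = family.records.get(sp)
            accession = rec.accession if rec else "NA"
            fh.write(f">{sp}|{accession}|{msa.gene_symbol}\n{msa.rows[sp]}\n")


def column_to_residue_number(msa: Msa, species: str, column: int) -> int:
    """Map an alignment column to a 1-based residue position in ``species``.

    Raises ``UndefinedPositionError`` if the species is gapped there: a gap
    has no precursor coordinate.
    """
    row = msa.rows[species]
    if not 0 <= column < msa.length:
        raise IndexError(f"column {column} out of range [0, {msa.length})")
    if row[column] == GAP:
        raise UndefinedPositionError(
            f"{species} is gapped at column {column}; no residue number"
        )
    return 1 + sum(1 for ch in row[:column] if ch != GAP)


def henikoff_weights(msa: Msa) -> dict[str, float]:
    """Position-based sequence weights, normalized to sum to 1.

    Per sequence the raw weight is the mean over columns of
    ``1 / (r_c * k_{c,a})`` where ``r_c`` is the number of distinct
    non-gap residue types in column ``c`` and ``k_{c,a}`` the number of
    sequences carrying this sequence's residue ``a`` there.  All-gap
    columns are skipped; at a sequence's own gap positions the neutral
    value ``1/n`` is contributed so gappy rows keep defined weights.
    """
    species = list(msa.rows)
    n = len(species)
    raw = {sp: 0.0 for sp in species}
    used_columns = 0
    for c in range(msa.length):
        col = [msa.rows[sp][c] for sp in species]
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue  # all-gap column carries no information
        used_columns += 1
        r = len(counts)
        for sp, ch in zip(species, col):
            raw[sp] += 1.0 / n if ch == GAP else 1.0 / (r * counts[ch])
    if used_columns == 0:
        raise MsaValidationError("alignment has no residue-bearing columns")
    total = sum(raw.values())
    return {sp: raw[sp] / total for sp in species}


def column_view(
    msa: Msa, column: int, weights: Mapping[str, float]
) -> ColumnView:
    """Build a ColumnView with the weighted gap fraction over all rows."""
    residues = msa.column(column)
    return ColumnView(column, residues, gap_fraction(residues, weights))


def gap_fraction(residues: Mapping[str, str], weights: Mapping[str, float]) -> float:
    """Summed weight of gapped sequences in a column (weights must cover it)."""
    missing = set(residues) - set(weights)
    if missing:
        raise ValueError(f"weights missing for species {sorted(missing)}")
    return sum(weights[sp] for sp, ch in residues.items() if ch == GAP)
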