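"""Ortholog record ingest and per-species resolution.

Candidate protein records for a gene (several isoforms or database entries
per species) are read from FASTA, optionally filtered against a table of
accepted gene aliases, and collapsed to exactly one record per species by
maximum mean percent identity against a set of accepted reference
sequences (typically human, mouse, and one foreground species).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

#: 20 standard residues plus the ambiguity letters accepted on input.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "XBZ"
VALID_RESIDUES = frozenset(STANDARD_RESIDUES + AMBIGUOUS_RESIDUES)

GAP = "-"


class FastaDialectError(ValueError):
    """Raised when a FASTA entry violates the ``species|accession|gene`` header dialect."""


class SequenceValidationError(ValueError):
    """Raised when a protein sequence is empty, gapped, or non-amino-acid."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One candidate protein record for one species."""

    species_id: str
    accession: str
    gene_symbol: str
    sequence: str
    source: str = "reference-db"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise SequenceValidationError("species_id must be non-empty")
        if not self.sequence:
            raise SequenceValidationError(
                f"record {self.accession!r}: empty sequence"
            )
        if GAP in self.sequence:
            raise SequenceValidationError(
                f"record {self.accession!r}: sequence contains gap characters"
            )
        bad = set(self.sequence.upper()) - VALID_RESIDUES
        if bad:
            raise SequenceValidationError(
                f"record {self.accession!r}: invalid residue letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SpeciesConfig:
    """Foreground clade, ordered outgroup panel, and identity-anchor species.

    The default study design compares a two-species ground-squirrel
    foreground (Arctic and 13-lined ground squirrel) against nine other
    mammals, resolving records against human, mouse, and 13LGS references.
    """

    foreground_species: tuple[str, ...]
    outgroup_species: tuple[str, ...]
    reference_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.foreground_species:
            raise ValueError("foreground clade must contain at least one species")
        fg, og = set(self.foreground_species), set(self.outgroup_species)
        if fg & og:
            raise ValueError(f"foreground and outgroup overlap: {sorted(fg & og)}")
        extra = set(self.reference_species) - (fg | og)
        if extra:
            raise ValueError(
                f"reference species not in foreground or outgroup: {sorted(extra)}"
            )

    @property
    def all_species(self) -> tuple[str, ...]:
        return tuple(self.foreground_species) + tuple(self.outgroup_species)


@dataclass
class OrthologFamily:
    """One resolved record per species for a single gene."""

    gene_symbol: str
    records: dict[str, SpeciesRecord]
    config: SpeciesConfig

    def __post_init__(self) -> None:
        for sp, rec in self.records.items():
            if rec.species_id != sp:
                raise ValueError(f"record keyed {sp!r} has species_id {rec.species_id!r}")
            if rec.gene_symbol.upper() != self.gene_symbol.upper():
                raise ValueError(
                    f"record {rec.accession!r} gene {rec.gene_symbol!r} does not "
                    f"match family gene {self.gene_symbol!r}"
                )

    @property
    def missing_foreground(self) -> tuple[str, ...]:
        return tuple(
            sp for sp in self.config.foreground_species if sp not in self.records
        )


@dataclass
class AliasTable:
    """Accepted gene aliases, matched case-insensitively after trimming."""

    aliases: dict[str, frozenset[str]] = field(default_factory=dict)

    @staticmethod
    def _norm(s: str) -> str:
        return s.strip().upper()

    def for_gene(self, gene: str) -> frozenset[str]:
        return self.aliases.get(self._norm(gene), frozenset())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        """Read a two-column TSV: gene symbol, alias (one alias per line)."""
        table: dict[str, set[str]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>alias")
            gene, alias = cls._norm(parts[0]), cls._norm(parts[1])
            table.setdefault(gene, set()).add(alias)
            table[gene].add(gene)
        return cls({g: frozenset(a) for g, a in table.items()})


def parse_family_fasta(path: str | Path, config: SpeciesConfig) -> list[SpeciesRecord]:
    """Read candidate records from FASTA with ``species_id|accession|gene_symbol`` headers.

    Entries for species absent from ``config`` are retained with source tag
    ``"unknown"`` and a warning, so that upstream panel mistakes surface in
    logs rather than silently shrinking families.
    """
    path = Path(path)
    known = set(config.all_species)
    records: list[SpeciesRecord] = []
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        parts = entry.id.split("|")
        if len(parts) != 3 or not all(parts):
            raise FastaDialectError(
                f"{path} entry {i} ({entry.id!r}): header must be "
                "'species_id|accession|gene_symbol'"
            )
        species_id, accession, gene_symbol = parts
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaDialectError(f"{path} entry {i} ({entry.id!r}): empty sequence")
        if species_id in config.foreground_species:
            source = "foreground-db"
        elif species_id in known:
            source = "reference-db"
        else:
            logger.warning("%s entry %d: unknown species %r", path, i, species_id)
            source = "unknown"
        records.append(
            SpeciesRecord(species_id, accession, gene_symbol, seq, source)
        )
    if not records:
        raise FastaDialectError(f"{path}: no FASTA entries found")
    return records


def filter_by_alias(
    records: Iterable[SpeciesRecord], gene: str, aliases: AliasTable
) -> list[SpeciesRecord]:
    """Keep records whose gene symbol is an accepted alias of ``gene``.

    An empty alias set for the gene keeps everything (with a warning):
    filtering is an optional guard against mis-annotated database records,
    not a hard requirement.
    """
    accepted = aliases.for_gene(gene)
    records = list(records)
    if not accepted:
        logger.warning("no aliases for gene %r; keeping all %d records", gene, len(records))
        return records
    kept = []
    for rec in records:
        if AliasTable._norm(rec.gene_symbol) in accepted:
            kept.append(rec)
        else:
            logger.info(
                "dropping %s (%s): gene symbol %r not in accepted aliases of %r",
                rec.accession, rec.species_id, rec.gene_symbol, gene,
            )
    return kept


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity of two ungapped protein sequences.

    Needleman–Wunsch with BLOSUM62 scoring (gap open 11, extend 1);
    identity = identical aligned pairs / alignment length, counting gapped
    columns in the denominator.  The pair is lexicographically ordered
    before aligning so the result is exactly symmetric even when
    co-optimal alignments exist.
    """
    if not a or not b:
        raise SequenceValidationError("percent_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != GAP for x, y in zip(row_a, row_b))
    return matches / len(row_a)


def resolve_species_records(
    candidates: list[SpeciesRecord], references: list[SpeciesRecord]
) -> SpeciesRecord:
    """Pick the one candidate with maximum mean percent identity to the references.

    Ties break by longer sequence, then lexicographically smallest
    accession, so resolution is invariant to candidate order.
    """
    if not candidates:
        raise ValueError("no candidate records to resolve")
    if not references:
        raise ValueError("no reference records for identity resolution")
    if len(candidates) == 1:
        return candidates[0]

    def key(rec: SpeciesRecord) -> tuple[float, int, str]:
        mean_pid = sum(
            percent_identity(rec.sequence, ref.sequence) for ref in references
        ) / len(references)
        # accession negated via sort direction below; build a max-key
        return (mean_pid, len(rec.sequence), rec.accession)

    scored = [(key(rec), rec) for rec in candidates]
    scored.sort(key=lambda kr: (-kr[0][0], -kr[0][1], kr[0][2]))
    return scored[0][1]


def assemble_family(
    gene: str,
    records: Iterable[SpeciesRecord],
    config: SpeciesConfig,
    reference_sequences: Mapping[str, str] | None = None,
) -> OrthologFamily:
    """Group candidates by species and resolve one record per species.

    ``reference_sequences`` optionally supplies accepted anchor sequences
    keyed by species; by default the single (or resolved-first) candidates
    of ``config.reference_species`` are used as anchors.
    """
    by_species: dict[str, list[SpeciesRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)

    if reference_sequences:
        refs = [
            SpeciesRecord(sp, f"ref-{sp}", gene, seq, "reference-db")
            for sp, seq in sorted(reference_sequences.items())
        ]
    else:
        refs = []
        for sp in config.reference_species:
            cands = by_species.get(sp, [])
            if len(cands) == 1:
                refs.append(cands[0])
            elif len(cands) > 1:
                # anchor on the longest candidate; smallest accession breaks ties
                refs.append(
                    sorted(cands, key=lambda r: (-len(r.sequence), r.accession))[0]
                )
    if not refs:
        raise ValueError(
            f"gene {gene!r}: no reference sequences available for resolution"
        )

    resolved: dict[str, SpeciesRecord] = {}
    for sp in config.all_species:
        cands = by_species.get(sp)
        if not cands:
            continue
        resolved[sp] = resolve_species_records(cands, refs)
    return OrthologFamily(gene, resolved, config)
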