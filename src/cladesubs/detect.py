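"""Foreground-clade-unique substitution and indel calling.

A substitution call is an alignment column where every foreground species
shows the same standard residue and that residue appears in no informative
outgroup species — the variant is "present in the foreground clade and in
no other included species".  An indel event is a maximal run of columns
gapped in exactly one of the two groups.

Ambiguity letters (X, B, Z) block a call when they occur in the
foreground; in the outgroup they are dropped from the informative set,
counting neither as a match nor a mismatch.  A minimum number of
informative outgroup species (default 5 of 9) guards against calls driven
by missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .msa import AMBIGUOUS, Msa, column_to_residue_number
from .records import GAP, STANDARD_RESIDUES, SpeciesConfig

_STANDARD = frozenset(STANDARD_RESIDUES)

DEFAULT_MIN_OUTGROUP = 5


@dataclass(frozen=True)
class SubstitutionCall:
    """A foreground-unique residue site in precursor and alignment coordinates."""

    gene_symbol: str
    column_index: int
    foreground_residue: str
    outgroup_residues: tuple[str, ...]  # one per informative outgroup species, panel order
    foreground_positions: dict[str, int] = field(hash=False, default_factory=dict)

    @property
    def outgroup_consensus(self) -> str:
        """Most common informative outgroup residue (ties: alphabetical)."""
        counts: dict[str, int] = {}
        for ch in self.outgroup_residues:
            counts[ch] = counts.get(ch, 0) + 1
        return min(counts, key=lambda ch: (-counts[ch], ch))


@dataclass(frozen=True)
class IndelCall:
    """A maximal foreground-specific gap run, half-open in alignment columns."""

    gene_symbol: str
    column_start: int
    column_end: int
    kind: str  # "foreground-deletion" | "foreground-insertion"

    @property
    def length(self) -> int:
        return self.column_end - self.column_start


def _require_foreground(msa: Msa, config: SpeciesConfig) -> None:
    missing = [sp for sp in config.foreground_species if sp not in msa.rows]
    if missing:
        raise ValueError(
            f"{msa.gene_symbol}: foreground species {missing} absent from alignment; "
            "families missing foreground species must be excluded upstream"
        )


def detect_foreground_substitutions(
    msa: Msa,
    config: SpeciesConfig,
    min_outgroup: int = DEFAULT_MIN_OUTGROUP,
) -> list[SubstitutionCall]:
    """Call columns where the foreground clade shares a residue absent from the outgroup.

    A column is called iff (a) every foreground species shows the same
    standard residue (no gap, no ambiguity letter); (b) no informative
    outgroup species shows that residue; (c) at least ``min_outgroup``
    outgroup species are informative (standard residue, non-gap) there.
    """
    _require_foreground(msa, config)
    calls: list[SubstitutionCall] = []
    outgroup_present = [sp for sp in config.outgroup_species if sp in msa.rows]
    for c in range(msa.length):
        fg = {sp: msa.rows[sp][c] for sp in config.foreground_species}
        fg_residues = set(fg.values())
        if len(fg_residues) != 1:
            continue
        residue = next(iter(fg_residues))
        if residue not in _STANDARD:
            continue
        informative = [
            (sp, msa.rows[sp][c])
            for sp in outgroup_present
            if msa.rows[sp][c] in _STANDARD
        ]
        if len(informative) < min_outgroup:
            continue
        if any(ch == residue for _, ch in informative):
            continue
        calls.append(
            SubstitutionCall(
                gene_symbol=msa.gene_symbol,
                column_index=c,
                foreground_residue=residue,
                outgroup_residues=tuple(ch for _, ch in informative),
                foreground_positions={
                    sp: column_to_residue_number(msa, sp, c)
                    for sp in config.foreground_species
                },
            )
        )
    return calls


def detect_partial_substitutions(
    msa: Msa,
    config: SpeciesConfig,
    min_outgroup: int = DEFAULT_MIN_OUTGROUP,
) -> list[SubstitutionCall]:
    """Diagnostic listing of near-miss sites: outgroup-absent residues carried by
    some but not all foreground species.  Never scored."""
    _require_foreground(msa, config)
    outgroup_present = [sp for sp in config.outgroup_species if sp in msa.rows]
    partial: list[SubstitutionCall] = []
    for c in range(msa.length):
        fg = {sp: msa.rows[sp][c] for sp in config.foreground_species}
        fg_residues = {ch for ch in fg.values() if ch in _STANDARD}
        if len(fg_residues) < 1 or len(set(fg.values())) == 1:
            continue
        informative = [
            (sp, msa.rows[sp][c])
            for sp in outgroup_present
            if msa.rows[sp][c] in _STANDARD
        ]
        if len(informative) < min_outgroup:
            continue
        for residue in sorted(fg_residues):
            carriers = [sp for sp, ch in fg.items() if ch == residue]
            if not carriers or any(ch == residue for _, ch in informative):
                continue
            partial.append(
                SubstitutionCall(
                    gene_symbol=msa.gene_symbol,
                    column_index=c,
                    foreground_residue=residue,
                    outgroup_residues=tuple(ch for _, ch in informative),
                    foreground_positions={
                        sp: column_to_residue_number(msa, sp, c) for sp in carriers
                    },
                )
            )
    return partial


def detect_foreground_indels(msa: Msa, config: SpeciesConfig) -> list[IndelCall]:
    """Call maximal runs of columns gapped in exactly one group.

    ``foreground-deletion``: all foreground gapped, all outgroup
    residue-bearing.  ``foreground-insertion``: all outgroup gapped, all
    foreground residue-bearing.  A column where any member of the
    "residue-bearing" group is also gapped is not foreground-specific and
    breaks the run.
    """
    _require_foreground(msa, config)
    outgroup_present = [sp for sp in config.outgroup_species if sp in msa.rows]

    def pattern(c: int) -> str | None:
        fg_gapped = [msa.rows[sp][c] == GAP for sp in config.foreground_species]
        og_gapped = [msa.rows[sp][c] == GAP for sp in outgroup_present]
        if all(fg_gapped) and og_gapped and not any(og_gapped):
            return "foreground-deletion"
        if og_gapped and all(og_gapped) and not any(fg_gapped):
            return "foreground-insertion"
        return None

    calls: list[IndelCall] = []
    c = 0
    while c < msa.length:
        kind = pattern(c)
        if kind is None:
            c += 1
            continue
        start = c
        while c < msa.length and pattern(c) == kind:
            c += 1
        calls.append(IndelCall(msa.gene_symbol, start, c, kind))
    return calls
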