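"""Synthetic ortholog families with planted, fully-known ground truth.

The simulator emulates what the scoring pipeline actually consumes —
per-column residue compositions of an 11-species mammalian panel — rather
than sequence evolution along a tree.  Each family gets:

* per-column outgroup conservation drawn from a two-point
  conserved/variable mix (a column's residues are the consensus with
  probability equal to its conservation level, otherwise background
  draws);
* planted foreground-unique substitutions whose BLOSUM62 score against
  the outgroup consensus falls in a controlled severity range and whose
  residue is guaranteed absent from the outgroup column;
* planted foreground-specific indels as maximal gap runs;
* optional nuisance features: missing outgroup species, decoy isoform
  records (the true record with 5% of residues mutated), and ambiguous
  X residues.

Homoplasy is excluded by construction: at every non-planted column at
least one outgroup sequence carries the consensus residue the foreground
copies, so the planted truth table is exactly the set of callable sites.
Generation is a pure function of (seed, family_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .msa import Msa
from .records import (
    GAP,
    STANDARD_RESIDUES,
    OrthologFamily,
    SpeciesConfig,
    SpeciesRecord,
)
from .scoring import background_distribution

#: Default 11-species panel mirroring a two-ground-squirrel foreground
#: (Arctic and 13-lined ground squirrel) against nine other mammals.
DEFAULT_PANEL = SpeciesConfig(
    foreground_species=("ags", "itri"),
    outgroup_species=(
        "mmus", "rnor", "sara", "pabe", "hsap", "ecab", "btau", "ocun", "sscr"
    ),
    reference_species=("hsap", "mmus", "itri"),
)

_RESIDUES = np.array(list(STANDARD_RESIDUES))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic ortholog generator."""

    n_families: int = 100
    n_columns: int = 300
    species_panel: SpeciesConfig = DEFAULT_PANEL
    conserved_fraction: float = 0.5
    conservation_high: float = 0.98
    conservation_low: float = 0.6
    n_planted_substitutions: int = 1
    severity_range: tuple[float, float] = (-4.0, -1.0)
    planted_conservation: float | None = None
    n_planted_indels: int = 1
    indel_max_length: int = 3
    p_missing_species: float = 0.0
    p_extra_isoform: float = 0.0
    p_ambiguous: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_planted_substitutions < 0 or self.n_planted_indels < 0:
            raise ValueError("counts must be non-negative")
        if self.n_columns <= 0:
            raise ValueError("n_columns must be positive")
        for p in (self.p_missing_species, self.p_extra_isoform, self.p_ambiguous,
                  self.conserved_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedSubstitution:
    gene_symbol: str
    column: int
    foreground_residue: str
    outgroup_consensus: str
    severity: float  # BLOSUM62 score of foreground residue vs consensus
    conservation: float  # per-column conservation level used


@dataclass(frozen=True)
class PlantedIndel:
    gene_symbol: str
    column_start: int
    column_end: int
    kind: str


@dataclass
class PlantedTruth:
    """Ground truth for one family or a combined dataset."""

    substitutions: list[PlantedSubstitution] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)

    def extend(self, other: "PlantedTruth") -> None:
        self.substitutions.extend(other.substitutions)
        self.indels.extend(other.indels)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#cladesubs planted truth v1\n")
            fh.write("event\tgene\tcolumn_start\tcolumn_end\tforeground_residue\t"
                     "outgroup_consensus\tseverity\tconservation\tkind\n")
            for s in self.substitutions:
                fh.write(
                    f"substitution\t{s.gene_symbol}\t{s.column}\t{s.column + 1}\t"
                    f"{s.foreground_residue}\t{s.outgroup_consensus}\t"
                    f"{s.severity:g}\t{s.conservation:g}\t.\n"
                )
            for i in self.indels:
                fh.write(
                    f"indel\t{i.gene_symbol}\t{i.column_start}\t{i.column_end}\t"
                    f".\t.\t.\t.\t{i.kind}\n"
                )


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, family_index]))


def _draw_background(rng: np.random.Generator, bg_p: np.ndarray, size: int) -> np.ndarray:
    return _RESIDUES[rng.choice(len(_RESIDUES), size=size, p=bg_p)]


def simulate_family(
    config: SimulationConfig, family_index: int
) -> tuple[OrthologFamily, Msa, PlantedTruth]:
    """Generate one family; byte-identical for identical (seed, family_index)."""
    rng = _family_rng(config.seed, family_index)
    panel = config.species_panel
    gene = f"SYNGENE{family_index:04d}"
    matrix = substitution_matrices.load("BLOSUM62")
    bg = background_distribution("blosum62")
    bg_p = np.array([bg[a] for a in STANDARD_RESIDUES])

    outgroup = list(panel.outgroup_species)
    present_outgroup = [
        sp for sp in outgroup if rng.random() >= config.p_missing_species
    ]
    # never let the informative panel collapse entirely
    if not present_outgroup:
        present_outgroup = [outgroup[int(rng.integers(len(outgroup)))]]
    foreground = list(panel.foreground_species)
    species = foreground + present_outgroup

    n_cols = config.n_columns
    # reserve non-overlapping, non-adjacent column ranges for indels first,
    # then distinct single columns for substitutions
    blocked = np.zeros(n_cols, dtype=bool)
    indel_plan: list[tuple[int, int, str]] = []
    for j in range(config.n_planted_indels):
        length = int(rng.integers(1, config.indel_max_length + 1))
        for _ in range(200):
            start = int(rng.integers(0, n_cols - length + 1))
            lo, hi = max(0, start - 1), min(n_cols, start + length + 1)
            if not blocked[lo:hi].any():
                kind = "foreground-deletion" if j % 2 == 0 else "foreground-insertion"
                indel_plan.append((start, start + length, kind))
                blocked[lo:hi] = True
                break
        else:
            raise RuntimeError("could not place planted indel; alignment too small")
    sub_columns: list[int] = []
    for _ in range(config.n_planted_substitutions):
        for _ in range(500):
            c = int(rng.integers(0, n_cols))
            if not blocked[c]:
                sub_columns.append(c)
                blocked[c] = True
                break
        else:
            raise RuntimeError("could not place planted substitution")
    sub_columns.sort()
    indel_plan.sort()

    indel_cols: dict[int, str] = {}
    for start, end, kind in indel_plan:
        for c in range(start, end):
            indel_cols[c] = kind

    if config.planted_conservation is not None:
        planted_level = config.planted_conservation
    else:
        planted_level = None  # drawn per column like any other

    columns: dict[str, list[str]] = {sp: [] for sp in species}
    truth = PlantedTruth()
    for start, end, kind in indel_plan:
        truth.indels.append(PlantedIndel(gene, start, end, kind))

    for c in range(n_cols):
        kind = indel_cols.get(c)
        if kind is not None:
            residues = _draw_background(rng, bg_p, len(species))
            for i, sp in enumerate(species):
                fg = sp in foreground
                gapped = (kind == "foreground-deletion") == fg
                columns[sp].append(GAP if gapped else str(residues[i]))
            continue

        level = (
            config.conservation_high
            if rng.random() < config.conserved_fraction
            else config.conservation_low
        )
        if c in sub_columns and planted_level is not None:
            level = planted_level
        consensus = str(_draw_background(rng, bg_p, 1)[0])

        if c in sub_columns:
            consensus, fg_res, og_res = _plant_substitution(
                rng, matrix, bg_p, consensus, level, len(present_outgroup),
                config.severity_range,
            )
            truth.substitutions.append(
                PlantedSubstitution(
                    gene, c, fg_res, consensus,
                    float(matrix[fg_res, consensus]), level,
                )
            )
            for sp in foreground:
                columns[sp].append(fg_res)
            for sp, ch in zip(present_outgroup, og_res):
                columns[sp].append(ch)
        else:
            og_res = _draw_column(rng, bg_p, consensus, level, len(present_outgroup))
            if consensus not in og_res:
                # force the consensus into one outgroup row so the
                # foreground (which copies it) is never accidentally unique
                og_res[int(rng.integers(len(og_res)))] = consensus
            for sp in foreground:
                columns[sp].append(consensus)
            for sp, ch in zip(present_outgroup, og_res):
                columns[sp].append(ch)

    rows = {sp: "".join(chars) for sp, chars in columns.items()}
    if config.p_ambiguous > 0.0:
        protected = set(sub_columns)
        rows = {
            sp: _sprinkle_ambiguity(
                rng, row, config.p_ambiguous,
                protected if sp in foreground else frozenset(),
            )
            for sp, row in rows.items()
        }
    msa = Msa(gene, rows)

    records: dict[str, SpeciesRecord] = {}
    decoys: dict[str, SpeciesRecord] = {}
    for sp in species:
        seq = rows[sp].replace(GAP, "")
        source = "foreground-db" if sp in foreground else "synthetic"
        records[sp] = SpeciesRecord(sp, f"SYN-{sp}-{family_index:04d}-1", gene, seq, source)
        if rng.random() < config.p_extra_isoform:
            decoys[sp] = SpeciesRecord(
                sp, f"SYN-{sp}-{family_index:04d}-2", gene,
                _mutate(rng, seq, 0.05), "synthetic",
            )
    family = OrthologFamily(gene, records, panel)
    family.decoys = decoys  # extra candidate records, for ingest-stage tests
    return family, msa, truth


def _draw_column(
    rng: np.random.Generator, bg_p: np.ndarray, consensus: str, level: float, n: int
) -> list[str]:
    keep = rng.random(n) < level
    alt = _draw_background(rng, bg_p, n)
    return [consensus if k else str(a) for k, a in zip(keep, alt)]


def _plant_substitution(
    rng: np.random.Generator,
    matrix,
    bg_p: np.ndarray,
    consensus: str,
    level: float,
    n_outgroup: int,
    severity_range: tuple[float, float],
    max_retries: int = 50,
):
    """Pick (consensus, foreground residue, outgroup column) such that the
    foreground residue scores within severity_range vs the consensus and is
    absent from every outgroup row."""
    lo, hi = severity_range
    for _ in range(max_retries):
        choices = [
            a for a in STANDARD_RESIDUES
            if a != consensus and lo <= matrix[a, consensus] <= hi
        ]
        if not choices:
            consensus = str(_draw_background(rng, bg_p, 1)[0])
            continue
        fg_res = choices[int(rng.integers(len(choices)))]
        for _ in range(max_retries):
            og = _draw_column(rng, bg_p, consensus, level, n_outgroup)
            if fg_res not in og:
                return consensus, fg_res, og
        consensus = str(_draw_background(rng, bg_p, 1)[0])
    raise RuntimeError(
        f"severity range {severity_range} unsatisfiable after {max_retries} retries"
    )


def _sprinkle_ambiguity(
    rng: np.random.Generator, row: str, p: float, protected: frozenset[int] | set[int]
) -> str:
    chars = list(row)
    for i, ch in enumerate(chars):
        if ch != GAP and i not in protected and rng.random() < p:
            chars[i] = "X"
    return "".join(chars)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_mut = max(1, int(round(rate * len(chars))))
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for i in positions:
        alternatives = [a for a in STANDARD_RESIDUES if a != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[tuple[OrthologFamily, Msa]], PlantedTruth]:
    """Generate ``n_families`` independent families with a combined truth table."""
    families: list[tuple[OrthologFamily, Msa]] = []
    truth = PlantedTruth()
    for i in range(config.n_families):
        family, msa, fam_truth = simulate_family(config, i)
        families.append((family, msa))
        truth.extend(fam_truth)
    return families, truth


def write_dataset(
    families: list[tuple[OrthologFamily, Msa]],
    truth: PlantedTruth,
    outdir: str | Path,
) -> dict[str, dict[str, str]]:
    """Write per-gene FASTA + aligned FASTA and the truth TSV; return a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for family, msa in families:
        gene = family.gene_symbol
        fasta = outdir / f"{gene}.fasta"
        afa = outdir / f"{gene}.afa"
        with open(fasta, "w") as fh:
            for sp in sorted(family.records):
                rec = family.records[sp]
                fh.write(f">{sp}|{rec.accession}|{gene}\n{rec.sequence}\n")
            for sp in sorted(getattr(family, "decoys", {})):
                rec = family.decoys[sp]
                fh.write(f">{sp}|{rec.accession}|{gene}\n{rec.sequence}\n")
        with open(afa, "w") as fh:
            for sp in sorted(msa.rows):
                rec = family.records[sp]
                fh.write(f">{sp}|{rec.accession}|{gene}\n{msa.rows[sp]}\n")
        manifest[gene] = {"fasta": str(fasta), "msa": str(afa)}
    truth.to_tsv(outdir / "truth.tsv")
    return manifest
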