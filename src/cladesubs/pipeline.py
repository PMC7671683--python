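"""End-to-end orchestration: ingest -> resolve -> align/load -> detect -> score -> rank.

Per gene the pipeline alias-filters candidate records, resolves one
record per species, loads (or produces via an aligner adapter) the MSA,
calls foreground-unique substitutions and indels, and scores them; all
genes are then pooled, percentile-ranked, and the top fraction flagged.
Outputs are diff-able versioned TSV reports plus a JSON run summary, and
two runs with identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .align import Aligner, validate_aligned
from .detect import (
    DEFAULT_MIN_OUTGROUP,
    IndelCall,
    detect_foreground_indels,
    detect_foreground_substitutions,
)
from .msa import Msa, henikoff_weights, load_msa
from .records import (
    AliasTable,
    OrthologFamily,
    SpeciesConfig,
    assemble_family,
    filter_by_alias,
    parse_family_fasta,
)
from .scoring import ScoredSubstitution, ScoringConfig, rank_and_flag, score_substitutions

logger = logging.getLogger(__name__)

REPORT_VERSION = "cladesubs report v1"


@dataclass
class GeneInput:
    gene_symbol: str
    fasta_path: Path
    msa_path: Path | None = None


@dataclass
class RunConfig:
    genes: list[GeneInput]
    species: SpeciesConfig
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    alias_table: AliasTable | None = None
    min_outgroup: int = DEFAULT_MIN_OUTGROUP
    genes_of_interest: tuple[str, ...] = ()
    aligner: Aligner | None = None
    output_dir: Path | None = None


@dataclass
class RunResult:
    scored: list[ScoredSubstitution]
    indels: list[IndelCall]
    summary: dict

    @property
    def flagged(self) -> list[ScoredSubstitution]:
        return [s for s in self.scored if s.flagged]


def process_gene(
    gene: GeneInput,
    config: RunConfig,
) -> tuple[OrthologFamily, Msa] | None:
    """Ingest and resolve one gene; returns None (with a logged reason) on skip."""
    records = parse_family_fasta(gene.fasta_path, config.species)
    if config.alias_table is not None:
        records = filter_by_alias(records, gene.gene_symbol, config.alias_table)
        if not records:
            logger.warning("%s: no records survive alias filtering", gene.gene_symbol)
            return None
    family = assemble_family(gene.gene_symbol, records, config.species)
    if family.missing_foreground:
        logger.warning(
            "%s: skipped, missing foreground species %s",
            gene.gene_symbol, list(family.missing_foreground),
        )
        return None
    if gene.msa_path is not None:
        msa = load_msa(gene.msa_path, family)
    elif config.aligner is not None:
        msa = _align_family(family, config.aligner)
    else:
        raise ValueError(
            f"{gene.gene_symbol}: no MSA path given and no aligner configured"
        )
    return family, msa


def _align_family(family: OrthologFamily, aligner: Aligner) -> Msa:
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "in.fasta"
        fasta_out = Path(tmp) / "out.afa"
        with open(fasta_in, "w") as fh:
            for sp in sorted(family.records):
                rec = family.records[sp]
                fh.write(f">{sp}|{rec.accession}|{family.gene_symbol}\n{rec.sequence}\n")
        aligner(fasta_in, fasta_out)
        validate_aligned(fasta_in, fasta_out)
        return load_msa(fasta_out, family)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis over the manifest and pool results across genes."""
    scored_all: list[ScoredSubstitution] = []
    indels_all: list[IndelCall] = []
    skipped: list[dict] = []
    per_gene_counts: dict[str, dict[str, int]] = {}

    for gene in config.genes:
        try:
            result = process_gene(gene, config)
        except (ValueError, OSError) as exc:
            logger.warning("%s: skipped (%s)", gene.gene_symbol, exc)
            skipped.append({"gene": gene.gene_symbol, "reason": str(exc)})
            continue
        if result is None:
            skipped.append(
                {"gene": gene.gene_symbol, "reason": "missing foreground species or empty after filtering"}
            )
            continue
        family, msa = result
        weights = henikoff_weights(msa)
        calls = detect_foreground_substitutions(msa, config.species, config.min_outgroup)
        indels = detect_foreground_indels(msa, config.species)
        scored = score_substitutions(
            msa, calls, weights, config.scoring, species_config=config.species
        )
        scored_all.extend(scored)
        indels_all.extend(indels)
        per_gene_counts[gene.gene_symbol] = {
            "records": len(family.records),
            "substitution_calls": len(calls),
            "indel_calls": len(indels),
        }
        logger.info(
            "%s: %d substitution calls, %d indel events",
            gene.gene_symbol, len(calls), len(indels),
        )

    if not scored_all:
        raise ValueError("no substitutions called across the whole run; nothing to rank")
    scored_all = rank_and_flag(scored_all, config.scoring)
    # deterministic output order: gene, then column
    scored_all.sort(key=lambda s: (s.call.gene_symbol, s.call.column_index))
    indels_all.sort(key=lambda i: (i.gene_symbol, i.column_start))

    summary = {
        "report_version": REPORT_VERSION,
        "n_genes_input": len(config.genes),
        "n_genes_scored": len(per_gene_counts),
        "n_genes_skipped": len(skipped),
        "skipped": sorted(skipped, key=lambda d: d["gene"]),
        "n_substitutions": len(scored_all),
        "n_indels": len(indels_all),
        "n_flagged": sum(s.flagged for s in scored_all),
        "per_gene": {g: per_gene_counts[g] for g in sorted(per_gene_counts)},
    }
    result = RunResult(scored_all, indels_all, summary)
    if config.output_dir is not None:
        write_reports(result, config, config.output_dir)
    return result


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_reports(result: RunResult, config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Write substitution/indel/scatter TSVs and the JSON run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "substitutions": outdir / "substitutions.tsv",
        "indels": outdir / "indels.tsv",
        "scatter": outdir / "scatter.tsv",
        "summary": outdir / "run_summary.json",
    }
    fg_species = list(config.species.foreground_species)
    with open(paths["substitutions"], "w") as fh:
        fh.write(f"#{REPORT_VERSION}\n")
        pos_cols = "\t".join(f"pos_{sp}" for sp in fg_species)
        fh.write(
            "gene\tcolumn\tforeground_residue\t" + pos_cols +
            "\toutgroup_consensus\toutgroup_residues\tjsd\tmean_blosum\t"
            "jsd_percentile\tblosum_percentile\tcomposite\tflagged\n"
        )
        for s in result.scored:
            call = s.call
            positions = "\t".join(
                str(call.foreground_positions.get(sp, ".")) for sp in fg_species
            )
            fh.write(
                f"{call.gene_symbol}\t{call.column_index}\t{call.foreground_residue}\t"
                f"{positions}\t{call.outgroup_consensus}\t"
                f"{''.join(call.outgroup_residues)}\t{_fmt(s.jsd)}\t{_fmt(s.mean_blosum)}\t"
                f"{_fmt(s.jsd_percentile)}\t{_fmt(s.blosum_percentile)}\t"
                f"{_fmt(s.composite)}\t{int(s.flagged)}\n"
            )
    with open(paths["indels"], "w") as fh:
        fh.write(f"#{REPORT_VERSION}\n")
        fh.write("gene\tcolumn_start\tcolumn_end\tlength\tkind\n")
        for i in result.indels:
            fh.write(
                f"{i.gene_symbol}\t{i.column_start}\t{i.column_end}\t{i.length}\t{i.kind}\n"
            )
    scatter = export_scatter(result.scored, config.genes_of_interest)
    with open(paths["scatter"], "w") as fh:
        fh.write(f"#{REPORT_VERSION}\n")
        fh.write("gene\tcolumn\tjsd\tmean_blosum\tflagged\thighlight\n")
        for row in scatter:
            fh.write(
                f"{row['gene']}\t{row['column']}\t{_fmt(row['jsd'])}\t"
                f"{_fmt(row['mean_blosum'])}\t{int(row['flagged'])}\t{int(row['highlight'])}\n"
            )
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def export_scatter(
    scored: Sequence[ScoredSubstitution], genes_of_interest: Sequence[str] = ()
) -> list[dict]:
    """One row per substitution with the two plot axes, the top-fraction flag,
    and a highlight mark for user-designated genes of interest."""
    if not scored:
        raise ValueError("no scored substitutions to export")
    goi = {g.upper() for g in genes_of_interest}
    return [
        {
            "gene": s.call.gene_symbol,
            "column": s.call.column_index,
            "jsd": s.jsd,
            "mean_blosum": s.mean_blosum,
            "flagged": s.flagged,
            "highlight": s.call.gene_symbol.upper() in goi,
        }
        for s in scored
    ]
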