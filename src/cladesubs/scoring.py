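"""Conservation and divergence scoring of foreground-unique substitutions.

Each called site gets two numbers:

* a sequence-weighted Jensen–Shannon divergence (JSD) between the column's
  residue distribution and a background amino-acid distribution, in bits
  and normalized to [0, 1], linearly penalized by the column's weighted
  gap fraction — high values at gap-free columns mean the site is
  conserved away from background among the comparison species;
* the arithmetic mean of BLOSUM62 scores of the foreground residue
  against every informative outgroup residue ("foreground vs outgroup
  BLOSUM62") — strongly negative means the replacement is chemically
  drastic.

Sites are then percentile-ranked over the pooled multi-gene dataset and
the top fraction (default 1%) of high-JSD / low-BLOSUM candidates is
flagged, either by a composite rank or by a strict two-threshold
quadrant.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .detect import SubstitutionCall
from .msa import Msa, henikoff_weights
from .records import GAP, STANDARD_RESIDUES, SpeciesConfig

_STANDARD = frozenset(STANDARD_RESIDUES)

#: BLOSUM62 marginal amino-acid frequencies (standard background of the
#: position-specific conservation literature), normalized below.
_BLOSUM62_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}


def background_distribution(name: str = "blosum62", msa: Msa | None = None) -> dict[str, float]:
    """Return a named 20-residue background distribution.

    ``blosum62``: BLOSUM62 marginal frequencies; ``uniform``: 1/20 each;
    ``alignment``: residue frequencies pooled over the given alignment.
    """
    if name == "blosum62":
        total = sum(_BLOSUM62_BACKGROUND.values())
        return {a: v / total for a, v in _BLOSUM62_BACKGROUND.items()}
    if name == "uniform":
        return {a: 1.0 / 20 for a in STANDARD_RESIDUES}
    if name == "alignment":
        if msa is None:
            raise ValueError("alignment-derived background requires an Msa")
        counts = {a: 0 for a in STANDARD_RESIDUES}
        for row in msa.rows.values():
            for ch in row:
                if ch in _STANDARD:
                    counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("alignment has no standard residues")
        return {a: c / total for a, c in counts.items()}
    raise ValueError(f"unknown background {name!r}")


def load_matrix(name_or_path: str = "BLOSUM62"):
    """Load a substitution matrix by name or from an NCBI-format file."""
    p = Path(name_or_path)
    if p.exists():
        return substitution_matrices.read(str(p))
    return substitution_matrices.load(name_or_path)


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the conservation/divergence scorer.

    ``lam`` is the JSD mixture weight between column and background;
    ``window_radius``/``window_weight`` enable the classic +/-3-column,
    half-weight smoothing (off by default); ``top_fraction`` is the
    flagged share of the pooled dataset.
    """

    lam: float = 0.5
    background: str = "blosum62"
    pseudocount: float = 1e-7
    window_radius: int = 0
    window_weight: float = 0.5
    matrix: str = "BLOSUM62"
    include_foreground_in_conservation: bool = False
    top_fraction: float = 0.01
    flag_mode: str = "composite-rank"

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lam must lie in (0, 1)")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.flag_mode not in ("composite-rank", "quadrant"):
            raise ValueError(f"unknown flag_mode {self.flag_mode!r}")


@dataclass(frozen=True)
class ColumnDistribution:
    """Estimated residue distribution of a column plus its weighted gap share."""

    p: dict[str, float]
    gap_fraction: float


@dataclass
class ScoredSubstitution:
    """A substitution call annotated with conservation and divergence scores."""

    call: SubstitutionCall
    jsd: float
    mean_blosum: float
    jsd_percentile: float = math.nan
    blosum_percentile: float = math.nan
    composite: float = math.nan
    flagged: bool = False


def column_distribution(
    residues: Mapping[str, str],
    weights: Mapping[str, float],
    config: ScoringConfig,
    contributing_species: Sequence[str],
) -> ColumnDistribution:
    """Weighted residue distribution over the contributing species.

    Weights are renormalized over the contributing set; ambiguity letters
    contribute like gaps to neither the distribution nor (unlike gaps) the
    gap fraction.  A pseudocount keeps downstream divergences finite.
    """
    if not contributing_species:
        raise ValueError("contributing_species must be non-empty")
    missing = set(contributing_species) - set(weights)
    if missing:
        raise ValueError(f"weights missing for {sorted(missing)}")
    wtot = sum(weights[sp] for sp in contributing_species)
    mass = {a: config.pseudocount for a in STANDARD_RESIDUES}
    informative_mass = 0.0
    gap_mass = 0.0
    for sp in contributing_species:
        ch = residues[sp]
        w = weights[sp] / wtot
        if ch == GAP:
            gap_mass += w
        elif ch in _STANDARD:
            mass[ch] += w
            informative_mass += w
    if informative_mass == 0.0:
        raise ValueError("all contributing sequences are gapped or ambiguous")
    total = sum(mass.values())
    return ColumnDistribution({a: m / total for a, m in mass.items()}, gap_mass)


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd_conservation(
    dist: ColumnDistribution,
    config: ScoringConfig,
    background: Mapping[str, float] | None = None,
    neighbor_scores: Sequence[float] | None = None,
) -> float:
    """Gap-penalized Jensen–Shannon divergence of a column from background, in [0, 1].

    With mixture ``r = lam*p + (1-lam)*q`` the raw score is
    ``lam*KL(p||r) + (1-lam)*KL(q||r)`` in bits; the reported score is
    ``(1 - gap_fraction) * raw``.  If ``window_radius > 0`` and neighbor
    scores are supplied, the score is blended with their mean at
    ``window_weight``.
    """
    q_map = background or background_distribution(config.background)
    order = list(STANDARD_RESIDUES)
    p = np.array([dist.p[a] for a in order], dtype=float)
    q = np.array([q_map[a] for a in order], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("column distribution is not a probability vector")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("background is not a probability vector")
    lam = config.lam
    r = lam * p + (1.0 - lam) * q
    raw = lam * _kl_bits(p, r) + (1.0 - lam) * _kl_bits(q, r)
    score = (1.0 - dist.gap_fraction) * raw
    if config.window_radius > 0 and neighbor_scores:
        w = config.window_weight
        score = (1.0 - w) * score + w * (sum(neighbor_scores) / len(neighbor_scores))
    return score


def mean_outgroup_blosum(call: SubstitutionCall, config: ScoringConfig, matrix=None) -> float:
    """Mean substitution-matrix score of the foreground residue vs each outgroup residue."""
    if not call.outgroup_residues:
        raise ValueError("call has no informative outgroup residues")
    m = matrix if matrix is not None else load_matrix(config.matrix)
    try:
        return float(
            sum(m[call.foreground_residue, o] for o in call.outgroup_residues)
            / len(call.outgroup_residues)
        )
    except (KeyError, IndexError) as exc:
        raise ValueError(f"residue not in matrix alphabet: {exc}") from exc


def score_substitutions(
    msa: Msa,
    calls: Sequence[SubstitutionCall],
    weights: Mapping[str, float] | None,
    config: ScoringConfig,
    species_config: SpeciesConfig | None = None,
) -> list[ScoredSubstitution]:
    """Score each call's column; percentiles and flags are filled later by
    :func:`rank_and_flag` over the pooled multi-gene dataset.

    Conservation is computed on the outgroup-only column by default: the
    interesting sites are those otherwise highly conserved among the
    comparison species, which the divergent foreground residue would
    dilute.  Set ``include_foreground_in_conservation`` to score the full
    column instead.
    """
    if not calls:
        return []
    if weights is None:
        weights = henikoff_weights(msa)
    if species_config is None:
        raise ValueError("species_config is required to pick contributing species")
    matrix = load_matrix(config.matrix)
    bg = background_distribution(config.background, msa=msa)
    if config.include_foreground_in_conservation:
        contributing = [sp for sp in species_config.all_species if sp in msa.rows]
    else:
        contributing = [sp for sp in species_config.outgroup_species if sp in msa.rows]

    def column_score(c: int) -> float:
        dist = column_distribution(msa.column(c), weights, config, contributing)
        return jsd_conservation(dist, config, background=bg)

    scored: list[ScoredSubstitution] = []
    for call in calls:
        c = call.column_index
        base = column_score(c)
        if config.window_radius > 0:
            neighbors = []
            for d in range(c - config.window_radius, c + config.window_radius + 1):
                if d == c or not 0 <= d < msa.length:
                    continue
                try:
                    neighbors.append(column_score(d))
                except ValueError:
                    continue  # all-gap neighbor columns carry no signal
            if neighbors:
                w = config.window_weight
                base = (1.0 - w) * base + w * (sum(neighbors) / len(neighbors))
        scored.append(
            ScoredSubstitution(
                call=call,
                jsd=base,
                mean_blosum=mean_outgroup_blosum(call, config, matrix=matrix),
            )
        )
    return scored


def rank_and_flag(
    scored: Sequence[ScoredSubstitution], config: ScoringConfig
) -> list[ScoredSubstitution]:
    """Percentile-rank the pooled dataset and flag the top candidates.

    ``composite-rank`` flags the ``ceil(top_fraction * n)`` items with the
    highest ``(jsd_percentile + (1 - blosum_percentile)) / 2``; the
    ``quadrant`` mode instead requires jsd at or above the
    ``1 - top_fraction`` quantile AND mean BLOSUM at or below the
    ``top_fraction`` quantile.  Ties break by higher jsd, lower BLOSUM,
    gene symbol, then column, so the flagged set is order-independent.
    """
    if not scored:
        raise ValueError("cannot rank an empty dataset")
    n = len(scored)
    jsds = sorted(s.jsd for s in scored)
    blos = sorted(s.mean_blosum for s in scored)

    out: list[ScoredSubstitution] = []
    for s in scored:
        jp = bisect.bisect_right(jsds, s.jsd) / n
        bp = bisect.bisect_right(blos, s.mean_blosum) / n
        composite = (jp + (1.0 - bp)) / 2.0
        out.append(replace_scores(s, jp, bp, composite))

    if config.flag_mode == "composite-rank":
        k = math.ceil(config.top_fraction * n)
        order = sorted(
            range(n),
            key=lambda i: (
                -out[i].composite,
                -out[i].jsd,
                out[i].mean_blosum,
                out[i].call.gene_symbol,
                out[i].call.column_index,
            ),
        )
        for rank, i in enumerate(order):
            out[i].flagged = rank < k
    else:
        jsd_cut = float(np.quantile(jsds, 1.0 - config.top_fraction))
        blo_cut = float(np.quantile(blos, config.top_fraction))
        for s in out:
            s.flagged = s.jsd >= jsd_cut and s.mean_blosum <= blo_cut
    return out


def replace_scores(
    s: ScoredSubstitution, jp: float, bp: float, composite: float
) -> ScoredSubstitution:
    return ScoredSubstitution(
        call=s.call,
        jsd=s.jsd,
        mean_blosum=s.mean_blosum,
        jsd_percentile=jp,
        blosum_percentile=bp,
        composite=composite,
        flagged=s.flagged,
    )
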