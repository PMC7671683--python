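# Methods

`cladesubs` implements a comparative-genomics screen for clade-unique
amino acid substitutions in candidate proteins: given orthologous protein
sequences for a species panel split into a small *foreground clade* (by
default two ground squirrels — Arctic, AGS, and 13-lined, 13LGS) and an
*outgroup* (nine other mammals), it finds alignment sites where the
foreground carries a residue found in no outgroup species, and ranks
those sites by how conserved the surrounding outgroup column is and how
chemically drastic the replacement is.

## Record resolution

Ortholog databases typically return several candidate records per
species (isoforms, re-annotations). The pipeline keeps exactly one per
species: the candidate with the highest **mean percent identity** against
a set of accepted reference sequences (defaults: human, mouse, 13LGS).
Percent identity is defined on a deterministic Needleman–Wunsch global
alignment with BLOSUM62 scoring, gap open 11 / extend 1, as identical
aligned pairs divided by alignment length (gapped columns count in the
denominator). The sequence pair is lexicographically ordered before
alignment so the measure is exactly symmetric even when co-optimal
alignments exist. Ties break by longer sequence, then smallest
accession; resolution is therefore invariant to candidate order. Mean
(not max) aggregation over references is the default; max is available
(`resolve_species_records` operates on whatever reference list it is
given, so callers can restrict to one).

Records may first be filtered against a table of accepted gene aliases
(case-insensitive, whitespace-trimmed). The table is file-driven; there
is no live database access anywhere in the core. A family missing any
foreground species is excluded from calling and reported in the run
summary — clade-uniqueness is untestable when a clade member is absent.

## Substitution and indel calling

All calls are made per alignment column. A column is a **substitution
call** iff (a) every foreground species shows the same standard residue
(no gap, no X/B/Z); (b) no informative outgroup species shows that
residue; (c) at least `min_outgroup` (default 5 of 9) outgroup species
are informative there. Ambiguity letters in the foreground block the
call; in the outgroup they are simply uninformative — treating X as
evidence in either direction would manufacture or suppress calls.
Near-miss sites where only part of the foreground carries the
outgroup-absent residue go to a separate diagnostic listing and are
never scored. **Indel events** are maximal runs of columns gapped in all
foreground and none of the outgroup (foreground-deletion) or vice versa
(foreground-insertion); a run is one event regardless of length.

Columns are 0-based internally; every reported position is the 1-based
residue index in that species' ungapped precursor sequence (so a
candidate reads like "leucine-32").

## Sequence weights

Position-based (Henikoff-style) weights: per sequence, the raw weight is
the mean over columns of `1/(r·k)`, where `r` is the number of distinct
non-gap residue types in the column and `k` the count of sequences
sharing this sequence's residue; all-gap columns are skipped; at a
sequence's own gap positions the neutral value `1/n` is contributed so
gappy rows keep defined weights. Weights are normalized to sum to 1 and
are computed once, globally per alignment (not per window).

## Conservation score (JSD)

For each called column, the weighted residue distribution `p` is
estimated over the **outgroup only** by default: the interesting sites
are those otherwise highly conserved among the comparison species, and
including the divergent foreground residue would dilute exactly the
signal being measured (`include_foreground_in_conservation` restores the
inclusive variant). Weights are renormalized over the contributing set;
a pseudocount (default 1e-7 per residue) keeps divergences finite.

With background `q` (default: the BLOSUM62 marginal amino-acid
frequencies; `uniform` and `alignment`-derived available) and mixture
weight λ (default 0.5), the score is the Jensen–Shannon divergence in
bits,

    r = λ·p + (1−λ)·q
    JSD = λ·KL(p‖r) + (1−λ)·KL(q‖r),      KL in log base 2, 0·log0 ≡ 0,

multiplied by the linear gap penalty `(1 − gap_fraction)` where
`gap_fraction` is the weighted share of gapped contributing sequences.
With λ = 0.5 and base-2 logs the unwindowed score is bounded by 1, giving
a fixed testable range; a point mass against the uniform background
evaluates to 0.854997 bits in closed form, which the tests verify against
an independently coded direct summation (max deviation < 1e-10 over 1000
random distribution pairs). Window smoothing (±`window_radius` columns
blended at `window_weight`) is available for compatibility with the
classic conservation-scoring setup but defaults off.

## Divergence score (mean outgroup BLOSUM62)

Each call's foreground residue is scored with BLOSUM62 against every
informative outgroup residue and the scores are averaged. BLOSUM62 is
used rather than PAM-family matrices to prioritize replacements with
higher probability of chemical/functional difference; the matrix is
pluggable (any NCBI-format matrix file) but BLOSUM62 is the default and
the one used throughout the tests.

## Prioritization

Percentile ranks for JSD and mean BLOSUM62 are computed over the pooled
multi-gene dataset (fraction of pooled values ≤ the item's value). The
default **composite-rank** mode flags the `ceil(top_fraction·n)` items
(default top 1%) with the highest
`(jsd_percentile + (1 − blosum_percentile))/2`, ties broken by higher
JSD, lower BLOSUM, gene symbol, then column — fully deterministic and
order-independent. A strict **quadrant** mode (JSD ≥ its
`1 − top_fraction` quantile AND BLOSUM ≤ its `top_fraction` quantile) is
provided because "top x% of high-conservation, low-BLOSUM sites" admits
both readings; composite-rank is the default since it always returns a
non-empty, fixed-size candidate set.

## Synthetic data generator

The simulator emulates what the scoring pipeline consumes — per-column
residue compositions of an 11-species panel — rather than sequence
evolution along a phylogeny. Defaults: 100 families × 300 columns, 2
foreground + 9 outgroup species; each column draws a consensus from the
background and a conservation level from a two-point mix (98% consensus
columns with probability 0.5, else 60%); each outgroup residue is the
consensus with that probability, otherwise a background draw. Planted
substitutions choose a foreground residue whose BLOSUM62 score against
the consensus lies in a configurable severity range (default −4…−1) and
resample until the residue is absent from the outgroup column; planted
indels are maximal gap runs (1–3 columns) placed non-adjacently. Nuisance
knobs add missing outgroup species, decoy isoform records (the true
sequence with 5% of residues mutated — same length, so the true record
also wins the resolution tie-break), and ambiguous X residues.

Two deliberate constructions make recovery testing exact: at every
non-planted column at least one outgroup sequence is forced to carry the
consensus (so the foreground, which copies the consensus, can never be
accidentally clade-unique), and planted events never overlap or touch
each other. Generation is a pure function of `(seed, family_index)` via
per-family substreams, so any family is reproducible in isolation.

What the simulator does **not** model: phylogenetic correlation between
outgroup species, insertion/deletion length distributions from real
aligners, alignment error, and compositional biases of real proteomes.
Passing recovery tests therefore demonstrates the detector and scorer
are correct for the stated column-level definitions — not that real
alignments are free of artifacts that would violate those definitions
(e.g. misalignment creating spurious clade-unique columns).

## Bundled demonstration family

`cladesubs.datasets` builds a fully synthetic ATP5G1-like family — the
sequences are invented, only the *situation* is modeled: three
foreground-unique substitutions in an otherwise conserved N-terminal
region (a leucine at precursor position 32 against a proline column,
plus N→D and T→P sites) and two small foreground-specific indels. It
exists so the worked example, tests, and the acceptance script can
exercise the complete pipeline, including isoform resolution against a
decoy record, without any network access.

## Numerical and design choices

- Log base 2 everywhere; scores reported to 6 decimals in TSV output.
- Percentiles use the inclusive (≤) convention; with n items the minimum
  value has percentile 1/n, never 0.
- Reports are tab-separated with a versioned header comment; the run
  summary is JSON with sorted keys. Two runs on identical inputs are
  byte-identical (no hash- or iteration-order dependence).
- Alignment production is a pluggable adapter ("unaligned FASTA in,
  aligned FASTA out, same headers"); the core never assumes a specific
  aligner. `CommandAligner` wraps any shell aligner with FASTA on stdout
  (e.g. mafft); tests use a pure-Python stand-in.
- Problem sizes in tests and the acceptance script (100 families × 300
  columns; 1000 oracle pairs) were chosen as the smallest sizes at which
  the recovery and ordering statistics are stable and exact; the whole
  suite runs in seconds.

## Known limitations

- Uniqueness is evaluated per alignment column, so alignment errors
  translate directly into call errors; the method has no realignment or
  alignment-confidence stage.
- The JSD score treats the outgroup as exchangeable sequences (weighted,
  but phylogeny-free); deep conservation driven by close relatives is
  partially, not fully, corrected by sequence weighting.
- Indel events are reported but not scored; prioritization covers
  substitutions only.
- `min_outgroup` trades sensitivity against robustness to missing data;
  with fewer than 5 informative outgroup species a column is never
  callable under the defaults.
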