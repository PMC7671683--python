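"""How the two scores behave: JSD conservation and mean outgroup BLOSUM62.

Builds single-column toy alignments and prints the scores, showing that a
fully conserved outgroup column scores much higher JSD than a variable
one, and that chemically drastic replacements get more negative BLOSUM62
means than conservative ones.
"""

from cladesubs import (
    ScoringConfig,
    SpeciesConfig,
    detect_foreground_substitutions,
    henikoff_weights,
    score_substitutions,
)
from cladesubs.msa import Msa

panel = SpeciesConfig(
    foreground_species=("ags", "itri"),
    outgroup_species=("mmus", "rnor", "sara", "pabe", "hsap", "ecab", "btau",
                      "ocun", "sscr"),
)
config = ScoringConfig()

cases = {
    "L vs conserved P column": "LL" + "P" * 9,       # drastic, conserved site
    "L vs variable column":    "LL" + "PGAWCMKRH",   # drastic, unconserved site
    "I vs conserved L column": "II" + "L" * 9,       # conservative replacement
}

print(f"{'case':<28}{'jsd':>8}{'mean_blosum':>13}")
for name, column in cases.items():
    rows = {sp: column[i] for i, sp in enumerate(panel.all_species)}
    msa = Msa("TOY", rows)
    calls = detect_foreground_substitutions(msa, panel)
    [scored] = score_substitutions(msa, calls, henikoff_weights(msa), config,
                                   species_config=panel)
    print(f"{name:<28}{scored.jsd:>8.4f}{scored.mean_blosum:>13.2f}")

# The prioritized candidates are top-right in (jsd, -mean_blosum) space:
# high conservation among the outgroup AND a chemically drastic foreground
# replacement, like leucine against a column of prolines.
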