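"""Bundled synthetic demonstration family (ATP5G1-like).

Everything here is SYNTHETIC: the sequences are constructed in code, not
downloaded, and stand in for a real ortholog set of the ATP synthase
membrane subunit c gene ATP5G1.  The family encodes the qualitative
situation of interest — a two-ground-squirrel foreground carrying three
clade-unique substitutions in an otherwise mammal-conserved N-terminal
region (a leucine at precursor position 32, plus N34D-like and T39P-like
sites) and two small foreground-specific indels — so the full pipeline
can be demonstrated and exercised without network access.
"""

from __future__ import annotations

from pathlib import Path

from .msa import Msa
from .records import OrthologFamily, SpeciesRecord
from .simulate import DEFAULT_PANEL

GENE = "ATP5G1"

# Synthetic backbone, loosely c-subunit-like: a targeting-peptide-flavored
# N-terminal half and a hydrophobic C-terminal half.  Not a real sequence.
_BACKBONE_SEED = (
    "MFAARLVSRSAVSSLARAAPTRAPVRDFKTAPVNAAPATQSVLKAAAPSLKAGTAEGKIR"
    "DIDTAAKFIGAGAATVGVAGSGAGIGTVFGSLIIGYARNPSLKQQLFSYAILGFALSEAM"
    "GLFCLMVAFLILFAM"
)

# Foreground-unique sites, 1-based in the outgroup precursor:
#   32 P->L (the leucine-32 site), 34 N->D, 39 T->P.
_SUBSTITUTIONS = {31: ("P", "L"), 33: ("N", "D"), 38: ("T", "P")}
_INSERTION_AFTER = 45   # foreground gains "VA" after backbone index 44
_INSERTION_SEQ = "VA"
_DELETION_AT = 52       # foreground lacks the residue at backbone index 52


def _backbone() -> list[str]:
    bb = list(_BACKBONE_SEED)
    for idx, (outgroup_res, _) in _SUBSTITUTIONS.items():
        bb[idx] = outgroup_res
    return bb


def synthetic_atp5g1_family() -> tuple[OrthologFamily, Msa, dict]:
    """Build the synthetic family, its alignment, and the expected findings.

    Returns ``(family, msa, expected)`` where ``expected`` records what a
    correct pipeline must report: 3 substitutions (foreground residues L,
    D, P at foreground precursor positions 32, 34, 39), 2 indel events,
    and the leucine site at position 32.
    """
    panel = DEFAULT_PANEL
    bb = _backbone()

    outgroup_aln = (
        "".join(bb[:_INSERTION_AFTER])
        + "-" * len(_INSERTION_SEQ)
        + "".join(bb[_INSERTION_AFTER:])
    )

    fg = list(bb)
    for idx, (_, fg_res) in _SUBSTITUTIONS.items():
        fg[idx] = fg_res
    foreground_aln = (
        "".join(fg[:_INSERTION_AFTER])
        + _INSERTION_SEQ
        + "".join(fg[_INSERTION_AFTER:_DELETION_AT])
        + "-"
        + "".join(fg[_DELETION_AT + 1 :])
    )
    assert len(foreground_aln) == len(outgroup_aln)

    rows = {sp: foreground_aln for sp in panel.foreground_species}
    rows.update({sp: outgroup_aln for sp in panel.outgroup_species})
    msa = Msa(GENE, dict(rows))

    records = {}
    for sp in panel.all_species:
        source = "foreground-db" if sp in panel.foreground_species else "reference-db"
        records[sp] = SpeciesRecord(
            sp, f"SYN-{GENE}-{sp}", GENE, rows[sp].replace("-", ""), source
        )
    family = OrthologFamily(GENE, records, panel)

    expected = {
        "n_substitutions": 3,
        "n_indels": 2,
        "foreground_residues": ["L", "D", "P"],
        "foreground_positions": [32, 34, 39],
        "leucine_position": 32,
        "indel_kinds": ["foreground-insertion", "foreground-deletion"],
    }
    return family, msa, expected


def decoy_ags_isoform(family: OrthologFamily) -> SpeciesRecord:
    """A synthetic second AGS candidate record (true sequence with a few
    mutations), for demonstrating isoform resolution."""
    true = family.records["ags"].sequence
    chars = list(true)
    for i in (5, 20, 60, 90, 110, 130):
        chars[i % len(chars)] = "G" if chars[i % len(chars)] != "G" else "A"
    return SpeciesRecord("ags", f"SYN-{GENE}-ags-iso2", GENE, "".join(chars),
                         "foreground-db")


def write_synthetic_atp5g1(outdir: str | Path, include_decoy: bool = True) -> dict[str, Path]:
    """Write the synthetic family as FASTA + aligned FASTA; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family, msa, _ = synthetic_atp5g1_family()
    fasta = outdir / "ATP5G1_synthetic.fasta"
    afa = outdir / "ATP5G1_synthetic.afa"
    with open(fasta, "w") as fh:
        for sp in sorted(family.records):
            rec = family.records[sp]
            fh.write(f">{sp}|{rec.accession}|{GENE}\n{rec.sequence}\n")
        if include_decoy:
            d = decoy_ags_isoform(family)
            fh.write(f">ags|{d.accession}|{GENE}\n{d.sequence}\n")
    with open(afa, "w") as fh:
        for sp in sorted(msa.rows):
            rec = family.records[sp]
            fh.write(f">{sp}|{rec.accession}|{GENE}\n{msa.rows[sp]}\n")
    return {"fasta": fasta, "msa": afa}
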