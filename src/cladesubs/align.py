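"""Pluggable external-aligner adapter.

Multiple sequence alignment itself is delegated: the contract is
"unaligned FASTA in, aligned FASTA out, same set of headers".  Any
command-line aligner that reads FASTA on a path argument and writes
aligned FASTA to stdout (mafft, kalign, ...) can be wrapped with
:class:`CommandAligner`; a plain callable satisfying the same contract
(e.g. for tests) can be passed wherever an aligner is accepted.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Callable, Protocol

#: An aligner maps an unaligned FASTA path to an aligned FASTA path.
AlignerFn = Callable[[Path, Path], None]


class Aligner(Protocol):
    def __call__(self, fasta_in: Path, fasta_out: Path) -> None: ...


class CommandAligner:
    """Wrap a shell aligner invoked as ``<cmd> <args...> <input>`` with
    aligned FASTA on stdout."""

    def __init__(self, command: str, args: tuple[str, ...] = ()):
        if shutil.which(command) is None:
            raise FileNotFoundError(f"aligner command {command!r} not on PATH")
        self.command = command
        self.args = args

    def __call__(self, fasta_in: Path, fasta_out: Path) -> None:
        with open(fasta_out, "w") as out:
            subprocess.run(
                [self.command, *self.args, str(fasta_in)],
                stdout=out,
                stderr=subprocess.DEVNULL,
                check=True,
            )


def validate_aligned(fasta_in: Path, fasta_out: Path) -> None:
    """Check the adapter contract: the output holds the same headers as the input."""
    from Bio import SeqIO

    ids_in = {r.id for r in SeqIO.parse(str(fasta_in), "fasta")}
    ids_out = {r.id for r in SeqIO.parse(str(fasta_out), "fasta")}
    if ids_in != ids_out:
        raise ValueError(
            f"aligner changed the record set: missing {sorted(ids_in - ids_out)}, "
            f"added {sorted(ids_out - ids_in)}"
        )
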