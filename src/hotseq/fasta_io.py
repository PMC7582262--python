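"""FASTA input and per-residue table output.

Input files follow the plain multi-chain dialect used by sequence-only hot-spot
prediction servers: each chain is a header line starting with ``>`` followed by
one or more lines of single-letter amino-acid codes. Only the 20 standard
residues are accepted; non-standard letters (X, B, Z, U, ...) are rejected by
default because the downstream feature scheme is undefined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when a file is not parseable as FASTA at all."""


class FastaValidationError(ValueError):
    """Raised when a parsed chain violates the sequence contract."""


@dataclass(frozen=True)
class ProteinChain:
    """One FASTA entry: an identifier plus its residue string.

    Parameters
    ----------
    chain_id:
        FASTA header without the leading ``>``.
    sequence:
        Uppercase single-letter residue codes, one per residue.
    """

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise FastaValidationError("chain_id must be non-empty")
        for i, residue in enumerate(self.sequence, start=1):
            if residue not in _STANDARD_SET:
                raise FastaValidationError(
                    f"chain {self.chain_id!r}: non-standard residue "
                    f"{residue!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, *, skip_invalid_chains: bool = False) -> list[ProteinChain]:
    """Read and validate a multi-chain FASTA file.

    Sequence lines are concatenated in order, surrounding whitespace stripped
    and letters uppercased. Blank lines between records and ``\\r\\n`` endings
    are tolerated.

    Parameters
    ----------
    path:
        FASTA file with at least one ``>`` header.
    skip_invalid_chains:
        If true, chains containing non-standard letters are dropped with a
        logged warning instead of raising.

    Raises
    ------
    FastaParseError
        Empty file or no header line.
    FastaValidationError
        Non-standard residue (naming chain, position and character) or a
        duplicate chain identifier.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # e.g. sequence data before any ">" header
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")

    chains: list[ProteinChain] = []
    seen: set[str] = set()
    for record in records:
        chain_id = record.description.strip()
        if chain_id in seen:
            raise FastaValidationError(f"duplicate chain_id {chain_id!r}")
        seen.add(chain_id)
        sequence = str(record.seq).strip().upper()
        try:
            chains.append(ProteinChain(chain_id=chain_id, sequence=sequence))
        except FastaValidationError:
            if skip_invalid_chains:
                logger.warning("skipping chain %r: non-standard residues", chain_id)
                continue
            raise
    return chains


def load_example_chains() -> list[ProteinChain]:
    """The bundled two-chain example input: the heavy and light chains of a
    public antibody Fab fragment (PDB 6Q1G)."""
    from importlib import resources

    resource = resources.files("hotseq").joinpath("data/example_chains.fasta")
    with resources.as_file(resource) as path:
        return read_fasta(path)


def write_fasta(chains: Iterable[ProteinChain], path: str | Path, *, width: int = 60) -> None:
    """Write chains as plain FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    with path.open("w") as handle:
        for chain in chains:
            handle.write(f">{chain.chain_id}\n")
            for start in range(0, chain.length, width):
                handle.write(chain.sequence[start:start + width] + "\n")


def write_residue_table(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write per-residue records as a comma-delimited UTF-8 table.

    The first columns are chain_id, position (1-based) and amino_acid when
    present; any payload columns follow. An empty input produces a header-only
    file. Round-trips losslessly through :func:`read_residue_table`.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    leading = [c for c in ("chain_id", "position", "amino_acid") if c in frame.columns]
    rest = [c for c in frame.columns if c not in leading]
    frame = frame[leading + rest]
    frame.to_csv(path, index=False)


def read_residue_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_residue_table`."""
    return pd.read_csv(path)
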