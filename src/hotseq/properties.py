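"""The 19 literature-based amino-acid properties used as raw residue features.

The bundled table covers the physicochemical categories relevant to hot-spot
energetics: secondary-structure propensity, pKa-associated values, atomic
composition, and standard area/mass values, assembled from classical public
reference scales (Chou-Fasman propensities; free-amino-acid pKa and pI;
atom counts of the free amino acid; average residue mass; theoretical maximum
accessible surface area; Kyte-Doolittle hydropathy; Zamyatnin residue volume;
Grantham polarity; Bhaskaran-Ponnuswamy average flexibility).

Residues without an ionizable side chain carry the sentinel 0.0 in the
``pka_side_chain`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from hotseq.fasta_io import STANDARD_AMINO_ACIDS

N_PROPERTIES = 19

#: One-line provenance note per property column.
PROVENANCE: dict[str, str] = {
    "helix_propensity": "Chou-Fasman alpha-helix propensity P(a)",
    "sheet_propensity": "Chou-Fasman beta-sheet propensity P(b)",
    "turn_propensity": "Chou-Fasman beta-turn propensity P(t)",
    "pka_carboxyl": "pKa of the alpha-carboxyl group, free amino acid",
    "pka_amine": "pKa of the alpha-amino group, free amino acid",
    "pka_side_chain": "side-chain pKa; 0.0 sentinel when not ionizable",
    "isoelectric_point": "isoelectric point pI of the free amino acid",
    "atoms_carbon": "carbon atoms in the free amino acid",
    "atoms_hydrogen": "hydrogen atoms in the free amino acid",
    "atoms_nitrogen": "nitrogen atoms in the free amino acid",
    "atoms_oxygen": "oxygen atoms in the free amino acid",
    "atoms_sulfur": "sulfur atoms in the free amino acid",
    "atoms_heavy": "non-hydrogen atoms in the free amino acid",
    "residue_mass": "average residue mass within a peptide chain, Da",
    "max_asa": "theoretical maximum accessible surface area, A^2 (Tien et al. 2013)",
    "hydropathy": "Kyte-Doolittle hydropathy index",
    "volume": "residue volume, A^3 (Zamyatnin 1972)",
    "polarity": "Grantham polarity",
    "flexibility": "average flexibility index (Bhaskaran & Ponnuswamy 1988)",
}


class PropertyTableError(RuntimeError):
    """Bundled property resource missing or corrupt."""


class PropertyLookupError(KeyError):
    """Unknown amino acid or property name."""


@dataclass(frozen=True)
class PropertyTable:
    """Mapping of each of the 20 standard amino acids to 19 named real values."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        frame = self.frame
        if list(frame.index) != sorted(frame.index):
            frame = frame.sort_index()
        missing_aa = set(STANDARD_AMINO_ACIDS) - set(frame.index)
        if missing_aa or len(frame.index) != 20:
            raise PropertyTableError(f"table must cover the 20 standard amino acids; missing {sorted(missing_aa)}")
        if len(frame.columns) != N_PROPERTIES:
            raise PropertyTableError(f"expected {N_PROPERTIES} properties, got {len(frame.columns)}")
        if not np.isfinite(frame.to_numpy(dtype=float)).all():
            raise PropertyTableError("property table contains non-finite values")
        object.__setattr__(self, "frame", frame.astype(float))

    @property
    def property_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def amino_acids(self) -> list[str]:
        return list(self.frame.index)

    def values_for(self, aa: str) -> np.ndarray:
        """The 19 property values of one amino acid, in column order."""
        if aa not in self.frame.index:
            raise PropertyLookupError(f"unknown amino acid {aa!r}")
        return self.frame.loc[aa].to_numpy()

    def as_matrix(self) -> pd.DataFrame:
        """A defensive copy of the 20x19 table (rows = amino acids)."""
        return self.frame.copy()


def load_default_properties() -> PropertyTable:
    """Load the bundled 20x19 property table.

    Deterministic across runs and installs; raises
    :class:`PropertyTableError` if the bundled CSV is missing or malformed.
    """
    try:
        resource = resources.files("hotseq").joinpath("data/amino_acid_properties.csv")
        with resources.as_file(resource) as csv_path:
            frame = pd.read_csv(csv_path, index_col="amino_acid")
    except (FileNotFoundError, ValueError, OSError) as exc:
        raise PropertyTableError(f"bundled property table unavailable: {exc}") from exc
    return PropertyTable(frame=frame)


def load_properties_csv(path: str | Path) -> PropertyTable:
    """Load a user-supplied property table (same CSV schema as the bundle)."""
    frame = pd.read_csv(path, index_col="amino_acid")
    return PropertyTable(frame=frame)


def get_property(aa: str, name: str, table: PropertyTable) -> float:
    """The stored scalar for one (amino acid, property) pair."""
    if name not in table.frame.columns:
        raise PropertyLookupError(f"unknown property {name!r}")
    if aa not in table.frame.index:
        raise PropertyLookupError(f"unknown amino acid {aa!r}")
    return float(table.frame.at[aa, name])


def export_properties_csv(table: PropertyTable, path: str | Path) -> None:
    """Export the table so users can audit or substitute it."""
    table.frame.to_csv(path, index_label="amino_acid")
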