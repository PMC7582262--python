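"""Per-residue feature extraction from sequence alone.

Each residue of a chain is described by an ordered vector of 173 values:

* 20 — one-hot encoding of the residue identity;
* 1  — relative-position quartile (1-4, which quarter of the chain);
* 19 — raw physicochemical properties of the residue;
* 133 — the same 19 properties averaged over symmetric sliding windows of
  half-width 2, 5, 7, 10, 25, 50 and 75 residues centred on the target
  (19 x 7).

Windows include the target residue and are truncated at chain boundaries
(no padding), so a window that covers the whole chain reduces to the
unweighted whole-chain property mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from hotseq.fasta_io import STANDARD_AMINO_ACIDS, ProteinChain
from hotseq.properties import PropertyLookupError, PropertyTable

DEFAULT_WINDOW_SIZES: tuple[int, ...] = (2, 5, 7, 10, 25, 50, 75)
N_FEATURES = 173

#: Metadata columns preceding the feature block in extracted tables.
ID_COLUMNS = ("chain_id", "position", "amino_acid")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings.

    ``window_sizes`` are half-widths: a window of size ``w`` covers positions
    ``[i - w, i + w]`` clipped to the chain. ``one_hot_order`` fixes the
    column order of the identity block.
    """

    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    include_target_in_window: bool = True
    one_hot_order: tuple[str, ...] = STANDARD_AMINO_ACIDS

    def __post_init__(self) -> None:
        sizes = tuple(int(w) for w in self.window_sizes)
        if any(w < 1 for w in sizes) or list(sizes) != sorted(set(sizes)):
            raise ValueError("window_sizes must be strictly increasing positive integers")
        if sorted(self.one_hot_order) != sorted(STANDARD_AMINO_ACIDS):
            raise ValueError("one_hot_order must be a permutation of the 20 standard codes")
        object.__setattr__(self, "window_sizes", sizes)
        object.__setattr__(self, "one_hot_order", tuple(self.one_hot_order))


def feature_names(table: PropertyTable, config: FeatureConfig | None = None) -> list[str]:
    """The frozen, ordered names of every feature column."""
    config = config or FeatureConfig()
    names = [f"onehot_{aa}" for aa in config.one_hot_order]
    names.append("position_quartile")
    names.extend(table.property_names)
    for w in config.window_sizes:
        names.extend(f"win{w}_{prop}" for prop in table.property_names)
    return names


def one_hot(aa: str, config: FeatureConfig | None = None) -> np.ndarray:
    """Binary identity encoding: a single 1 at the index of ``aa``."""
    config = config or FeatureConfig()
    try:
        index = config.one_hot_order.index(aa)
    except ValueError:
        raise PropertyLookupError(f"unknown amino acid {aa!r}") from None
    vector = np.zeros(20)
    vector[index] = 1.0
    return vector


def relative_position_quartile(position: int, length: int) -> int:
    """Which quarter of the chain a residue lies in (1-4).

    Computed as ``ceil(4 * position / length)``; position 1 maps to quartile 1
    and the last residue to quartile 4 for every length >= 1.
    """
    if length < 1 or not 1 <= position <= length:
        raise ValueError(f"position {position} out of range for length {length}")
    return min(4, ceil(4 * position / length))


def window_average(
    sequence: str,
    position: int,
    window_size: int,
    table: PropertyTable,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Mean of each of the 19 properties over a symmetric window.

    The window spans positions ``[position - window_size,
    position + window_size]`` intersected with the chain, target included.
    """
    length = len(sequence)
    if not 1 <= position <= length:
        raise ValueError(f"position {position} out of range for length {length}")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lo = max(1, position - window_size)
    hi = min(length, position + window_size)
    rows = np.stack([table.values_for(aa) for aa in sequence[lo - 1:hi]])
    return rows.mean(axis=0)


def extract_features(
    chain: ProteinChain,
    table: PropertyTable | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Compute the full 173-feature vector for every residue of a chain.

    Returns a frame with one row per residue: chain_id, position (1-based),
    amino_acid, then the 173 feature columns in the frozen order of
    :func:`feature_names`.
    """
    from hotseq.properties import load_default_properties

    table = table or load_default_properties()
    config = config or FeatureConfig()
    length = chain.length
    codes = list(chain.sequence)

    aa_index = {aa: i for i, aa in enumerate(config.one_hot_order)}
    onehot = np.zeros((length, 20))
    onehot[np.arange(length), [aa_index[aa] for aa in codes]] = 1.0

    quartiles = np.minimum(4, np.ceil(4 * np.arange(1, length + 1) / length)).astype(int)

    prop_matrix = np.stack([table.values_for(aa) for aa in codes])  # L x 19

    # Sliding-window means via prefix sums: O(L) per (window, property).
    prefix = np.vstack([np.zeros(prop_matrix.shape[1]), np.cumsum(prop_matrix, axis=0)])
    window_blocks = []
    idx = np.arange(length)
    for w in config.window_sizes:
        lo = np.maximum(0, idx - w)
        hi = np.minimum(length, idx + w + 1)
        sums = prefix[hi] - prefix[lo]
        window_blocks.append(sums / (hi - lo)[:, None])

    values = np.hstack([onehot, quartiles[:, None].astype(float), prop_matrix, *window_blocks])
    frame = pd.DataFrame(values, columns=feature_names(table, config))
    frame.insert(0, "amino_acid", codes)
    frame.insert(0, "position", np.arange(1, length + 1))
    frame.insert(0, "chain_id", chain.chain_id)
    return frame


def extract_features_many(
    chains: list[ProteinChain],
    table: PropertyTable | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for several chains, concatenated in input order."""
    frames = [extract_features(chain, table, config) for chain in chains]
    return pd.concat(frames, ignore_index=True)
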