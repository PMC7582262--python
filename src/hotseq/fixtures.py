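"""Synthetic chains and labeled residue sets with realistic class structure.

The generator emulates the statistical shape of curated alanine-scanning
hot-spot collections: a few hundred labeled residues over a handful of
chains, roughly one hot spot per three null spots overall, tyrosine enriched
for hot spots, cysteine and methionine never hot, and no alanine at all
(alanine-scanning cannot assay alanine). Hot spots are not scattered
uniformly: each chain carries one or more contiguous "hot segments" whose
composition is biased toward hydrophobic and aromatic residues, mimicking
interface patches. Labels are drawn from a logistic model of the
window-averaged physicochemical properties, so the learnable signal lies, by
construction, inside the same 173-feature space the extractor produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hotseq.fasta_io import STANDARD_AMINO_ACIDS, ProteinChain
from hotseq.features import FeatureConfig, extract_features_many
from hotseq.properties import PropertyTable, load_default_properties
from hotseq.splitting import HS, NS


class FixtureSpecError(ValueError):
    """Raised on infeasible generation targets."""


def _default_hs_ratios() -> dict[str, float]:
    # Tyrosine-enriched hot spots; CYS/MET null-only; no alanine anywhere.
    ratios = {aa: 0.23 for aa in STANDARD_AMINO_ACIDS if aa != "A"}
    ratios["Y"] = 0.55
    ratios["C"] = 0.0
    ratios["M"] = 0.0
    return ratios


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``hs_ratios`` maps amino acid -> target HS fraction; amino acids absent
    from the mapping do not occur in the generated chains, and a ratio of 0
    pins that amino acid to the NS class (single-class types). The overall HS
    rate is the composition-weighted mean of the ratios. ``effect_size`` is
    the logistic slope on the standardized window-averaged informative-
    property score (in score-standard-deviation units); 0 makes labels
    independent of the sequence. ``label_noise`` flips labels with the given
    probability for amino acids with both classes allowed.
    """

    n_chains: int = 8
    chain_length_range: tuple[int, int] = (60, 74)
    total_residues: int = 534
    hs_ratios: dict[str, float] = field(default_factory=_default_hs_ratios)
    informative_properties: tuple[str, ...] = ("hydropathy", "max_asa")
    informative_window: int = 5
    effect_size: float = 6.0
    label_noise: float = 0.0
    segment_bias: float = 3.5
    background_bias: float = 1.25
    segment_length_range: tuple[int, int] = (12, 22)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 1.0:
            raise FixtureSpecError("label_noise must be a probability")
        if self.effect_size < 0:
            raise FixtureSpecError("effect_size must be >= 0")
        for aa, ratio in self.hs_ratios.items():
            if aa not in STANDARD_AMINO_ACIDS:
                raise FixtureSpecError(f"unknown amino acid {aa!r} in hs_ratios")
            if not 0.0 <= ratio <= 1.0:
                raise FixtureSpecError(f"hs_ratio for {aa} must be in [0, 1]")
        if self.n_chains < 1 or self.total_residues < self.n_chains:
            raise FixtureSpecError("need at least one residue per chain")


def paper_like_spec(**overrides) -> FixtureSpec:
    """The bundled realistic spec: 534 residues, ~24% HS, TYR-heavy hot
    segments, single-class CYS/MET, absent ALA."""
    return replace(FixtureSpec(), **overrides) if overrides else FixtureSpec()


def _chain_lengths(spec: FixtureSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.chain_length_range
    lengths = list(rng.integers(lo, hi + 1, size=spec.n_chains))
    # Rescale to hit the requested total exactly, keeping every chain >= 1.
    deficit = spec.total_residues - int(sum(lengths))
    i = 0
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        if lengths[i % spec.n_chains] + step >= 1:
            lengths[i % spec.n_chains] += step
            deficit -= step
        i += 1
    return [int(length) for length in lengths]


def _hot_weights(alphabet: list[str], spec: FixtureSpec, table: PropertyTable) -> np.ndarray:
    """Hot-segment composition: exponential tilt along the informative score,
    with aromatic tyrosine boosted the way interface patches are."""
    values = np.stack([
        np.array([table.frame.at[aa, p] for aa in alphabet], dtype=float)
        for p in spec.informative_properties
    ])
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    tilt = np.exp(spec.segment_bias * z.mean(axis=0))
    # aromatic tyrosine is as common in interface patches as the most
    # hydrophobic residues, despite its unfavourable tilt
    for i, aa in enumerate(alphabet):
        if aa == "Y":
            tilt[i] = tilt.max()
    return tilt / tilt.sum()


def _background_weights(alphabet: list[str], spec: FixtureSpec, table: PropertyTable) -> np.ndarray:
    """Non-interface background: tilted toward hydrophilic surface residues."""
    values = np.stack([
        np.array([table.frame.at[aa, p] for aa in alphabet], dtype=float)
        for p in spec.informative_properties
    ])
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    tilt = np.exp(-spec.background_bias * z.mean(axis=0))
    return tilt / tilt.sum()


def _sample_chain(length: int, alphabet: list[str], hot_w: np.ndarray,
                  bg_w: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> str:
    residues = list(rng.choice(alphabet, size=length, p=bg_w))
    # Cover roughly a quarter of the chain with hot segments.
    target_hot = int(round(0.25 * length))
    covered = 0
    guard = 0
    while covered < target_hot and guard < 20:
        guard += 1
        lo, hi = spec.segment_length_range
        seg_len = min(int(rng.integers(lo, hi + 1)), length, target_hot - covered + lo)
        start = int(rng.integers(0, max(1, length - seg_len + 1)))
        for i in range(start, start + seg_len):
            residues[i] = str(rng.choice(alphabet, p=hot_w))
        covered += seg_len
    return "".join(residues)


def generate_dataset(
    spec: FixtureSpec,
    table: PropertyTable | None = None,
    config: FeatureConfig | None = None,
) -> tuple[list[ProteinChain], pd.DataFrame]:
    """Generate synthetic chains and their labeled residue table.

    The HS probability of residue i is ``sigmoid(effect_size * (score_i - q))``
    where score_i is the standardized mean of the window-averaged informative
    properties and q the global score quantile matching the composition-
    weighted overall HS target; amino acids with a zero HS ratio are pinned to
    NS. At effect size 0 every residue receives the overall rate with no
    per-type pinning — a pure null in which the label is independent of every
    feature, identity included. Labels are then
    flipped with probability ``label_noise`` (never for single-class amino
    acids). Deterministic under ``spec.seed``.
    """
    table = table or load_default_properties()
    config = config or FeatureConfig()
    for name in spec.informative_properties:
        if name not in table.property_names:
            raise FixtureSpecError(f"unknown informative property {name!r}")
    if spec.informative_window not in config.window_sizes:
        raise FixtureSpecError(f"informative_window {spec.informative_window} not among window sizes")

    rng = np.random.default_rng(spec.seed)
    alphabet = sorted(spec.hs_ratios)
    if not alphabet:
        raise FixtureSpecError("hs_ratios must allow at least one amino acid")

    hot_w = _hot_weights(alphabet, spec, table)
    bg_w = _background_weights(alphabet, spec, table)
    chains = [
        ProteinChain(
            chain_id=f"synthetic|chain_{i + 1}",
            sequence=_sample_chain(length, alphabet, hot_w, bg_w, spec, rng),
        )
        for i, length in enumerate(_chain_lengths(spec, rng))
    ]

    features = extract_features_many(chains, table, config)
    cols = [f"win{spec.informative_window}_{name}" for name in spec.informative_properties]
    block = features[cols].to_numpy()
    z = (block - block.mean(axis=0)) / np.where(block.std(axis=0) > 0, block.std(axis=0), 1.0)
    score = z.mean(axis=1)

    aas = features["amino_acid"].to_numpy()
    eligible = np.array([spec.hs_ratios[aa] > 0 for aa in aas])
    counts = pd.Series(aas).value_counts()
    overall = float(sum(counts.get(aa, 0) * r for aa, r in spec.hs_ratios.items()) / len(aas))

    prob = np.zeros(len(features))
    if spec.effect_size == 0:
        # Pure null: a single overall rate for every residue, no per-type
        # pinning, so not even the one-hot identity block predicts the label.
        prob[:] = overall
    elif eligible.any() and 0.0 < overall < 1.0:
        q = np.quantile(score[eligible], 1.0 - overall / eligible.mean())
        with np.errstate(over="ignore"):
            prob[eligible] = 1.0 / (1.0 + np.exp(-spec.effect_size * (score[eligible] - q)))

    labels = rng.random(len(prob)) < prob
    if spec.label_noise > 0:
        flippable = np.array([0.0 < spec.hs_ratios[aa] < 1.0 for aa in aas])
        flips = (rng.random(len(prob)) < spec.label_noise) & flippable
        labels = labels ^ flips

    label_frame = pd.DataFrame(
        {
            "chain_id": features["chain_id"],
            "position": features["position"],
            "amino_acid": features["amino_acid"],
            "label": np.where(labels, HS, NS),
        }
    )
    return chains, label_frame
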