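"""Per-amino-acid hot-spot probability correction.

Class imbalance differs by residue type, so a single 0.5 probability cutoff
under-calls hot spots for some amino acids. The correction is fitted on a
tuning split, separately per amino acid: let mFN be the highest raw HS
probability among false negatives (actual HS predicted NS) and mTN the
highest among true negatives. When false negatives exist and mFN > mTN, the
correction factor is

    correction = 0.50 - mFN

added to every raw HS probability of that amino acid, which lifts exactly the
false negatives above the 0.5 line while provably creating no new false
positives on the tuning set: every true negative's raw probability is at most
mTN < mFN, so raw + (0.50 - mFN) < 0.50.

A residue is classified HS when its corrected probability reaches 0.50
(closed boundary, so the maximal lifted false negative is recovered); the
pre-correction class uses the strict raw > 0.5 rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hotseq.splitting import HS, NS

#: Raw-probability decision rule (pre-correction): HS iff raw > RAW_THRESHOLD.
RAW_THRESHOLD = 0.5
#: Corrected-probability decision rule: HS iff corrected >= CORRECTED_THRESHOLD.
CORRECTED_THRESHOLD = 0.5


class CalibrationError(ValueError):
    """Raised on an empty or invalid tuning set."""


@dataclass(frozen=True)
class CalibrationTable:
    """Per-amino-acid additive corrections to the raw HS probability.

    ``correction`` maps amino-acid code -> non-negative factor in [0, 0.5];
    amino acids absent from the tuning set carry 0 (no extrapolation across
    residue types). ``stats`` records, per amino acid, the max false-negative
    and max true-negative HS probabilities observed during fitting.
    """

    correction: dict[str, float] = field(default_factory=dict)
    fitted_on: str = ""
    stats: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa, value in self.correction.items():
            if not 0.0 <= value <= 0.5:
                raise CalibrationError(f"correction for {aa} out of [0, 0.5]: {value}")

    def factor(self, aa: str) -> float:
        return self.correction.get(aa, 0.0)

    def to_json(self, path: str | Path) -> None:
        payload = {"correction": self.correction, "fitted_on": self.fitted_on, "stats": self.stats}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            correction=payload["correction"],
            fitted_on=payload.get("fitted_on", ""),
            stats=payload.get("stats", {}),
        )


def fit_correction_from_probabilities(
    raw_probabilities: Sequence[float] | np.ndarray,
    labels: Sequence[str],
    amino_acids: Sequence[str],
    *,
    fitted_on: str = "",
) -> CalibrationTable:
    """Fit the per-amino-acid correction from raw tuning-set probabilities.

    For each amino acid present in the tuning set: correction =
    clamp(0.50 - mFN, 0, 0.5) when false negatives exist and mFN exceeds mTN
    (mTN taken as -inf when no true negatives exist), else 0.
    """
    raw = np.asarray(raw_probabilities, dtype=float)
    if raw.size == 0:
        raise CalibrationError("empty tuning set")
    if not (len(labels) == len(amino_acids) == raw.size):
        raise CalibrationError("raw probabilities, labels and amino acids must align")

    predicted_ns = raw <= RAW_THRESHOLD
    actual_hs = np.asarray([lbl == HS for lbl in labels])
    aas = np.asarray(amino_acids)

    correction: dict[str, float] = {}
    stats: dict[str, dict[str, float | None]] = {}
    for aa in sorted({str(a) for a in aas}):
        mask = aas == aa
        fn = mask & actual_hs & predicted_ns
        tn = mask & ~actual_hs & predicted_ns
        m_fn = float(raw[fn].max()) if fn.any() else None
        m_tn = float(raw[tn].max()) if tn.any() else None
        stats[aa] = {"max_false_negative_probability": m_fn, "max_true_negative_probability": m_tn}
        guard = m_fn is not None and (m_tn is None or m_fn > m_tn)
        correction[aa] = float(np.clip(0.50 - m_fn, 0.0, 0.5)) if guard else 0.0
    return CalibrationTable(correction=correction, fitted_on=fitted_on, stats=stats)


def fit_correction(model, tuning_features: pd.DataFrame, tuning_labels: Sequence[str], *, fitted_on: str = "tuning") -> CalibrationTable:
    """Fit the correction from a model and a labeled tuning feature table.

    The tuning set must be disjoint from the training data (caller's
    responsibility; the pipeline asserts it via the training fingerprint).
    """
    from hotseq.model import predict_hs_probability

    if len(tuning_features) == 0:
        raise CalibrationError("empty tuning set")
    raw = predict_hs_probability(model, tuning_features)
    return fit_correction_from_probabilities(
        raw, list(tuning_labels), list(tuning_features["amino_acid"]), fitted_on=fitted_on
    )


def apply_correction(predictions: pd.DataFrame, table: CalibrationTable) -> pd.DataFrame:
    """Add corrected probabilities and final classes to a prediction table.

    ``predictions`` needs columns amino_acid and raw_hs_probability. Output
    adds corrected_hs_probability = min(1, raw + correction), a
    predicted_class_raw column (HS iff raw > 0.5) and predicted_class (HS iff
    corrected >= 0.5). Residues already classified HS keep their class.
    """
    out = predictions.copy()
    factors = out["amino_acid"].map(table.factor).fillna(0.0).to_numpy()
    raw = out["raw_hs_probability"].to_numpy(dtype=float)
    corrected = np.minimum(1.0, raw + factors)
    out["corrected_hs_probability"] = corrected
    out["predicted_class_raw"] = np.where(raw > RAW_THRESHOLD, HS, NS)
    # The closed >= boundary exists to recover the maximal lifted false
    # negative (raw + correction == 0.50 exactly); with a zero correction the
    # calibration must be a strict identity, so the boundary rule only
    # applies where a positive correction was fitted.
    lifted = (factors > 0) & (corrected >= CORRECTED_THRESHOLD)
    out["predicted_class"] = np.where((raw > RAW_THRESHOLD) | lifted, HS, NS)
    return out
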