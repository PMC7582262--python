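"""Optional: run the pipeline against the published curated dataset.

The published benchmark of sequence-only hot-spot prediction was trained on
a curated set of 534 alanine-scanning residues (127 HS / 407 NS) deposited
at https://github.com/MoreiraLAB/spotone. That dataset is an external
download and the original 19-property value table and split seed were not
published, so agreement with the published summary metrics is expected to be
approximate only. This script is NOT part of the test suite and requires the
user to fetch the data first.

Expected label CSV schema: chain_id, position, amino_acid, label[, ddg],
with label in {HS, NS}; FASTA with one entry per chain matching chain_id.

Usage:
    python scripts/reproduce_published.py \
        --fasta <downloaded chains.fasta> --labels <downloaded labels.csv> \
        --seed 0 --out-dir results/published
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from hotseq.model import ModelParams
from hotseq.pipeline import RunConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", type=Path, required=True)
    parser.add_argument("--labels", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/published"))
    args = parser.parse_args()

    config = RunConfig(
        fasta_path=args.fasta,
        labels_path=args.labels,
        out_dir=args.out_dir,
        seed=args.seed,
        model_params=ModelParams(random_seed=args.seed),
    )
    result = run_pipeline(config)
    print(json.dumps({"independent": result.independent_metrics,
                      "tuning": result.tuning_metrics}, indent=2))


if __name__ == "__main__":
    main()
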