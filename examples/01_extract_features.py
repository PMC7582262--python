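"""Extract the 173 per-residue features for the bundled example chains.

Every residue of a protein chain is described from sequence alone: its
one-hot identity (20), the quarter of the chain it sits in (1), its 19
physicochemical property values, and those properties averaged over seven
symmetric sequence windows (133).
"""

from hotseq import extract_features, load_default_properties
from hotseq.fasta_io import load_example_chains

chains = load_example_chains()
table = load_default_properties()

for chain in chains:
    frame = extract_features(chain, table)
    n_features = frame.shape[1] - 3  # minus chain_id, position, amino_acid
    print(f"{chain.chain_id}: {chain.length} residues x {n_features} features")

# Look at one residue in detail: the first tyrosine of the heavy chain.
frame = extract_features(chains[0], table)
tyr = frame[frame.amino_acid == "Y"].iloc[0]
print(f"\nfirst TYR at position {int(tyr.position)}:")
print(f"  quartile              {int(tyr.position_quartile)}  (1 = N-terminal quarter)")
print(f"  hydropathy (raw)      {tyr.hydropathy:+.2f}  (Kyte-Doolittle, negative = hydrophilic)")
print(f"  hydropathy (win +-5)  {tyr.win5_hydropathy:+.2f}  (mean over the 11-residue neighbourhood)")
print(f"  hydropathy (win +-75) {tyr.win75_hydropathy:+.2f}  (saturates to the whole-chain mean)")
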