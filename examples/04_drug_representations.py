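"""The six drug representation schemes computed from standardized SMILES.

A drug can enter the model as a 1024-bit Morgan (ECFP4-equivalent) or
layered fingerprint, a tokenized one-hot SMILES matrix for TextCNN, a
molecular graph for GCN/GAT encoders, a precomputed 512-d embedding, or
a bare one-hot identifier (the diagnostic baseline that cannot
generalize to unseen drugs).
"""

from synscreen.drug_features import (
    SmilesVocab,
    bit_atom_environments,
    layered_fingerprint,
    morgan_fingerprint,
    one_hot_identity,
    smiles_to_graph,
    tokenize_and_encode,
)

smiles = "CC(=O)Oc1ccccc1C(=O)O"  # aspirin
fp = morgan_fingerprint(smiles)
print(f"Morgan r2/1024: {int(fp.bits.sum())} bits on; first on-bits {fp.on_bits[:6]}")
print(f"layered/1024:   {int(layered_fingerprint(smiles).bits.sum())} bits on")

# each on-bit corresponds to one or more circular atom environments
bit = fp.on_bits[0]
print(f"bit {bit} environments (center atom, radius): "
      f"{bit_atom_environments(smiles, bit)}")

vocab = SmilesVocab.fit([smiles, "CCO", "c1ccncc1Cl"])
enc = tokenize_and_encode("CCOc1ccccc1Br", vocab, max_len=30)
print(f"tokens ({len(enc.tokens)}): {list(enc.tokens)}")
print(f"one-hot matrix {enc.one_hot.shape}, row sums pad correctly: "
      f"{enc.one_hot.sum(axis=1)[:len(enc.tokens)].tolist()}")

graph = smiles_to_graph(smiles)
print(f"graph: {graph.n_atoms} atoms, {int(graph.adjacency.sum() / 2)} bonds, "
      f"node features {graph.node_features.shape[1]}-d")

print("one-hot id for DRUG-B over [A, B, C]:",
      one_hot_identity("DRUG-B", ["DRUG-A", "DRUG-B", "DRUG-C"]).tolist())
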