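"""Relation builders and the TSV interchange formats.

Builds a drug-drug Tanimoto similarity matrix from Morgan fingerprints
(computed from SMILES with RDKit), row-normalizes an alignment-score matrix,
and round-trips an interaction table through the file readers.
"""

import numpy as np

from erfusion import (read_interactions, row_normalize, smiles_fingerprints,
                      tanimoto_matrix)

drugs = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}
fps = smiles_fingerprints(drugs, n_bits=1028, radius=2)
S = tanimoto_matrix(fps)
print("Tanimoto similarity (Morgan radius 2, 1028 bits):")
for i, a in enumerate(fps.ids):
    row = "  ".join(f"{S[i, j]:.2f}" for j in range(len(fps.ids)))
    print(f"  {a:12s} {row}")
print("Aspirin/ibuprofen share carboxylic-acid chemistry, hence the largest")
print("off-diagonal entry; the diagonal is 1 by definition.")

bitscores = np.array([[90.0, 30.0, 0.0], [30.0, 80.0, 10.0], [0.0, 10.0, 70.0]])
print("\nrow-normalized alignment scores (each row sums to 1):")
print(np.round(row_normalize(bitscores), 3))

import tempfile, pathlib
with tempfile.TemporaryDirectory() as d:
    p = pathlib.Path(d) / "interactions.tsv"
    p.write_text("aspirin\tCOX1\t1\naspirin\tCOX2\t1\ncaffeine\tCOX1\t0\n")
    cells, values, drug_ids, protein_ids = read_interactions(p)
    print(f"\nread {len(cells)} cells; registries: {drug_ids} x {protein_ids}")
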