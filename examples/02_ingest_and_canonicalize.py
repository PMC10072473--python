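"""Canonicalize a raw screen table and standardize compound structures.

A raw ALMANAC-style table stores <cell line, drugA, drugB> triplets in
both drug orders; reverse-order records are the same experiment, so they
are collapsed onto the lexicographically ordered pair with their scores
averaged. Structures arrive as salt-containing SMILES and are reduced to
the standardized parent compound.
"""

import io
import tempfile
from pathlib import Path

from synscreen.ingest import deduplicate_triplets, read_screen_table, standardize_structure

raw_csv = """cell_line_id,drug_a_id,drug_b_id,combo_score
SR,NSC-609699,NSC-715055,108.0
SR,NSC-715055,NSC-609699,104.0
SR,NSC-609699,NSC-3088,55.0
MDA-N,NSC-609699,NSC-715055,12.0
"""
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "screen.csv"
    path.write_text(raw_csv)
    table = read_screen_table(path, excluded_cell_lines={"MDA-N"})

print(f"read {len(table)} raw records; excluding {sorted(table.excluded_cell_lines)}")
canonical = deduplicate_triplets(table)
print(canonical.records.to_string(index=False))
# the SR / NSC-609699+NSC-715055 pair collapses to one record at the
# mean score (108+104)/2 = 106, and the excluded cell line is dropped.

for raw in ["CCO.Cl", "OCC", "C[NH3+].[Cl-]"]:
    print(f"{raw!r:18} -> {standardize_structure(raw)!r}")
# salt/solvent fragments are stripped and charges neutralized, so all
# writings of the same parent compound map to one canonical SMILES.
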