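"""Structural analytics on a small synthetic coordinate model: salt bridges
and spatial clustering of substitutions.

The PDB fixture is synthetic (three residues placed by hand) so the example
runs without downloads; point it at a real single-chain PDB file to analyze
an actual design.
"""
from pathlib import Path

from deepevo.analysis import (mutation_profile, salt_bridges,
                              spatial_mutation_clusters)
from deepevo.seqio import SequenceRecord, read_structure

pdb_text = """\
ATOM      1  CA  LYS A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  NZ  LYS A   1       0.000   3.000   0.000  1.00  0.00           N
ATOM      3  CA  GLU A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  OE1 GLU A   2       3.500   3.000   0.000  1.00  0.00           O
ATOM      5  CA  ALA A   3       9.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY A   4      25.000   0.000   0.000  1.00  0.00           C
END
"""
path = Path("scratch/example_structure.pdb")
path.parent.mkdir(exist_ok=True)
path.write_text(pdb_text)

structure = read_structure(path, "A")
bridges = salt_bridges(structure, cutoff=4.0)
print(f"salt bridges: {bridges.count}")
for b in bridges.pairs:
    print(f"  Glu{b.acidic_residue}-Lys{b.basic_residue} "
          f"({b.atom_pair[0]}...{b.atom_pair[1]}, {b.distance:.2f} A)")

variant = SequenceRecord("var", "KESG")
reference = SequenceRecord("ref", "KEAG")  # A3S substitution
mutations, _ = mutation_profile(variant, reference)
# pretend positions 1-3 all mutated to show clustering, 4 is far away
from deepevo.analysis import MutationSet
mutations = MutationSet("ref", "var", [(1, "K", "R"), (2, "E", "D"),
                                       (3, "A", "S"), (4, "G", "A")])
clusters = spatial_mutation_clusters(mutations, structure, cutoff=8.0)
print(f"spatial clusters: {[sorted(c) for c in clusters.clusters]}, "
      f"singles {sorted(clusters.singles)}")
print(f"clustered fraction: {clusters.clustered_fraction:.2f}")
print("-> residues 1-3 sit within 8 A of each other (one mutation network); "
      "residue 4 is an isolated single change.")
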