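"""Simulate a synthetic enzyme family with a planted thermal signal.

Builds the default desk-scale family (400 sequences, length 128, ten
invariant motif positions, sixteen charged-trait sites), writes it as
FASTA + OGT TSV, and prints summary statistics.
"""
from pathlib import Path

import numpy as np

from deepevo import synthdata
from deepevo.candidate_selection import percent_identity
from deepevo.seqio import CHARGED_RESIDUES, HTTP

records, truth, ogt = synthdata.default_family(seed=7)
out = Path("scratch/example_family")
fasta, tsv = synthdata.write_fixture(records, ogt, out)

config = synthdata.FamilyConfig()
rng = np.random.default_rng(0)
sample = [records[i] for i in rng.choice(len(records), 20, replace=False)]
mean_id = np.mean([percent_identity(a.residues, b.residues)
                   for i, a in enumerate(sample) for b in sample[i + 1:]])

traits = sorted(config.trait_positions)
def charged_fraction(cls):
    recs = [r for r in records if truth.per_record_class[r.id] == cls]
    return np.mean([[r.residues[p - 1] in CHARGED_RESIDUES for p in traits]
                    for r in recs])

print(f"wrote {fasta} and {tsv}")
print(f"mean pairwise identity (20-seq sample): {mean_id:.1f}%")
print(f"charged fraction at trait sites: HTTP {charged_fraction('HTTP'):.2f}, "
      f"LTTP {charged_fraction('LTTP'):.2f}")
print("-> the ~0.6 gap between the classes is the planted signal the "
      "selector must recover; identity ~86% makes this a realistic family.")
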