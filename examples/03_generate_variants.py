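"""Train the GAN variant generator and check the fidelity of its samples.

Fidelity readouts: per-column Shannon-entropy correlation with the natural
family (positional variability), decoding validity, and discriminator score
separation between natural and uniform-random sequences.
"""
import numpy as np

from deepevo import synthdata, variant_generator as vg
from deepevo.analysis import positional_entropy
from deepevo.seqio import AMINO_ACIDS, SequenceRecord

records, truth, _ = synthdata.default_family(seed=7)
pair = vg.train_gan(records, vg.GanConfig(total_steps=1200, seed=1))

generated, n_invalid = vg.generate(pair, 300, seed=9,
                                   return_invalid_count=True)
nat = positional_entropy([r.residues for r in records])
gen = positional_entropy([g.residues.ljust(128, "-")[:128]
                          for g in generated])
ok = ~np.isnan(nat) & ~np.isnan(gen)
r = np.corrcoef(nat[ok], gen[ok])[0, 1]

rng = np.random.default_rng(3)
junk = [SequenceRecord(f"r{i}", "".join(rng.choice(list(AMINO_ACIDS), 128)))
        for i in range(64)]
s_nat = np.mean([s for _, s in vg.discriminator_score(pair, records[:64])])
s_junk = np.mean([s for _, s in vg.discriminator_score(pair, junk)])

print(f"valid samples: {len(generated)}/300 ({n_invalid} invalid)")
print(f"entropy-profile Pearson r vs natural family: {r:.3f}")
print(f"discriminator score: natural {s_nat:.2f} vs random {s_junk:.2f}")
print("-> r >= 0.7 means generated sequences vary where the family varies "
      "and are conserved where it is conserved; the discriminator ranks "
      "family members above random sequences.")
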