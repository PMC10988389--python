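# deepevo

In-silico deep evolution of thermotolerant enzymes: a GAN **variant
generator** confined to one enzyme family and an OGT-supervised
**thermotolerance selector**, iterated so that generated functional
sequences are progressively enriched for the high-temperature trait — plus
the downstream candidate-selection filters (discriminator score, gap-free
functional motif, identity band to the nearest natural sequence, plddt
hook) and the sequence/structure analytics used to understand what the
designed variants changed (mutation profiles, salt bridges, spatial
mutation clusters, positional entropy).

The package is aimed at protein-engineering groups who want to prototype
generate-and-select evolution loops, and at methods researchers who need a
fully testable desk-scale replica of the procedure: a synthetic-family
module generates every input, so nothing is downloaded and every pipeline
stage is covered by oracle-checked tests.

## The models

**Selector.** Sequences are labeled by the optimal growth temperature
(OGT) of their source organism: OGT ≥ 50 °C → HTTP
(high-temperature-tolerant protein), OGT < 30 °C → LTTP, mid-range
excluded. A 3-layer MLP (input : 64 : 16 : 1, sigmoid head) is trained
with binary cross-entropy (Adam, lr 10⁻³, batch 100, 75 epochs) on either
external protein-language-model embeddings (TSV hook) or the built-in
420-d compositional embedding. A probability ≥ 0.5 counts as HTTP.

**Generator.** A GAN over fixed-length one-hot sequence matrices
(L × 21: 20 residues + terminal pad). Both networks are residual blocks of
three 1-D convolutions with ReLU plus one multi-head self-attention block;
training uses the nonsaturating loss with R1 regularization
(γ/2)·E‖∇ₓD‖², Adam with learning rate decayed 10⁻³ → 5·10⁻⁵, and batches
of 64 generated + 64 natural sequences. A likelihood warm start with a
persistent anchor makes desk-scale (CPU) training converge; see
`docs/methods.md`.

**Loop.** generate → keep top 20 % by discriminator score → require the
functional motif (e.g. NAD-binding residues 12, 13, 35, 78, 316 and
substrate-binding 151, 152, 181, 183, 234 of the template) to align
gap-free → classify with the selector → feed predicted HTTPs plus all
natural HTTPs back into continued generator training. The per-round HTTP
fraction (predicted HTTP / motif-passing) is the enrichment readout.

## Worked example

```python
from deepevo import synthdata, thermo_selector as ts, variant_generator as vg
from deepevo import deepevo_loop as dl
from deepevo.candidate_selection import MotifSpec
from deepevo.seqio import HTTP

records, truth, ogt = synthdata.default_family(seed=7)

dataset = ts.LabeledDataset.from_ogt(records, ogt)
embedder = ts.composition_embedder()
selector = ts.train_selector(dataset, embedder, seed=3)
print(f"selector held-out accuracy: "
      f"{ts.evaluate(selector, embedder, dataset).accuracy:.3f}")

pair = vg.train_gan(records, vg.GanConfig(total_steps=1500, seed=1))
motif = MotifSpec("ancestor", truth.ancestor,
                  tuple(sorted(synthdata.FamilyConfig().motif_positions)))
state = dl.EvolutionState(
    gan=pair, selector=selector, embedder=embedder,
    natural_pool=records, motif=motif,
    natural_http=[r for r in records
                  if truth.per_record_class[r.id] == HTTP])
r1 = dl.run_round(state, 400, seed=5)
dl.refine_generator(state, steps=500, seed=6)
r2 = dl.run_round(state, 400, seed=7)
print(f"round 1 HTTP fraction: {r1.http_fraction:.3f}")
print(f"round 2 HTTP fraction: {r2.http_fraction:.3f}")
```

Typical output (about five minutes on one CPU):

```
selector held-out accuracy: 0.983
round 1 HTTP fraction: 0.425
round 2 HTTP fraction: 0.812
```

The selector recovers the planted charged-residue signal almost perfectly;
after one feedback refinement the fraction of generated, motif-passing
sequences classified as thermotolerant rises — the desk-scale analogue of
the enrichment that motivates the iterative procedure.

Short narrative scripts, one per capability, live in `examples/`:

```sh
python examples/01_simulate_family.py
python examples/02_train_selector.py
python examples/03_generate_variants.py
python examples/04_evolution_loop.py
python examples/05_select_candidates.py
python examples/06_structure_analysis.py
```

A thin command-line interface wraps the same functions
(`deepevo simulate|train-selector|train-generator|generate|evolve|
select-candidates|analyze`); every command writes a run manifest with the
config hash and seeds.

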