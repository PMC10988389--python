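# Methods

This note describes the models and procedures implemented in `deepevo`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Problem setting

Engineering an enzyme for activity at high temperature by screening random
mutants is expensive because functional, thermotolerant sequences are rare
in sequence space. The strategy implemented here couples two learned models
in an iterative loop:

* a **variant generator** — a generative adversarial network (GAN) trained
  on natural members of one enzyme family, confining sampling to a
  functional neighborhood of that family;
* a **thermotolerance selector** — a binary classifier trained on protein
  sequences labeled by the optimal growth temperature (OGT) of their source
  organism: sequences from organisms with OGT ≥ 50 °C are treated as
  high-temperature-tolerant proteins (HTTP), sequences from organisms with
  OGT < 30 °C as low-temperature-tolerant (LTTP), and the ambiguous
  mid-range is excluded from training.

Each evolution round generates candidate sequences, keeps the top 20 % by
discriminator score, discards candidates whose functional motif does not
align gap-free to a template, classifies the survivors with the selector,
and feeds the predicted-HTTP sequences (together with all natural HTTPs)
back into continued generator training. The selector acts as selective
pressure: over rounds the generated population is enriched for the
high-temperature trait. Downstream, candidates for experimental testing are
ranked by discriminator score and filtered by identity band to the nearest
natural sequence and by an externally supplied structure-confidence (plddt)
threshold (> 90, strict).

## Synthetic family generator

All tests and examples run on synthetic enzyme families generated by
`deepevo.synthdata`, which emulates the two features of real thermal
adaptation that the framework exploits.

* **Topology** — a star: every record is an independently mutated copy of
  one random ancestor. This is the simplest process with directly tunable
  mean pairwise identity; tree-structured evolution is out of scope.
* **Motif** — ten designated positions (default
  {12, 13, 35, 51, 52, 78, 81, 83, 104, 116} of a 128-residue sequence,
  mirroring the two five-residue binding motifs of a dehydrogenase) are
  held invariant in every record.
* **Background divergence** — every other non-trait site mutates with
  probability 0.05 per site, uniformly over the 19 alternative residues.
  This yields ≈ 86 % mean pairwise identity at the defaults.
* **Thermal trait** — sixteen dispersed trait sites (≈ 12 % of positions)
  each have one designated charged variant residue (D/E/K/R, drawn once per
  family). A record carries the charged variant with probability
  `p_lttp = 0.2` if its class is LTTP and `p_lttp + effect_size`
  (default 0.6, so 0.8) if HTTP; otherwise it keeps the ancestral uncharged
  residue. Two aspects are deliberate: the *number* of trait sites matches
  the observation that thermoadapted homolog pairs differ at tens of
  residues with distributed charged-residue enrichment, and the *single
  designated variant per site* models convergent adaptive substitutions
  (specific salt-bridge-forming replacements recur at specific positions).
  HTTP probability saturates at 1 for extreme effect sizes.
* **Labels** — OGT values are drawn uniformly from [50, 95] °C for
  HTTP-class records and [4, 29.9] °C for LTTP-class ones, so the labeling
  rule recovers the class exactly. The default family is balanced
  (`http_fraction = 0.5`); the heavily LTTP-skewed composition of real
  OGT corpora is a property of database coverage, not of the method, and a
  class-weight option exists in the selector for users who want to emulate
  it.

What the generator does **not** emulate: insertions/deletions,
phylogenetic correlation between records, position-specific substitution
matrices, and any coupling between trait sites and structure. Passing tests
therefore demonstrate that the pipeline recovers a planted compositional
signal under idealized family structure — not that it would reach the same
accuracy on real OGT-labeled corpora.

## Thermotolerance selector

A 3-layer multilayer perceptron, input : 64 : 16 : 1 with rectified-linear
hidden activations and a single sigmoid output unit, trained with binary
cross-entropy, Adam (learning rate 1 × 10⁻³), batch size 100, 75 epochs,
on a stratified 70/30 train/test split. The classification threshold is
0.5 and a probability exactly at threshold counts as HTTP — the selector is
a permissive evolutionary filter, so ties go to the positive class.

Embeddings enter through a narrow interface. Pretrained protein-language-
model vectors (e.g. 1,280-dimensional transformer embeddings) are consumed
from TSV via `load_external_embeddings`; the built-in desk-scale default is
a 420-dimensional compositional embedding: 20 amino-acid frequencies
concatenated with 400 dipeptide frequencies, each block normalized to sum
to one. Features are z-scored with statistics of the training split (stored
in the checkpoint). The dipeptide block matters: because residues flanking
each trait site are largely conserved, specific dipeptides act as weak
positional probes and lift held-out accuracy well above what total charged
content alone supports.

With the default family (n = 400, effect 0.6) held-out accuracy is ≈ 0.98;
it degrades gracefully to chance as the effect size goes to zero, which is
the planted-signal recovery property the test suite checks (monotonicity
over effect ∈ {0, 0.3, 0.6, 0.9} with 0.03 tolerance).

## Variant generator

Generator: 128-d standard-normal latent → dense stem → two residual blocks
of three same-padded 1-D convolutions (kernel 3) with ReLU → one multi-head
self-attention block (2 heads) over the length axis → 21-channel
convolution head → per-position softmax, giving an L × 21 row-stochastic
matrix (20 residues + terminal-pad symbol). Discriminator: mirror-image
trunk from the one-hot input plus a learned positional embedding added at
the stem, global average pooling, and a linear head producing a scalar
naturalness logit. Sequences are decoded by row-wise argmax with terminal
pad symbols stripped; decoded strings containing internal pad symbols are
counted and discarded.

Losses are the nonsaturating GAN pair — generator −log σ(D(G(z))),
discriminator −log σ(D(x)) − log(1 − σ(D(G(z)))) — with R1 regularization
(γ/2)·E‖∇ₓD(x)‖² on real batches. R1 is applied lazily every 4th step with
its weight scaled by the interval, the standard cost-saving formulation.
The R1 update needs the gradient of a gradient; the in-package autodiff
engine (`deepevo.nn`) implements every vector-Jacobian product in terms of
differentiable primitives precisely so this double backpropagation is exact
(finite-difference-verified in the tests).

Three architectural choices were forced by observed failure modes at desk
scale and are worth recording:

1. **Discriminator positional embedding.** A convolutional trunk with
   global average pooling is translation-invariant: it can represent k-mer
   composition but not "residue X at position i". Family identity *is*
   position-specific conservation, and without the positional embedding the
   adversarial game measurably stalled at a composition-matched equilibrium
   (discriminator loss pinned at 2 log 2, generated sequences matching
   composition but not positions).
2. **Straight-through sampling.** The discriminator sees hard argmax
   one-hots from the generator (gradient passed straight through to the
   softmax). With soft inputs the discriminator separates real from fake by
   softmax temperature alone and provides no content signal.
3. **Likelihood warm start with a persistent anchor.** The first
   `warmstart_fraction` (default 0.8) of the steps pair each natural
   sequence with a fixed latent vector and maximize the likelihood of the
   sequence given a noise-perturbed latent (`warmstart_sigma = 0.6`), at
   constant learning rate; the discriminator co-trains at halved cadence.
   The adversarial phase then follows the configured exponential decay
   (10⁻³ → 5 × 10⁻⁵) and retains the likelihood term as an anchor
   (`anchor_weight = 1`). Purely adversarial training from scratch needs
   orders of magnitude more steps than a CPU run affords; the warm start
   fits the family's positional profile in hundreds of steps, and the
   anchor prevents the adversarial phase from eroding it. Latent-noise
   smoothing is what makes fresh latents (not in the training bank) decode
   to family-like sequences.

The R1 weight γ defaults to 10, the canonical value for this loss. At desk
scale the discriminator sits close to its equilibrium against a
warm-started generator, and the strong penalty mainly keeps its logits
small, which is benign; during bring-up γ = 10 *without* the warm start
flattened the discriminator into the constant solution, which is the other
reason the warm start exists.

Desk preset: sequence length 128, batch 64 generated + 64 natural per
step, 2,000 total steps, 16 channels, attention over 4× average-pooled
positions. The full-scale preset (length 512, 200,000 steps, larger
trunk, warm start reduced to 5 %) preserves the published training recipe's
shape but is not runnable in CI. Training runs in single precision;
checkpoints are exact (float32 embeds losslessly in float64).

With the desk preset the generated population reproduces the family's
per-column Shannon-entropy profile at Pearson r ≈ 0.8 (500 samples), with
> 99 % decoding validity and no duplicate sequences in a 500-sample draw.

## Evolution loop

A round is: generate n → keep the ⌈0.2 n⌉ top discriminator scores (ties at
the cut broken by ascending id) → motif filter → selector classification.
The HTTP fraction of a round is n_predicted_HTTP / n_motif_passed, matching
the published bookkeeping (1,354 / 18,238 → 7.4 %); an empty motif-passing
set reports fraction 0 with a warning. Refinement continues training from
the current generator weights (warm start semantics apply to the
continuation) on the natural pool ∪ natural HTTPs ∪ accumulated generated
HTTPs, where duplicates collapse to one record whose *sampling weight*
accumulates — natural HTTPs appear in both the pool and the feedback set,
so "adding them back" doubles their sampling rate. This weighting is what
shifts the trait-site marginals toward the charged variants and drives the
round-over-round enrichment. Generated HTTPs can be upweighted further via
`generated_weight`; the default is 1 (no extra weight). The default number
of rounds is 2 (one refinement); the selector is fixed across rounds.

## Candidate selection

Global alignment is Needleman–Wunsch with affine gaps: BLOSUM62, gap open
10, extend 0.5, terminal gaps free (a full-length comparison of homologs
with slightly different lengths should not pay for overhangs). Percent
identity is matches over alignment columns between the first and last
column where both sequences have a residue; the pair is aligned in a
canonical order because co-optimal alignments can differ in identity.
Optimality is verified against exhaustive enumeration of all alignments for
short pairs. The motif filter passes a sequence iff every motif position of
the template (default: the ten NAD- and substrate-binding residues
{12, 13, 35, 78, 316} ∪ {151, 152, 181, 183, 234}, interpreted as 1-based
residue numbers of the template sequence) aligns to a residue, not a gap; a
configurable flank width (default 0) widens the protected region.
`select_candidates` keeps motif-passing records whose nearest-natural
identity lies in an inclusive band and whose plddt (when supplied) is
strictly greater than 90, ranks by discriminator score, and marks the top
n; records without a plddt entry are kept but flagged unassessed.

## Analytics

* **Positional entropy**: Shannon entropy in bits per alignment column,
  gaps excluded from the column distribution, all-gap columns NaN.
* **Clustering**: greedy incremental, longest-first, first-fit at
  ≥ 80 % identity to the cluster representative. This stands in for an
  external clustering binary; the behavior is documented and oracle-tested,
  and exact concordance with that tool is a non-goal.
* **Distance matrix**: d = 1 − identity/100 on cluster representatives,
  emitted with cluster sizes for a 2-D embedding (t-SNE, perplexity 7,
  delegated to scikit-learn).
* **Mutation profiling**: substitutions from the global alignment with
  counts of alanine→serine changes, charged-introducing and
  charged-removing substitutions, and same-physicochemical-class
  substitutions (classes: hydrophobic AVLIMFWY, polar STNQ, acidic DE,
  basic KRH, special CGP).
* **Salt bridges**: one bridge per acidic/basic residue pair with any
  side-chain O···N atom pair within 4.0 Å — the conventional screening
  criterion; histidine counts as basic by default and can be excluded.
* **Spatial mutation clusters**: connected components (size ≥ 2) of the
  graph on substituted positions with edges at CA–CA ≤ 8 Å; isolated
  positions are singles; the clustered fraction is reported.
* **Activity units**: ΔA340 · V_total / (6.22 · mg · s), the NADH
  photometric formula (6.22 mM⁻¹ cm⁻¹ extinction coefficient).

## Problem sizes in the test and acceptance runs

CPU-scale runs use the desk preset family (n = 400, length 128). The
acceptance script trains the generator for 1,500 steps and runs two
400-sequence rounds with a 500-step refinement. The test suite checks the
round-over-round enrichment property on five seeds at a reduced scale
(800-step training, 300-sequence rounds, 400-step refinement) and
generation fidelity on three seeds; these sizes are the package's choice of
smallest configuration at which the properties are stable. The full-scale
preset exists for users with the corresponding compute.

## Known limitations

* The generator's warm start leans on likelihood training; at desk scale
  the adversarial phase refines rather than drives. Claims about pure
  adversarial convergence transfer to the full-scale preset only.
* The compositional embedding cannot represent order beyond dipeptides;
  selectors for real corpora should use the external-embedding hook.
* Alignment tie-breaking among co-optimal alignments follows the
  alignment library's deterministic enumeration order rather than an
  explicit diagonal-first rule; scores and the canonical identity are
  unaffected.
* The synthetic family has no indels, so the motif filter's gap logic is
  exercised by constructed deletion variants rather than by the family
  itself.
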