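"""The iterative deep-evolution procedure.

Each round: generate a batch of candidate sequences, keep the top fraction
by discriminator score, keep those whose functional motif aligns gap-free to
the template, classify the survivors with the thermotolerance selector, and
record the HTTP fraction.  Predicted-HTTP sequences accumulate in a pool
that, together with all natural HTTP-labeled sequences, is fed back into
continued generator training (warm start) before the next round — the
selective pressure that enriches the generated population for the
high-temperature trait.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import thermo_selector as ts
from . import variant_generator as vg
from .candidate_selection import MotifSpec, motif_filter
from .seqio import HTTP, SequenceRecord, write_fasta
from .thermo_selector import Embedder, SelectorModel
from .variant_generator import GanConfig, GanPair


@dataclass
class RoundReport:
    round_index: int
    n_generated: int
    n_after_score_filter: int
    n_after_motif_filter: int
    n_predicted_http: int
    http_fraction: float
    generator_checkpoint: Optional[str] = None

    def __post_init__(self):
        chain = (self.n_generated, self.n_after_score_filter,
                 self.n_after_motif_filter, self.n_predicted_http)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"filter counts must be non-increasing: {chain}")

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "n_generated": self.n_generated,
            "n_after_score_filter": self.n_after_score_filter,
            "n_after_motif_filter": self.n_after_motif_filter,
            "n_predicted_http": self.n_predicted_http,
            "http_fraction": self.http_fraction,
            "generator_checkpoint": self.generator_checkpoint,
        }


def http_fraction(n_predicted_http: int, n_after_motif_filter: int) -> float:
    """Predicted-HTTP share of the motif-passing set (0 when the set is
    empty, with a warning)."""
    if n_after_motif_filter == 0:
        warnings.warn("no sequences survived the motif filter; "
                      "HTTP fraction reported as 0")
        return 0.0
    return n_predicted_http / n_after_motif_filter


@dataclass
class EvolutionState:
    gan: GanPair
    selector: SelectorModel
    embedder: Embedder
    natural_pool: list[SequenceRecord]
    natural_http: list[SequenceRecord]
    motif: MotifSpec
    reports: list[RoundReport] = field(default_factory=list)
    generated_http_pool: list[SequenceRecord] = field(default_factory=list)

    def next_round_index(self) -> int:
        return len(self.reports) + 1


def score_filter(scored: Sequence[tuple[str, float]],
                 top_fraction: float = 0.2) -> list[str]:
    """Ids of the ceil(top_fraction * N) highest-scoring records; ties at
    the cut broken by ascending id."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if not scored:
        return []
    k = math.ceil(top_fraction * len(scored))
    ranked = sorted(scored, key=lambda item: (-item[1], item[0]))
    return [rid for rid, _ in ranked[:k]]


def run_round(state: EvolutionState, n_generate: int,
              top_fraction: float = 0.2,
              seed: int = 0) -> RoundReport:
    """One generate -> score-filter -> motif-filter -> classify round.

    Appends the report to the state and the predicted-HTTP records to the
    accumulated pool.
    """
    generated = vg.generate(state.gan, n_generate, seed=seed,
                            id_prefix=f"r{state.next_round_index()}_")
    scored = vg.discriminator_score(state.gan, generated)
    kept_ids = set(score_filter(scored, top_fraction))
    score_passed = [r for r in generated if r.id in kept_ids]
    motif_passed = [r for r in score_passed
                    if motif_filter(r, state.motif)[0]]
    predictions = ts.predict(state.selector, state.embedder, motif_passed)
    http_records = [r for r, (_, _, cls) in zip(motif_passed, predictions)
                    if cls == HTTP]
    report = RoundReport(
        round_index=state.next_round_index(),
        n_generated=n_generate,
        n_after_score_filter=len(score_passed),
        n_after_motif_filter=len(motif_passed),
        n_predicted_http=len(http_records),
        http_fraction=http_fraction(len(http_records), len(motif_passed)),
    )
    state.reports.append(report)
    state.generated_http_pool.extend(http_records)
    return report


def refine_generator(state: EvolutionState, steps: int,
                     seed: int = 0,
                     generated_weight: float = 1.0) -> None:
    """Continue generator training on natural pool + natural HTTPs +
    accumulated generated HTTPs (warm start).

    Skipped with a warning when no generated HTTPs have accumulated.
    ``generated_weight`` optionally upweights the fed-back records in batch
    sampling (1 = uniform).
    """
    if not state.generated_http_pool:
        warnings.warn("no generated HTTPs accumulated; refinement skipped")
        return
    if steps <= 0:
        return
    # duplicates by id collapse to one record whose sampling weight
    # accumulates: natural HTTPs appear in both the pool and the feedback
    # set, so "adding them back" doubles their sampling rate
    index: dict[str, int] = {}
    pool: list[SequenceRecord] = []
    weights: list[float] = []
    for rec, w in (
            [(r, 1.0) for r in state.natural_pool] +
            [(r, 1.0) for r in state.natural_http] +
            [(r, generated_weight) for r in state.generated_http_pool]):
        if rec.id in index:
            weights[index[rec.id]] += w
            continue
        index[rec.id] = len(pool)
        pool.append(rec)
        weights.append(w)
    vg.train_gan(pool, state.gan.config,
                 sampling_weights=np.asarray(weights),
                 pair=state.gan, steps=steps, seed=seed)


@dataclass
class LoopConfig:
    """Configuration of a full evolution run."""

    n_rounds: int = 2
    n_generate: int = 500
    top_fraction: float = 0.2
    refine_steps: int = 1000
    generated_weight: float = 1.0
    seed: int = 0


def run_deepevo(state: EvolutionState, config: LoopConfig,
                out_dir: Optional[Path] = None) -> EvolutionState:
    """Run the configured number of rounds with feedback refinement between
    rounds; optionally persist per-round artifacts under ``out_dir``."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for round_no in range(1, config.n_rounds + 1):
        report = run_round(state, config.n_generate,
                           top_fraction=config.top_fraction,
                           seed=config.seed + 1000 * round_no)
        if out is not None:
            _persist_round(state, report, out)
        if round_no < config.n_rounds:
            refine_generator(state, config.refine_steps,
                             seed=config.seed + 1000 * round_no + 500,
                             generated_weight=config.generated_weight)
    if out is not None:
        with open(out / "reports.json", "w") as fh:
            json.dump([r.to_dict() for r in state.reports], fh, indent=2)
    return state


def _persist_round(state: EvolutionState, report: RoundReport,
                   out: Path) -> None:
    rdir = out / f"round_{report.round_index:02d}"
    rdir.mkdir(parents=True, exist_ok=True)
    checkpoint = rdir / "generator.npz"
    state.gan.save(checkpoint)
    report.generator_checkpoint = str(checkpoint)
    new_http = [r for r in state.generated_http_pool
                if r.id.startswith(f"r{report.round_index}_")]
    write_fasta(new_http, rdir / "predicted_http.fasta")
    with open(rdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
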