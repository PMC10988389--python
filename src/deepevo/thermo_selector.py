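"""The high-temperature-tolerance selector: embedding interface, a 3-layer
MLP binary classifier (input : 64 : 16 : sigmoid head), training with binary
cross-entropy, and evaluation.

The selector is a deliberately modest model: it acts as selective pressure in
the evolution loop, not as a precise thermostability predictor.  Protein-
language-model embeddings (e.g. a 1,280-d transformer representation) enter
through :func:`load_external_embeddings`; the built-in desk-scale default is
a 420-d compositional embedding (amino-acid + dipeptide frequencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .seqio import (AMINO_ACIDS, HTTP, LTTP, SequenceRecord, label_by_ogt)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Sequences with HTTP/LTTP labels and an optional train/test split."""

    records: list[SequenceRecord]
    labels: dict[str, str]
    train_ids: Optional[list[str]] = None
    test_ids: Optional[list[str]] = None

    @classmethod
    def from_ogt(cls, records: Sequence[SequenceRecord],
                 ogt: dict[str, float]) -> "LabeledDataset":
        """Label records by source-organism OGT; mid-range records (class
        EXCLUDED) are dropped."""
        kept, labels = [], {}
        for rec in records:
            if rec.id not in ogt:
                continue
            cls_ = label_by_ogt(ogt[rec.id])
            if cls_ in (HTTP, LTTP):
                kept.append(rec)
                labels[rec.id] = cls_
        return cls(kept, labels)

    def split(self, seed: int, train_fraction: float = 0.7) -> None:
        """Stratified split: train_fraction of each class goes to training."""
        rng = np.random.default_rng(seed)
        train, test = [], []
        for cls_ in (HTTP, LTTP):
            ids = sorted(r.id for r in self.records if self.labels[r.id] == cls_)
            rng.shuffle(ids)
            k = int(round(train_fraction * len(ids)))
            train.extend(ids[:k])
            test.extend(ids[k:])
        self.train_ids = sorted(train)
        self.test_ids = sorted(test)

    def subset(self, ids: Sequence[str]) -> list[SequenceRecord]:
        wanted = set(ids)
        return [r for r in self.records if r.id in wanted]


# ---------------------------------------------------------------------------
# Embedders
# ---------------------------------------------------------------------------

@dataclass
class Embedder:
    """A named, fixed-dimension map from sequence to real vector."""

    name: str
    output_dim: int
    embed: Callable[[SequenceRecord], np.ndarray]

    def embed_many(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        return np.stack([self.embed(r) for r in records])


_AA_TO_I = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _composition_vector(record: SequenceRecord) -> np.ndarray:
    seq = record.residues
    if not seq:
        raise ValueError("cannot embed an empty sequence")
    mono = np.zeros(20)
    for aa in seq:
        mono[_AA_TO_I[aa]] += 1.0
    mono /= mono.sum()
    di = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        di[_AA_TO_I[a], _AA_TO_I[b]] += 1.0
    if di.sum() > 0:
        di /= di.sum()
    return np.concatenate([mono, di.ravel()])


def composition_embedder() -> Embedder:
    """420-d embedding: 20 amino-acid frequencies + 400 dipeptide
    frequencies, each block normalized to sum 1."""
    return Embedder("composition", 420, _composition_vector)


def embed_composition(record: SequenceRecord) -> np.ndarray:
    return _composition_vector(record)


def load_external_embeddings(path) -> dict[str, np.ndarray]:
    """Read precomputed per-sequence vectors (e.g. from a pretrained protein
    language model) from a TSV of ``id`` followed by vector components."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            vec = np.array([float(x) for x in parts[1:]])
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}:{line_no}: ragged row (got {vec.size} values, "
                    f"expected {dim})")
            vectors[parts[0]] = vec
    return vectors


def write_external_embeddings(vectors: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for rid, vec in vectors.items():
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n")


def external_embedder(vectors: dict[str, np.ndarray]) -> Embedder:
    dims = {v.size for v in vectors.values()}
    if len(dims) != 1:
        raise ValueError("external embeddings have inconsistent dimensions")
    dim = dims.pop()

    def embed(record: SequenceRecord) -> np.ndarray:
        if record.id not in vectors:
            raise KeyError(f"no external embedding for {record.id!r}")
        return vectors[record.id]

    return Embedder("external", dim, embed)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class SelectorHyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 100
    epochs: int = 75
    hidden: tuple[int, int] = (64, 16)
    #: optional positive-class weight for the BCE loss; off by default
    http_class_weight: Optional[float] = None


@dataclass
class SelectorModel:
    """Trained MLP classifier with its hyperparameters and loss history."""

    net: nn.MLP
    input_dim: int
    embedder_name: str
    hyperparams: SelectorHyperparams
    threshold: float = 0.5
    seed: int = 0
    loss_history: list[float] = field(default_factory=list)
    #: feature standardization fitted on the training split
    feature_mean: Optional[np.ndarray] = None
    feature_std: Optional[np.ndarray] = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_std

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        z = self._standardize(np.atleast_2d(x))
        logits = self.net(ag.Tensor(z)).data[:, 0]
        return 1.0 / (1.0 + np.exp(-logits))

    def save(self, path) -> None:
        arrays = {f"w{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path, meta=np.array([
            self.input_dim, self.hyperparams.hidden[0],
            self.hyperparams.hidden[1], self.threshold, self.seed],
            dtype=float), loss=np.array(self.loss_history),
            embedder=np.array(self.embedder_name),
            feature_mean=(self.feature_mean if self.feature_mean is not None
                          else np.array([])),
            feature_std=(self.feature_std if self.feature_std is not None
                         else np.array([])), **arrays)

    @classmethod
    def load(cls, path) -> "SelectorModel":
        data = np.load(path, allow_pickle=False)
        meta = data["meta"]
        input_dim, h1, h2 = int(meta[0]), int(meta[1]), int(meta[2])
        hp = SelectorHyperparams(hidden=(h1, h2))
        net = nn.MLP([input_dim, h1, h2, 1], np.random.default_rng(0))
        arrays = [data[f"w{i}"] for i in range(len(net.state_arrays()))]
        net.load_state_arrays(arrays)
        mean = data["feature_mean"] if data["feature_mean"].size else None
        std = data["feature_std"] if data["feature_std"].size else None
        model = cls(net, input_dim, str(data["embedder"]), hp,
                    threshold=float(meta[3]), seed=int(meta[4]),
                    loss_history=list(data["loss"]),
                    feature_mean=mean, feature_std=std)
        return model


def _bce_loss(logits: ag.Tensor, y: np.ndarray,
              pos_weight: Optional[float]) -> ag.Tensor:
    """Binary cross-entropy with logits: y*softplus(-z) + (1-y)*softplus(z)."""
    yv = ag.Tensor(y[:, None])
    pos = ag.softplus(-logits) * yv
    neg = ag.softplus(logits) * (1.0 - yv)
    if pos_weight is not None:
        pos = pos * float(pos_weight)
    return (pos + neg).mean()


def train_selector(dataset: LabeledDataset, embedder: Embedder,
                   hyperparams: Optional[SelectorHyperparams] = None,
                   seed: int = 0) -> SelectorModel:
    """Train the MLP selector on the dataset's training split.

    If the dataset is unsplit, a stratified 70/30 split is applied first.
    Training is mini-batch Adam on binary cross-entropy; the per-epoch mean
    loss is recorded.
    """
    hp = hyperparams or SelectorHyperparams()
    if dataset.train_ids is None:
        dataset.split(seed)
    train_records = dataset.subset(dataset.train_ids)
    classes = {dataset.labels[r.id] for r in train_records}
    if classes != {HTTP, LTTP}:
        raise ValueError(f"training split must contain both classes, "
                         f"got {sorted(classes)}")

    x_raw = embedder.embed_many(train_records)
    mean = x_raw.mean(axis=0)
    std = x_raw.std(axis=0)
    std[std < 1e-12] = 1.0
    x = (x_raw - mean) / std
    y = np.array([1.0 if dataset.labels[r.id] == HTTP else 0.0
                  for r in train_records])

    rng = np.random.default_rng(seed)
    net = nn.MLP([embedder.output_dim, *hp.hidden, 1], rng)
    opt = nn.Adam(net.parameters(), lr=hp.learning_rate)
    history: list[float] = []
    n = len(train_records)
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            logits = net(ag.Tensor(x[idx]))
            loss = _bce_loss(logits, y[idx], hp.http_class_weight)
            grads = nn.backward(loss, net.parameters())
            opt.step(grads)
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return SelectorModel(net, embedder.output_dim, embedder.name, hp,
                         seed=seed, loss_history=history,
                         feature_mean=mean, feature_std=std)


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict(model: SelectorModel, embedder: Embedder,
            records: Sequence[SequenceRecord]) -> list[tuple[str, float, str]]:
    """Per-record (id, probability, class); HTTP iff p >= threshold."""
    if embedder.output_dim != model.input_dim:
        raise ValueError(f"embedder dim {embedder.output_dim} != model "
                         f"input dim {model.input_dim}")
    if not records:
        return []
    probs = model.probabilities(embedder.embed_many(records))
    return [(r.id, float(p), HTTP if p >= model.threshold else LTTP)
            for r, p in zip(records, probs)]


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)


def evaluate(model: SelectorModel, embedder: Embedder,
             dataset: LabeledDataset,
             ids: Optional[Sequence[str]] = None) -> ClassMetrics:
    """Confusion-matrix metrics (HTTP = positive class) on the test split
    (or on explicit ``ids``)."""
    if ids is None:
        ids = dataset.test_ids
    if not ids:
        raise ValueError("evaluation set is empty")
    records = dataset.subset(ids)
    preds = predict(model, embedder, records)
    tp = fp = fn = tn = 0
    for rid, _, cls_ in preds:
        truth = dataset.labels[rid]
        if cls_ == HTTP and truth == HTTP:
            tp += 1
        elif cls_ == HTTP:
            fp += 1
        elif truth == HTTP:
            fn += 1
        else:
            tn += 1
    return ClassMetrics(tp, fp, fn, tn)
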