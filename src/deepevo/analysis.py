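"""Evaluation analytics for generated sequence sets and engineered variants:
positional Shannon entropy, identity-based clustering with representatives,
distance matrices for low-dimensional embedding, mutation profiling, salt
bridges, spatial mutation clusters from CA geometry, and the photometric
activity-unit formula for the dehydrogenase assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .candidate_selection import global_align, percent_identity
from .seqio import (ACIDIC_RESIDUES, BASIC_RESIDUES, GAP, SequenceRecord,
                    StructureModel)

#: physicochemical classes used for same-type substitution counting
RESIDUE_CLASSES = {
    "hydrophobic": set("AVLIMFWY"),
    "polar": set("STNQ"),
    "charged-acidic": set("DE"),
    "charged-basic": set("KRH"),
    "special": set("CGP"),
}


def residue_class(aa: str) -> str:
    for name, members in RESIDUE_CLASSES.items():
        if aa in members:
            return name
    raise ValueError(f"unknown residue {aa!r}")


# ---------------------------------------------------------------------------
# Positional entropy
# ---------------------------------------------------------------------------

def positional_entropy(aligned: Sequence[str]) -> np.ndarray:
    """Per-column Shannon entropy (bits) of a pre-aligned set of sequences.

    Gap characters are excluded from each column's distribution; an all-gap
    column is reported as NaN.
    """
    if not aligned:
        raise ValueError("no sequences given")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("sequences must be pre-aligned to equal length")
    entropy = np.empty(length)
    for col in range(length):
        residues = [s[col] for s in aligned if s[col] != GAP]
        if not residues:
            entropy[col] = np.nan
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        entropy[col] = float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0
    return entropy


def entropy_profile(records: Sequence[SequenceRecord],
                    length: Optional[int] = None) -> np.ndarray:
    """Entropy profile of equal-length (or truncated/padded) record sets."""
    if not records:
        raise ValueError("no records given")
    if length is None:
        length = len(records[0])
    padded = [r.residues[:length].ljust(length, GAP) for r in records]
    return positional_entropy(padded)


# ---------------------------------------------------------------------------
# Clustering and distance matrices
# ---------------------------------------------------------------------------

@dataclass
class SequenceCluster:
    representative: SequenceRecord
    members: list[SequenceRecord]

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_sequences(records: Sequence[SequenceRecord],
                      min_identity: float = 80.0) -> list[SequenceCluster]:
    """Greedy incremental clustering, longest-first.

    A record joins the first existing cluster whose representative it
    matches at >= min_identity percent, else founds a new cluster with
    itself as representative.
    """
    if not records:
        raise ValueError("no records given")
    clusters: list[SequenceCluster] = []
    for rec in sorted(records, key=lambda r: (-len(r), r.id)):
        for cluster in clusters:
            if percent_identity(rec.residues,
                                cluster.representative.residues) >= min_identity:
                cluster.members.append(rec)
                break
        else:
            clusters.append(SequenceCluster(rec, [rec]))
    return clusters


def distance_matrix(representatives: Sequence[SequenceRecord]
                    ) -> tuple[np.ndarray, list[str]]:
    """Symmetric identity-based distances d = 1 - identity/100, zero
    diagonal; returned with the id order used."""
    if len(representatives) < 2:
        raise ValueError("need at least 2 representatives")
    n = len(representatives)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - percent_identity(representatives[i].residues,
                                       representatives[j].residues) / 100.0
            dist[i, j] = dist[j, i] = d
    return dist, [r.id for r in representatives]


def tsne_embed(dist: np.ndarray, sizes: Sequence[int],
               perplexity: float = 7.0, seed: int = 0) -> np.ndarray:
    """2-D embedding of a precomputed distance matrix (perplexity 7 by
    default); returned coordinates are plotted with point sizes proportional
    to cluster size."""
    from sklearn.manifold import TSNE

    if len(sizes) != dist.shape[0]:
        raise ValueError("sizes must match the distance matrix")
    perplexity = min(perplexity, (dist.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, random_state=seed)
    return tsne.fit_transform(dist)


# ---------------------------------------------------------------------------
# Mutation profiling
# ---------------------------------------------------------------------------

@dataclass
class MutationSet:
    reference_id: str
    variant_id: str
    #: (1-based reference position, reference residue, variant residue)
    substitutions: list[tuple[int, str, str]]
    n_indel_columns: int = 0

    def __post_init__(self):
        positions = [p for p, _, _ in self.substitutions]
        if positions != sorted(set(positions)):
            raise ValueError("substitution positions must be unique and sorted")
        if any(a == b for _, a, b in self.substitutions):
            raise ValueError("substitution with identical residues")


@dataclass
class MutationSummary:
    total: int
    ala_to_ser: int
    charged_introduced: int
    charged_removed: int
    same_class: int


CHARGED = set("DEKR")


def mutation_profile(variant: SequenceRecord, reference: SequenceRecord
                     ) -> tuple[MutationSet, MutationSummary]:
    """Substitutions between a variant and its reference, from the global
    alignment; indel columns are counted but not profiled."""
    alignment = global_align(variant.residues, reference.residues)
    substitutions: list[tuple[int, str, str]] = []
    n_indels = 0
    ref_pos = 0
    for cv, cr in zip(alignment.aligned_query, alignment.aligned_target):
        if cr != GAP:
            ref_pos += 1
        if cv == GAP or cr == GAP:
            n_indels += 1
            continue
        if cv != cr:
            substitutions.append((ref_pos, cr, cv))
    mset = MutationSet(reference.id, variant.id, substitutions, n_indels)
    summary = MutationSummary(
        total=len(substitutions),
        ala_to_ser=sum(1 for _, r, v in substitutions if r == "A" and v == "S"),
        charged_introduced=sum(1 for _, r, v in substitutions
                               if v in CHARGED and r not in CHARGED),
        charged_removed=sum(1 for _, r, v in substitutions
                            if r in CHARGED and v not in CHARGED),
        same_class=sum(1 for _, r, v in substitutions
                       if residue_class(r) == residue_class(v)),
    )
    return mset, summary


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

@dataclass
class SaltBridge:
    acidic_residue: int
    basic_residue: int
    atom_pair: tuple[str, str]
    distance: float


@dataclass
class SaltBridgeSet:
    pairs: list[SaltBridge]

    @property
    def count(self) -> int:
        return len(self.pairs)


def salt_bridges(structure: StructureModel,
                 cutoff: float = 4.0,
                 include_his: bool = True) -> SaltBridgeSet:
    """Acidic/basic residue pairs with any side-chain O...N contact within
    ``cutoff`` Angstrom; each residue pair is counted once (closest atom
    pair reported)."""
    acidic = [(num, name, atom, xyz)
              for num, name, atom, xyz in structure.charged_atoms
              if name in ACIDIC_RESIDUES]
    basic_names = BASIC_RESIDUES if include_his else (BASIC_RESIDUES - {"HIS"})
    basic = [(num, name, atom, xyz)
             for num, name, atom, xyz in structure.charged_atoms
             if name in basic_names]
    best: dict[tuple[int, int], SaltBridge] = {}
    for a_num, _, a_atom, a_xyz in acidic:
        for b_num, _, b_atom, b_xyz in basic:
            dist = float(np.linalg.norm(a_xyz - b_xyz))
            if dist > cutoff:
                continue
            key = (a_num, b_num)
            if key not in best or dist < best[key].distance:
                best[key] = SaltBridge(a_num, b_num, (a_atom, b_atom), dist)
    return SaltBridgeSet(sorted(best.values(),
                                key=lambda p: (p.acidic_residue,
                                               p.basic_residue)))


# ---------------------------------------------------------------------------
# Spatial mutation clusters
# ---------------------------------------------------------------------------

@dataclass
class SpatialClusters:
    clusters: list[set[int]]
    singles: set[int]
    cutoff: float

    @property
    def clustered_fraction(self) -> float:
        n_clustered = sum(len(c) for c in self.clusters)
        total = n_clustered + len(self.singles)
        return n_clustered / total if total else 0.0


def spatial_mutation_clusters(mutations: MutationSet,
                              structure: StructureModel,
                              cutoff: float = 8.0) -> SpatialClusters:
    """Connected components of the CA-contact graph over mutated positions.

    Two substituted positions are linked when their CA atoms lie within
    ``cutoff`` Angstrom; components of size >= 2 are clusters, isolated
    positions are singles.
    """
    positions = [p for p, _, _ in mutations.substitutions]
    coords = {}
    for p in positions:
        try:
            coords[p] = structure.ca_for(p)
        except KeyError:
            raise KeyError(f"mutated position {p} has no CA in the structure")
    graph = nx.Graph()
    graph.add_nodes_from(positions)
    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            if np.linalg.norm(coords[p] - coords[q]) <= cutoff:
                graph.add_edge(p, q)
    clusters = [set(c) for c in nx.connected_components(graph) if len(c) >= 2]
    clusters.sort(key=min)
    singles = {p for p in positions
               if not any(p in c for c in clusters)}
    return SpatialClusters(clusters, singles, cutoff)


# ---------------------------------------------------------------------------
# Activity units
# ---------------------------------------------------------------------------

#: millimolar extinction coefficient of NADH at 340 nm (mM^-1 cm^-1)
NADH_EXTINCTION = 6.22


def activity_units(delta_a340: float, volume_total: float,
                   concentration_mg: float, time_s: float) -> float:
    """Dehydrogenase activity from the NADH absorbance change:
    Units = dA340 * V_total / (6.22 * concentration_mg * time_s)."""
    if concentration_mg <= 0:
        raise ValueError(f"concentration must be positive, got {concentration_mg}")
    if time_s <= 0:
        raise ValueError(f"time must be positive, got {time_s}")
    if volume_total <= 0:
        raise ValueError(f"volume must be positive, got {volume_total}")
    return delta_a340 * volume_total / (NADH_EXTINCTION * concentration_mg * time_s)
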