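"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: alignment by
exhaustive enumeration, salt bridges by all-atom-pair scan, spatial clusters
by union-find over all pairs.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def enumerate_alignments(a: str, b: str):
    """All monotone global alignments of a and b as (aligned_a, aligned_b)."""
    results = []

    def rec(i, j, ca, cb):
        if i == len(a) and j == len(b):
            results.append(("".join(ca), "".join(cb)))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ca + [a[i]], cb + [b[j]])
        if i < len(a):
            rec(i + 1, j, ca + [a[i]], cb + ["-"])
        if j < len(b):
            rec(i, j + 1, ca + ["-"], cb + [b[j]])

    rec(0, 0, [], [])
    return results


def _gap_runs(aligned: str):
    """(start, length) of '-' runs in an aligned string."""
    runs, start = [], None
    for idx, ch in enumerate(aligned):
        if ch == "-" and start is None:
            start = idx
        elif ch != "-" and start is not None:
            runs.append((start, idx - start))
            start = None
    if start is not None:
        runs.append((start, len(aligned) - start))
    return runs


def score_alignment(aligned_a: str, aligned_b: str) -> float:
    """Affine-gap score (BLOSUM62, open 10, extend 0.5, free end gaps)."""
    score = 0.0
    n = len(aligned_a)
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            score += _BLOSUM62[ca, cb]
    for aligned in (aligned_a, aligned_b):
        for start, length in _gap_runs(aligned):
            if start == 0 or start + length == n:
                continue  # terminal gaps free
            score += GAP_OPEN + (length - 1) * GAP_EXTEND
    return score


def identity_of_alignment(aligned_a: str, aligned_b: str) -> float:
    both = [i for i, (x, y) in enumerate(zip(aligned_a, aligned_b))
            if x != "-" and y != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    matches = sum(1 for x, y in zip(aligned_a[lo:hi + 1], aligned_b[lo:hi + 1])
                  if x == y)
    return 100.0 * matches / (hi - lo + 1)


def brute_force_align(a: str, b: str):
    """(best score, set of identities among co-optimal alignments)."""
    best_score = -np.inf
    identities: set[float] = set()
    for ca, cb in enumerate_alignments(a, b):
        s = score_alignment(ca, cb)
        if s > best_score + 1e-9:
            best_score = s
            identities = {identity_of_alignment(ca, cb)}
        elif abs(s - best_score) <= 1e-9:
            identities.add(identity_of_alignment(ca, cb))
    return best_score, identities


def brute_force_salt_bridges(structure, cutoff=4.0, include_his=True) -> int:
    """Residue-pair count by scanning every acidic-O/basic-N atom pair."""
    from deepevo.seqio import ACIDIC_RESIDUES, BASIC_RESIDUES

    basic_names = BASIC_RESIDUES if include_his else (BASIC_RESIDUES - {"HIS"})
    pairs = set()
    for num_a, name_a, _, xyz_a in structure.charged_atoms:
        if name_a not in ACIDIC_RESIDUES:
            continue
        for num_b, name_b, _, xyz_b in structure.charged_atoms:
            if name_b not in basic_names:
                continue
            if float(np.linalg.norm(xyz_a - xyz_b)) <= cutoff:
                pairs.add((num_a, num_b))
    return len(pairs)


def brute_force_components(positions, coords, cutoff=8.0):
    """Connected components via union-find over all position pairs."""
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            if np.linalg.norm(coords[p] - coords[q]) <= cutoff:
                parent[find(p)] = find(q)
    groups: dict = {}
    for p in positions:
        groups.setdefault(find(p), set()).add(p)
    clusters = sorted((g for g in groups.values() if len(g) >= 2), key=min)
    singles = {p for g in groups.values() if len(g) == 1 for p in g}
    return clusters, singles
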