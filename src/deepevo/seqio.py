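"""Sequence and structure I/O, alphabet handling, OGT labeling, length and
redundancy filters, and one-hot encoding.

Conventions
-----------
* The alphabet is the 20 canonical amino acids; a 21st symbol ``-`` is used
  only as the pad/gap token of fixed-length one-hot matrices.  Records with
  any other character (``B J O U X Z`` or gaps) are rejected on input: the
  vocabulary has no unknown token, so ambiguous residues cannot be encoded.
* One-hot matrices are left-aligned: residues occupy the first ``true_length``
  rows and every trailing row is the gap symbol.
* Thermal classes derive from the source organism's optimal growth
  temperature (OGT): >= 50 degC is high-temperature-tolerant (HTTP), < 30 degC
  low-temperature-tolerant (LTTP), and the ambiguous mid range is excluded
  from training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
VOCAB = AMINO_ACIDS + GAP  # 21 symbols
AA_INDEX = {aa: i for i, aa in enumerate(VOCAB)}
CHARGED_RESIDUES = frozenset("DEKR")

HTTP = "HTTP"
LTTP = "LTTP"
EXCLUDED = "EXCLUDED"

#: side-chain atoms that carry formal charge, per residue type
CHARGED_SIDECHAIN_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"ARG", "LYS", "HIS"})


@dataclass
class SequenceRecord:
    """One protein sequence with an id and an optional OGT label (degC)."""

    id: str
    residues: str
    ogt: Optional[float] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OneHotMatrix:
    """Fixed-length one-hot encoding, L_max x 21, left-aligned."""

    values: np.ndarray
    true_length: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read protein FASTA; records with non-canonical residues are dropped
    with a warning (the model vocabulary has no unknown token)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(SequenceRecord(rec.id, seq))
        except ValueError as exc:
            warnings.warn(f"skipping FASTA record: {exc}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# OGT tables and labeling
# ---------------------------------------------------------------------------

def read_ogt_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if list(df.columns) != ["id", "ogt_celsius"]:
        raise ValueError(f"{path}: expected columns ['id', 'ogt_celsius'], "
                         f"got {list(df.columns)}")
    return dict(zip(df["id"], df["ogt_celsius"].astype(float)))


def write_ogt_table(rows: dict[str, float] | Iterable[tuple[str, float]], path) -> None:
    items = rows.items() if isinstance(rows, dict) else rows
    df = pd.DataFrame(items, columns=["id", "ogt_celsius"])
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def label_by_ogt(ogt: float) -> str:
    """Map an organism OGT (degC) to a thermal class.

    >= 50 -> HTTP, < 30 -> LTTP, [30, 50) -> EXCLUDED (mid-range sequences
    are not used for training the selector).
    """
    ogt = float(ogt)
    if not np.isfinite(ogt):
        raise ValueError(f"OGT must be finite, got {ogt}")
    if ogt >= 50.0:
        return HTTP
    if ogt < 30.0:
        return LTTP
    return EXCLUDED


def read_plddt_table(path) -> dict[str, float]:
    """Structure-confidence table: externally computed per-sequence scores."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if list(df.columns) != ["id", "plddt"]:
        raise ValueError(f"{path}: expected columns ['id', 'plddt'], "
                         f"got {list(df.columns)}")
    return dict(zip(df["id"], df["plddt"].astype(float)))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def length_filter(records: list[SequenceRecord], min_len: int = 300,
                  max_len: int = 800) -> list[SequenceRecord]:
    """Keep records with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [r for r in records if min_len <= len(r) <= max_len]


def redundancy_filter(records: list[SequenceRecord],
                      max_identity: float = 50.0) -> list[SequenceRecord]:
    """Greedy redundancy reduction in input order.

    A record is kept iff its pairwise identity to every already-kept record
    is <= max_identity percent, so the output satisfies the all-pairs bound.
    """
    from .candidate_selection import percent_identity

    kept: list[SequenceRecord] = []
    for rec in records:
        if all(percent_identity(rec.residues, k.residues) <= max_identity
               for k in kept):
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def encode_onehot(record: SequenceRecord, l_max: int = 512) -> OneHotMatrix:
    if len(record) > l_max:
        raise ValueError(
            f"record {record.id!r} has length {len(record)} > L_max {l_max}")
    mat = np.zeros((l_max, 21), dtype=np.int8)
    for i, aa in enumerate(record.residues):
        mat[i, AA_INDEX[aa]] = 1
    mat[len(record):, AA_INDEX[GAP]] = 1
    return OneHotMatrix(mat, len(record))


def decode_onehot(matrix: OneHotMatrix | np.ndarray) -> str:
    """Per-row argmax decoding; leading/trailing gap symbols stripped.

    Internal gaps (if any) are preserved in the returned string so callers
    can flag the sequence invalid.
    """
    values = matrix.values if isinstance(matrix, OneHotMatrix) else matrix
    idx = np.asarray(values).argmax(axis=1)
    chars = [VOCAB[i] for i in idx]
    return "".join(chars).strip(GAP)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """CA trace plus charged side-chain atoms for one chain."""

    chain_id: str
    residue_numbers: np.ndarray          # (n,) int, strictly increasing
    residue_names: list[str]             # 3-letter codes
    ca_coords: np.ndarray                # (n, 3) Angstrom
    charged_atoms: list[tuple[int, str, str, np.ndarray]]
    # each: (residue number, residue name, atom name, xyz)

    def ca_for(self, residue_number: int) -> np.ndarray:
        pos = np.searchsorted(self.residue_numbers, residue_number)
        if pos >= len(self.residue_numbers) or \
                self.residue_numbers[pos] != residue_number:
            raise KeyError(f"no CA for residue {residue_number} "
                           f"in chain {self.chain_id}")
        return self.ca_coords[pos]


def read_structure(pdb_path, chain: str) -> StructureModel:
    """Extract CA and charged side-chain atom coordinates for one chain.

    Altloc conflicts are resolved by highest occupancy; residues without a
    CA atom are skipped with a warning.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise KeyError(f"chain {chain!r} not found in {pdb_path}")
    atoms = atoms[~atoms.hetero]

    res_numbers, res_names, ca_coords = [], [], []
    charged: list[tuple[int, str, str, np.ndarray]] = []
    for res in struc.residue_iter(atoms):
        num = int(res.res_id[0])
        name = str(res.res_name[0])
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            warnings.warn(f"residue {name} {num}: no CA atom, skipped")
            continue
        res_numbers.append(num)
        res_names.append(name)
        ca_coords.append(np.asarray(ca.coord[0], dtype=float))
        for atom_name in CHARGED_SIDECHAIN_ATOMS.get(name, ()):
            hit = res[res.atom_name == atom_name]
            if hit.array_length():
                charged.append((num, name, atom_name,
                                np.asarray(hit.coord[0], dtype=float)))
    if not res_numbers:
        raise KeyError(f"chain {chain!r} in {pdb_path} has no usable residues")
    return StructureModel(chain, np.asarray(res_numbers), res_names,
                          np.asarray(ca_coords), charged)
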