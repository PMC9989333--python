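"""Ancestral sequences: FASTA I/O, missing-site imputation, trinucleotide
context accounting, and a synthetic-sequence generator.

The synthetic generator stands in for real reference chromosomes: it draws
i.i.d. bases at a given composition (e.g. the ~41% GC typical of human and
chimpanzee autosomes), which is all the downstream mutation model consumes —
per-site rates depend only on the local trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AncestralSequence",
    "BASES",
    "HUMAN_LIKE_COMPOSITION",
    "load_fasta",
    "write_fasta",
    "impute_missing",
    "context_counts",
    "generate_sequence",
    "triplet_string",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_DECODE = np.frombuffer(b"ACGTN", dtype="S1")

#: Approximate autosomal base composition of the human (and chimpanzee)
#: genome, ~59% AT / 41% GC, order A, C, G, T.
HUMAN_LIKE_COMPOSITION = (0.295, 0.205, 0.205, 0.295)

TRIPLETS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def triplet_string(code: int) -> str:
    """Triplet for a 0..63 code (base-4 digits over ACGT)."""
    return TRIPLETS[code]


def _encode(bases: str) -> np.ndarray:
    raw = np.frombuffer(bases.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, _CODE["N"], dtype=np.uint8)
    for b, i in _CODE.items():
        codes[raw == ord(b)] = i
    return codes


@dataclass
class AncestralSequence:
    """A single ancestral chromosome or region.

    ``codes`` holds one byte per site: 0..3 for A, C, G, T and 4 for missing
    (N).  ``composition`` is the relative frequency of A, C, G, T among
    non-missing sites.
    """

    codes: np.ndarray
    label: str = "seq"

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 1:
            raise ValueError("sequence codes must be one-dimensional")

    @classmethod
    def from_string(cls, bases: str, label: str = "seq") -> "AncestralSequence":
        return cls(_encode(bases), label=label)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def bases(self) -> str:
        return _DECODE[self.codes].tobytes().decode("ascii")

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(self.codes == 4))

    @property
    def composition(self) -> np.ndarray:
        counts = np.bincount(self.codes, minlength=5)[:4].astype(float)
        total = counts.sum()
        if total == 0:
            raise ValueError("sequence has no non-missing bases")
        return counts / total

    def triplet_codes(self) -> np.ndarray:
        """Code 0..63 of the triplet centred on each interior site
        (positions 1..L-2); requires no missing bases.  Cached."""
        cached = getattr(self, "_triplets", None)
        if cached is not None:
            return cached
        if self.n_missing:
            raise ValueError("sequence contains missing bases; impute first")
        if len(self) < 3:
            raise ValueError("sequence shorter than 3 bases has no triplets")
        c = self.codes.astype(np.int16)
        out = (16 * c[:-2] + 4 * c[1:-1] + c[2:]).astype(np.uint8)
        object.__setattr__(self, "_triplets", out)
        return out


# ---------------------------------------------------------------------------


def load_fasta(path: Union[str, Path], multi: bool = False):
    """Read a FASTA file into :class:`AncestralSequence`.

    Bases are uppercased; anything outside ACGTN becomes N.  By default the
    file must contain exactly one record; with ``multi=True`` a list is
    returned instead.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA")
    seqs = [AncestralSequence.from_string(str(r.seq), label=r.id) for r in records]
    for s in seqs:
        if len(s) == 0:
            raise ValueError(f"{path}: record {s.label!r} has an empty sequence")
    if multi:
        return seqs
    if len(seqs) != 1:
        raise ValueError(
            f"{path}: expected a single record, found {len(seqs)} (use multi=True)"
        )
    return seqs[0]


def write_fasta(seq: AncestralSequence, path: Union[str, Path]) -> None:
    record = SeqRecord(Seq(seq.bases), id=seq.label, description="")
    SeqIO.write([record], str(path), "fasta")


def impute_missing(seq: AncestralSequence, seed) -> AncestralSequence:
    """Replace every N by a base drawn from the sequence-wide composition.

    Draws are independent across sites and deterministic given ``seed``;
    non-missing positions are left untouched.
    """
    rng = np.random.default_rng(seed)
    composition = seq.composition  # raises on all-missing input
    codes = seq.codes.copy()
    missing = np.flatnonzero(codes == 4)
    if missing.size:
        codes[missing] = rng.choice(4, size=missing.size, p=composition).astype(np.uint8)
    return AncestralSequence(codes, label=seq.label)


def context_counts(seq: AncestralSequence) -> dict:
    """Counts of all 64 overlapping trinucleotides; the total is L - 2."""
    counts = np.bincount(seq.triplet_codes(), minlength=64)
    return {TRIPLETS[i]: int(counts[i]) for i in range(64)}


def generate_sequence(
    length: int,
    composition: Sequence[float] = HUMAN_LIKE_COMPOSITION,
    seed=None,
    label: str = "synthetic",
) -> AncestralSequence:
    """Synthetic ancestral sequence with i.i.d. bases at ``composition``
    (order A, C, G, T), deterministic given ``seed``."""
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
        raise ValueError("composition must be 4 non-negative frequencies summing to 1")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=int(length), p=comp / comp.sum()).astype(np.uint8)
    return AncestralSequence(codes, label=label)
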