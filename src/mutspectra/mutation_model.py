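"""Context-specific mutation rate matrices over the 192 mutation types.

A mutation type is an ancestral trinucleotide plus a derived middle base
(64 triplets x 3 alternative bases = 192 types, e.g. ``TCC>T`` for
5'-TCC-3' -> 5'-TTC-3').  A :class:`MutationRateMatrix` assigns each type a
per-site per-generation rate; after :func:`normalize_overall_rate` the
sequence-averaged total per-site rate equals a target (the simulations use
1e-8 per bp per generation).  Matrices live in the stranded 192 space;
collapsing to 96 strand-symmetric categories happens only when spectra are
reported (see :mod:`mutspectra.spectra`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .sequence import BASES, TRIPLETS, AncestralSequence

__all__ = [
    "MutationType",
    "MutationRateMatrix",
    "ALL_TYPES",
    "N_TYPES",
    "type_index",
    "build_uniform_matrix",
    "build_jukes_cantor_matrix",
    "load_matrix",
    "write_matrix",
    "shipped_matrix_path",
    "apply_fold_shift",
    "normalize_overall_rate",
    "site_rate",
    "expected_type_proportions",
]

N_TYPES = 192


class MutationType(NamedTuple):
    """An ancestral triplet and the derived middle base, e.g. ('TCC', 'T')."""

    ancestral_triplet: str
    derived_base: str

    @property
    def label(self) -> str:
        return f"{self.ancestral_triplet}>{self.derived_base}"


def _check_type(t: MutationType) -> MutationType:
    t = MutationType(*t)
    if len(t.ancestral_triplet) != 3 or any(b not in BASES for b in t.ancestral_triplet):
        raise ValueError(f"invalid ancestral triplet {t.ancestral_triplet!r}")
    if t.derived_base not in BASES:
        raise ValueError(f"invalid derived base {t.derived_base!r}")
    if t.derived_base == t.ancestral_triplet[1]:
        raise ValueError(f"derived base equals ancestral middle base in {t.label}")
    return t


# Derived-base codes for each triplet: the three bases != middle, in ACGT order.
_DERIVED_CODE = np.empty((64, 3), dtype=np.uint8)
for _tri in range(64):
    _mid = (_tri >> 2) & 3
    _DERIVED_CODE[_tri] = [b for b in range(4) if b != _mid]

#: The 192 mutation types in canonical order: triplets lexicographic,
#: derived bases in ACGT order within each triplet.
ALL_TYPES: tuple[MutationType, ...] = tuple(
    MutationType(TRIPLETS[tri], BASES[_DERIVED_CODE[tri, slot]])
    for tri in range(64)
    for slot in range(3)
)

_TYPE_INDEX = {t: i for i, t in enumerate(ALL_TYPES)}


def type_index(t: MutationType) -> int:
    """Position of a mutation type in the canonical 192 ordering."""
    return _TYPE_INDEX[_check_type(t)]


# slot of each derived base code per triplet (-1 where base == middle base)
_SLOT = np.full((64, 4), -1, dtype=np.int8)
for _tri in range(64):
    for _s in range(3):
        _SLOT[_tri, _DERIVED_CODE[_tri, _s]] = _s


def type_indices(tri_codes: np.ndarray, derived_codes: np.ndarray) -> np.ndarray:
    """Vectorized canonical 192-index for arrays of (triplet code, derived
    base code) pairs; raises if any derived base equals its middle base."""
    slots = _SLOT[tri_codes, derived_codes].astype(np.int64)
    if np.any(slots < 0):
        raise ValueError("derived base equals the ancestral middle base in some row")
    return tri_codes.astype(np.int64) * 3 + slots


def derived_slot(tri_code: int, base_code: int) -> int:
    """Which of the three derived slots ``base_code`` occupies for a triplet."""
    slots = _DERIVED_CODE[tri_code]
    hit = np.flatnonzero(slots == base_code)
    if hit.size != 1:
        raise ValueError("derived base equals the ancestral middle base")
    return int(hit[0])


@dataclass(frozen=True)
class MutationRateMatrix:
    """Rates for the 192 mutation types, stored as a (64, 3) array aligned to
    the canonical derived-slot ordering.  ``overall_rate`` is set by
    :func:`normalize_overall_rate` and records the sequence-averaged total
    per-site rate the matrix was scaled to."""

    rates: np.ndarray
    overall_rate: Optional[float] = None

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (64, 3):
            raise ValueError("rates must have shape (64, 3)")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "rates", r)

    @property
    def normalized(self) -> bool:
        return self.overall_rate is not None

    @property
    def triplet_totals(self) -> np.ndarray:
        """Total mutation rate per ancestral triplet, shape (64,)."""
        return self.rates.sum(axis=1)

    def rate_of(self, t: MutationType) -> float:
        idx = type_index(t)
        return float(self.rates[idx // 3, idx % 3])

    def as_flat(self) -> np.ndarray:
        """Rates in canonical 192 order."""
        return self.rates.reshape(-1).copy()

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "triplet": [t.ancestral_triplet for t in ALL_TYPES],
                "derived": [t.derived_base for t in ALL_TYPES],
                "rate": self.as_flat(),
            }
        )


# ---------------------------------------------------------------------------
# constructors


def build_uniform_matrix(rate: float = 1.0) -> MutationRateMatrix:
    """All 192 entries equal: every site mutates at the same total rate and
    picks each of its three derived bases with probability 1/3.  This is the
    Jukes-Cantor model expressed on the triplet space (rates are relative
    until :func:`normalize_overall_rate`)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return MutationRateMatrix(np.full((64, 3), float(rate)))


#: The fine-scale experiments call the uniform matrix by its field name.
build_jukes_cantor_matrix = build_uniform_matrix


def load_matrix(source: Union[str, Path, pd.DataFrame]) -> MutationRateMatrix:
    """Load a 192-row matrix table (TSV columns triplet/derived/rate,
    ``#`` comments allowed) and validate completeness."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype={"triplet": str, "derived": str})
    required = {"triplet", "derived", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"matrix table needs columns {sorted(required)}")
    if len(df) != N_TYPES:
        raise ValueError(f"matrix table must have exactly {N_TYPES} rows, found {len(df)}")
    rates = np.full((64, 3), np.nan)
    for triplet, derived, rate in df[["triplet", "derived", "rate"]].itertuples(index=False):
        idx = type_index(MutationType(str(triplet), str(derived)))
        if not np.isnan(rates[idx // 3, idx % 3]):
            raise ValueError(f"duplicate mutation type {triplet}>{derived}")
        if rate < 0:
            raise ValueError(f"negative rate for {triplet}>{derived}")
        rates[idx // 3, idx % 3] = float(rate)
    # completeness follows from 192 unique rows
    return MutationRateMatrix(rates)


def write_matrix(matrix: MutationRateMatrix, path: Union[str, Path], header: str = "") -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        matrix.as_table().to_csv(fh, sep="\t", index=False)


def shipped_matrix_path(name: str) -> Path:
    """Path of a matrix file shipped with the package
    (``uniform`` / ``human_like_synthetic``)."""
    fname = name if name.endswith(".tsv") else f"{name}.tsv"
    path = resources.files("mutspectra") / "data" / "matrices" / fname
    if not path.is_file():
        raise FileNotFoundError(f"no shipped matrix {name!r}")
    return Path(str(path))


# ---------------------------------------------------------------------------
# transformations


def apply_fold_shift(
    matrix: MutationRateMatrix, mutation_type: MutationType, fold: float
) -> MutationRateMatrix:
    """Multiply the rate of one mutation type by ``fold`` (0.9x-2.0x in the
    experiments), leaving the other 191 entries untouched.  The result is no
    longer normalized; renormalize to hold the overall rate fixed."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    idx = type_index(mutation_type)
    rates = matrix.rates.copy()
    rates[idx // 3, idx % 3] *= fold
    return MutationRateMatrix(rates)


def normalize_overall_rate(
    matrix: MutationRateMatrix, seq: AncestralSequence, target_rate: float
) -> MutationRateMatrix:
    """Scale the whole matrix by one constant so that the average total
    per-site rate over the sequence's interior sites equals ``target_rate``."""
    if target_rate < 0:
        raise ValueError("target_rate must be non-negative")
    if target_rate == 0:
        return MutationRateMatrix(np.zeros((64, 3)), overall_rate=0.0)
    tri_counts = np.bincount(seq.triplet_codes(), minlength=64)
    mean_rate = float(tri_counts @ matrix.triplet_totals) / tri_counts.sum()
    if mean_rate == 0:
        raise ValueError("cannot normalize an all-zero matrix to a positive rate")
    return MutationRateMatrix(matrix.rates * (target_rate / mean_rate), overall_rate=float(target_rate))


def site_rate(seq: AncestralSequence, position: int, matrix: MutationRateMatrix):
    """Total mutation rate at an interior site and the conditional
    distribution over its three derived bases (ACGT order minus the
    ancestral middle base)."""
    if not 1 <= position <= len(seq) - 2:
        raise ValueError(f"position {position} is not interior (needs both neighbours)")
    tri = int(seq.triplet_codes()[position - 1])
    row = matrix.rates[tri]
    total = float(row.sum())
    conditional = row / total if total > 0 else np.full(3, np.nan)
    derived = tuple(BASES[b] for b in _DERIVED_CODE[tri])
    return total, conditional, derived


def expected_type_proportions(matrix: MutationRateMatrix, seq: AncestralSequence) -> np.ndarray:
    """Expected share of each of the 192 types among mutations arising on
    ``seq``: triplet frequency times type rate, normalized to sum 1."""
    tri_counts = np.bincount(seq.triplet_codes(), minlength=64).astype(float)
    weights = tri_counts[:, None] * matrix.rates
    total = weights.sum()
    if total == 0:
        raise ValueError("matrix assigns zero rate everywhere on this sequence")
    return (weights / total).reshape(-1)
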