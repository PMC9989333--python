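"""Population-private SNP extraction and 192/96-category mutational spectra.

A population's mutational spectrum is the distribution of its
population-specific (private) segregating variants over mutation-type
categories: 192 stranded (ancestral triplet, derived base) types, or 96
after merging each type with its reverse complement into a
pyrimidine-centred representative (middle ancestral base C or T — the
convention of the mutational-signature literature).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mutation_model import ALL_TYPES, N_TYPES, MutationType, _check_type, type_index
from .variants import VariantTable

__all__ = [
    "Spectrum",
    "STRANDED_192",
    "COLLAPSED_96",
    "LABELS_192",
    "LABELS_96",
    "classify",
    "private_segregating",
    "compute_spectrum",
    "collapse_strands",
    "write_spectrum",
    "read_spectrum",
]

STRANDED_192 = "stranded192"
COLLAPSED_96 = "collapsed96"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_type(t: MutationType) -> MutationType:
    tri = "".join(_COMPLEMENT[b] for b in reversed(t.ancestral_triplet))
    return MutationType(tri, _COMPLEMENT[t.derived_base])


def _build_collapse():
    reps = []
    mapping = np.empty(N_TYPES, dtype=np.int64)
    rep_of: dict = {}
    for i, t in enumerate(ALL_TYPES):
        rep = t if t.ancestral_triplet[1] in "CT" else _revcomp_type(t)
        if rep not in rep_of:
            rep_of[rep] = len(reps)
            reps.append(rep)
        mapping[i] = rep_of[rep]
    return mapping, tuple(reps)


#: Map from 192-space index to 96-space index, and the 96 representatives
#: (pyrimidine-centred) in first-appearance order of the canonical 192 list.
COLLAPSE_MAP, TYPES_96 = _build_collapse()

LABELS_192 = tuple(t.label for t in ALL_TYPES)
LABELS_96 = tuple(t.label for t in TYPES_96)


def classify(triplet: str, derived: str) -> MutationType:
    """The mutation-type category of one variant row; the derived base must
    differ from the ancestral middle base."""
    return _check_type(MutationType(triplet, derived))


@dataclass
class Spectrum:
    """Counts (and proportions) over mutation-type categories for one
    population.  ``proportions`` is None for an empty spectrum (zero total),
    where proportions are undefined."""

    counts: np.ndarray
    space: str = STRANDED_192

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = {STRANDED_192: 192, COLLAPSED_96: 96}.get(self.space)
        if expected is None:
            raise ValueError(f"unknown spectrum space {self.space!r}")
        if self.counts.shape != (expected,):
            raise ValueError(f"{self.space} spectrum needs {expected} counts")
        if np.any(self.counts < 0):
            raise ValueError("negative category count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def proportions(self) -> Optional[np.ndarray]:
        if self.empty:
            return None
        return self.counts / self.total

    @property
    def labels(self) -> tuple:
        return LABELS_192 if self.space == STRANDED_192 else LABELS_96


def private_segregating(table: VariantTable, focal: str) -> VariantTable:
    """Rows segregating in ``focal`` (0 < derived count < haplotype count)
    while every other population in the table is fixed ancestral."""
    if focal not in table.populations:
        raise KeyError(f"focal population {focal!r} not in table")
    if len(table.populations) < 2:
        raise ValueError("privacy needs at least two populations in the table")
    c = table.derived_count(focal)
    keep = (c > 0) & (c < table.n_haplotypes(focal))
    for pop in table.populations:
        if pop != focal:
            keep &= table.derived_count(pop) == 0
    return table.subset(keep)


def compute_spectrum(table: VariantTable, space: str = STRANDED_192) -> Spectrum:
    """Tally a table's rows into the 192 stranded categories (optionally
    collapsing to 96).  An empty table gives an all-zero spectrum whose
    proportions are flagged undefined."""
    counts = np.bincount(table.type_indices(), minlength=N_TYPES) if len(table) else np.zeros(N_TYPES, dtype=np.int64)
    spectrum = Spectrum(counts, STRANDED_192)
    if space == COLLAPSED_96:
        spectrum = collapse_strands(spectrum)
    elif space != STRANDED_192:
        raise ValueError(f"unknown spectrum space {space!r}")
    return spectrum


def collapse_strands(spectrum: Spectrum) -> Spectrum:
    """Merge reverse-complement pairs into 96 pyrimidine-centred categories;
    the total count is conserved.  Collapsing twice is rejected."""
    if spectrum.space != STRANDED_192:
        raise ValueError("spectrum is already strand-collapsed")
    counts96 = np.zeros(96, dtype=np.int64)
    np.add.at(counts96, COLLAPSE_MAP, spectrum.counts)
    return Spectrum(counts96, COLLAPSED_96)


def collapse_type(t: MutationType) -> int:
    """96-space index of a (possibly purine-centred) mutation type."""
    return int(COLLAPSE_MAP[type_index(t)])


def write_spectrum(spectrum: Spectrum, path: Union[str, Path]) -> None:
    props = spectrum.proportions
    pd.DataFrame(
        {
            "category": list(spectrum.labels),
            "count": spectrum.counts,
            "proportion": props if props is not None else np.nan,
        }
    ).to_csv(path, sep="\t", index=False)


def read_spectrum(path: Union[str, Path]) -> Spectrum:
    df = pd.read_csv(path, sep="\t", comment="#")
    space = STRANDED_192 if len(df) == 192 else COLLAPSED_96
    labels = LABELS_192 if space == STRANDED_192 else LABELS_96
    counts = df.set_index("category")["count"].reindex(list(labels)).to_numpy()
    return Spectrum(counts.astype(np.int64), space)
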