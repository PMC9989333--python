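"""Subsampling individuals and quantifying spectrum distortion.

The broad-scale experiment asks how closely the mutational spectrum of a
subsample of diploid individuals (drawn with replacement) matches the
whole population's spectrum.  The distortion statistic is the total
difference: the sum over categories of absolute proportion differences
(twice the total variation distance, range [0, 2]); reports express it as a
percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mutation_model import N_TYPES
from .spectra import COLLAPSE_MAP, COLLAPSED_96, STRANDED_192, Spectrum, private_segregating
from .variants import VariantTable

__all__ = [
    "SamplingScheme",
    "default_scheme",
    "subsample_individuals",
    "total_difference",
    "convergence_curve",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Ordered diploid sample sizes and replicate draws per size."""

    sizes: tuple
    replicates_per_size: int = 5

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if not sizes or sizes[0] < 1:
            raise ValueError("sizes must be positive")
        if self.replicates_per_size < 1:
            raise ValueError("replicates_per_size must be at least 1")
        object.__setattr__(self, "sizes", sizes)


def default_scheme() -> SamplingScheme:
    """The full experimental grid: 5-200 by 5, 300-1,000 by 100,
    2,000-10,000 by 1,000 diploid individuals; five replicates each
    (57 sizes in total)."""
    sizes = list(range(5, 201, 5)) + list(range(300, 1001, 100)) + list(range(2000, 10001, 1000))
    return SamplingScheme(tuple(sizes), replicates_per_size=5)


def subsample_individuals(
    table: VariantTable,
    focal: str,
    size: int,
    seed=None,
    replace: bool = True,
) -> VariantTable:
    """Resample ``size`` diploid individuals of the focal population
    (uniformly, with replacement by default) and rebuild the table.

    Focal derived/haplotype counts are recomputed from the drawn
    individuals; rows that no longer segregate in the subsampled focal
    population AND carry no derived allele elsewhere are dropped.  Other
    populations are untouched, so privacy filters still see their full
    samples.  Deterministic given ``seed``.
    """
    if size < 1:
        raise ValueError("size must be at least 1")
    if focal not in table.populations:
        raise KeyError(f"focal population {focal!r} not in table")
    n_ind = table.n_haplotypes(focal) // 2
    if not replace and size > n_ind:
        raise ValueError(f"cannot draw {size} individuals from {n_ind} without replacement")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_ind, size=size, replace=replace)
    if not replace:
        chosen = np.sort(chosen)

    lo, _ = table.hap_offsets[focal]
    hap_cols = np.empty(2 * size, dtype=np.int64)
    hap_cols[0::2] = lo + 2 * chosen
    hap_cols[1::2] = lo + 2 * chosen + 1

    # new column layout: same population order, focal replaced
    from scipy import sparse

    blocks, offsets, off = [], {}, 0
    for pop in table.populations:
        plo, phi = table.hap_offsets[pop]
        cols = hap_cols if pop == focal else np.arange(plo, phi)
        blocks.append(table.genotypes[:, cols])
        offsets[pop] = (off, off + cols.size)
        off += cols.size
    G = sparse.hstack(blocks, format="csr")

    new = VariantTable(table.positions, table.tri_codes, table.derived_codes, G, offsets, label=table.label)
    c = new.derived_count(focal)
    keep = (c > 0) & (c < 2 * size)
    for pop in new.populations:
        if pop != focal:
            keep |= new.derived_count(pop) > 0
    return new.subset(keep)


def total_difference(sub: Spectrum, full: Spectrum) -> float:
    """Sum over categories of |p_sub - p_full| between two normalized
    spectra of the same space; 0 for identical spectra, 2 for disjoint
    support.  Raises on empty spectra (undefined proportions)."""
    if sub.space != full.space:
        raise ValueError(f"mismatched spectrum spaces: {sub.space} vs {full.space}")
    if sub.empty or full.empty:
        raise ValueError("total difference undefined for an empty spectrum")
    return float(np.abs(sub.proportions - full.proportions).sum())


def convergence_curve(
    table: VariantTable,
    focal: str,
    scheme: SamplingScheme,
    seed=None,
    space: str = STRANDED_192,
) -> pd.DataFrame:
    """Run the whole subsampling grid against one simulated dataset.

    For every (size, replicate) cell, ``size`` focal individuals are drawn
    with replacement, their private-SNP spectrum recomputed, and the total
    difference to the whole (fully sampled) focal population's spectrum
    recorded.  Each cell has its own reproducible seed stream derived from
    ``(seed, size, replicate)``.  Returns a tidy frame with columns size /
    replicate / total_difference / percent (NaN when a subsample yields an
    empty spectrum).
    """
    from .pipeline import seed_stream  # local import: pipeline depends on us

    base = private_segregating(table, focal)
    full = _spectrum_from_counts(base.type_indices(), space)
    if full.empty:
        raise ValueError(f"population {focal!r} has no private segregating variants")
    dosage = base.individual_dosage(focal).tocsc()
    n_ind = table.n_haplotypes(focal) // 2
    types = base.type_indices()
    if space == COLLAPSED_96:
        types = COLLAPSE_MAP[types]

    rows = []
    for size in scheme.sizes:
        for rep in range(scheme.replicates_per_size):
            rng = np.random.default_rng(seed_stream(seed, "subsample", size, rep))
            chosen = rng.choice(n_ind, size=size, replace=True)
            mult = np.bincount(chosen, minlength=n_ind).astype(np.float64)
            counts = dosage @ mult
            seg = (counts > 0) & (counts < 2 * size)
            k = 96 if space == COLLAPSED_96 else N_TYPES
            sub_counts = np.bincount(types[seg], minlength=k)
            sub = Spectrum(sub_counts, space)
            td = np.nan if sub.empty else total_difference(sub, full)
            rows.append((size, rep, td, 100.0 * td))
    return pd.DataFrame(rows, columns=["size", "replicate", "total_difference", "percent"])


def _spectrum_from_counts(type_idx: np.ndarray, space: str) -> Spectrum:
    if space == COLLAPSED_96:
        return Spectrum(np.bincount(COLLAPSE_MAP[type_idx], minlength=96), COLLAPSED_96)
    if space == STRANDED_192:
        return Spectrum(np.bincount(type_idx, minlength=N_TYPES), STRANDED_192)
    raise ValueError(f"unknown spectrum space {space!r}")
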