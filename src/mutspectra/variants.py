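"""The VariantTable container: simulated biallelic SNPs with ancestral
trinucleotide context, derived allele, per-population allele counts and
per-haplotype genotypes.

Haplotype columns are grouped by population, two consecutive haplotypes per
diploid individual.  Positions are 0-based internally and 1-based in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from scipy import sparse

from .mutation_model import type_indices
from .sequence import BASES, TRIPLETS

__all__ = ["VariantTable"]

_TRI_CODE = {t: i for i, t in enumerate(TRIPLETS)}
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class VariantTable:
    """Biallelic variants from one simulated dataset.

    ``genotypes`` is a CSR boolean/int8 matrix of shape
    (n_variants, total haplotypes); ``hap_offsets`` maps each population to
    its contiguous [start, end) column range.
    """

    positions: np.ndarray
    tri_codes: np.ndarray
    derived_codes: np.ndarray
    genotypes: sparse.csr_matrix
    hap_offsets: dict
    label: str = "sim"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.tri_codes = np.asarray(self.tri_codes, dtype=np.uint8)
        self.derived_codes = np.asarray(self.derived_codes, dtype=np.uint8)
        self.genotypes = sparse.csr_matrix(self.genotypes, dtype=np.int8)
        n = self.positions.size
        if not (self.tri_codes.size == self.derived_codes.size == n == self.genotypes.shape[0]):
            raise ValueError("inconsistent VariantTable component lengths")
        total = self.genotypes.shape[1]
        spans = sorted(self.hap_offsets.values())
        if spans and (spans[0][0] != 0 or spans[-1][1] != total or any(
            spans[i][1] != spans[i + 1][0] for i in range(len(spans) - 1)
        )):
            raise ValueError("hap_offsets must tile the genotype columns")
        mids = (self.tri_codes >> 2) & 3
        if np.any(mids == self.derived_codes):
            raise ValueError("derived base equals ancestral middle base in some row")
        self._counts: dict = {}

    # -- basic accessors ----------------------------------------------------

    @property
    def populations(self) -> tuple:
        return tuple(self.hap_offsets)

    def n_haplotypes(self, pop: str) -> int:
        lo, hi = self.hap_offsets[pop]
        return hi - lo

    def __len__(self) -> int:
        return int(self.positions.size)

    def derived_count(self, pop: str) -> np.ndarray:
        """Derived-allele count per row in one population."""
        if pop not in self._counts:
            lo, hi = self.hap_offsets[pop]
            self._counts[pop] = np.asarray(
                self.genotypes[:, lo:hi].sum(axis=1)
            ).ravel().astype(np.int64)
        return self._counts[pop]

    def type_indices(self) -> np.ndarray:
        """Canonical 192-space mutation-type index per row."""
        return type_indices(self.tri_codes, self.derived_codes)

    @property
    def triplets(self) -> np.ndarray:
        return np.array([TRIPLETS[c] for c in self.tri_codes])

    @property
    def derived_bases(self) -> np.ndarray:
        return np.array([BASES[c] for c in self.derived_codes])

    # -- construction -------------------------------------------------------

    @classmethod
    def from_carriers(
        cls,
        positions: Sequence[int],
        tri_codes: Sequence[int],
        derived_codes: Sequence[int],
        carriers: Sequence[np.ndarray],
        hap_offsets: Mapping[str, tuple],
        label: str = "sim",
    ) -> "VariantTable":
        """Build from per-row arrays of carrier haplotype indices."""
        n = len(positions)
        total = max((hi for _, hi in hap_offsets.values()), default=0)
        indptr = np.zeros(n + 1, dtype=np.int64)
        for i, c in enumerate(carriers):
            indptr[i + 1] = indptr[i] + len(c)
        indices = (
            np.concatenate([np.asarray(c, dtype=np.int32) for c in carriers])
            if n and indptr[-1]
            else np.empty(0, dtype=np.int32)
        )
        data = np.ones(indices.size, dtype=np.int8)
        G = sparse.csr_matrix((data, indices, indptr), shape=(n, total))
        return cls(
            np.asarray(positions), np.asarray(tri_codes), np.asarray(derived_codes),
            G, dict(hap_offsets), label=label,
        )

    @classmethod
    def concat(cls, tables: Sequence["VariantTable"]) -> "VariantTable":
        if not tables:
            raise ValueError("cannot concatenate zero tables")
        first = tables[0]
        for t in tables[1:]:
            if t.hap_offsets != first.hap_offsets:
                raise ValueError("tables have differing sample layouts")
        return cls(
            np.concatenate([t.positions for t in tables]),
            np.concatenate([t.tri_codes for t in tables]),
            np.concatenate([t.derived_codes for t in tables]),
            sparse.vstack([t.genotypes for t in tables], format="csr"),
            dict(first.hap_offsets),
            label=first.label,
        )

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.positions[mask],
            self.tri_codes[mask],
            self.derived_codes[mask],
            self.genotypes[mask],
            dict(self.hap_offsets),
            label=self.label,
        )

    def individual_dosage(self, pop: str) -> sparse.csr_matrix:
        """(n_variants x n_individuals) derived-allele dosage (0/1/2) for one
        population; individuals are consecutive haplotype pairs."""
        lo, hi = self.hap_offsets[pop]
        if (hi - lo) % 2:
            raise ValueError(f"population {pop!r} has an odd haplotype count")
        G = self.genotypes[:, lo:hi]
        return (G[:, 0::2] + G[:, 1::2]).tocsr()

    # -- dataframe / TSV ----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pos": self.positions, "triplet": self.triplets, "derived": self.derived_bases}
        )
        for pop in self.populations:
            df[f"count_{pop}"] = self.derived_count(pop)
            df[f"n_{pop}"] = self.n_haplotypes(pop)
        return df

    def to_tsv(self, path: Union[str, Path], header_lines: Iterable[str] = ()) -> None:
        df = self.to_dataframe()
        carriers = []
        G = self.genotypes.tocsr()
        for i in range(len(self)):
            row = G.indices[G.indptr[i]:G.indptr[i + 1]]
            carriers.append(",".join(map(str, row.tolist())))
        df["carriers"] = carriers
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# haplotypes\t{';'.join(f'{p}:{lo}-{hi}' for p, (lo, hi) in self.hap_offsets.items())}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "VariantTable":
        hap_offsets = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# haplotypes\t"):
                    for part in line.split("\t", 1)[1].strip().split(";"):
                        pop, span = part.rsplit(":", 1)
                        lo, hi = span.split("-")
                        hap_offsets[pop] = (int(lo), int(hi))
        if not hap_offsets:
            raise ValueError(f"{path}: missing '# haplotypes' header line")
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"carriers": str})
        carriers = [
            np.array([int(x) for x in str(c).split(",")] if isinstance(c, str) and c else [], dtype=np.int32)
            for c in df.get("carriers", pd.Series([""] * len(df)))
        ]
        return cls.from_carriers(
            df["pos"].to_numpy(),
            np.array([_TRI_CODE[t] for t in df["triplet"]], dtype=np.uint8),
            np.array([_BASE_CODE[b] for b in df["derived"]], dtype=np.uint8),
            carriers,
            hap_offsets,
        )

    # -- VCF -----------------------------------------------------------------

    def to_vcf(self, path: Union[str, Path], contig: str = "sim", contig_length: Optional[int] = None) -> None:
        """Minimal VCF export: one ALT per row, diploid samples named
        ``{pop}_{i}`` over consecutive haplotype pairs, phased GT."""
        header = pysam.VariantHeader()
        length = int(contig_length or (self.positions.max() + 2 if len(self) else 1))
        header.contigs.add(contig, length=length)
        header.formats.add("GT", 1, "String", "Genotype")
        header.info.add("TRI", 1, "String", "Ancestral trinucleotide context")
        sample_pops = []
        for pop in self.populations:
            n_ind = self.n_haplotypes(pop) // 2
            for i in range(n_ind):
                header.add_sample(f"{pop}_{i}")
                sample_pops.append(pop)
        order = np.argsort(self.positions, kind="stable")
        G = self.genotypes.tocsr()
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for i in order:
                i = int(i)
                tri = TRIPLETS[self.tri_codes[i]]
                rec = vcf.new_record(
                    contig=contig,
                    start=int(self.positions[i]),
                    alleles=(tri[1], BASES[self.derived_codes[i]]),
                )
                rec.info["TRI"] = tri
                row = np.zeros(G.shape[1], dtype=np.int8)
                row[G.indices[G.indptr[i]:G.indptr[i + 1]]] = 1
                col = 0
                for pop in self.populations:
                    lo, hi = self.hap_offsets[pop]
                    for h in range(lo, hi, 2):
                        rec.samples[col]["GT"] = (int(row[h]), int(row[h + 1]))
                        rec.samples[col].phased = True
                        col += 1
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: Union[str, Path]) -> "VariantTable":
        positions, tris, derived, carriers = [], [], [], []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            pops = []
            for s in samples:
                pop = s.rsplit("_", 1)[0]
                if pop not in pops:
                    pops.append(pop)
            hap_offsets, off = {}, 0
            for pop in pops:
                n = 2 * sum(1 for s in samples if s.rsplit("_", 1)[0] == pop)
                hap_offsets[pop] = (off, off + n)
                off += n
            for rec in vcf:
                tri = rec.info["TRI"]
                positions.append(rec.start)
                tris.append(_TRI_CODE[tri])
                derived.append(_BASE_CODE[rec.alts[0]])
                row = []
                col = 0
                for s in samples:
                    gt = rec.samples[s]["GT"]
                    for j, allele in enumerate(gt):
                        if allele:
                            row.append(col + j)
                    col += len(gt)
                carriers.append(np.array(row, dtype=np.int32))
        return cls.from_carriers(positions, tris, derived, carriers, hap_offsets)
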