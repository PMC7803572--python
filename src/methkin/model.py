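"""Shared data model for the WGBS methylome pipeline.

Coordinate convention: every interval in memory is 0-based half-open
[start, end); GTF input (1-based inclusive) is converted at the reader
boundary.  CpG sites on opposite strands of the same dinucleotide are
distinct records: position ``p`` carries the '+' cytosine and ``p+1``
the '-' cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand"]


@dataclass(frozen=True)
class CpGSite:
    """A single cytosine in CpG context on one strand."""

    chrom: str
    pos: int  # 0-based position of the cytosine
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class MethCountMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``sites`` is a DataFrame with columns chrom, pos, strand, sorted by
    (chrom, pos, strand).  ``meth`` and ``total`` are int arrays of shape
    (n_sites, n_samples).  ``missing`` marks cells with no observation;
    a cell with total == 0 is always missing (0/0 has no level).
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        for name in ("meth", "total", "missing"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n_sites, n_samples)}"
                )
        if ((self.total < 0) & ~self.missing).any():
            raise ValueError("negative totals in observed cells")
        if ((self.meth > self.total) & ~self.missing).any():
            raise ValueError("meth > total in observed cells")
        # total == 0 carries no level information
        self.missing = self.missing | (self.total <= 0)
        if self.sites.duplicated(SITE_COLUMNS).any():
            raise ValueError("duplicate (chrom, pos, strand) site records")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def levels(self) -> np.ndarray:
        """Methylation level meth/total with NaN at missing cells."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.meth / np.where(self.total > 0, self.total, 1)
        return np.where(self.missing, np.nan, lv)

    def subset_sites(self, index: np.ndarray) -> "MethCountMatrix":
        return MethCountMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            meth=self.meth[index],
            total=self.total[index],
            missing=self.missing[index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethCountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return MethCountMatrix(
            sites=self.sites.copy(),
            samples=list(sample_ids),
            meth=self.meth[:, idx],
            total=self.total[:, idx],
            missing=self.missing[:, idx],
        )


@dataclass
class SampleRecord:
    """Design factors plus parentage for one tissue sample.

    Two samples from the same animal (e.g. muscle and testis) share an
    ``animal_id``; kinship is defined between animals.
    """

    sample_id: str
    tissue: str
    breed: str
    age_years: float
    sex: str
    pedigree_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    animal_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"age must be positive, got {self.age_years}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.animal_id is None:
            self.animal_id = self.sample_id


def sample_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    return pd.DataFrame(rows)


@dataclass
class GenomeSequence:
    """Chromosome name -> upper-case base string over {A,C,G,T,N}."""

    chroms: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    @property
    def size(self) -> int:
        """Total genome size GS in bp."""
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chroms[chrom]
        return seq[max(start, 0): min(end, len(seq))]


@dataclass
class GeneModel:
    """Minimal gene model: TSS, exons and 5'UTR intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.utr5 = sorted((int(a), int(b)) for a, b in self.utr5)
        for a, b in self.exons + self.utr5:
            if a >= b:
                raise ValueError(f"{self.gene_id}: empty interval ({a},{b})")
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class RegionSet:
    """Labelled genomic intervals, 0-based half-open.

    Backed by a DataFrame with columns chrom, start, end, label plus an
    optional free-form payload column.
    """

    COLUMNS = ["chrom", "start", "end", "label"]

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"RegionSet frame missing column {col!r}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("RegionSet requires start < end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def with_label(self, label: str) -> "RegionSet":
        return RegionSet(self.df[self.df["label"] == label].reset_index(drop=True))

    def merged(self, gap: int = 0) -> "RegionSet":
        """Merge overlapping/adjacent intervals within each (chrom, label)."""
        rows = []
        for (chrom, label), sub in self.df.groupby(["chrom", "label"], sort=True):
            cur_s = cur_e = None
            for _, r in sub.sort_values("start").iterrows():
                if cur_s is None:
                    cur_s, cur_e = r["start"], r["end"]
                elif r["start"] <= cur_e + gap:
                    cur_e = max(cur_e, r["end"])
                else:
                    rows.append((chrom, cur_s, cur_e, label))
                    cur_s, cur_e = r["start"], r["end"]
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e, label))
        return RegionSet(pd.DataFrame(rows, columns=self.COLUMNS))


@dataclass
class ExpressionTable:
    """Gene x sample FPKM matrix."""

    values: pd.DataFrame  # index gene_id, columns sample ids

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)
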