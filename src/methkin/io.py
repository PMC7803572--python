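"""Readers and writers for the plain-text formats the pipeline touches.

Formats: MethylDackel-style bedGraph (chrom, start, end, percent, n_meth,
n_unmeth), FASTA, BED4, minimal GTF (gene/exon/five_prime_utr), TSV for
sample sheets, expression tables, count matrices and result tables.
Gzip-compressed text (.gz suffix) is accepted everywhere.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .model import (
    SITE_COLUMNS,
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    MethCountMatrix,
    RegionSet,
    SampleRecord,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message names file and line number."""


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# per-sample methylation counts


def read_methyldackel_bedgraph(
    path: PathLike, sample_id: str, strand: str = "+"
) -> pd.DataFrame:
    """Read one sample's CpG counts from a MethylDackel bedGraph.

    Rows are ``chrom  start  end  percent  n_methylated  n_unmethylated``;
    an optional ``track`` header line is skipped.  The format carries no
    per-row strand, so ``strand`` is stamped onto every site (load plus
    and minus extractions separately to keep both strands distinct).

    Returns a frame with columns chrom, pos, strand, meth, total sorted
    by (chrom, pos); total = methylated + unmethylated, and a row with
    total 0 is retained (downstream treats it as missing).
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 fields, got {len(parts)}")
            try:
                chrom = parts[0]
                pos = int(parts[1])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative counts")
            rows.append((chrom, pos, strand, n_meth, n_meth + n_unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "total"])
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    df.attrs["sample_id"] = sample_id
    return df


def assemble_matrix(
    per_sample: dict[str, pd.DataFrame],
    sample_ids: Optional[Sequence[str]] = None,
) -> MethCountMatrix:
    """Union per-sample count frames into one MethCountMatrix.

    Cells absent from a sample's file are missing, not zero.  When
    ``sample_ids`` is given (e.g. from a sample sheet) every id must have
    a count frame.
    """
    if sample_ids is None:
        sample_ids = list(per_sample)
    missing_samples = [s for s in sample_ids if s not in per_sample]
    if missing_samples:
        raise ValueError(f"no count data for sample(s): {', '.join(missing_samples)}")
    if not sample_ids:
        raise ValueError("need at least one sample")

    frames = []
    for s in sample_ids:
        df = per_sample[s]
        if df.duplicated(SITE_COLUMNS).any():
            raise ValueError(f"duplicate site records in sample {s}")
        frames.append(df[SITE_COLUMNS])
    sites = (
        pd.concat(frames)
        .drop_duplicates()
        .sort_values(SITE_COLUMNS, kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(sites)
    n_sites, n_samples = len(sites), len(sample_ids)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    missing = np.ones((n_sites, n_samples), dtype=bool)
    for j, s in enumerate(sample_ids):
        df = per_sample[s]
        idx = key.get_indexer(pd.MultiIndex.from_frame(df[SITE_COLUMNS]))
        meth[idx, j] = df["meth"].to_numpy()
        total[idx, j] = df["total"].to_numpy()
        missing[idx, j] = False
    return MethCountMatrix(sites, list(sample_ids), meth, total, missing)


# ---------------------------------------------------------------------------
# genome / annotation


def read_fasta(path: PathLike) -> GenomeSequence:
    chroms: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    chroms[name] = "".join(parts).upper()
                name = line[1:].split()[0]
                parts = []
            elif name is not None:
                parts.append(line.strip())
    if name is not None:
        chroms[name] = "".join(parts).upper()
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path: PathLike, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_bed(path: PathLike, genome: Optional[GenomeSequence] = None) -> RegionSet:
    """BED4 (label optional, defaults to 'region').

    Rows on chromosomes absent from ``genome`` (when given) are skipped
    with a logged count.
    """
    rows, skipped = [], 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "region"
            if genome is not None and chrom not in genome.chroms:
                skipped += 1
                continue
            rows.append((chrom, start, end, label))
    if skipped:
        log.warning("read_bed(%s): skipped %d rows on unknown chromosomes", path, skipped)
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))


def write_regions_bed(regions: RegionSet, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in regions.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def _gtf_attribute(attrs: str, key: str) -> Optional[str]:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip().strip('"')
    return None


def read_gtf_minimal(path: PathLike) -> list[GeneModel]:
    """Parse gene models from GTF, using only gene/exon/five_prime_utr rows.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    TSS is the strand-appropriate extreme exon boundary (0-based position
    of the first transcribed base).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon", "five_prime_utr"):
                continue
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            meta.setdefault(gene_id, (chrom, strand))
            if feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            elif feature == "five_prime_utr":
                utr5.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id, (chrom, strand) in meta.items():
        ex = sorted(exons.get(gene_id, []))
        if not ex:
            continue
        tss = ex[0][0] if strand == "+" else ex[-1][1] - 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tss=tss,
                exons=ex,
                utr5=sorted(utr5.get(gene_id, [])),
            )
        )
    return genes


def write_gtf_minimal(genes: Iterable[GeneModel], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            s, e = g.span
            fh.write(
                f"{g.chrom}\tmethkin\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\tmethkin\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for a, b in g.utr5:
                fh.write(
                    f"{g.chrom}\tmethkin\tfive_prime_utr\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# sample sheet / expression / matrices


SHEET_COLUMNS = [
    "sample_id",
    "tissue",
    "breed",
    "age_years",
    "sex",
    "pedigree_id",
    "sire_id",
    "dam_id",
    "animal_id",
]


def read_sample_sheet(path: PathLike) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = SHEET_COLUMNS[:6]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    records = []
    for _, r in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=r["sample_id"],
                tissue=r["tissue"],
                breed=r["breed"],
                age_years=float(r["age_years"]),
                sex=r["sex"],
                pedigree_id=r["pedigree_id"],
                sire_id=r.get("sire_id") or None,
                dam_id=r.get("dam_id") or None,
                animal_id=r.get("animal_id") or None,
            )
        )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        d = vars(r).copy()
        d["sire_id"] = d["sire_id"] or ""
        d["dam_id"] = d["dam_id"] or ""
        rows.append(d)
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path: PathLike) -> ExpressionTable:
    """TSV with first column gene_id and one column of FPKM per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return ExpressionTable(df.astype(float))


def write_expression(table: ExpressionTable, path: PathLike) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_matrix_tsv(matrix: MethCountMatrix, path: PathLike) -> None:
    """Serialize a count matrix; cell format 'meth:total', '.' for missing."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SITE_COLUMNS + list(matrix.samples)) + "\n")
        for i in range(matrix.n_sites):
            site = matrix.sites.iloc[i]
            cells = [
                "." if matrix.missing[i, j] else f"{matrix.meth[i, j]}:{matrix.total[i, j]}"
                for j in range(matrix.n_samples)
            ]
            fh.write(f"{site.chrom}\t{site.pos}\t{site.strand}\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: PathLike) -> MethCountMatrix:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[3:]
        rows, meths, totals, miss = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + len(samples):
                raise ParseError(f"{path}:{lineno}: wrong field count")
            rows.append((parts[0], int(parts[1]), parts[2]))
            m_row, t_row, x_row = [], [], []
            for cell in parts[3:]:
                if cell == ".":
                    m_row.append(0); t_row.append(0); x_row.append(True)
                else:
                    m, t = cell.split(":")
                    m_row.append(int(m)); t_row.append(int(t)); x_row.append(False)
            meths.append(m_row); totals.append(t_row); miss.append(x_row)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return MethCountMatrix(
        sites,
        samples,
        np.asarray(meths, dtype=np.int64).reshape(len(rows), len(samples)),
        np.asarray(totals, dtype=np.int64).reshape(len(rows), len(samples)),
        np.asarray(miss, dtype=bool).reshape(len(rows), len(samples)),
    )


def write_results_tsv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
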