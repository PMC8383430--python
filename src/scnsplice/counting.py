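"""Fragment-to-bin counting, junction extraction, and CPM normalization.

A ``ReadPlacement`` is one sequenced fragment reduced to its ordered
aligned blocks on the genome (split alignments have >=2 blocks).  The
counting rule is DEXSeq-like at fragment level: a fragment contributes +1
to every counting bin that any of its blocks overlaps by at least one
base, and at most +1 per bin however many blocks touch it.  Gaps between
consecutive blocks of at least ``min_intron`` bases are recorded as
exon-exon junction observations; shorter gaps are treated as deletions.

Placements arrive either from a portable TSV (sample, chrom, strand,
comma-separated "start-end" blocks) or from a coordinate-sorted BAM via
the pysam adapter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .annotation import CountingBin


class LibrarySizeError(ValueError):
    pass


@dataclass(frozen=True)
class ReadPlacement:
    sample_id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    blocks: tuple[tuple[int, int], ...]

    def gaps(self) -> list[tuple[int, int]]:
        """Gaps between consecutive blocks (candidate introns)."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


class ExonMatrix:
    """Per-bin x per-sample fragment counts, optionally CPM-normalized."""

    def __init__(
        self,
        counts: pd.DataFrame,
        cpm: pd.DataFrame | None = None,
        library_size: pd.Series | None = None,
        skipped_placements: int = 0,
    ):
        self.counts = counts
        self.cpm = cpm
        self.library_size = library_size
        self.skipped_placements = skipped_placements

    @property
    def bin_keys(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


class JunctionTable:
    """Split-read counts keyed by (chrom, donor_end, acceptor_start, strand)."""

    INDEX_NAMES = ("chrom", "donor_end", "acceptor_start", "strand")

    def __init__(self, counts: pd.DataFrame):
        if list(counts.index.names) != list(self.INDEX_NAMES):
            raise ValueError("junction index must be (chrom, donor_end, acceptor_start, strand)")
        self.counts = counts

    @property
    def junctions(self) -> list[tuple]:
        return list(self.counts.index)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def empty(cls, sample_ids: Sequence[str] = ()) -> "JunctionTable":
        idx = pd.MultiIndex.from_tuples([], names=cls.INDEX_NAMES)
        return cls(pd.DataFrame(0, index=idx, columns=list(sample_ids), dtype=int))


def count_bins(
    placements: Iterable[ReadPlacement],
    bins: Sequence[CountingBin],
    chrom_of: dict[str, str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ExonMatrix:
    """Count fragments into flattened bins (one hit per overlapped bin).

    ``chrom_of`` maps gene_id -> chromosome; without it all bins are
    assumed to share the chromosome of the placements they are matched
    against by coordinate only (single-chromosome toy use).  Placements on
    chromosomes without any bins are skipped and counted in
    ``skipped_placements``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    keys = [b.key for b in bins]
    if chrom_of is None:
        chrom_of = {}
    grouped: dict[str, list[tuple[int, int, int]]] = {}
    for i, b in enumerate(bins):
        chrom = chrom_of.get(b.gene_id, "*")
        grouped.setdefault(chrom, []).append((b.start, b.end, i))
    for chrom, items in grouped.items():
        items.sort()
        starts = np.array([it[0] for it in items], dtype=np.int64)
        ends = np.array([it[1] for it in items], dtype=np.int64)
        idx = [it[2] for it in items]
        by_chrom[chrom] = (starts, ends, idx)

    sample_index: dict[str, int] = {s: i for i, s in enumerate(sample_ids or [])}
    counts_cols: list[np.ndarray] = [np.zeros(len(bins), dtype=np.int64) for _ in sample_index]
    skipped = 0

    wildcard = by_chrom.get("*")
    for pl in placements:
        entry = by_chrom.get(pl.chrom, wildcard)
        if entry is None:
            skipped += 1
            continue
        starts, ends, idx = entry
        hit: set[int] = set()
        for bs, be in pl.blocks:
            i0 = int(np.searchsorted(ends, bs, side="right"))
            i1 = int(np.searchsorted(starts, be, side="left"))
            for j in range(i0, i1):
                hit.add(idx[j])
        col = sample_index.get(pl.sample_id)
        if col is None:
            sample_index[pl.sample_id] = col = len(sample_index)
            counts_cols.append(np.zeros(len(bins), dtype=np.int64))
        vec = counts_cols[col]
        for j in hit:
            vec[j] += 1

    order = sorted(sample_index, key=sample_index.get)
    mat = (
        np.column_stack([counts_cols[sample_index[s]] for s in order])
        if order
        else np.zeros((len(bins), 0), dtype=np.int64)
    )
    counts = pd.DataFrame(mat, index=keys, columns=order)
    return ExonMatrix(counts=counts, skipped_placements=skipped)


def extract_junctions(
    placements: Iterable[ReadPlacement],
    min_intron: int = 20,
    sample_ids: Sequence[str] | None = None,
) -> JunctionTable:
    """Turn block gaps >= ``min_intron`` into junction observations."""
    tallies: dict[tuple, dict[str, int]] = {}
    samples: dict[str, None] = dict.fromkeys(sample_ids or [])
    for pl in placements:
        samples.setdefault(pl.sample_id)
        for gap_start, gap_end in pl.gaps():
            if gap_end - gap_start >= min_intron:
                key = (pl.chrom, gap_start, gap_end, pl.strand)
                per = tallies.setdefault(key, {})
                per[pl.sample_id] = per.get(pl.sample_id, 0) + 1
    cols = list(samples)
    idx = pd.MultiIndex.from_tuples(sorted(tallies), names=JunctionTable.INDEX_NAMES)
    df = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    for key, per in tallies.items():
        for s, c in per.items():
            df.loc[key, s] = c
    return JunctionTable(df)


def cpm_normalize(
    matrix: ExonMatrix, library_size: pd.Series | None = None
) -> ExonMatrix:
    """Fill CPM: counts / library_size * 1e6.

    ``library_size`` supplies whole-transcriptome totals; in self-contained
    mode (None) it is the per-sample sum of all bin counts.
    """
    if library_size is None:
        library_size = matrix.counts.sum(axis=0)
    else:
        library_size = library_size.reindex(matrix.counts.columns)
    bad = library_size[(library_size <= 0) | library_size.isna()]
    if len(bad):
        raise LibrarySizeError(
            f"non-positive or missing library size for sample(s): {', '.join(map(str, bad.index))}"
        )
    cpm = matrix.counts.div(library_size, axis=1) * 1e6
    return ExonMatrix(
        counts=matrix.counts,
        cpm=cpm,
        library_size=library_size.astype(float),
        skipped_placements=matrix.skipped_placements,
    )


def read_bam(
    path: str | Path,
    region: str | None = None,
    sample_id: str | None = None,
) -> Iterator[ReadPlacement]:
    """Stream placements from a coordinate-sorted, indexed BAM.

    Blocks follow CIGAR M/=/X (advancing both sequences); D advances the
    reference within the current block; N closes the block and opens a new
    one after the gap.  Secondary, supplementary and unmapped records are
    skipped.
    """
    import pysam

    sid = sample_id or Path(path).stem
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if region is not None and not bam.has_index():
            raise FileNotFoundError(f"BAM index required for region fetch: {path}")
        reads = bam.fetch(region=region) if region else bam.fetch(until_eof=True)
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            blocks: list[list[int]] = []
            pos = read.reference_start
            open_block: list[int] | None = None
            for op, length in read.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    if open_block is None:
                        open_block = [pos, pos + length]
                        blocks.append(open_block)
                    else:
                        open_block[1] = pos + length
                    pos += length
                elif op == 2:  # D: reference gap inside the block
                    if open_block is not None:
                        open_block[1] = pos + length
                    pos += length
                elif op == 3:  # N: intron
                    pos += length
                    open_block = None
                # I, S, H, P consume no reference
            if blocks:
                strand = "-" if read.is_reverse else "+"
                yield ReadPlacement(
                    sample_id=sid,
                    chrom=read.reference_name,
                    strand=strand,
                    blocks=tuple((int(a), int(b)) for a, b in blocks),
                )


def write_placements_tsv(placements: Iterable[ReadPlacement], path: str | Path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write("sample_id\tchrom\tstrand\tblocks\n")
        for pl in placements:
            blocks = ",".join(f"{s}-{e}" for s, e in pl.blocks)
            out.write(f"{pl.sample_id}\t{pl.chrom}\t{pl.strand}\t{blocks}\n")
            n += 1
    return n


def read_placements_tsv(path: str | Path) -> Iterator[ReadPlacement]:
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample_id", "chrom", "strand", "blocks"]:
            raise ValueError(f"unexpected placement TSV header in {path}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: malformed placement row at line {lineno}")
            blocks = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in fields[3].split(",")
            )
            yield ReadPlacement(fields[0], fields[1], fields[2], blocks)


def write_matrix_tsv(matrix: ExonMatrix, counts_path: str | Path, cpm_path: str | Path | None = None) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="bin")
    if cpm_path is not None:
        if matrix.cpm is None:
            raise ValueError("matrix has no CPM values; run cpm_normalize first")
        matrix.cpm.to_csv(cpm_path, sep="\t", index_label="bin")


def read_matrix_tsv(counts_path: str | Path, cpm_path: str | Path | None = None) -> ExonMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="bin")
    cpm = pd.read_csv(cpm_path, sep="\t", index_col="bin") if cpm_path else None
    return ExonMatrix(counts=counts, cpm=cpm)


def write_junctions_tsv(table: JunctionTable, path: str | Path) -> None:
    long = (
        table.counts.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_4": "sample_id"})
    )
    long.columns = ["chrom", "donor_end", "acceptor_start", "strand", "sample_id", "count"]
    long = long[long["count"] > 0]
    long.to_csv(path, sep="\t", index=False)


def read_junctions_tsv(path: str | Path, sample_ids: Sequence[str] | None = None) -> JunctionTable:
    long = pd.read_csv(path, sep="\t")
    if long.empty:
        return JunctionTable.empty(sample_ids or [])
    wide = long.pivot_table(
        index=["chrom", "donor_end", "acceptor_start", "strand"],
        columns="sample_id",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    wide.columns.name = None
    if sample_ids is not None:
        wide = wide.reindex(columns=list(sample_ids), fill_value=0)
    return JunctionTable(wide.astype(int))
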