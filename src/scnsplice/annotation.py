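"""Gene models and DEXSeq-style flattening of transcript exons into counting bins.

Voltage-gated sodium channel genes (SCN1A/2A/3A/8A) carry overlapping
protein-coding transcripts whose exons must be reduced to disjoint
"counting bins" before exon-level read counting: every bin is wholly
contained in, or wholly disjoint from, the exon set of every transcript,
so a bin unambiguously reports on the isoforms that contain it.  Bins
present in all protein-coding transcripts are "consistent"; the rest
(including the mutually exclusive 5A/5N and 18A/18N exon copies) are
"variable".

All internal coordinates are 0-based half-open; GTF input/output converts
at the boundary (GTF is 1-based closed).  Only CDS features of
protein-coding transcripts are binned; UTRs and non-coding exons are out
of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

CONSISTENT = "consistent"
VARIABLE = "variable"


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message carries the line number."""


class GeneNotFoundError(KeyError):
    """A requested gene is absent from the annotation."""


class MutualExclusivityError(ValueError):
    """Two bins proposed as mutually exclusive co-occur in a transcript."""


@dataclass(frozen=True)
class Transcript:
    """One protein-coding transcript: an ordered chain of CDS intervals."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no intervals")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty interval [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: intervals overlap or unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def contains(self, start: int, end: int) -> bool:
        """True if [start,end) lies wholly inside one CDS interval."""
        return any(s <= start and end <= e for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: protein-coding transcripts on one chromosome and strand."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all transcript intervals."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def longest_transcript(self) -> Transcript:
        """Transcript with the largest total CDS length (first on ties)."""
        return max(self.transcripts, key=lambda t: t.length)


@dataclass
class CountingBin:
    """A disjoint sub-exon interval, the unit of exon-level counting.

    ``bin_id`` is a 3-digit zero-padded ordinal increasing with genomic
    start, mirroring DEXSeq's exonic-part naming.  ``cds_index`` numbers
    the bin by its CDS exon within the longest transcript, walked in
    translation order (5'->3' respecting strand); bins absent from that
    transcript have none.
    """

    gene_id: str
    bin_id: str
    start: int
    end: int
    bin_class: str | None = None
    cds_index: int | None = None

    @property
    def key(self) -> str:
        return f"{self.gene_id}:{self.bin_id}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MxePair:
    """A registered pair of mutually exclusive exon bins (e.g. 5A/5N)."""

    gene_id: str
    label: str
    bin_a: str
    bin_n: str


def _prescan_gtf(path: Path) -> None:
    """Cheap structural validation so parse errors carry a line number."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GtfParseError(f"line {lineno}: bad coordinate range {start}-{end}")


def read_gtf(path: str | Path, gene_ids: Iterable[str]) -> list[GeneModel]:
    """Read GENCODE-dialect GTF and return one GeneModel per requested gene.

    Only CDS features on transcripts tagged ``protein_coding`` are kept.
    GTF 1-based closed coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    wanted = set(gene_ids)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid not in wanted:
            continue
        ttype = feat.attributes.get("transcript_type", ["protein_coding"])[0]
        if ttype != "protein_coding":
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise GtfParseError(f"CDS feature without transcript_id in gene {gid}")
        info = per_gene.setdefault(
            gid,
            {
                "gene_name": feat.attributes.get("gene_name", [gid])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "transcripts": {},
            },
        )
        # GTF is 1-based closed: [start, end] -> [start-1, end)
        info["transcripts"].setdefault(tid, []).append((feat.start - 1, feat.end))

    missing = wanted - set(per_gene)
    if missing:
        raise GeneNotFoundError(
            f"gene not found (no protein-coding CDS): {', '.join(sorted(missing))}"
        )

    models = []
    for gid in sorted(per_gene):
        info = per_gene[gid]
        transcripts = tuple(
            Transcript(tid, tuple(sorted(ivs)))
            for tid, ivs in sorted(info["transcripts"].items())
        )
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=info["gene_name"],
                chrom=info["chrom"],
                strand=info["strand"],
                transcripts=transcripts,
            )
        )
    return models


def flatten_gene_model(model: GeneModel) -> list[CountingBin]:
    """Flatten transcript exons into disjoint counting bins.

    Contiguous bases sharing an identical transcript-membership signature
    form one bin, so each bin is wholly inside or wholly outside every
    transcript's exon set and the union of bins equals the exon union.
    """
    edges = sorted({p for t in model.transcripts for iv in t.exons for p in iv})
    segments: list[tuple[int, int, frozenset[str]]] = []
    for a, b in zip(edges, edges[1:]):
        sig = frozenset(t.transcript_id for t in model.transcripts if t.contains(a, b))
        if sig:
            segments.append((a, b, sig))
    merged: list[list] = []
    for a, b, sig in segments:
        if merged and merged[-1][1] == a and merged[-1][2] == sig:
            merged[-1][1] = b
        else:
            merged.append([a, b, sig])
    bins = [
        CountingBin(gene_id=model.gene_id, bin_id=f"{i:03d}", start=a, end=b)
        for i, (a, b, _sig) in enumerate(merged, start=1)
    ]
    _assign_cds_indices(model, bins)
    return bins


def _assign_cds_indices(model: GeneModel, bins: list[CountingBin]) -> None:
    longest = model.longest_transcript()
    exons = list(longest.exons)
    if model.strand == "-":
        exons = exons[::-1]  # translation order for negative-strand genes
    for cds_number, (s, e) in enumerate(exons, start=1):
        for b in bins:
            if s <= b.start and b.end <= e:
                b.cds_index = cds_number


def classify_bins(
    model: GeneModel, bins: Sequence[CountingBin], min_fraction: float = 1.0
) -> list[CountingBin]:
    """Label each bin consistent/variable by transcript-membership fraction.

    A bin is ``consistent`` when the fraction of transcripts containing it
    is at least ``min_fraction`` (default 1.0: present in all protein-coding
    transcripts), otherwise ``variable``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(model.transcripts)
    out = []
    for b in bins:
        frac = sum(t.contains(b.start, b.end) for t in model.transcripts) / n
        out.append(replace_bin_class(b, CONSISTENT if frac >= min_fraction else VARIABLE))
    return out


def replace_bin_class(b: CountingBin, bin_class: str) -> CountingBin:
    return CountingBin(
        gene_id=b.gene_id,
        bin_id=b.bin_id,
        start=b.start,
        end=b.end,
        bin_class=bin_class,
        cds_index=b.cds_index,
    )


def register_mxe_pair(
    model: GeneModel,
    bins: Sequence[CountingBin],
    bin_a: str,
    bin_n: str,
    label: str,
) -> MxePair:
    """Register two bins as a mutually exclusive exon pair.

    Mutual exclusivity is verified against the gene model: no transcript
    may contain both bins.
    """
    by_id = {b.bin_id: b for b in bins}
    try:
        a, n = by_id[bin_a], by_id[bin_n]
    except KeyError as exc:
        raise KeyError(f"bin {exc.args[0]} not found in gene {model.gene_id}") from exc
    if bin_a == bin_n:
        raise ValueError("bin_a and bin_n must differ")
    for t in model.transcripts:
        if t.contains(a.start, a.end) and t.contains(n.start, n.end):
            raise MutualExclusivityError(
                f"{model.gene_id}: transcript {t.transcript_id} contains both "
                f"{bin_a} and {bin_n}; not mutually exclusive"
            )
    return MxePair(gene_id=model.gene_id, label=label, bin_a=bin_a, bin_n=bin_n)


def write_bins_bed(
    models: Sequence[GeneModel], bins_by_gene: dict[str, Sequence[CountingBin]], path: str | Path
) -> None:
    """Write bins as BED-like TSV: chrom, start, end, gene:bin, class, strand."""
    by_gene = {m.gene_id: m for m in models}
    with open(path, "w") as out:
        for gid, bins in bins_by_gene.items():
            m = by_gene[gid]
            for b in bins:
                out.write(
                    f"{m.chrom}\t{b.start}\t{b.end}\t{b.key}\t"
                    f"{b.bin_class or '.'}\t{m.strand}\n"
                )


def write_mxe_json(pairs: Sequence[MxePair], path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(
            [
                {"gene_id": p.gene_id, "label": p.label, "bin_a": p.bin_a, "bin_n": p.bin_n}
                for p in pairs
            ],
            out,
            indent=2,
        )


def write_gtf(models: Sequence[GeneModel], path: str | Path, source: str = "scnsplice") -> None:
    """Write gene models as GENCODE-dialect GTF (CDS features only)."""
    with open(path, "w") as out:
        out.write("##description: synthetic gene models\n")
        for m in models:
            for t in m.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{m.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'gene_name "{m.gene_name}"; transcript_type "protein_coding";'
                    )
                    out.write(
                        f"{m.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n"
                    )
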