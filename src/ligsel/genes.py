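"""Gene models and annotation I/O (GTF 2.2 and BED12).

A :class:`GeneModel` is the anchor object for all TSS-centred profiling:
it carries the strand and the transcription start sites (TSSs) of every
annotated transcript.  Internally all coordinates are 0-based; GTF output
is 1-based closed and BED output 0-based half-open, per the respective
format conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import DataError

__all__ = ["GeneModel", "read_gtf", "write_gtf", "write_bed12"]


@dataclass
class GeneModel:
    """A gene with its transcript TSS list.

    Parameters
    ----------
    gene_id
        Unique identifier.
    chrom, start, end
        0-based half-open genomic span of the gene.
    strand
        ``"+"`` or ``"-"``.
    tss_list
        Genomic positions (0-based) of each transcript's start site,
        primary transcript first.  For a minus-strand gene a TSS is the
        *rightmost* transcribed base of its transcript.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss_list: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise DataError(f"{self.gene_id}: start must be < end")
        if not self.tss_list:
            self.tss_list = (self.start,) if self.strand == "+" else (self.end - 1,)

    @property
    def primary_tss(self) -> int:
        return self.tss_list[0]

    def tss_to_end_offset(self, tss: int) -> int:
        """Oriented offset of the last gene base downstream of `tss`."""
        return (self.end - 1 - tss) if self.strand == "+" else (tss - self.start)

    def transcript_span(self, tss: int) -> tuple[int, int]:
        """0-based half-open span of the transcript starting at `tss`,
        running to the annotated gene end."""
        if self.strand == "+":
            return tss, self.end
        return self.start, tss + 1


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "ligsel") -> None:
    """Write gene/transcript/exon GTF records (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, tss in enumerate(g.tss_list):
                t_start, t_end = g.transcript_span(tss)
                t_attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{i + 1}";'
                for feat in ("transcript", "exon"):
                    fh.write(
                        f"{g.chrom}\t{source}\t{feat}\t{t_start + 1}\t{t_end}\t.\t"
                        f"{g.strand}\t.\t{t_attrs}\n"
                    )


def _parse_attrs(field8: str) -> dict[str, str]:
    out = {}
    for part in field8.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a GTF into gene models, recovering per-transcript TSSs."""
    spans: dict[str, tuple[str, int, int, str]] = {}
    tss: dict[str, list[tuple[str, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise DataError(f"malformed GTF line: {line[:80]!r}")
            chrom, _, feat, start1, end1, _, strand, _, attr_s = f[:9]
            attrs = _parse_attrs(attr_s)
            gid = attrs.get("gene_id")
            if gid is None:
                raise DataError("GTF record lacks gene_id")
            start, end = int(start1) - 1, int(end1)
            if feat == "gene":
                spans[gid] = (chrom, start, end, strand)
                order.append(gid)
            elif feat == "transcript":
                pos = start if strand == "+" else end - 1
                tss.setdefault(gid, []).append((attrs.get("transcript_id", ""), pos))
                if gid not in spans:
                    spans[gid] = (chrom, start, end, strand)
                    order.append(gid)
                else:
                    c, s, e, st = spans[gid]
                    spans[gid] = (c, min(s, start), max(e, end), st)
    genes = []
    for gid in order:
        chrom, start, end, strand = spans[gid]
        tlist = tuple(pos for _, pos in sorted(tss.get(gid, []))) or ()
        genes.append(GeneModel(gid, chrom, start, end, strand, tlist))
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write one BED12 line per transcript (0-based half-open), single block."""
    with open(path, "w") as fh:
        for g in genes:
            for i, tss in enumerate(g.tss_list):
                s, e = g.transcript_span(tss)
                name = f"{g.gene_id}.t{i + 1}"
                fh.write(
                    f"{g.chrom}\t{s}\t{e}\t{name}\t0\t{g.strand}\t{s}\t{e}\t0\t1\t"
                    f"{e - s},\t0,\n"
                )
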