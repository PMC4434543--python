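"""Per-base coverage tracks and bedGraph I/O.

A :class:`CoverageTrack` holds one dense per-base count vector per
chromosome plus the library size used as the reads-per-million (RPM)
denominator.  bedGraph files are 4-column, 0-based half-open, with runs
of equal value merged; the library size is carried in a
``# total_mapped_reads=N`` comment so that normalization survives a
round trip through disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

__all__ = ["CoverageTrack", "normalize_rpm", "read_bedgraph", "write_bedgraph"]


@dataclass
class CoverageTrack:
    """Dense per-base coverage with an RPM denominator."""

    chroms: dict[str, np.ndarray]
    total_mapped_reads: float
    name: str = "track"

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise DataError("total_mapped_reads must be > 0")
        for chrom, arr in self.chroms.items():
            if np.any(np.asarray(arr) < 0):
                raise DataError(f"negative coverage on {chrom}")

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.total_mapped_reads

    def rpm(self, chrom: str) -> np.ndarray:
        """Per-base RPM vector for one chromosome."""
        if chrom not in self.chroms:
            raise DataError(f"chromosome {chrom!r} absent from track {self.name!r}")
        return np.asarray(self.chroms[chrom], dtype=float) * self.rpm_factor

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Return a new track whose values are in RPM.

    The returned track's denominator is 10^6, so normalizing is
    idempotent and the RPM values are preserved by further calls.
    """
    scaled = {c: np.asarray(a, dtype=float) * track.rpm_factor for c, a in track.chroms.items()}
    return CoverageTrack(scaled, total_mapped_reads=1e6, name=track.name)


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_bedgraph(track: CoverageTrack, path: str | Path, write_zero: bool = False) -> None:
    """Write a 4-column bedGraph, merging runs of equal value.

    Zero runs are omitted unless ``write_zero``; with known chromosome
    lengths the representation is lossless either way.
    """
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track.name}\n")
        fh.write(f"# total_mapped_reads={_fmt(track.total_mapped_reads)}\n")
        for chrom in sorted(track.chroms):
            arr = np.asarray(track.chroms[chrom])
            fh.write(f"# chrom_length {chrom} {len(arr)}\n")
            if len(arr) == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0 and not write_zero:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    total_mapped_reads: float | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a dense track.

    Chromosome lengths and the RPM denominator are taken from the file's
    comments when present; explicit arguments override them.  Without
    either, lengths default to the last covered base and the denominator
    to the summed coverage.
    """
    lengths: dict[str, int] = dict(chrom_lengths or {})
    file_total: float | None = None
    name = Path(path).stem
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("total_mapped_reads="):
                    file_total = float(body.split("=", 1)[1])
                elif body.startswith("chrom_length"):
                    _, chrom, n = body.split()
                    lengths.setdefault(chrom, int(n))
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise DataError(f"malformed bedGraph line: {line[:80]!r}")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            if not 0 <= s < e:
                raise DataError(f"invalid interval {s}-{e} on {chrom}")
            records.setdefault(chrom, []).append((s, e, v))
    chroms: dict[str, np.ndarray] = {}
    all_chroms = set(records) | set(lengths)
    for chrom in all_chroms:
        recs = records.get(chrom, [])
        n = lengths.get(chrom, max((e for _, e, _ in recs), default=0))
        arr = np.zeros(n, dtype=float)
        for s, e, v in recs:
            if e > n:
                raise DataError(f"interval end {e} beyond length {n} on {chrom}")
            arr[s:e] = v
        chroms[chrom] = arr
    total = total_mapped_reads if total_mapped_reads is not None else file_total
    if total is None:
        total = float(sum(a.sum() for a in chroms.values())) or 1.0
    return CoverageTrack(chroms, total_mapped_reads=total, name=name)
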