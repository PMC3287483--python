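"""Reading and writing tags, regions and sites in BED-flavoured text formats.

Internal coordinates are 0-based half-open throughout; BED is the native
dialect.  A *tag* is a uniquely mapped read reduced to the 5'-most genomic
position of its source fragment on its strand: for a forward-strand BED
record that is ``chromStart``, for a reverse-strand record ``chromEnd - 1``
(the right-most aligned base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

log = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

_STRAND_ALIASES = {
    "+": FORWARD,
    "F": FORWARD,
    "f": FORWARD,
    "-": REVERSE,
    "R": REVERSE,
    "r": REVERSE,
}


@dataclass(frozen=True)
class Tag:
    """One mapped read reduced to its fragment-proximal 5' position."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"tag position must be >= 0, got {self.pos}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class TagTrack:
    """Per-chromosome, per-strand sorted arrays of tag 5' positions."""

    def __init__(self, data: dict[str, dict[str, np.ndarray]] | None = None):
        self._data: dict[str, dict[str, np.ndarray]] = {}
        if data:
            for chrom, strands in data.items():
                fwd = np.sort(np.asarray(strands.get(FORWARD, []), dtype=np.int64))
                rev = np.sort(np.asarray(strands.get(REVERSE, []), dtype=np.int64))
                self._data[chrom] = {FORWARD: fwd, REVERSE: rev}

    @classmethod
    def from_tags(cls, tags: Iterable[Tag]) -> "TagTrack":
        buckets: dict[str, dict[str, list[int]]] = {}
        for t in tags:
            buckets.setdefault(t.chrom, {FORWARD: [], REVERSE: []})[t.strand].append(t.pos)
        return cls({c: {s: np.asarray(v) for s, v in d.items()} for c, d in buckets.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        """Sorted tag positions on one strand (empty array if absent)."""
        return self._data.get(chrom, {}).get(strand, np.empty(0, dtype=np.int64))

    def combined(self, chrom: str) -> np.ndarray:
        """Sorted pooled positions of both strands on a chromosome."""
        fwd = self.positions(chrom, FORWARD)
        rev = self.positions(chrom, REVERSE)
        return np.sort(np.concatenate([fwd, rev]))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tags (both strands) with position in [start, end)."""
        n = 0
        for strand in (FORWARD, REVERSE):
            pos = self.positions(chrom, strand)
            n += int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        return n

    def total(self) -> int:
        return sum(
            len(strands[s]) for strands in self._data.values() for s in (FORWARD, REVERSE)
        )

    def iter_tags(self) -> Iterator[Tag]:
        for chrom in self.chroms:
            for strand in (FORWARD, REVERSE):
                for pos in self.positions(chrom, strand):
                    yield Tag(chrom, int(pos), strand)


def _parse_strand(symbol: str, lineno: int) -> str:
    try:
        return _STRAND_ALIASES[symbol]
    except KeyError:
        raise ValueError(f"line {lineno}: unknown strand symbol {symbol!r}") from None


def read_tags(path: str, format: str = "bed") -> TagTrack:
    """Read mapped tags from a BED or 3-column taglist file.

    BED records need >= 6 columns; the tag position is ``chromStart`` on the
    forward strand and ``chromEnd - 1`` on the reverse strand.  The taglist
    dialect is ``chrom <TAB> pos <TAB> strand``.  Malformed lines raise a
    :class:`ValueError` naming the offending line number.
    """
    if format not in ("bed", "taglist"):
        raise ValueError(f"unknown format {format!r}")
    tags: list[Tag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    if len(fields) < 6:
                        raise ValueError("expected >= 6 BED columns")
                    chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
                    strand = _parse_strand(strand, lineno)
                    pos = start if strand == FORWARD else end - 1
                else:
                    if len(fields) < 3:
                        raise ValueError("expected 3 taglist columns")
                    chrom, pos = fields[0], int(fields[1])
                    strand = _parse_strand(fields[2], lineno)
                tags.append(Tag(chrom, pos, strand))
            except ValueError as exc:
                if str(exc).startswith("line "):
                    raise
                raise ValueError(f"line {lineno}: malformed record: {exc}") from None
    if not tags:
        log.warning("no tags read from %s", path)
    return TagTrack.from_tags(tags)


def write_taglist(track: TagTrack, path: str) -> None:
    """Write tags as ``chrom <TAB> pos <TAB> strand`` lines."""
    with open(path, "w") as fh:
        for tag in track.iter_tags():
            fh.write(f"{tag.chrom}\t{tag.pos}\t{tag.strand}\n")


def write_tags_bed(track: TagTrack, path: str, read_len: int = 1) -> None:
    """Write tags as BED6 records of width ``read_len`` anchored at the tag.

    Forward reads start at the tag position; reverse reads end at the tag
    position (half-open end = pos + 1), so reading the file back recovers
    every tag exactly.
    """
    with open(path, "w") as fh:
        for i, tag in enumerate(track.iter_tags()):
            if tag.strand == FORWARD:
                start, end = tag.pos, tag.pos + read_len
            else:
                start, end = tag.pos - read_len + 1, tag.pos + 1
            start = max(start, 0)
            fh.write(f"{tag.chrom}\t{start}\t{end}\tt{i}\t0\t{tag.strand}\n")


def write_regions(regions, path: str) -> None:
    """Write binding regions as BED6+4: name, score, strand, then tag count,
    density, P and Q columns.  Regions are ordered by (chrom, start)."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for i, r in enumerate(ordered):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tregion{i}\t0\t.\t"
                f"{r.count}\t{r.density:.6g}\t{r.pvalue:.6g}\t{r.qvalue:.6g}\n"
            )


def write_sites(sites, path: str) -> None:
    """Write binding sites as 1-bp BED intervals.

    The name encodes the source region and the strand evidence (F, R or FR);
    the score column carries the relative binding affinity (fit slope).
    """
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t"
                f"{s.region_id}_{s.evidence}\t{s.affinity:.6g}\t.\n"
            )
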