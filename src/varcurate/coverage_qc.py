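"""Three-level coverage QC: gene, exon and base-pair gap reports.

A diagnostic result is only as good as the bases the assay actually
interrogated.  From a per-base depth track (BEDTools ``coverage -d``
style TSV over the capture target) this module derives:

* a **gap report** — every maximal run of bases whose depth falls
  strictly below a configurable threshold, at base-pair resolution;
* an **exon report** — per exon, the fraction of bases below threshold
  and a FULL / PARTIAL / NONE status;
* a **gene report** — per gene, a GREEN / AMBER / RED traffic light on
  the fraction of targeted bases adequately covered.

All intervals are 0-based half-open.  Medians of even-length arrays use
the lower median so every reported depth is one that was actually
observed.  Target bases missing from the coverage file are treated as
sequencing dropout (depth 0), not as an error.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError

__all__ = [
    "CoverageTrack",
    "CoverageInterval",
    "GapRegion",
    "Exon",
    "ExonCoverageRow",
    "GeneCoverageRow",
    "read_per_base_coverage",
    "read_exon_bed",
    "find_gaps",
    "exon_report",
    "gene_report",
    "lower_median",
]


def lower_median(values: np.ndarray) -> int:
    """Median using the lower middle element for even-length input."""
    if len(values) == 0:
        return 0
    return int(np.sort(np.asarray(values))[(len(values) - 1) // 2])


@dataclass(frozen=True)
class CoverageInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    depths: np.ndarray  # length == end - start

    def __post_init__(self) -> None:
        if len(self.depths) != self.end - self.start:
            raise ParseError(
                f"{self.chrom}:{self.start}-{self.end}: depth array length "
                f"{len(self.depths)} != interval length {self.end - self.start}"
            )


@dataclass
class CoverageTrack:
    """Per-base sequencing depth over the capture target for one sample."""

    sample_id: str
    intervals: list[CoverageInterval] = field(default_factory=list)

    def depths_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth for every base of [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=np.int64)
        filled = 0
        for iv in self.intervals:
            if iv.chrom != chrom or iv.end <= start or iv.start >= end:
                continue
            lo, hi = max(start, iv.start), min(end, iv.end)
            out[lo - start : hi - start] = iv.depths[lo - iv.start : hi - iv.start]
            filled += hi - lo
        if filled < end - start:
            warnings.warn(
                f"{chrom}:{start}-{end}: {end - start - filled} target bases "
                "absent from coverage track, counted as depth 0",
                stacklevel=2,
            )
        return out


def read_per_base_coverage(path: str | Path, sample_id: str | None = None) -> CoverageTrack:
    """Parse a BEDTools ``coverage -d``-style per-base depth TSV.

    Expected columns: chrom, start, end, [name,] offset (1-based within
    the interval), depth.  Offsets must run contiguously from 1 to the
    interval length; a skipped or non-monotone offset, or a negative
    depth, is a :class:`ParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coverage file not found: {path}")
    if sample_id is None:
        sample_id = path.stem.split(".")[0]

    intervals: list[CoverageInterval] = []
    current: tuple[str, int, int] | None = None
    depths: list[int] = []

    def flush() -> None:
        if current is not None:
            chrom, start, end = current
            if len(depths) != end - start:
                raise ParseError(
                    f"{path}: interval {chrom}:{start}-{end} ended with "
                    f"{len(depths)} of {end - start} offsets"
                )
            intervals.append(
                CoverageInterval(chrom, start, end, np.array(depths, dtype=np.int64))
            )

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 6:
                chrom, start_s, end_s, _name, off_s, depth_s = parts
            elif len(parts) == 5:
                chrom, start_s, end_s, off_s, depth_s = parts
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 or 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(start_s), int(end_s)
                offset, depth = int(off_s), int(depth_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate/offset/depth"
                ) from None
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {depth}")
            key = (chrom, start, end)
            if key != current:
                flush()
                current, depths = key, []
            if offset != len(depths) + 1:
                raise ParseError(
                    f"{path}:{lineno}: offset {offset} out of order "
                    f"(expected {len(depths) + 1})"
                )
            if offset > end - start:
                raise ParseError(
                    f"{path}:{lineno}: offset {offset} beyond interval length "
                    f"{end - start}"
                )
            depths.append(depth)
    flush()
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    for a, b in zip(intervals, intervals[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ParseError(
                f"{path}: overlapping intervals {a.chrom}:{a.start}-{a.end} "
                f"and {b.chrom}:{b.start}-{b.end}"
            )
    return CoverageTrack(sample_id=sample_id, intervals=intervals)


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    gene: str
    rank: int | None = None


_EXON_NAME = re.compile(r"^(?P<gene>.+?)_exon(?P<rank>\d+)$", re.IGNORECASE)


def read_exon_bed(path: str | Path) -> list[Exon]:
    """Read exon definitions from a BED file.

    The name column carries ``GENE_exonN``; a bare gene symbol is also
    accepted, in which case ranks are assigned by position per gene.
    """
    path = Path(path)
    raw: list[Exon] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: BED line needs >= 4 columns (name required)"
                )
            chrom, start_s, end_s, name = parts[:4]
            m = _EXON_NAME.match(name)
            if m:
                raw.append(
                    Exon(chrom, int(start_s), int(end_s), m.group("gene").upper(),
                         int(m.group("rank")))
                )
            else:
                raw.append(Exon(chrom, int(start_s), int(end_s), name.upper(), None))
    # assign positional ranks where the name carried none
    raw.sort(key=lambda e: (e.chrom, e.start))
    counters: dict[str, int] = {}
    out: list[Exon] = []
    for exon in raw:
        counters[exon.gene] = counters.get(exon.gene, 0) + 1
        rank = exon.rank if exon.rank is not None else counters[exon.gene]
        out.append(Exon(exon.chrom, exon.start, exon.end, exon.gene, rank))
    return out


@dataclass(frozen=True)
class GapRegion:
    """Maximal run of target bases below the coverage threshold."""

    chrom: str
    start: int
    end: int
    min_depth: int
    median_depth: int
    gene: str | None = None
    exon_rank: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _annotate_gap(
    chrom: str, start: int, end: int, exons: list[Exon] | None
) -> tuple[str | None, int | None]:
    if not exons:
        return None, None
    best: Exon | None = None
    best_overlap = 0
    for exon in exons:
        if exon.chrom != chrom:
            continue
        overlap = min(end, exon.end) - max(start, exon.start)
        if overlap > best_overlap:
            best, best_overlap = exon, overlap
    if best is None:
        return None, None
    return best.gene, best.rank


def find_gaps(
    track: CoverageTrack, threshold: int, exons: list[Exon] | None = None
) -> list[GapRegion]:
    """All maximal sub-threshold runs in the track, sorted by position.

    A base belongs to a gap iff its depth is strictly below
    ``threshold`` — depth equal to the threshold counts as covered.
    Each gap is annotated with the exon it overlaps most, when exon
    definitions are given.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    gaps: list[GapRegion] = []
    for iv in track.intervals:
        below = iv.depths < threshold
        if not below.any():
            continue
        # run boundaries from the sign changes of the below-mask
        padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            seg = iv.depths[s:e]
            gene, rank = _annotate_gap(iv.chrom, iv.start + s, iv.start + e, exons)
            gaps.append(
                GapRegion(
                    chrom=iv.chrom,
                    start=int(iv.start + s),
                    end=int(iv.start + e),
                    min_depth=int(seg.min()),
                    median_depth=lower_median(seg),
                    gene=gene,
                    exon_rank=rank,
                )
            )
    gaps.sort(key=lambda g: (g.chrom, g.start))
    return gaps


@dataclass(frozen=True)
class ExonCoverageRow:
    gene: str
    exon_rank: int | None
    chrom: str
    start: int
    end: int
    n_below: int
    median_depth: int
    status: str  # FULL | PARTIAL | NONE

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fraction_below_threshold(self) -> float:
        return self.n_below / self.length if self.length else 0.0


def exon_report(
    track: CoverageTrack, exons: list[Exon], threshold: int
) -> list[ExonCoverageRow]:
    """Per-exon coverage adequacy: FULL, PARTIAL or NONE.

    FULL iff no base is below the threshold, NONE iff every base is,
    PARTIAL otherwise.  Exon bases absent from the track count as depth
    0 (with a warning from the track).
    """
    rows: list[ExonCoverageRow] = []
    for exon in exons:
        depths = track.depths_over(exon.chrom, exon.start, exon.end)
        n_below = int((depths < threshold).sum())
        if n_below == 0:
            status = "FULL"
        elif n_below == len(depths):
            status = "NONE"
        else:
            status = "PARTIAL"
        rows.append(
            ExonCoverageRow(
                gene=exon.gene,
                exon_rank=exon.rank,
                chrom=exon.chrom,
                start=exon.start,
                end=exon.end,
                n_below=n_below,
                median_depth=lower_median(depths),
                status=status,
            )
        )
    return rows


@dataclass(frozen=True)
class GeneCoverageRow:
    gene: str
    median_depth: int
    fraction_targeted_bases_ok: float
    n_exons: int
    n_exons_partial_or_none: int
    colour: str  # GREEN | AMBER | RED


def gene_report(
    track: CoverageTrack,
    exons: list[Exon],
    threshold: int,
    green_min_ok: float = 0.95,
    amber_min_ok: float = 0.80,
) -> list[GeneCoverageRow]:
    """Traffic-light summary per gene.

    GREEN needs at least ``green_min_ok`` of the gene's targeted bases
    at/above the threshold *and* no completely uncovered exon; AMBER
    needs ``amber_min_ok``; anything less is RED.
    """
    if not amber_min_ok < green_min_ok:
        raise ValueError("amber_min_ok must be strictly below green_min_ok")
    exon_rows = exon_report(track, exons, threshold)
    by_gene: dict[str, list[tuple[Exon, ExonCoverageRow]]] = {}
    for exon, row in zip(exons, exon_rows):
        by_gene.setdefault(exon.gene, []).append((exon, row))
    out: list[GeneCoverageRow] = []
    for gene in sorted(by_gene):
        pairs = by_gene[gene]
        all_depths = np.concatenate(
            [track.depths_over(e.chrom, e.start, e.end) for e, _ in pairs]
        )
        total = int(sum(r.length for _, r in pairs))
        below = int(sum(r.n_below for _, r in pairs))
        frac_ok = (total - below) / total if total else 0.0
        any_none = any(r.status == "NONE" for _, r in pairs)
        if frac_ok >= green_min_ok and not any_none:
            colour = "GREEN"
        elif frac_ok >= amber_min_ok:
            colour = "AMBER"
        else:
            colour = "RED"
        out.append(
            GeneCoverageRow(
                gene=gene,
                median_depth=lower_median(all_depths),
                fraction_targeted_bases_ok=frac_ok,
                n_exons=len(pairs),
                n_exons_partial_or_none=sum(
                    1 for _, r in pairs if r.status != "FULL"
                ),
                colour=colour,
            )
        )
    return out
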