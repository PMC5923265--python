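"""Interval arithmetic, BED/TSS I/O, and TSS-relative region annotation.

Coordinates are 0-based half-open (BED convention) throughout.  A region's
reference point for distance computations is its integer midpoint
``(start + end) // 2``.  Signed TSS distances are measured in the gene's
reading direction: positive values lie downstream of the TSS (into the gene
body), negative values upstream.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

# Promoter window around the TSS, in reading direction.
PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 500
# Distal elements: strictly more than DISTAL_MIN and at most DISTAL_MAX
# from the nearest TSS.
DISTAL_MIN = 2000
DISTAL_MAX = 100_000


class BedParseError(ValueError):
    """Raised for malformed BED input, naming the offending line."""


@dataclass(frozen=True)
class Region:
    """A genomic interval, the unit of accessibility quantification."""

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.id}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.id}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"region {self.id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of a gene; strand is mandatory."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"TSS {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"TSS {self.gene_id}: negative position")


@dataclass(frozen=True)
class RegionAnnotation:
    """Nearest-TSS assignment and promoter/distal class of one region."""

    region_id: str
    gene_id: Optional[str]
    signed_distance: Optional[int]
    location_class: str  # promoter | distal | unassigned


def read_regions(path: str | Path) -> list[Region]:
    """Read a BED3/BED6 file into an ordered region set.

    Ids come from column 4 when present, otherwise ``region_<n>`` in file
    order.  Duplicate ids, non-integer coordinates and empty intervals are
    rejected with the line number.
    """
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinate"
                ) from exc
            rid = fields[3] if len(fields) >= 4 and fields[3] else f"region_{lineno}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            if rid in seen:
                raise BedParseError(f"line {lineno}: duplicate region id {rid!r}")
            seen.add(rid)
            try:
                regions.append(Region(chrom, start, end, rid, strand))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table.

    Accepts either a 4-column TSV (gene_id, chrom, tss, strand; optional
    header) with 0-based positions, or a minimal GTF whose gene lines carry a
    ``gene_id`` attribute (1-based; converted by -1 on the strand-appropriate
    end).  One record per gene_id is enforced.
    """
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9 and fields[2] == "gene":
                attr = fields[8]
                gene_id = attr.split("gene_id")[1].split(";")[0].strip().strip('"')
                start1, end1 = int(fields[3]), int(fields[4])
                strand = fields[6]
                tss = start1 - 1 if strand == "+" else end1 - 1
                rec = TSSRecord(gene_id, fields[0], tss, strand)
            else:
                if len(fields) < 4:
                    raise BedParseError(f"line {lineno}: fewer than 4 columns")
                if fields[0] == "gene_id":  # header
                    continue
                rec = TSSRecord(fields[0], fields[1], int(fields[2]), fields[3])
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in TSS table")
            seen.add(rec.gene_id)
            records.append(rec)
    return records


def classify_distance(signed_distance: int) -> str:
    """Promoter / distal / unassigned class of a signed TSS distance."""
    if -PROMOTER_UPSTREAM <= signed_distance <= PROMOTER_DOWNSTREAM:
        return "promoter"
    if DISTAL_MIN < abs(signed_distance) <= DISTAL_MAX:
        return "distal"
    return "unassigned"


def annotate_nearest_tss(
    regions: Sequence[Region], tss_records: Sequence[TSSRecord]
) -> list[RegionAnnotation]:
    """Assign each region to its nearest TSS and classify the distance.

    The nearest TSS minimizes the absolute genomic distance from the region
    midpoint; ties break to the lexicographically smallest gene_id.  The
    signed distance is strand-aware (``midpoint - tss`` on +, ``tss -
    midpoint`` on -) so that negative values are upstream of the TSS.
    Regions on chromosomes with no TSS are left unassigned.
    """
    if not tss_records:
        raise ValueError("tss_records must be non-empty")
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)
    index: dict[str, tuple[list[int], list[TSSRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda t: (t.tss, t.gene_id))
        index[chrom] = ([t.tss for t in recs], recs)

    out: list[RegionAnnotation] = []
    for region in regions:
        if region.chrom not in index:
            out.append(RegionAnnotation(region.id, None, None, "unassigned"))
            continue
        positions, recs = index[region.chrom]
        mid = region.midpoint
        i = bisect_left(positions, mid)
        best = None
        if i > 0:
            best = mid - positions[i - 1]
        if i < len(positions):
            d = positions[i] - mid
            if best is None or d < best:
                best = d
        # All records at exactly the minimal absolute distance.
        candidates: list[TSSRecord] = []
        j = i - 1
        while j >= 0 and mid - positions[j] == best:
            candidates.append(recs[j])
            j -= 1
        j = i
        while j < len(positions) and positions[j] - mid == best:
            candidates.append(recs[j])
            j += 1
        winner = min(candidates, key=lambda t: t.gene_id)
        signed = mid - winner.tss if winner.strand == "+" else winner.tss - mid
        out.append(
            RegionAnnotation(region.id, winner.gene_id, signed, classify_distance(signed))
        )
    return out


def overlap_pairs(
    set_a: Sequence[Region], set_b: Sequence[Region]
) -> list[tuple[str, str, int]]:
    """All (a_id, b_id, overlap_bp) pairs with >= 1 bp intersection.

    Half-open arithmetic: [0,10) and [10,20) do not overlap.  Each pair is
    reported exactly once, in the order of ``set_a``.
    """
    trees: dict[str, IntervalTree] = {}
    for b in set_b:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b.id)
    pairs: list[tuple[str, str, int]] = []
    for a in set_a:
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(a.start, a.end), key=lambda iv: (iv.begin, iv.data))
        for iv in hits:
            bp = min(a.end, iv.end) - max(a.start, iv.begin)
            if bp >= 1:
                pairs.append((a.id, iv.data, bp))
    return pairs


def write_annotations(
    annotations: Iterable[RegionAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tgene_id\tsigned_distance\tlocation_class\n")
        for a in annotations:
            gene = a.gene_id if a.gene_id is not None else ""
            dist = a.signed_distance if a.signed_distance is not None else ""
            fh.write(f"{a.region_id}\t{gene}\t{dist}\t{a.location_class}\n")


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("region_id")
        for line in fh:
            rid, gene, dist, cls = line.rstrip("\n").split("\t")
            out.append(
                RegionAnnotation(
                    rid, gene or None, int(dist) if dist else None, cls
                )
            )
    return out
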