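"""PWM scanning, Tn5-insertion footprint profiles, and motif trajectories.

A transposase insertion leaves a staggered cut whose 5' read ends must be
shifted (+4 on the forward strand, -5 on the reverse) to recover the true
insertion point.  Aggregating insertion counts around oriented motif
occurrences yields a footprint: bound factors protect the motif core while
the flanking nucleosome-free chromatin remains accessible, so the profile
dips over the core.

Per-motif accessibility trajectories average rppm over the differential
regions containing the motif and are correlated (Spearman) with the
transcription factor's expression across the five divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

DEFAULT_WINDOW = 100  # bp of flank on each side of the motif


@dataclass(frozen=True)
class RawReads:
    """Unshifted mapped read 5' ends (positions + strands)."""

    positions: np.ndarray
    strands: np.ndarray  # '+' or '-'


@dataclass(frozen=True)
class CutSites:
    """Tn5 insertion points after strand-specific shifting."""

    positions: np.ndarray


@dataclass(frozen=True)
class PWM:
    """Position weight matrix (4 x L column-stochastic probabilities)."""

    motif_id: str
    matrix: np.ndarray  # rows A, C, G, T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    tf_gene_id: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4 x L with L >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if not np.isclose(np.asarray(self.background).sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            np.asarray(self.background)[::-1].copy(),
            self.tf_gene_id,
        )


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float  # log-odds, bits
    region_id: str | None = None


def shift_to_cut_sites(reads: RawReads) -> CutSites:
    """Apply the +4/-5 Tn5 shift to raw read 5' ends."""
    if not isinstance(reads, RawReads):
        raise TypeError("shift_to_cut_sites accepts raw reads only")
    pos = np.asarray(reads.positions, dtype=np.int64)
    strands = np.asarray(reads.strands)
    shifted = np.where(strands == "+", pos + 4, pos - 5)
    return CutSites(shifted)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _logodds_lut(pwm: PWM, floor: float = 1e-9) -> np.ndarray:
    """5 x L log2 odds lookup; N scores 0 bits at every position."""
    lo = np.zeros((5, pwm.length))
    lo[:4] = np.log2(
        np.maximum(pwm.matrix, floor)
        / np.maximum(np.asarray(pwm.background)[:, None], floor)
    )
    return lo


def _scan_one_strand(codes: np.ndarray, lut: np.ndarray) -> np.ndarray:
    length = lut.shape[1]
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for offset in range(length):
        scores += lut[codes[offset : offset + n], offset]
    return scores


def scan_pwm(
    sequence: str, pwm: PWM, threshold_bits: float,
    chrom: str = ".", offset: int = 0, region_id: str | None = None,
) -> list[MotifOccurrence]:
    """Log-odds scan of both strands; hits at or above threshold.

    A minus-strand hit at genomic start ``s`` means the reverse complement
    of sequence[s:s+L] matches the motif.  Overlapping hits on opposite
    strands are both kept.  N bases contribute 0 bits.
    """
    codes = _encode(sequence)
    hits: list[MotifOccurrence] = []
    for strand, p in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _scan_one_strand(codes, _logodds_lut(p))
        for i in np.flatnonzero(scores >= threshold_bits - 1e-9):
            hits.append(
                MotifOccurrence(
                    pwm.motif_id, chrom, offset + int(i),
                    offset + int(i) + pwm.length, strand,
                    float(scores[i]), region_id,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_regions(
    genome, regions: Sequence, pwm: PWM, threshold_bits: float
) -> list[MotifOccurrence]:
    """Scan each region's sequence; occurrences lie fully inside regions.

    ``genome`` is a pyfaidx.Fasta (or any mapping of chrom -> sliceable
    sequence).
    """
    hits: list[MotifOccurrence] = []
    for r in regions:
        seq = str(genome[r.chrom][r.start : r.end])
        hits.extend(scan_pwm(seq, pwm, threshold_bits, r.chrom, r.start, r.id))
    return hits


def footprint_profile(
    occurrences: Sequence[MotifOccurrence],
    cut_sites: Mapping[str, np.ndarray],
    in_peak_insertions: int,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Mean insertions per occurrence per million in-peak insertions.

    Offsets run -window .. L+window-1 in motif orientation (minus-strand
    occurrences are reversed), so index ``window`` is the first motif base.
    """
    if not occurrences:
        raise ValueError("no occurrences supplied for footprint profile")
    length = occurrences[0].end - occurrences[0].start
    size = 2 * window + length
    profile = np.zeros(size)
    sorted_sites = {c: np.sort(np.asarray(p)) for c, p in cut_sites.items()}
    for occ in occurrences:
        sites = sorted_sites.get(occ.chrom)
        if sites is None:
            continue
        lo = occ.start - window
        hi = occ.end + window
        sel = sites[np.searchsorted(sites, lo) : np.searchsorted(sites, hi)]
        if occ.strand == "-":
            idx = (occ.end - 1 + window) - sel
        else:
            idx = sel - lo
        profile += np.bincount(idx, minlength=size)
    profile /= len(occurrences)
    profile *= 1e6 / in_peak_insertions
    return profile


def core_flank_ratio(profile: np.ndarray, motif_length: int,
                     window: int = DEFAULT_WINDOW) -> float:
    """Mean insertion rate over the motif core divided by the flank mean."""
    core = profile[window : window + motif_length]
    flank = np.concatenate([profile[:window], profile[window + motif_length :]])
    return float(core.mean() / flank.mean())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman correlation (average ranks, then Pearson).

    Returns NaN when either vector has no rank variation (degenerate ranks),
    rather than forcing 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def motif_trajectory(
    division_mean_rppm: pd.DataFrame,
    dar_ids: set[str],
    occurrence_region_ids: set[str],
    tf_expression: Sequence[float],
    min_regions: int = 3,
) -> dict | None:
    """Average accessibility of motif-bearing DARs per division, and its
    Spearman correlation with the factor's expression trajectory.

    ``division_mean_rppm`` is regions x divisions (replicates already
    averaged).  Returns None (motif skipped) when fewer than ``min_regions``
    DARs contain the motif.
    """
    ids = sorted(dar_ids & occurrence_region_ids)
    if len(ids) < min_regions:
        return None
    traj = division_mean_rppm.loc[ids].mean(axis=0)
    rho = spearman_rho(traj.to_numpy(), np.asarray(tf_expression, dtype=float))
    return {
        "n_regions": len(ids),
        "trajectory": traj,
        "rho": rho,
    }


def target_gene_summary(
    occurrence_region_ids: set[str],
    dar_ids: set[str],
    annotations: Sequence,
    expression: pd.DataFrame,
    div_late: str = "Div8",
    div_ref: str = "Div0",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Expression change of genes whose DARs contain the motif.

    Targets are the genes annotated (nearest TSS) to DAR regions with >= 1
    occurrence.  The per-gene log2 fold change between the last and first
    division uses a pseudocount on the normalized expression values; the
    fraction increasing/decreasing uses a threshold of 0.
    """
    region_gene = {
        a.region_id: a.gene_id for a in annotations if a.gene_id is not None
    }
    genes = sorted(
        {
            region_gene[rid]
            for rid in occurrence_region_ids & dar_ids
            if rid in region_gene
        }
        & set(expression.index)
    )
    if not genes:
        out = pd.DataFrame(columns=["gene_id", "log2fc"])
        out.attrs["fraction_up"] = float("nan")
        out.attrs["fraction_down"] = float("nan")
        return out
    fc = np.log2(
        (expression.loc[genes, div_late] + pseudocount)
        / (expression.loc[genes, div_ref] + pseudocount)
    )
    out = pd.DataFrame({"gene_id": genes, "log2fc": fc.to_numpy()})
    out.attrs["fraction_up"] = float((out["log2fc"] > 0).mean())
    out.attrs["fraction_down"] = float((out["log2fc"] < 0).mean())
    return out


def negative_rho_percent(rhos: Sequence[float]) -> int:
    """Share of motifs with a negative correlation, as integer percent."""
    arr = np.asarray(rhos, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("no finite correlations")
    return int(round(100 * float((arr < 0).mean())))


def read_pwms(path: str | Path) -> list[PWM]:
    """Read the package PWM text format.

    One record per motif: a ``>motif_id [tf=GENE]`` line followed by four
    whitespace-separated probability rows in A, C, G, T order.
    """
    pwms: list[PWM] = []
    motif_id = None
    tf = None
    rows: list[list[float]] = []

    def flush():
        if motif_id is not None:
            if len(rows) != 4:
                raise ValueError(f"{motif_id}: expected 4 matrix rows")
            pwms.append(PWM(motif_id, np.array(rows), tf_gene_id=tf))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                motif_id = parts[0]
                tf = None
                for p in parts[1:]:
                    if p.startswith("tf="):
                        tf = p[3:]
                rows = []
            else:
                rows.append([float(v) for v in line.split()])
    flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            tag = f" tf={p.tf_gene_id}" if p.tf_gene_id else ""
            fh.write(f">{p.motif_id}{tag}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def write_occurrences(occs: Sequence[MotifOccurrence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in occs:
            fh.write(
                f"{o.chrom}\t{o.start}\t{o.end}\t{o.motif_id}"
                f"\t{o.score:.4f}\t{o.strand}\t{o.region_id or ''}\n"
            )


def read_occurrences(path: str | Path) -> list[MotifOccurrence]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, mid, score, strand, rid = line.rstrip("\n").split("\t")
            out.append(
                MotifOccurrence(
                    mid, chrom, int(start), int(end), strand,
                    float(score), rid or None,
                )
            )
    return out
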