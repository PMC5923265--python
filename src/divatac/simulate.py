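"""Synthetic division-resolved dataset with planted truth.

Emulates the study design the pipeline targets: five division states
(Div0, Div1, Div3, Div5, Div8) with two ATAC replicates each, NB-distributed
region counts with division-linked fold changes concentrated at Div8,
insertion-level footprints with core depletion at planted motif sites,
monotone CpG demethylation at planted enhancers, class-coupled expression
trajectories (primed: flat-high Div0 promoter accessibility with late
expression; induced: closed Div0 promoter opening with expression), and a
repressive histone mark on a primed-promoter subset that is lost in the
plasmablast state.

Every gene owns one promoter region and a fixed ladder of distal regions
within its own TSS neighborhood, so planted region effects map
unambiguously onto genes.  A single seed determines all outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import DIVISIONS
from .accessibility import SampleStats, write_sample_sheet
from .footprint import PWM, DEFAULT_WINDOW, write_pwms
from .genomic import Region, TSSRecord, write_regions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 7
    n_chrom: int = 2
    n_genes: int = 500
    regions_per_gene: int = 10  # 1 promoter + (n-1) distal
    replicates: int = 2
    region_width: int = 500
    gene_spacing: int = 30_000
    # negative binomial: var = mu + dispersion * mu^2
    nb_mean_distal: float = 100.0
    nb_dispersion: float = 0.1
    # planted fractions
    frac_dar_up: float = 0.06      # of all regions
    frac_dar_down: float = 0.06
    frac_primed: float = 0.10      # of genes
    frac_induced: float = 0.10
    frac_silent: float = 0.05
    frac_dml: float = 0.5          # of planted distal DAR regions
    frac_marked_primed: float = 0.3
    frac_marked_induced: float = 0.3
    frac_marked_background: float = 0.02
    # effect sizes
    dar_log2fc: float = 2.0
    dml_levels: tuple = (0.85, 0.75, 0.60, 0.45, 0.25)  # per division
    footprint_depletion: float = 0.5  # core weight relative to flank
    # footprints
    n_motifs_up: int = 4
    n_motifs_down: int = 4
    motif_length: int = 10
    occurrences_per_motif: int = 60
    insertions_per_occurrence: int = 30
    footprint_window: int = DEFAULT_WINDOW
    # library
    frip_target: float = 0.3
    dars_per_gene: int = 3
    onset_divisions: tuple = ("Div3", "Div5", "Div8")
    onset_probs: tuple = (0.1, 0.1, 0.8)

    def __post_init__(self) -> None:
        for name in (
            "frac_dar_up", "frac_dar_down", "frac_primed", "frac_induced",
            "frac_silent", "frac_dml", "frac_marked_primed",
            "frac_marked_induced", "frac_marked_background",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_primed + self.frac_induced > 1:
            raise ValueError("frac_primed + frac_induced exceeds 1")
        if not 0 < self.frip_target <= 1:
            raise ValueError("frip_target outside (0, 1]")
        n_special = (
            self._n_primed + self._n_induced + self._n_silent
            + self._n_up_genes + self._n_down_genes
        )
        if n_special > self.n_genes:
            raise ValueError(
                "planted gene classes exceed n_genes; lower the fractions"
            )
        if (
            self.n_motifs_up * self.occurrences_per_motif
            > self._n_up_genes * self.dars_per_gene
            or self.n_motifs_down * self.occurrences_per_motif
            > self._n_down_genes * self.dars_per_gene
        ):
            raise ValueError("not enough planted DAR regions for motif sites")

    @property
    def n_regions(self) -> int:
        return self.n_genes * self.regions_per_gene

    @property
    def _n_primed(self) -> int:
        return round(self.frac_primed * self.n_genes)

    @property
    def _n_induced(self) -> int:
        return round(self.frac_induced * self.n_genes)

    @property
    def _n_silent(self) -> int:
        return round(self.frac_silent * self.n_genes)

    @property
    def _n_up_genes(self) -> int:
        # genes carrying planted up distal DARs
        return round(self.frac_dar_up * self.n_regions / self.dars_per_gene)

    @property
    def _n_down_genes(self) -> int:
        return round(self.frac_dar_down * self.n_regions / self.dars_per_gene)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data = data.get("simulate", data)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown simulate config keys: {sorted(bad)}")
        for k in ("dml_levels", "onset_divisions", "onset_probs"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("dml_levels", "onset_divisions", "onset_probs"):
            d[k] = list(d[k])
        return d


@dataclass
class SimResult:
    """Paths of the generated dataset plus in-memory truth tables."""

    outdir: Path
    paths: dict
    dar_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    dml_truth: pd.DataFrame
    motif_truth: pd.DataFrame
    mark_truth: pd.DataFrame


def _write_fasta(seqs: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, codes in seqs.items():
            fh.write(f">{chrom}\n")
            text = codes.tobytes().decode("ascii")
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float
             ) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(r, p)


def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate the full on-disk dataset and truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    # ---- gene layout -------------------------------------------------
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chrom)
    chrom_len = genes_per_chrom * cfg.gene_spacing + 10_000
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]

    gene_ids = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    tss_records = []
    for i, gid in enumerate(gene_ids):
        chrom = chrom_names[i // genes_per_chrom]
        slot = i % genes_per_chrom
        tss = slot * cfg.gene_spacing + 5000
        tss_records.append(TSSRecord(gid, chrom, tss, str(strands[i])))

    # ---- gene class assignment ---------------------------------------
    order = rng.permutation(cfg.n_genes)
    n_p, n_i, n_s = cfg._n_primed, cfg._n_induced, cfg._n_silent
    n_u, n_dn = cfg._n_up_genes, cfg._n_down_genes
    idx_primed = order[:n_p]
    idx_induced = order[n_p : n_p + n_i]
    idx_up = order[n_p + n_i : n_p + n_i + n_u]
    idx_down = order[n_p + n_i + n_u : n_p + n_i + n_u + n_dn]
    idx_silent = order[n_p + n_i + n_u + n_dn : n_p + n_i + n_u + n_dn + n_s]
    gene_class = np.array(["flat"] * cfg.n_genes, dtype=object)
    gene_class[idx_primed] = "primed"
    gene_class[idx_induced] = "induced"
    gene_class[idx_up] = "up"
    gene_class[idx_down] = "down"
    gene_class[idx_silent] = "silent"

    onset = np.array(["Div8"] * cfg.n_genes, dtype=object)
    movers = np.concatenate([idx_up, idx_down])
    onset[movers] = rng.choice(
        cfg.onset_divisions, size=len(movers), p=cfg.onset_probs
    )

    # ---- regions -----------------------------------------------------
    half = cfg.region_width // 2
    regions: list[Region] = []
    region_gene: list[str] = []
    region_kind: list[str] = []
    for i, t in enumerate(tss_records):
        # promoter: midpoint 50 bp into the gene body
        if t.strand == "+":
            pstart = t.tss - (half - 50)
        else:
            pstart = t.tss - (half + 50)
        regions.append(
            Region(t.chrom, pstart, pstart + cfg.region_width,
                   f"{t.gene_id}_prom")
        )
        region_gene.append(t.gene_id)
        region_kind.append("promoter")
        for j in range(cfg.regions_per_gene - 1):
            d = 2600 + j * 1300
            start = t.tss + d - half
            regions.append(
                Region(t.chrom, start, start + cfg.region_width,
                       f"{t.gene_id}_dist{j + 1}")
            )
            region_gene.append(t.gene_id)
            region_kind.append("distal")

    region_ids = [r.id for r in regions]
    rid_index = {rid: i for i, rid in enumerate(region_ids)}

    # ---- planted region effects --------------------------------------
    n_reg = len(regions)
    base_mean = np.exp(
        rng.normal(np.log(cfg.nb_mean_distal), 0.4, size=n_reg)
    )
    lfc = np.zeros(n_reg)
    reg_onset = np.array(["-"] * n_reg, dtype=object)
    dar_rows = []
    for gi, gid in enumerate(gene_ids):
        cls = gene_class[gi]
        prom = rid_index[f"{gid}_prom"]
        if cls == "primed":
            base_mean[prom] = 160.0
        elif cls == "induced":
            base_mean[prom] = 0.5
            lfc[prom] = np.log2(60.0 / 0.5)
            reg_onset[prom] = "Div8"
            dar_rows.append(
                {"region_id": region_ids[prom], "direction": "up",
                 "onset": "Div8", "log2fc": lfc[prom], "kind": "promoter"}
            )
        elif cls in ("up", "down"):
            base_mean[prom] = 8.0
            sign = 1.0 if cls == "up" else -1.0
            for j in range(cfg.dars_per_gene):
                ri = rid_index[f"{gid}_dist{j + 1}"]
                base_mean[ri] = np.exp(rng.normal(np.log(120.0), 0.3))
                lfc[ri] = sign * cfg.dar_log2fc
                reg_onset[ri] = onset[gi]
                dar_rows.append(
                    {"region_id": region_ids[ri],
                     "direction": "up" if sign > 0 else "down",
                     "onset": onset[gi], "log2fc": lfc[ri], "kind": "distal"}
                )
        else:
            base_mean[prom] = np.exp(rng.normal(np.log(50.0), 0.5))
    dar_truth = pd.DataFrame(
        dar_rows, columns=["region_id", "direction", "onset", "log2fc", "kind"]
    )

    # ---- counts ------------------------------------------------------
    div_rank = {d: k for k, d in enumerate(DIVISIONS)}
    sample_ids = []
    col_means = {}
    for div in DIVISIONS:
        active = np.array(
            [o != "-" and div_rank[div] >= div_rank[o] for o in reg_onset]
        )
        mu_div = base_mean * np.where(active, 2.0**lfc, 1.0)
        for rep in range(1, cfg.replicates + 1):
            sid = f"{div}_r{rep}"
            sample_ids.append(sid)
            depth = np.exp(rng.normal(0.0, 0.15))
            col_means[sid] = mu_div * depth
    counts = pd.DataFrame(
        {sid: _nb_draw(rng, col_means[sid], cfg.nb_dispersion)
         for sid in sample_ids},
        index=pd.Index(region_ids, name="region_id"),
    )

    samples = []
    for sid in sample_ids:
        div, rep = sid.split("_r")
        in_peak = int(counts[sid].sum())
        unique = int(round(in_peak / cfg.frip_target))
        samples.append(SampleStats(sid, div, int(rep), unique, in_peak))

    # ---- expression --------------------------------------------------
    expr_base = np.exp(rng.normal(np.log(100.0), 0.6, size=cfg.n_genes))
    traj = np.zeros((cfg.n_genes, len(DIVISIONS)))
    for gi in range(cfg.n_genes):
        cls = gene_class[gi]
        for k, div in enumerate(DIVISIONS):
            late = div_rank[div] >= div_rank[onset[gi]]
            if cls == "flat":
                traj[gi, k] = expr_base[gi]
            elif cls == "silent":
                traj[gi, k] = 0.05
            elif cls == "primed":
                traj[gi, k] = 500.0 if late else 5.0
            elif cls == "induced":
                traj[gi, k] = 150.0 if late else 5.0
            elif cls == "up":
                traj[gi, k] = 80.0 if late else 20.0
            else:  # down
                traj[gi, k] = 40.0 if late else 160.0
    expr_counts = pd.DataFrame(
        index=pd.Index(gene_ids, name="gene_id")
    )
    for k, div in enumerate(DIVISIONS):
        for rep in range(1, cfg.replicates + 1):
            depth = np.exp(rng.normal(0.0, 0.15))
            expr_counts[f"{div}_r{rep}"] = _nb_draw(
                rng, traj[:, k] * depth, cfg.nb_dispersion
            )
    cpm = expr_counts * 1e6 / expr_counts.sum(axis=0)
    expression = pd.DataFrame(
        {div: cpm[[f"{div}_r{r}" for r in range(1, cfg.replicates + 1)]]
         .mean(axis=1) for div in DIVISIONS},
        index=expr_counts.index,
    )

    # ---- genome + motifs ---------------------------------------------
    seqs = {
        c: _BASES[rng.integers(0, 4, size=chrom_len)].copy()
        for c in chrom_names
    }
    motif_ids = (
        [f"MOTIF_UP{i + 1}" for i in range(cfg.n_motifs_up)]
        + [f"MOTIF_DN{i + 1}" for i in range(cfg.n_motifs_down)]
    )
    motif_dir = ["up"] * cfg.n_motifs_up + ["down"] * cfg.n_motifs_down
    tf_pool = {"up": list(idx_up), "down": list(idx_down)}
    dir_counter = {"up": 0, "down": 0}
    pwms = []
    motif_rows = []
    consensus_map = {}
    for mi, mid in enumerate(motif_ids):
        cons = "".join(
            "ACGT"[b] for b in rng.integers(0, 4, size=cfg.motif_length)
        )
        mat = np.full((4, cfg.motif_length), 0.01)
        for j, b in enumerate(cons):
            mat["ACGT".index(b), j] = 0.97
        direction = motif_dir[mi]
        tf_gene = gene_ids[tf_pool[direction][dir_counter[direction]]]
        dir_counter[direction] += 1
        pwms.append(PWM(mid, mat, tf_gene_id=tf_gene))
        consensus_map[mid] = cons
        motif_rows.append(
            {"motif_id": mid, "tf_gene_id": tf_gene,
             "direction": motif_dir[mi],
             "n_planted": cfg.occurrences_per_motif, "activity": "activating"}
        )
    motif_truth = pd.DataFrame(motif_rows)

    pools = {
        "up": dar_truth.query("direction == 'up' and kind == 'distal'")
        ["region_id"].tolist(),
        "down": dar_truth.query("direction == 'down'")["region_id"].tolist(),
    }
    for d in pools:
        pools[d] = list(rng.permutation(pools[d]))
    planted_occ: list[tuple[str, str, int, str]] = []  # motif, chrom, start, strand
    for mi, mid in enumerate(motif_ids):
        pool = pools[motif_dir[mi]]
        take, pools[motif_dir[mi]] = (
            pool[: cfg.occurrences_per_motif],
            pool[cfg.occurrences_per_motif :],
        )
        for rid in take:
            r = regions[rid_index[rid]]
            start = r.midpoint - cfg.motif_length // 2
            strand = str(rng.choice(["+", "-"]))
            site = consensus_map[mid]
            if strand == "-":
                site = "".join(_COMP[b] for b in reversed(site))
            seqs[r.chrom][start : start + cfg.motif_length] = np.frombuffer(
                site.encode(), dtype=np.uint8
            )
            planted_occ.append((mid, r.chrom, start, strand))

    # ---- cut sites (footprint windows only) --------------------------
    w = cfg.footprint_window
    length = cfg.motif_length
    weights = np.ones(2 * w + length)
    weights[w : w + length] = cfg.footprint_depletion
    weights /= weights.sum()
    cutsite_paths = {}
    for div in DIVISIONS:
        rows_pos: list[np.ndarray] = []
        rows_chrom: list[np.ndarray] = []
        for mid, chrom, start, strand in planted_occ:
            offs = rng.choice(
                len(weights), size=cfg.insertions_per_occurrence, p=weights
            )
            rows_pos.append(start - w + offs)
            rows_chrom.append(np.repeat(chrom, len(offs)))
        path = outdir / f"cutsites_{div}.bed"
        if rows_pos:
            pos = np.concatenate(rows_pos)
            chroms = np.concatenate(rows_chrom)
            order2 = np.lexsort((pos, chroms))
            with open(path, "w") as fh:
                for i in order2:
                    fh.write(f"{chroms[i]}\t{pos[i]}\t{pos[i] + 1}\n")
        else:
            path.write_text("")
        cutsite_paths[div] = path

    # ---- DML ---------------------------------------------------------
    distal_dar = dar_truth.query("kind == 'distal'")["region_id"].tolist()
    n_dml_regions = round(cfg.frac_dml * len(distal_dar))
    dml_regions = list(rng.permutation(distal_dar)[:n_dml_regions])
    dml_rows = []
    for rid in dml_regions:
        r = regions[rid_index[rid]]
        for off in (-90, -30, 30, 90):
            dml_rows.append(
                {"chrom": r.chrom, "pos": r.midpoint + off,
                 "region_id": rid, "is_dml": True}
            )
    non_dar = [r for r in region_ids if r not in set(dar_truth["region_id"])]
    for rid in rng.permutation(non_dar)[:200]:
        r = regions[rid_index[rid]]
        dml_rows.append(
            {"chrom": r.chrom, "pos": r.midpoint, "region_id": rid,
             "is_dml": False}
        )
    dml_truth = pd.DataFrame(dml_rows)
    meth = pd.DataFrame({"chrom": dml_truth["chrom"], "pos": dml_truth["pos"]})
    for k, div in enumerate(DIVISIONS):
        level = np.where(
            dml_truth["is_dml"], cfg.dml_levels[k], 0.80
        )
        meth[f"meth_{div}"] = np.round(level, 4)
    meth = meth.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # ---- histone mark scores -----------------------------------------
    marked = np.zeros(cfg.n_genes, dtype=bool)
    for idx_set, frac in (
        (idx_primed, cfg.frac_marked_primed),
        (idx_induced, cfg.frac_marked_induced),
    ):
        k = round(frac * len(idx_set))
        marked[rng.permutation(idx_set)[:k]] = True
    others = np.setdiff1d(
        np.arange(cfg.n_genes), np.concatenate([idx_primed, idx_induced])
    )
    k_bg = round(cfg.frac_marked_background * len(others))
    marked[rng.permutation(others)[:k_bg]] = True

    score_b = np.where(
        marked,
        np.maximum(rng.normal(15.0, 2.0, cfg.n_genes), 2.0),
        np.abs(rng.normal(0.8, 0.2, cfg.n_genes)),
    )
    lost = marked & (gene_class == "primed")
    score_pb = np.where(
        lost, np.abs(rng.normal(0.8, 0.2, cfg.n_genes)), score_b
    )
    chip = pd.DataFrame(
        {
            "region_id": [f"{g}_prom" for g in gene_ids],
            "gene_id": gene_ids,
            "score_B": np.round(score_b, 4),
            "score_Pb": np.round(score_pb, 4),
        }
    )
    mark_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "region_id": [f"{g}_prom" for g in gene_ids],
            "gene_class": gene_class,
            "marked_b": marked,
            "lost_in_pb": lost,
        }
    )

    gene_truth = pd.DataFrame(
        {"gene_id": gene_ids, "gene_class": gene_class, "onset": onset}
    )

    # ---- write everything --------------------------------------------
    paths = {"outdir": outdir}
    paths["genome"] = outdir / "genome.fa"
    _write_fasta(seqs, paths["genome"])
    paths["regions"] = outdir / "regions.bed"
    write_regions(regions, paths["regions"])
    paths["tss"] = outdir / "tss.tsv"
    with open(paths["tss"], "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for t in tss_records:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.tss}\t{t.strand}\n")
    paths["samples"] = outdir / "samples.tsv"
    write_sample_sheet(samples, paths["samples"])
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    paths["expression_counts"] = outdir / "expression_counts.tsv"
    expr_counts.to_csv(paths["expression_counts"], sep="\t")
    paths["expression"] = outdir / "expression.tsv"
    expression.round(4).to_csv(paths["expression"], sep="\t")
    paths["dml"] = outdir / "dml.tsv"
    meth.to_csv(paths["dml"], sep="\t", index=False)
    paths["chip"] = outdir / "chip_scores.tsv"
    chip.to_csv(paths["chip"], sep="\t", index=False)
    paths["pwms"] = outdir / "pwms.txt"
    write_pwms(pwms, paths["pwms"])
    paths["cutsites"] = cutsite_paths
    paths["config"] = outdir / "sim_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)

    dar_truth.to_csv(outdir / "truth" / "dar_regions.tsv", sep="\t", index=False)
    gene_truth.to_csv(outdir / "truth" / "gene_classes.tsv", sep="\t", index=False)
    dml_truth.to_csv(outdir / "truth" / "dml.tsv", sep="\t", index=False)
    motif_truth.to_csv(outdir / "truth" / "motifs.tsv", sep="\t", index=False)
    mark_truth.to_csv(outdir / "truth" / "marks.tsv", sep="\t", index=False)

    return SimResult(
        outdir, paths, dar_truth, gene_truth, dml_truth, motif_truth, mark_truth
    )
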