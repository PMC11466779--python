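"""Coupled synthetic loop/peak/expression/mark datasets with planted truth.

The generator emulates the 2-diagnosis / 2-relapse longitudinal design:

* chromatin loops with log-normal strengths (a per-sample depth factor
  exercises TMM); a planted fraction is differential, one group
  multiplied by 2**loop_effect_log2;
* replicate ATAC peak sets: background peaks present in every sample,
  plus state-specific peaks placed inside the anchors of planted
  differential loops, each appearing in both of its state's replicates
  with probability ``peak_reproducibility`` (otherwise in one);
* negative-binomial gene counts with planted differentially expressed
  genes shifted by 2**de_log2fc in the relapse group;
* a subset of upregulated genes "wired" to diagnosis-specific loops whose
  promoter anchor covers the gene's TSS and whose distal anchor lies
  >= 100 kb away; repressive (H3K27me3-like) marks cover the distal
  anchors of the silencer-loss subset, on top of sparse background marks.

All planted peaks are placed mutually non-overlapping so planted state
labels are unambiguous; an impossible geometry raises a "geometry
overflow" error. Every random draw comes from one seeded generator, so
identical configs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import (
    GenomicInterval,
    Gene,
    GeneAnnotation,
    LoopRecord,
    PeakSet,
    write_bed,
    write_bedpe_loops,
    write_chrom_sizes,
    write_gene_annotation,
)
from .stats import DIAGNOSIS, RELAPSE, CountMatrix, write_count_matrix

__all__ = [
    "SimConfig",
    "TruthTables",
    "SimulatedDataset",
    "default_desk_config",
    "simulate_expression",
    "simulate_dataset",
]

SAMPLES = ("D1", "D2", "R1", "R2")
GROUPS = {
    "D1": DIAGNOSIS,
    "D2": DIAGNOSIS,
    "R1": RELAPSE,
    "R2": RELAPSE,
}


@dataclass
class SimConfig:
    """Synthetic-dataset parameters (defaults = the desk-scale conditions)."""

    n_chrom: int = 2
    chrom_length_bp: int = 10_000_000
    n_loops: int = 20_000
    frac_diff_loops: float = 0.05
    loop_effect_log2: float = 2.0
    loop_noise_sd: float = 0.3  # SD of log2 loop strength within a group
    n_genes: int = 5_000
    n_de_genes: int = 200
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    peak_reproducibility: float = 0.9
    frac_silencer_loss_genes: float = 0.1  # of upregulated planted DE genes
    seed: int = 1337
    # geometry and nuisance structure
    anchor_width: int = 5_000
    peak_width: int = 500
    n_background_peaks: int = 2_000
    mark_background_fraction: float = 0.01
    mark_width: int = 2_000
    n_wired_relapse_up: int = 10
    n_wired_diagnosis_up_extra: int = 5
    n_wired_diagnosis_down: int = 5
    min_loop_distance: int = 100_000
    max_loop_distance: int = 2_000_000
    base_strength_log2_mean: float = 3.3
    base_strength_log2_sd: float = 1.0
    depth_factor_log2_sd: float = 0.25
    base_mean_log: float = math.log(300.0)
    base_mean_sd: float = 1.0
    min_de_mean: float = 30.0
    min_wired_mean: float = 300.0

    def validate(self) -> None:
        fracs = {
            "frac_diff_loops": self.frac_diff_loops,
            "peak_reproducibility": self.peak_reproducibility,
            "frac_silencer_loss_genes": self.frac_silencer_loss_genes,
            "mark_background_fraction": self.mark_background_fraction,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "n_chrom": self.n_chrom,
            "chrom_length_bp": self.chrom_length_bp,
            "n_loops": self.n_loops,
            "n_genes": self.n_genes,
            "anchor_width": self.anchor_width,
            "peak_width": self.peak_width,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be in [0, n_genes]")
        for name in ("loop_effect_log2", "de_log2fc", "loop_noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_loop_distance + 2 * self.anchor_width >= self.chrom_length_bp:
            raise ValueError("chromosomes too short for the loop distance range")


def default_desk_config() -> SimConfig:
    """The desk-scale configuration: runs end-to-end in minutes on one CPU."""
    cfg = SimConfig()
    cfg.validate()
    return cfg


@dataclass
class TruthTables:
    """Planted ground truth for every layer of a simulated dataset."""

    diff_loops: dict[str, str]  # loop_id -> diagnosis|relapse (stronger state)
    state_peaks: dict[str, str]  # peak_id -> state
    peak_reproduced: dict[str, bool]  # peak_id -> present in both replicates
    de_genes: dict[str, int]  # gene_id -> +1 (up in relapse) / -1
    silencer_loss_genes: list[str]
    tri_omic_genes: list[str]  # wired DE genes whose promoter peak reproduced
    wired_genes: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "diff_loops.tsv", "w") as fh:
            fh.write("#loop_id\tstate\n")
            for lid in sorted(self.diff_loops):
                fh.write(f"{lid}\t{self.diff_loops[lid]}\n")
        with open(out / "state_peaks.tsv", "w") as fh:
            fh.write("#peak_id\tstate\treproduced\n")
            for pid in sorted(self.state_peaks):
                fh.write(
                    f"{pid}\t{self.state_peaks[pid]}\t"
                    f"{int(self.peak_reproduced[pid])}\n"
                )
        with open(out / "de_genes.tsv", "w") as fh:
            fh.write("#gene_id\tdirection\n")
            for gid in sorted(self.de_genes):
                fh.write(f"{gid}\t{self.de_genes[gid]:+d}\n")
        (out / "silencer_loss_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(self.silencer_loss_genes))
        )
        (out / "tri_omic_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(self.tri_omic_genes))
        )
        with open(out / "wired_genes.tsv", "w") as fh:
            fh.write("#gene_id\trole\tstate\tloop_id\tpromoter_peak_reproduced\n")
            for gid in sorted(self.wired_genes):
                w = self.wired_genes[gid]
                fh.write(
                    f"{gid}\t{w['role']}\t{w['state']}\t{w['loop_id']}\t"
                    f"{int(w['promoter_peak_reproduced'])}\n"
                )


@dataclass
class SimulatedDataset:
    """In-memory handles to a simulated dataset (plus on-disk layout)."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    loop_records: dict[str, list[LoopRecord]]
    peak_sets: dict[str, PeakSet]
    counts: CountMatrix
    annotation: GeneAnnotation
    marks: PeakSet
    truth: TruthTables
    groups: dict[str, str] = field(default_factory=lambda: dict(GROUPS))

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        for sub in ("loops", "peaks", "expression", "annotation", "marks", "truth"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.chrom_sizes, out / "chrom_sizes.tsv")
        for s in SAMPLES:
            write_bedpe_loops(self.loop_records[s], out / "loops" / f"{s}.bedpe")
            write_bed(self.peak_sets[s], out / "peaks" / f"{s}.bed")
        write_count_matrix(self.counts, out / "expression" / "counts.tsv")
        write_gene_annotation(self.annotation, out / "annotation" / "genes.bed")
        write_bed(self.marks, out / "marks" / "h3k27me3.bed")
        self.truth.write(out / "truth")
        return out


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator):
    """Negative-binomial draws with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean))


def simulate_expression(
    n_genes: int = 10_000,
    n_de: int = 200,
    de_log2fc: float = 2.0,
    nb_dispersion: float = 0.1,
    seed: int = 21,
    base_mean_log: float = math.log(300.0),
    base_mean_sd: float = 1.0,
    min_de_mean: float = 30.0,
    depth_log2_sd: float = 0.15,
) -> tuple[CountMatrix, dict[str, int]]:
    """Standalone NB expression table for a 2v2 design with planted DE.

    Returns the CountMatrix and a gene_id -> direction (+1/-1) truth map.
    DE genes are drawn from genes with baseline mean >= min_de_mean so
    the planted fold change is identifiable.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    mu = np.exp(rng.normal(base_mean_log, base_mean_sd, size=n_genes))
    eligible = np.nonzero(mu >= min_de_mean)[0]
    if eligible.size < n_de:
        raise ValueError("not enough sufficiently expressed genes to plant DE")
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    direction = np.zeros(n_genes, dtype=int)
    n_up = n_de - n_de // 2
    direction[de_idx[:n_up]] = 1
    direction[de_idx[n_up:]] = -1
    sf = 2.0 ** rng.normal(0.0, depth_log2_sd, size=4)
    relapse = np.array([0, 0, 1, 1])
    mean = (
        mu[:, None]
        * sf[None, :]
        * 2.0 ** (de_log2fc * direction[:, None] * relapse[None, :])
    )
    values = _nb_counts(mean, nb_dispersion, rng).astype(float)
    cm = CountMatrix(gene_ids, list(SAMPLES), values, [GROUPS[s] for s in SAMPLES])
    truth = {gene_ids[i]: int(direction[i]) for i in de_idx}
    return cm, truth


class _PeakPlacer:
    """Rejection-samples non-overlapping planted peak positions."""

    def __init__(self) -> None:
        self._placed: dict[str, list[tuple[int, int]]] = {}

    def _collides(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and e > start for s, e in self._placed.get(chrom, []))

    def place_in(
        self,
        region: GenomicInterval,
        width: int,
        rng: np.random.Generator,
        tries: int = 200,
    ) -> GenomicInterval | None:
        lo, hi = region.start, region.end - width
        if hi < lo:
            return None
        for _ in range(tries):
            start = int(rng.integers(lo, hi + 1))
            if not self._collides(region.chrom, start, start + width):
                self._placed.setdefault(region.chrom, []).append(
                    (start, start + width)
                )
                return GenomicInterval(region.chrom, start, start + width)
        return None


def simulate_dataset(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate the full coupled dataset (and write it when out_dir given)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length_bp
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    chrom_sizes = {c: L for c in chroms}

    # ---- genes ------------------------------------------------------------
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1
    genes: list[Gene] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n = per_chrom[ci]
        slot = L // n
        if slot < 1_200:
            raise ValueError("geometry overflow: too many genes per chromosome")
        for k in range(n):
            length = int(rng.integers(1_000, min(3_000, slot - 100) + 1))
            offset = int(rng.integers(0, slot - length))
            start = k * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                Gene(
                    f"G{gi:05d}",
                    f"SYN{gi}",
                    GenomicInterval(chrom, start, start + length),
                    strand,
                )
            )
    ann = GeneAnnotation(genes)

    # ---- expression means and DE assignment -------------------------------
    mu = np.exp(rng.normal(cfg.base_mean_log, cfg.base_mean_sd, size=cfg.n_genes))
    eligible = np.nonzero(mu >= cfg.min_de_mean)[0]
    if eligible.size < cfg.n_de_genes:
        raise ValueError("not enough sufficiently expressed genes to plant DE")
    de_idx = rng.choice(eligible, size=cfg.n_de_genes, replace=False)
    n_up = cfg.n_de_genes - cfg.n_de_genes // 2
    up_idx = list(de_idx[:n_up])
    down_idx = list(de_idx[n_up:])
    direction = np.zeros(cfg.n_genes, dtype=int)
    direction[up_idx] = 1
    direction[down_idx] = -1

    # wired genes can never outnumber the planted differential loops
    n_diff = round(cfg.frac_diff_loops * cfg.n_loops)
    budget = n_diff
    n_sil = min(round(cfg.frac_silencer_loss_genes * len(up_idx)), budget)
    budget -= n_sil
    n_diag_up = min(cfg.n_wired_diagnosis_up_extra, budget)
    budget -= n_diag_up
    n_rel_up = min(cfg.n_wired_relapse_up, budget)
    budget -= n_rel_up
    n_diag_down = min(cfg.n_wired_diagnosis_down, budget, len(down_idx))
    n_up_wired = n_sil + n_diag_up + n_rel_up
    if n_up_wired > len(up_idx):
        raise ValueError("more wired genes requested than planted DE genes")

    def _pick_wired(idx_pool: list[int], n: int) -> list[int]:
        strong = [i for i in idx_pool if mu[i] >= cfg.min_wired_mean]
        if len(strong) < n:
            strong = sorted(idx_pool, key=lambda i: -mu[i])[:n]
        chosen = rng.choice(len(strong), size=n, replace=False)
        return [strong[int(c)] for c in chosen]

    wired_up = _pick_wired(up_idx, n_up_wired) if n_up_wired else []
    silencer_idx = wired_up[:n_sil]
    diag_up_idx = wired_up[n_sil : n_sil + n_diag_up]
    relapse_up_idx = wired_up[n_sil + n_diag_up :]
    diag_down_idx = _pick_wired(down_idx, n_diag_down) if n_diag_down else []

    wired_roles: list[tuple[int, str, str]] = (  # (gene index, role, loop state)
        [(i, "silencer_loss", DIAGNOSIS) for i in silencer_idx]
        + [(i, "diagnosis_up", DIAGNOSIS) for i in diag_up_idx]
        + [(i, "relapse_up", RELAPSE) for i in relapse_up_idx]
        + [(i, "diagnosis_down", DIAGNOSIS) for i in diag_down_idx]
    )

    # ---- loops ------------------------------------------------------------
    aw = cfg.anchor_width

    def _clip_anchor(chrom: str, center: int) -> GenomicInterval:
        start = int(np.clip(center - aw // 2, 0, L - aw))
        return GenomicInterval(chrom, start, start + aw)

    def _random_distal(chrom: str, promoter: GenomicInterval) -> GenomicInterval:
        for _ in range(200):
            dist = int(rng.integers(cfg.min_loop_distance, cfg.max_loop_distance + 1))
            sign = -1 if rng.random() < 0.5 else 1
            center = (promoter.start + promoter.end) // 2 + sign * dist
            if aw // 2 <= center <= L - aw // 2:
                return _clip_anchor(chrom, center)
        raise ValueError("geometry overflow: cannot place a distal anchor")

    loop_pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    loop_state: list[str | None] = []  # stronger state or None
    wired_loop_of_gene: dict[int, int] = {}  # gene index -> loop list index
    for gidx, _role, state in wired_roles:
        g = genes[gidx]
        promoter = _clip_anchor(g.body.chrom, g.tss)
        distal = _random_distal(g.body.chrom, promoter)
        wired_loop_of_gene[gidx] = len(loop_pairs)
        loop_pairs.append((promoter, distal))
        loop_state.append(state)

    n_random_loops = cfg.n_loops - len(wired_roles)
    n_random_diff = n_diff - len(wired_roles)
    for k in range(n_random_loops):
        chrom = chroms[int(rng.integers(0, cfg.n_chrom))]
        a_center = int(rng.integers(aw // 2, L - aw // 2 + 1))
        a = _clip_anchor(chrom, a_center)
        b = _random_distal(chrom, a)
        loop_pairs.append((a, b))
        if k < n_random_diff:
            loop_state.append(DIAGNOSIS if rng.random() < 0.5 else RELAPSE)
        else:
            loop_state.append(None)

    # assign ids in genomic order for deterministic, readable output
    order = sorted(
        range(len(loop_pairs)),
        key=lambda i: (
            min(loop_pairs[i][0].key(), loop_pairs[i][1].key()),
            max(loop_pairs[i][0].key(), loop_pairs[i][1].key()),
        ),
    )
    loop_id_of = {i: f"L{rank + 1:06d}" for rank, i in enumerate(order)}

    base = rng.normal(
        cfg.base_strength_log2_mean, cfg.base_strength_log2_sd, size=len(loop_pairs)
    )
    depth = rng.normal(0.0, cfg.depth_factor_log2_sd, size=len(SAMPLES))
    noise = rng.normal(0.0, cfg.loop_noise_sd, size=(len(loop_pairs), len(SAMPLES)))
    is_diag_sample = np.array([GROUPS[s] == DIAGNOSIS for s in SAMPLES])
    effect = np.zeros((len(loop_pairs), len(SAMPLES)))
    for i, state in enumerate(loop_state):
        if state == DIAGNOSIS:
            effect[i, is_diag_sample] = cfg.loop_effect_log2
        elif state == RELAPSE:
            effect[i, ~is_diag_sample] = cfg.loop_effect_log2
    log2_strength = base[:, None] + noise + effect + depth[None, :]
    strength = 2.0**log2_strength

    loop_records = {
        s: [
            LoopRecord(
                loop_pairs[i][0],
                loop_pairs[i][1],
                loop_id_of[i],
                float(strength[i, j]),
            )
            for i in order
        ]
        for j, s in enumerate(SAMPLES)
    }

    # ---- peaks ------------------------------------------------------------
    placer = _PeakPlacer()
    planted: list[tuple[str, GenomicInterval, str]] = []  # (peak_id, iv, state)
    promoter_peak_of_gene: dict[int, str] = {}
    pk = 0

    def _plant(region: GenomicInterval, state: str, required: bool) -> str | None:
        nonlocal pk
        iv = placer.place_in(region, cfg.peak_width, rng)
        if iv is None:
            if required:
                raise ValueError("geometry overflow: cannot place a planted peak")
            return None
        pk += 1
        pid = f"PK{pk:05d}"
        planted.append((pid, GenomicInterval(iv.chrom, iv.start, iv.end, pid), state))
        return pid

    for gidx, _role, state in wired_roles:
        promoter, distal = loop_pairs[wired_loop_of_gene[gidx]]
        promoter_peak_of_gene[gidx] = _plant(promoter, state, required=True)
        _plant(distal, state, required=True)
    for i, state in enumerate(loop_state):
        if state is None or i < len(wired_roles):
            continue
        anchor = loop_pairs[i][int(rng.integers(0, 2))]
        _plant(anchor, state, required=False)

    background: list[GenomicInterval] = []
    for k in range(cfg.n_background_peaks):
        chrom = chroms[int(rng.integers(0, cfg.n_chrom))]
        iv = placer.place_in(
            GenomicInterval(chrom, 0, L), cfg.peak_width, rng, tries=50
        )
        if iv is None:
            raise ValueError("geometry overflow: cannot place background peaks")
        pk += 1
        background.append(GenomicInterval(iv.chrom, iv.start, iv.end, f"BG{pk:05d}"))

    state_peaks: dict[str, str] = {}
    peak_reproduced: dict[str, bool] = {}
    per_sample: dict[str, list[GenomicInterval]] = {s: list(background) for s in SAMPLES}
    replicate_of_state = {
        DIAGNOSIS: ("D1", "D2"),
        RELAPSE: ("R1", "R2"),
    }
    for pid, iv, state in planted:
        state_peaks[pid] = state
        reps = replicate_of_state[state]
        both = rng.random() < cfg.peak_reproducibility
        peak_reproduced[pid] = bool(both)
        if both:
            targets = reps
        else:
            targets = (reps[int(rng.integers(0, 2))],)
        for s in targets:
            per_sample[s].append(iv)
    peak_sets = {s: PeakSet(s, per_sample[s]) for s in SAMPLES}

    # ---- expression counts ------------------------------------------------
    sf = 2.0 ** rng.normal(0.0, 0.15, size=len(SAMPLES))
    relapse_ind = (~is_diag_sample).astype(float)
    mean = (
        mu[:, None]
        * sf[None, :]
        * 2.0 ** (cfg.de_log2fc * direction[:, None] * relapse_ind[None, :])
    )
    values = _nb_counts(mean, cfg.nb_dispersion, rng).astype(float)
    counts = CountMatrix(
        [g.gene_id for g in genes],
        list(SAMPLES),
        values,
        [GROUPS[s] for s in SAMPLES],
    )

    # ---- repressive marks ---------------------------------------------------
    mark_ivs: list[GenomicInterval] = []
    for gidx in silencer_idx:
        _, distal = loop_pairs[wired_loop_of_gene[gidx]]
        mark_ivs.append(GenomicInterval(distal.chrom, distal.start, distal.end))
    total = cfg.n_chrom * L
    n_bg_marks = int(cfg.mark_background_fraction * total / cfg.mark_width)
    for _ in range(n_bg_marks):
        chrom = chroms[int(rng.integers(0, cfg.n_chrom))]
        start = int(rng.integers(0, L - cfg.mark_width + 1))
        mark_ivs.append(GenomicInterval(chrom, start, start + cfg.mark_width))
    marks = PeakSet("h3k27me3", mark_ivs)

    # ---- truth ------------------------------------------------------------
    diff_loops = {
        loop_id_of[i]: state
        for i, state in enumerate(loop_state)
        if state is not None
    }
    de_genes = {
        genes[i].gene_id: int(direction[i]) for i in de_idx
    }
    silencer_ids = [genes[i].gene_id for i in silencer_idx]
    wired_meta: dict[str, dict] = {}
    tri_omic: list[str] = []
    for gidx, role, state in wired_roles:
        gid = genes[gidx].gene_id
        promoter_pid = promoter_peak_of_gene[gidx]
        reproduced = peak_reproduced[promoter_pid]
        wired_meta[gid] = {
            "role": role,
            "state": state,
            "loop_id": loop_id_of[wired_loop_of_gene[gidx]],
            "promoter_peak_reproduced": reproduced,
        }
        if reproduced:
            tri_omic.append(gid)
    truth = TruthTables(
        diff_loops=diff_loops,
        state_peaks=state_peaks,
        peak_reproduced=peak_reproduced,
        de_genes=de_genes,
        silencer_loss_genes=sorted(silencer_ids),
        tri_omic_genes=sorted(tri_omic),
        wired_genes=wired_meta,
    )

    ds = SimulatedDataset(
        config=cfg,
        chrom_sizes=chrom_sizes,
        loop_records=loop_records,
        peak_sets=peak_sets,
        counts=counts,
        annotation=ann,
        marks=marks,
        truth=truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds
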