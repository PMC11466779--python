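"""End-to-end orchestration: simulate -> loops -> peaks -> expression -> integrate.

A RunConfig (YAML file or keyword arguments) either points at on-disk
inputs or asks for a simulated dataset; `run_all` executes the stages in
dependency order, writes each stage's outputs under the output
directory, logs parameters and input digests to run.log (the only file
that carries timestamps), and returns the integration report.
Re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import expression as expr_mod
from . import integration as integ
from .intervals import (
    read_bed,
    read_chrom_sizes,
    read_gene_annotation,
    write_bed,
)
from .loops import (
    build_loop_matrix,
    build_loop_matrix_from_files,
    call_differential_loops,
    state_anchors,
)
from .peaks import derive_states
from .simulate import SimConfig, simulate_dataset
from .stats import DIAGNOSIS, RELAPSE, read_count_matrix

__all__ = ["RunConfig", "run_all", "child_seed"]

log = logging.getLogger("chromalink")


def child_seed(master: int, stream: int) -> int:
    """Independent (< 2**31) substream seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Inputs and parameters for a full pipeline run."""

    out_dir: str
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    loop_files: list[str] = field(default_factory=list)
    loop_groups: list[str] = field(default_factory=list)
    peak_files: dict = field(default_factory=dict)  # d1/d2/r1/r2 -> path
    counts: str | None = None
    counts_groups: list[str] | None = None
    annotation: str | None = None
    marks: str | None = None
    chrom_sizes: str | None = None
    n_top: int = 100_000
    alpha: float = 0.1
    lfc: float = 1.0
    window: int = 20_000
    n_random: int = 10
    n_perm: int = 10_000
    seed: int = 1337
    de_weights: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            required = {
                "loop_files": self.loop_files,
                "peak_files": self.peak_files,
                "counts": self.counts,
                "annotation": self.annotation,
                "marks": self.marks,
                "chrom_sizes": self.chrom_sizes,
            }
            for name, value in required.items():
                if not value:
                    raise ValueError(f"config missing {name} (or set simulate: true)")
            if len(self.loop_files) != len(self.loop_groups):
                raise ValueError("loop_files and loop_groups differ in length")
            for key in ("d1", "d2", "r1", "r2"):
                if key not in self.peak_files:
                    raise ValueError(f"peak_files missing replicate {key!r}")
            paths = (
                list(self.loop_files)
                + list(self.peak_files.values())
                + [self.counts, self.annotation, self.marks, self.chrom_sizes]
            )
            missing = [p for p in paths if not Path(p).exists()]
            if missing:
                raise ValueError(f"input path(s) do not exist: {missing}")
        for name in ("n_top", "n_random", "n_perm", "window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the integration report."""
    cfg.validate()  # pre-flight: fail before any stage output is written
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    t0 = time.time()
    try:
        # ---- inputs ------------------------------------------------------
        if cfg.simulate:
            sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim_overrides})
            log.info("stage=simulate params=%s", sim_cfg)
            ds = simulate_dataset(sim_cfg, out / "simulated")
            lm = build_loop_matrix(ds.loop_records, ds.groups)
            peaks_in = [ds.peak_sets[s] for s in ("D1", "D2", "R1", "R2")]
            counts = ds.counts
            ann = ds.annotation
            marks = ds.marks
            chrom_sizes = ds.chrom_sizes
        else:
            for p in cfg.loop_files + list(cfg.peak_files.values()):
                log.info("input=%s sha256=%s", p, _digest(p))
            lm = build_loop_matrix_from_files(cfg.loop_files, cfg.loop_groups)
            peaks_in = [
                read_bed(cfg.peak_files[k]) for k in ("d1", "d2", "r1", "r2")
            ]
            counts = read_count_matrix(cfg.counts, cfg.counts_groups)
            ann = read_gene_annotation(cfg.annotation)
            marks = read_bed(cfg.marks, "marks")
            chrom_sizes = read_chrom_sizes(cfg.chrom_sizes)

        # ---- differential loops -----------------------------------------
        log.info("stage=diffloops n_top=%d alpha=%g", cfg.n_top, cfg.alpha)
        dl = call_differential_loops(lm, n_top=cfg.n_top, alpha=cfg.alpha)
        loops_out = out / "loops"
        loops_out.mkdir(exist_ok=True)
        with open(loops_out / "results.tsv", "w") as fh:
            fh.write("#" + "\t".join(dl.results.columns) + "\n")
            dl.results.to_csv(fh, sep="\t", header=False, index=False)
        anchors_by_state = {
            state: state_anchors(dl, state) for state in (DIAGNOSIS, RELAPSE)
        }
        write_bed(anchors_by_state[DIAGNOSIS], loops_out / "diagnosis_anchors.bed")
        write_bed(anchors_by_state[RELAPSE], loops_out / "relapse_anchors.bed")

        # ---- peak states -------------------------------------------------
        log.info("stage=peakstates")
        sp = derive_states(*peaks_in)
        sp.write(out / "peaks")

        # ---- differential expression ------------------------------------
        log.info("stage=diffexpr alpha=%g lfc=%g", cfg.alpha, cfg.lfc)
        de = expr_mod.differential_expression(
            counts, alpha=cfg.alpha, lfc=cfg.lfc, weights=cfg.de_weights
        )
        de.write(out / "expression")

        # ---- integration -------------------------------------------------
        log.info(
            "stage=integrate window=%d n_random=%d n_perm=%d seed=%d",
            cfg.window,
            cfg.n_random,
            cfg.n_perm,
            cfg.seed,
        )
        state_peak_sets = {
            DIAGNOSIS: sp.diagnosis_specific,
            RELAPSE: sp.relapse_specific,
        }
        state_loop_ids = {
            DIAGNOSIS: dl.diagnosis_specific,
            RELAPSE: dl.relapse_specific,
        }
        records_by_state = {}
        enrichment_by_state = {}
        for k, state in enumerate((DIAGNOSIS, RELAPSE)):
            records = integ.integration_records(
                dl.anchors,
                state_loop_ids[state],
                state_peak_sets[state],
                ann,
                de,
                state,
                marks=marks,
                window=cfg.window,
            )
            records_by_state[state] = records
            linked_up = sorted(
                {r.gene_id for r in records} & set(de.upregulated)
            )
            if linked_up and cfg.n_random > 0:
                enrichment_by_state[state] = integ.de_enrichment(
                    linked_up,
                    de,
                    de.universe,
                    n_random=cfg.n_random,
                    seed=child_seed(cfg.seed, k),
                )
            else:
                enrichment_by_state[state] = None

        candidates = [
            r
            for r in records_by_state[DIAGNOSIS]
            if r.gene_id in set(de.upregulated)
        ]
        silencer = None
        if candidates and len(marks) > 0 and cfg.n_perm > 0:
            silencer = integ.silencer_loss_test(
                candidates,
                marks,
                chrom_sizes,
                n_perm=cfg.n_perm,
                seed=child_seed(cfg.seed, 2),
            )

        params = {
            "n_top": cfg.n_top,
            "alpha": cfg.alpha,
            "lfc": cfg.lfc,
            "window": cfg.window,
            "n_random": cfg.n_random,
            "n_perm": cfg.n_perm,
            "seed": cfg.seed,
            "simulate": cfg.simulate,
        }
        report = integ.build_report(
            diff_loops=dl,
            state_peaks=sp,
            de=de,
            records_by_state=records_by_state,
            enrichment_by_state=enrichment_by_state,
            silencer=silencer,
            parameters=params,
        )
        integ.write_report(report, out)
        log.info("done in %.1fs", time.time() - t0)
        return report
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
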