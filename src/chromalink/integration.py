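"""Multi-omic integration of loops, open chromatin and expression.

The chain: state-specific loop anchors are intersected with state-specific
ATAC peaks ("accessible anchors"); genes within a 20 kb window of an
accessible anchor are linked to it; the other end of the loop becomes the
gene's distal anchor, a candidate enhancer or silencer. Linked
differentially expressed genes are scored against random size-matched
gene sets, and the "silencer-loss" hypothesis — upregulated genes whose
diagnosis-specific distal anchors sit in H3K27me3-marked chromatin more
often than chance — is tested with a width- and chromosome-matched
uniform permutation null and the add-one p-value estimator
(k + 1) / (n_perm + 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expression import DEtable
from .intervals import (
    GenomicInterval,
    GeneAnnotation,
    MarkIndex,
    PeakSet,
    check_shared_chromosomes,
    overlap_pairs,
)
from .stats import DIAGNOSIS, RELAPSE

__all__ = [
    "AccessibleAnchor",
    "IntegrationRecord",
    "EnrichmentResult",
    "PermutationTest",
    "accessible_anchors",
    "assign_genes",
    "integration_records",
    "de_enrichment",
    "silencer_loss_test",
    "truncate_sig",
    "build_report",
]


@dataclass(frozen=True)
class AccessibleAnchor:
    """A state-specific loop anchor overlapped by >=1 state-specific peak."""

    anchor: GenomicInterval
    peak_ids: tuple[str, ...]


@dataclass
class IntegrationRecord:
    """One gene <-> loop linkage through an accessible anchor."""

    gene_id: str
    state: str
    loop_id: str
    promoter_anchor: GenomicInterval
    distal_anchor: GenomicInterval
    peak_ids: tuple[str, ...]
    log_fc: float
    repressive_overlap: bool = False

    def __post_init__(self) -> None:
        if self.state not in (DIAGNOSIS, RELAPSE):
            raise ValueError(f"unknown state {self.state!r}")
        if self.promoter_anchor == self.distal_anchor:
            raise ValueError(
                f"gene {self.gene_id}: promoter and distal anchors coincide"
            )


def accessible_anchors(
    anchors: Sequence[GenomicInterval], peaks: PeakSet
) -> list[AccessibleAnchor]:
    """Anchors with at least one overlapping peak, carrying the peak ids.

    Peak ids fall back to coordinates when the BED had no name column.
    """
    check_shared_chromosomes(anchors, peaks.intervals, context="anchors vs peaks")
    pairs = overlap_pairs(anchors, peaks.intervals)
    by_anchor: dict[int, list[str]] = {}
    for i, j in pairs:
        peak = peaks.intervals[j]
        pid = peak.name if peak.name is not None else str(peak)
        by_anchor.setdefault(i, []).append(pid)
    return [
        AccessibleAnchor(anchors[i], tuple(sorted(set(ids))))
        for i, ids in sorted(by_anchor.items())
    ]


def assign_genes(
    regions: Sequence[GenomicInterval],
    ann: GeneAnnotation,
    window: int = 20_000,
) -> list[tuple[str, int]]:
    """(gene_id, region index) links where the region extended by
    ``window`` on both sides overlaps the gene body by >= 1 bp."""
    if window < 0:
        raise ValueError("window must be >= 0")
    extended = [
        GenomicInterval(r.chrom, max(0, r.start - window), r.end + window)
        for r in regions
    ]
    bodies = [g.body for g in ann.genes]
    links = {
        (ann.genes[j].gene_id, i)
        for i, j in overlap_pairs(extended, bodies)
    }
    return sorted(links)


def _gene_anchor_distance(gene_body: GenomicInterval, anchor: GenomicInterval) -> int:
    if anchor.overlap_width(gene_body) > 0:
        return 0
    if anchor.chrom != gene_body.chrom:
        return 2**62
    return max(gene_body.start - anchor.end, anchor.start - gene_body.end) + 1


def integration_records(
    loops: Mapping[str, tuple[GenomicInterval, GenomicInterval]],
    loop_ids: Iterable[str],
    peaks: PeakSet,
    ann: GeneAnnotation,
    de: DEtable,
    state: str,
    marks: PeakSet | None = None,
    window: int = 20_000,
) -> list[IntegrationRecord]:
    """Link genes to one state's significant loops through accessible anchors.

    For each significant loop of the state, its anchors that carry a
    state-specific peak are gene-assigned within ``window``; the linked
    anchor is the gene's promoter anchor and the loop's other end its
    distal anchor (when both anchors link the same gene, the farther one
    is distal). The record carries the gene's log2 fold change (NaN when
    the gene was filtered from the DE universe) and, when ``marks`` is
    given, whether the distal anchor overlaps a repressive-mark interval.
    """
    loop_ids = list(loop_ids)
    # unique anchors of the state's loops
    anchor_by_key: dict[tuple[str, int, int], GenomicInterval] = {}
    for lid in loop_ids:
        for a in loops[lid]:
            anchor_by_key.setdefault(a.key(), a)
    uniq = [anchor_by_key[k] for k in sorted(anchor_by_key)]
    acc = accessible_anchors(uniq, peaks)
    acc_by_key = {a.anchor.key(): a for a in acc}
    links = assign_genes([a.anchor for a in acc], ann, window=window)

    lfc = de.results.set_index("feature_id")["log_fc"]
    mark_idx = MarkIndex(marks.intervals) if marks is not None else None

    # anchor key -> loops touching it
    loops_of_anchor: dict[tuple[str, int, int], list[str]] = {}
    for lid in loop_ids:
        a, b = loops[lid]
        loops_of_anchor.setdefault(a.key(), []).append(lid)
        if b.key() != a.key():
            loops_of_anchor.setdefault(b.key(), []).append(lid)

    records: list[IntegrationRecord] = []
    seen: set[tuple[str, str]] = set()
    for gene_id, i in links:
        acc_anchor = acc[i]
        gene_body = ann[gene_id].body
        for lid in loops_of_anchor[acc_anchor.anchor.key()]:
            a, b = loops[lid]
            if a == b:
                continue
            if acc_anchor.anchor == a:
                promoter, distal = a, b
            else:
                promoter, distal = b, a
            # when both anchors link the gene, the farther one is distal
            dist_p = _gene_anchor_distance(gene_body, promoter)
            dist_d = _gene_anchor_distance(gene_body, distal)
            if dist_d <= window and dist_d < dist_p:
                promoter, distal = distal, promoter
            key = (gene_id, lid)
            if key in seen:
                continue
            seen.add(key)
            rep = (
                mark_idx.overlaps(distal.chrom, distal.start, distal.end)
                if mark_idx is not None
                else False
            )
            records.append(
                IntegrationRecord(
                    gene_id=gene_id,
                    state=state,
                    loop_id=lid,
                    promoter_anchor=promoter,
                    distal_anchor=distal,
                    peak_ids=(
                        acc_by_key[promoter.key()].peak_ids
                        if promoter.key() in acc_by_key
                        else acc_anchor.peak_ids
                    ),
                    log_fc=float(lfc.get(gene_id, math.nan)),
                    repressive_overlap=rep,
                )
            )
    records.sort(key=lambda r: (r.gene_id, r.loop_id))
    return records


@dataclass
class EnrichmentResult:
    """Observed summary statistic vs random size-matched gene sets."""

    observed_stat: float
    null_stats: np.ndarray
    n_random: int
    p_empirical: float
    seed: int
    statistic: str = "median"


def de_enrichment(
    linked_genes: Iterable[str],
    de: DEtable,
    universe: Iterable[str],
    n_random: int = 10,
    seed: int = 1337,
    statistic: str = "median",
) -> EnrichmentResult:
    """Log-fold-change enrichment of a linked gene set vs random sets.

    The observed statistic (median by default; "mean" optional) of the
    linked genes' log2 fold changes is compared with ``n_random`` simple
    random samples, of the same size, drawn without replacement from
    ``universe`` minus the linked set; ties count as exceedances and the
    add-one rule gives p = (#null >= observed + 1) / (n_random + 1).
    """
    linked = sorted(set(linked_genes))
    universe = sorted(set(universe))
    if not linked:
        raise ValueError("linked gene set is empty")
    if not set(linked) <= set(universe):
        raise ValueError("linked genes must be a subset of the universe")
    pool = [g for g in universe if g not in set(linked)]
    if len(pool) < len(linked):
        raise ValueError(
            f"universe minus linked genes ({len(pool)}) smaller than the "
            f"linked set ({len(linked)})"
        )
    stat_fn = {"median": np.median, "mean": np.mean}[statistic]
    observed = float(stat_fn(de.log_fc_of(linked)))
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_random)
    for k in range(n_random):
        sample = rng.choice(len(pool), size=len(linked), replace=False)
        null_stats[k] = stat_fn(de.log_fc_of([pool[i] for i in sample]))
    p = (int(np.sum(null_stats >= observed)) + 1) / (n_random + 1)
    return EnrichmentResult(observed, null_stats, n_random, p, seed, statistic)


@dataclass
class PermutationTest:
    """Permutation test of repressive-mark overlap at distal anchors."""

    observed_prop: float
    n_perm: int
    k_exceed: int
    p_value: float
    seed: int
    n_candidates: int
    genes_with_overlap: list[str] = field(default_factory=list)


def silencer_loss_test(
    candidates: Sequence[IntegrationRecord],
    marks: PeakSet,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 1337,
) -> PermutationTest:
    """Are candidate genes' distal anchors in repressive chromatin more
    often than chance?

    The observed statistic is the fraction of candidate genes with >= 1
    distal anchor overlapping a mark interval. Each permutation replaces
    every distal anchor with an interval of identical width placed
    uniformly on the same chromosome and recomputes the fraction; ties
    count as exceedances and p = (k_exceed + 1) / (n_perm + 1).
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    if len(marks) == 0:
        raise ValueError("repressive-mark set is empty")
    check_shared_chromosomes(
        [c.distal_anchor for c in candidates],
        marks.intervals,
        context="distal anchors vs marks",
    )
    genes = sorted({c.gene_id for c in candidates})
    gene_pos = {g: i for i, g in enumerate(genes)}
    # dedup distal anchors per gene
    per_gene_anchors: dict[str, dict[tuple[str, int, int], GenomicInterval]] = {}
    for c in candidates:
        per_gene_anchors.setdefault(c.gene_id, {}).setdefault(
            c.distal_anchor.key(), c.distal_anchor
        )
    flat: list[tuple[int, GenomicInterval]] = []
    for g, d in per_gene_anchors.items():
        for k in sorted(d):
            flat.append((gene_pos[g], d[k]))

    idx = MarkIndex(marks.intervals)
    observed_gene = np.zeros(len(genes), dtype=bool)
    for gi, anchor in flat:
        if idx.overlaps(anchor.chrom, anchor.start, anchor.end):
            observed_gene[gi] = True
    observed_prop = float(observed_gene.mean())

    rng = np.random.default_rng(seed)
    hit = np.zeros((len(genes), n_perm), dtype=bool)
    for gi, anchor in flat:
        length = chrom_sizes.get(anchor.chrom)
        if length is None:
            raise ValueError(f"no chromosome length for {anchor.chrom!r}")
        w = anchor.width
        if length < w:
            raise ValueError(
                f"chromosome {anchor.chrom} ({length} bp) shorter than "
                f"anchor width {w}"
            )
        starts = rng.integers(0, length - w + 1, size=n_perm)
        row = np.fromiter(
            (idx.overlaps(anchor.chrom, int(s), int(s) + w) for s in starts),
            dtype=bool,
            count=n_perm,
        )
        hit[gi] |= row
    props = hit.mean(axis=0)
    k_exceed = int(np.sum(props >= observed_prop))
    p_value = (k_exceed + 1) / (n_perm + 1)
    genes_with_overlap = [g for g, flag in zip(genes, observed_gene) if flag]
    return PermutationTest(
        observed_prop=observed_prop,
        n_perm=n_perm,
        k_exceed=k_exceed,
        p_value=p_value,
        seed=seed,
        n_candidates=len(genes),
        genes_with_overlap=genes_with_overlap,
    )


def truncate_sig(x: float, digits: int = 3) -> float:
    """Truncate (toward zero) to ``digits`` significant figures.

    The convention behind reporting an add-one permutation p-value of
    1/10001 as 9.99e-5.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (digits - 1 - exp)
    return math.trunc(x * factor) / factor


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _enrichment_dict(e: EnrichmentResult | None) -> dict | None:
    if e is None:
        return None
    return {
        "observed_stat": e.observed_stat,
        "null_stats": [float(v) for v in e.null_stats],
        "n_random": e.n_random,
        "p_empirical": e.p_empirical,
        "seed": e.seed,
        "statistic": e.statistic,
    }


def build_report(
    diff_loops=None,
    state_peaks=None,
    de: DEtable | None = None,
    records_by_state: Mapping[str, Sequence[IntegrationRecord]] | None = None,
    enrichment_by_state: Mapping[str, EnrichmentResult | None] | None = None,
    silencer: PermutationTest | None = None,
    parameters: Mapping | None = None,
    allow_missing: bool = False,
) -> dict:
    """Assemble the end-to-end JSON-serializable integration report.

    With ``allow_missing`` False (the default) every stage must be
    provided; the error names the first missing stage. Tri-omic genes
    are those significant in expression that are also linked, through a
    state-specific accessible anchor, to a state-specific loop.
    """
    stages = {
        "diff_loops": diff_loops,
        "state_peaks": state_peaks,
        "differential_expression": de,
        "integration_records": records_by_state,
    }
    if not allow_missing:
        for name, value in stages.items():
            if value is None:
                raise ValueError(f"missing stage output: {name}")

    report: dict = {"schema_version": "1.0", "parameters": dict(parameters or {})}

    if diff_loops is not None:
        report["loops"] = {
            "n_tested": int(len(diff_loops.results)),
            "n_significant": diff_loops.n_significant,
            "n_diagnosis_specific": len(diff_loops.diagnosis_specific),
            "n_relapse_specific": len(diff_loops.relapse_specific),
            "alpha": diff_loops.alpha,
        }
    if state_peaks is not None:
        report["peaks"] = state_peaks.counts()
    if de is not None:
        report["expression"] = {
            "n_tested": int(len(de.results)),
            "n_significant": de.n_significant,
            "n_upregulated": len(de.upregulated),
            "n_downregulated": len(de.downregulated),
            "alpha": de.alpha,
            "lfc_cutoff": de.lfc,
        }

    tri_omic: list[str] = []
    if records_by_state is not None:
        integration: dict = {}
        sig_genes = (
            set(de.upregulated) | set(de.downregulated) if de is not None else set()
        )
        for state in sorted(records_by_state):
            recs = list(records_by_state[state])
            genes = sorted({r.gene_id for r in recs})
            de_genes = sorted(set(genes) & sig_genes)
            tri_omic.extend(de_genes)
            entry = {
                "n_records": len(recs),
                "n_accessible_anchors": len(
                    {r.promoter_anchor.key() for r in recs}
                ),
                "n_linked_genes": len(genes),
                "linked_genes": genes,
                "de_linked_genes": de_genes,
            }
            if enrichment_by_state is not None:
                entry["enrichment"] = _enrichment_dict(
                    enrichment_by_state.get(state)
                )
            integration[state] = entry
        report["integration"] = integration
        report["tri_omic_genes"] = sorted(set(tri_omic))

    if silencer is not None:
        report["silencer_loss"] = {
            "n_candidate_genes": silencer.n_candidates,
            "observed_prop": silencer.observed_prop,
            "n_perm": silencer.n_perm,
            "k_exceed": silencer.k_exceed,
            "p_value": silencer.p_value,
            "p_value_3sig": truncate_sig(silencer.p_value, 3),
            "seed": silencer.seed,
            "genes_with_repressive_overlap": silencer.genes_with_overlap,
        }
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus a flat TSV of the headline counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows: list[tuple[str, str]] = []

    def _flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k in sorted(obj):
                _flatten(f"{prefix}.{k}" if prefix else k, obj[k])
        elif isinstance(obj, list):
            rows.append((prefix, ",".join(str(v) for v in obj)))
        else:
            rows.append((prefix, str(obj)))

    _flatten("", report)
    with open(out / "report.tsv", "w") as fh:
        fh.write("#key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
    return path
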