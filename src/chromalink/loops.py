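"""Differential chromatin-loop analysis.

Builds the loop x sample strength matrix from per-sample BEDPE files and
calls diagnosis-specific vs relapse-specific interactions with the
TMM -> log2-CPM -> top-variable -> moderated-t -> BH pipeline. Loops seen
in only one sample are retained with zeros elsewhere; the variance
ranking naturally promotes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, LoopRecord, ValidationError, read_bedpe_loops
from .stats import (
    DIAGNOSIS,
    RELAPSE,
    CountMatrix,
    ModeratedResult,
    log_norm,
    moderated_test,
    tmm_factors,
    top_variable,
)

__all__ = [
    "LoopMatrix",
    "DifferentialLoops",
    "build_loop_matrix",
    "build_loop_matrix_from_files",
    "call_differential_loops",
    "state_anchors",
]


@dataclass
class LoopMatrix:
    """Loop strengths as a CountMatrix plus the anchor pair of every loop."""

    matrix: CountMatrix
    anchors: dict[str, tuple[GenomicInterval, GenomicInterval]]

    def __post_init__(self) -> None:
        missing = set(self.matrix.features) - set(self.anchors)
        if missing:
            raise ValueError(f"{len(missing)} loop ids lack anchor coordinates")


def build_loop_matrix(
    records_per_sample: Mapping[str, Sequence[LoopRecord]],
    groups: Mapping[str, str],
) -> LoopMatrix:
    """Union-join per-sample loop records into a loop x sample matrix.

    The loop universe is the union of loop ids across samples; strengths
    missing from a sample are 0. Columns are ordered diagnosis samples
    first (in given order), then relapse. The same loop id must map to
    the same anchor pair everywhere.
    """
    sample_ids = list(records_per_sample)
    for s in sample_ids:
        if groups[s] not in (DIAGNOSIS, RELAPSE):
            raise ValueError(f"sample {s!r}: unknown group {groups[s]!r}")
    ordered = [s for s in sample_ids if groups[s] == DIAGNOSIS] + [
        s for s in sample_ids if groups[s] == RELAPSE
    ]
    if not any(groups[s] == DIAGNOSIS for s in ordered) or not any(
        groups[s] == RELAPSE for s in ordered
    ):
        raise ValueError("need at least one sample per group")

    anchors: dict[str, tuple[GenomicInterval, GenomicInterval]] = {}
    strengths: dict[str, dict[str, float]] = {}
    for s in ordered:
        seen: set[str] = set()
        for rec in records_per_sample[s]:
            if rec.loop_id in seen:
                raise ValidationError(
                    f"sample {s!r}: duplicate loop id {rec.loop_id!r}"
                )
            seen.add(rec.loop_id)
            pair = (rec.anchor_a, rec.anchor_b)
            if rec.loop_id in anchors and anchors[rec.loop_id] != pair:
                raise ValidationError(
                    f"loop id {rec.loop_id!r} maps to different anchors "
                    "in different samples"
                )
            anchors.setdefault(rec.loop_id, pair)
            strengths.setdefault(rec.loop_id, {})[s] = rec.strength

    # deterministic genomic row order
    loop_ids = sorted(
        anchors, key=lambda lid: (anchors[lid][0].key(), anchors[lid][1].key(), lid)
    )
    values = np.zeros((len(loop_ids), len(ordered)))
    for i, lid in enumerate(loop_ids):
        row = strengths[lid]
        for j, s in enumerate(ordered):
            values[i, j] = row.get(s, 0.0)
    cm = CountMatrix(loop_ids, ordered, values, [groups[s] for s in ordered])
    return LoopMatrix(cm, {lid: anchors[lid] for lid in loop_ids})


def build_loop_matrix_from_files(
    files: Sequence[str | Path],
    groups: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> LoopMatrix:
    if len(files) != len(groups):
        raise ValueError("one group label required per file")
    if sample_ids is None:
        sample_ids = [Path(f).stem for f in files]
    recs = {s: read_bedpe_loops(f) for s, f in zip(sample_ids, files)}
    return build_loop_matrix(recs, dict(zip(sample_ids, groups)))


@dataclass
class DifferentialLoops:
    """Moderated results over the tested loops plus the two specific sets."""

    results: pd.DataFrame
    relapse_specific: list[str]
    diagnosis_specific: list[str]
    anchors: dict[str, tuple[GenomicInterval, GenomicInterval]]
    alpha: float
    n_top: int
    d0: float
    s0_sq: float

    @property
    def n_significant(self) -> int:
        return len(self.relapse_specific) + len(self.diagnosis_specific)


def call_differential_loops(
    lm: LoopMatrix,
    n_top: int = 100_000,
    alpha: float = 0.1,
) -> DifferentialLoops:
    """Call state-specific loops at BH-adjusted p < alpha.

    Pipeline: TMM factors -> log2 CPM -> select the n_top most variable
    loops by row SD -> two-group moderated t -> BH over the tested subset
    -> partition by sign of log_fc (positive = relapse-specific; log_fc
    is relapse minus diagnosis).
    """
    cm = lm.matrix
    f = tmm_factors(cm)
    logm = log_norm(cm, f)
    idx = top_variable(logm, n_top)
    tested = [cm.features[i] for i in idx]
    mod: ModeratedResult = moderated_test(logm[idx], tested, cm.group)
    res = mod.table
    sig = res[res["p_adj"] < alpha]
    relapse_specific = sig.loc[sig["log_fc"] > 0, "feature_id"].tolist()
    diagnosis_specific = sig.loc[sig["log_fc"] < 0, "feature_id"].tolist()
    res = res.sort_values(["p", "feature_id"], kind="stable").reset_index(drop=True)
    return DifferentialLoops(
        results=res,
        relapse_specific=relapse_specific,
        diagnosis_specific=diagnosis_specific,
        anchors=lm.anchors,
        alpha=alpha,
        n_top=n_top,
        d0=mod.d0,
        s0_sq=mod.s0_sq,
    )


def state_anchors(dl: DifferentialLoops, state: str) -> list[GenomicInterval]:
    """Unique anchors (both ends) of one state's significant loops.

    Deduplication is by exact coordinates; overlapping-but-unequal
    anchors stay distinct. Returned in genomic order.
    """
    if state == RELAPSE:
        loop_ids = dl.relapse_specific
    elif state == DIAGNOSIS:
        loop_ids = dl.diagnosis_specific
    else:
        raise ValueError(f"unknown state {state!r}")
    seen: dict[tuple[str, int, int], GenomicInterval] = {}
    for lid in loop_ids:
        for anchor in dl.anchors[lid]:
            seen.setdefault(anchor.key(), anchor)
    return [seen[k] for k in sorted(seen)]
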