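"""Two-group differential gene expression with the study's thresholds.

Genes pass a minimal expression filter (CPM > 1 in at least 2 samples by
default); the filtered universe is both the tested set and the pool from
which random gene sets are later drawn. Significance requires
BH-adjusted p strictly below alpha and |log2 fold change| strictly above
the cutoff (defaults 0.1 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (
    CountMatrix,
    log_norm,
    moderated_test,
    tmm_factors,
)

__all__ = ["DEtable", "expression_filter", "differential_expression"]


@dataclass
class DEtable:
    """Moderated DE results plus the thresholded gene lists."""

    results: pd.DataFrame
    upregulated: list[str]
    downregulated: list[str]
    universe: list[str]
    alpha: float
    lfc: float

    @property
    def n_significant(self) -> int:
        return len(self.upregulated) + len(self.downregulated)

    def log_fc_of(self, gene_ids) -> np.ndarray:
        s = self.results.set_index("feature_id")["log_fc"]
        return s.loc[list(gene_ids)].to_numpy()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "de_results.tsv", "w") as fh:
            fh.write("#" + "\t".join(self.results.columns) + "\n")
            self.results.to_csv(fh, sep="\t", header=False, index=False)
        (out / "up.txt").write_text("".join(f"{g}\n" for g in self.upregulated))
        (out / "down.txt").write_text("".join(f"{g}\n" for g in self.downregulated))


def expression_filter(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> np.ndarray:
    """Indices of genes with CPM > min_cpm in >= min_samples samples."""
    lib = counts.values.sum(axis=0)
    cpm = counts.values / lib[np.newaxis, :] * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return np.nonzero(keep)[0]


def differential_expression(
    counts: CountMatrix,
    alpha: float = 0.1,
    lfc: float = 1.0,
    weights: bool = True,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> DEtable:
    """Moderated two-group DE with mean-variance trend weighting.

    Pipeline: expression filter -> TMM -> log2 CPM -> moderated t (with
    running-median trend weights by default, suited to count data) ->
    BH -> strict thresholding into up/down lists. Results are sorted by
    (p, gene id) for deterministic output.
    """
    idx = expression_filter(counts, min_cpm=min_cpm, min_samples=min_samples)
    if idx.size == 0:
        raise ValueError("no gene passes the expression filter")
    sub = counts.subset(idx)
    f = tmm_factors(sub)
    logm = log_norm(sub, f)
    mod = moderated_test(logm, sub.features, sub.group, use_trend_weights=weights)
    res = mod.table.sort_values(["p", "feature_id"], kind="stable").reset_index(
        drop=True
    )
    sig = res[res["p_adj"] < alpha]
    upregulated = sig.loc[sig["log_fc"] > lfc, "feature_id"].tolist()
    downregulated = sig.loc[sig["log_fc"] < -lfc, "feature_id"].tolist()
    return DEtable(
        results=res,
        upregulated=upregulated,
        downregulated=downregulated,
        universe=list(sub.features),
        alpha=alpha,
        lfc=lfc,
    )
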