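"""Normalization and moderated two-group statistics.

This module is the shared engine behind both the loop and the expression
analyses. It implements, from the published formulas:

* TMM (trimmed mean of M-values) between-sample normalization, with the
  standard defaults: 30% two-sided trim on log-ratios, 5% on average
  log-intensities, inverse approximate binomial variance weights, and the
  reference sample chosen as the one whose upper-quartile/library-size
  ratio is closest to the mean of those ratios.
* log2 counts-per-million with a prior count.
* An ordinary two-group linear fit (relapse minus diagnosis) with pooled
  residual variance.
* Empirical-Bayes variance moderation: the marginal distribution of the
  residual variances is matched to a scaled F by moments of log s^2, the
  prior degrees of freedom are recovered by inverting the trigamma
  function with a Newton iteration, and each variance is shrunk to the
  convex combination s2_post = (d0*s0^2 + df*s2) / (d0 + df). The
  moderated t has d0 + df degrees of freedom.
* Benjamini-Hochberg step-up FDR adjustment.

Values need not be integers: continuous nonnegative loop strengths go
through the same machinery, with library size defined as the column sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "CountMatrix",
    "NormFactors",
    "read_count_matrix",
    "write_count_matrix",
    "tmm_factors",
    "log_norm",
    "top_variable",
    "fit_two_group",
    "trigamma_inverse",
    "fit_f_dist",
    "squeeze_var",
    "ebayes",
    "bh_adjust",
    "trend_weights",
    "moderated_test",
    "DIAGNOSIS",
    "RELAPSE",
]

DIAGNOSIS = "diagnosis"
RELAPSE = "relapse"

_VARIANCE_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """A nonnegative features x samples matrix with two-group labels."""

    features: list[str]
    samples: list[str]
    values: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(self.group) != len(self.samples):
            raise ValueError("one group label required per sample")
        bad = set(self.group) - {DIAGNOSIS, RELAPSE}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if np.any(self.values < 0):
            raise ValueError("count matrix has negative entries")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature ids are not unique")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.group])

    def subset(self, idx: np.ndarray | Sequence[int]) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            [self.features[i] for i in idx],
            list(self.samples),
            self.values[idx],
            list(self.group),
        )


@dataclass
class NormFactors:
    """Library sizes and TMM scaling factors (geometric mean 1)."""

    lib_size: np.ndarray
    tmm_factor: np.ndarray

    def __post_init__(self) -> None:
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        self.tmm_factor = np.asarray(self.tmm_factor, dtype=float)
        gm = float(np.exp(np.mean(np.log(self.tmm_factor))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")

    @property
    def effective_lib_size(self) -> np.ndarray:
        return self.lib_size * self.tmm_factor


def read_count_matrix(
    path: str | Path, group: Sequence[str] | None = None
) -> CountMatrix:
    """Read a TSV count matrix (first column feature id, header sample ids).

    A header starting with '#' is accepted. ``group`` gives per-sample
    labels in column order; when omitted every sample must be named with
    a leading D/R to infer diagnosis/relapse.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df.columns = [c.lstrip("#") for c in df.columns]
    features = df.iloc[:, 0].astype(str).tolist()
    samples = list(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if group is None:
        group = []
        for s in samples:
            if s[:1].upper() == "D":
                group.append(DIAGNOSIS)
            elif s[:1].upper() == "R":
                group.append(RELAPSE)
            else:
                raise ValueError(
                    f"cannot infer group for sample {s!r}; pass group labels"
                )
    return CountMatrix(features, samples, values, list(group))


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#feature_id\t" + "\t".join(m.samples) + "\n")
        for i, fid in enumerate(m.features):
            row = "\t".join(repr(float(v)) for v in m.values[i])
            fh.write(f"{fid}\t{row}\n")


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def tmm_factors(
    m: CountMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against the reference, M-values (log2 ratio of
    library-scaled values) and A-values (average log2 intensity) are
    computed over features nonzero in both; the central M-values (after
    two-sided trimming on both M and A ranks) are averaged with inverse
    approximate binomial variance weights, and factors are rescaled to
    geometric mean 1. Pure library-depth differences therefore yield
    factors of 1.
    """
    y = m.values
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = [m.samples[j] for j in np.nonzero(lib <= 0)[0]]
        raise ValueError(f"sample(s) with zero library size: {bad}")

    # Reference: upper-quartile/library-size ratio closest to the mean ratio.
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr = y[:, ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj = y[:, j]
        keep = (yj > 0) & (yr > 0)
        if not np.any(keep):
            continue
        oj = yj[keep] / lib[j]
        orf = yr[keep] / lib[ref]
        M = np.log2(oj / orf)
        A = 0.5 * np.log2(oj * orf)
        # approximate binomial variance of M; weights are its inverse
        v = (lib[j] - yj[keep]) / (lib[j] * yj[keep]) + (lib[ref] - yr[keep]) / (
            lib[ref] * yr[keep]
        )
        if np.max(np.abs(M)) < 1e-6:
            continue
        n = M.size
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = _rank(M), _rank(A)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not np.any(kept) or np.sum(1.0 / v[kept]) <= 0:
            continue
        f = np.sum(M[kept] / v[kept]) / np.sum(1.0 / v[kept])
        if np.isfinite(f):
            factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(lib, factors)


def log_norm(m: CountMatrix, f: NormFactors, prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million on TMM-effective library sizes.

    value(i, j) = log2((count + prior) / (lib_size_j * tmm_factor_j) * 1e6).
    A positive prior keeps zero counts finite.
    """
    eff = f.effective_lib_size
    return np.log2((m.values + prior) / eff[np.newaxis, :] * 1e6)


def top_variable(logm: np.ndarray, n: int) -> np.ndarray:
    """Indices of the ``n`` rows with largest sample SD (ddof=1), stable ties.

    If fewer than ``n`` rows exist, all are returned. The returned indices
    are sorted ascending so row order is preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sd = np.std(logm, axis=1, ddof=1)
    order = np.argsort(-sd, kind="stable")[: min(n, logm.shape[0])]
    return np.sort(order)


# ---------------------------------------------------------------------------
# Two-group fit and empirical-Bayes moderation
# ---------------------------------------------------------------------------


def fit_two_group(
    logm: np.ndarray, group: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-row two-group fit: (log_fc, pooled residual variance, df).

    log_fc is mean(relapse) - mean(diagnosis); the pooled residual
    variance has n_samples - 2 degrees of freedom.
    """
    group = list(group)
    gd = np.array([g == DIAGNOSIS for g in group])
    gr = np.array([g == RELAPSE for g in group])
    nd, nr = int(gd.sum()), int(gr.sum())
    if nd < 2 or nr < 2:
        raise ValueError(f"need >=2 samples per group, got {nd} vs {nr}")
    md = logm[:, gd].mean(axis=1)
    mr = logm[:, gr].mean(axis=1)
    log_fc = mr - md
    ss = ((logm[:, gd] - md[:, None]) ** 2).sum(axis=1) + (
        (logm[:, gr] - mr[:, None]) ** 2
    ).sum(axis=1)
    df_resid = nd + nr - 2
    s2 = ss / df_resid
    return log_fc, s2, df_resid


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by a monotone Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled F distribution.

    Returns (df2, scale) = (prior degrees of freedom d0, prior variance
    s0^2) for the hierarchical model s2 ~ s0^2 * F(df1, d0). d0 may be
    +inf when the observed spread of log s^2 does not exceed what
    sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("fit_f_dist requires strictly positive variances")
    z = np.log(s2)
    if float(np.var(z)) < 1e-15:
        # zero spread in log s^2: no evidence of feature-specific variance,
        # shrink everything fully to the common value
        return math.inf, float(np.exp(np.mean(z)))
    e = z - float(special.digamma(df1 / 2.0)) + math.log(df1 / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(df2 / 2.0)) - math.log(df2 / 2.0)
        )
    else:
        df2 = math.inf
        s0_sq = math.exp(emean)
    return df2, s0_sq


def squeeze_var(
    s2: np.ndarray, df_resid: float
) -> tuple[float, float, np.ndarray]:
    """Shrink per-feature variances toward a common prior.

    Returns (d0, s0_sq, s2_post) with
    s2_post = (d0*s0_sq + df_resid*s2) / (d0 + df_resid).
    Fewer than 10 positive variances falls back to no-spread behavior
    (d0 = inf, everything shrunk to the mean variance); all-zero
    variances are an error directing the caller to apply a variance floor.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError(
            "all residual variances are zero; apply a variance floor "
            f"(e.g. {_VARIANCE_FLOOR}) before empirical-Bayes moderation"
        )
    positive = s2[s2 > 0]
    if positive.size < 10:
        s0_sq = float(np.mean(s2))
        return math.inf, s0_sq, np.full_like(s2, s0_sq)
    d0, s0_sq = fit_f_dist(np.maximum(s2, _VARIANCE_FLOOR), df1=df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    return d0, s0_sq, s2_post


def ebayes(
    log_fc: np.ndarray,
    s2: np.ndarray,
    df_resid: float,
    stdev_unscaled_sq: float,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> dict:
    """Moderated t-test given a two-group fit.

    ``stdev_unscaled_sq`` is the design-derived unscaled variance of the
    contrast (1/n1 + 1/n2 for two groups). ``d0``/``s0_sq`` may be forced
    (d0=0 recovers the ordinary t-statistic with df_resid df); otherwise
    they are estimated from the variances.
    """
    s2 = np.asarray(s2, dtype=float)
    if d0 is None:
        d0, s0_sq, s2_post = squeeze_var(s2, df_resid)
    else:
        if d0 == 0:
            s2_post = s2.copy()
            s0_sq = float("nan") if s0_sq is None else s0_sq
        elif math.isinf(d0):
            if s0_sq is None:
                raise ValueError("s0_sq required when forcing d0 = inf")
            s2_post = np.full_like(s2, s0_sq)
        else:
            if s0_sq is None:
                raise ValueError("s0_sq required when forcing d0")
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s2_post * stdev_unscaled_sq)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df=df_total)
    return {
        "d0": d0,
        "s0_sq": s0_sq,
        "s2_post": s2_post,
        "t_mod": t_mod,
        "p": p,
        "df_total": df_total,
    }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    # guard against 1-ulp float loss of the mathematical p_adj >= p
    return np.maximum(out, p)


def trend_weights(
    ave_expr: np.ndarray, s2: np.ndarray, span_frac: float = 0.1
) -> np.ndarray:
    """Precision weights from a running-median mean-variance trend.

    The quarter-power of the residual variance (i.e. sqrt of residual SD)
    is smoothed by a running median along average log-expression; weights
    are trend**-4, so dividing s2 by its trend leaves a roughly
    exchangeable set of variances for empirical-Bayes pooling. This is a
    simplified, per-feature analog of precision weighting for count data.
    """
    ave_expr = np.asarray(ave_expr, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n = s2.size
    quarter = np.maximum(s2, _VARIANCE_FLOOR) ** 0.25
    order = np.argsort(ave_expr, kind="stable")
    window = max(5, int(span_frac * n) | 1)  # odd, >= 5
    trend_sorted = (
        pd.Series(quarter[order])
        .rolling(window=window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    trend = np.empty(n)
    trend[order] = trend_sorted
    trend = np.maximum(trend, _VARIANCE_FLOOR**0.25)
    return trend**-4.0


@dataclass
class ModeratedResult:
    """Full moderated-test output for one analysis."""

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_total: float


def moderated_test(
    logm: np.ndarray,
    features: Sequence[str],
    group: Sequence[str],
    use_trend_weights: bool = False,
) -> ModeratedResult:
    """Two-group fit + empirical-Bayes moderation + BH adjustment.

    Returns a table (input feature order) with columns feature_id,
    log_fc, ave_expr, s2, s2_post, t_mod, p, p_adj. With
    ``use_trend_weights`` the variances are rescaled by a running-median
    mean-variance trend before moderation (intended for RNA counts).
    """
    group = list(group)
    log_fc, s2, df_resid = fit_two_group(logm, group)
    ave_expr = logm.mean(axis=1)
    nd = sum(g == DIAGNOSIS for g in group)
    nr = sum(g == RELAPSE for g in group)
    v = 1.0 / nd + 1.0 / nr
    s2_work = np.maximum(s2, _VARIANCE_FLOOR)
    if use_trend_weights:
        # Pool the trend-scaled variances, then map the posterior back to
        # the original scale: in the weighted model the contrast's
        # unscaled variance is v / w, so t = log_fc / sqrt(s2_post/w * v).
        w = trend_weights(ave_expr, s2_work)
        eb = ebayes(log_fc, s2_work * w, df_resid, v)
        s2_post = eb["s2_post"] / w
        t_mod = log_fc / np.sqrt(s2_post * v)
        if math.isinf(eb["df_total"]):
            p = 2.0 * sps.norm.sf(np.abs(t_mod))
        else:
            p = 2.0 * sps.t.sf(np.abs(t_mod), df=eb["df_total"])
        eb["s2_post"], eb["t_mod"], eb["p"] = s2_post, t_mod, p
    else:
        eb = ebayes(log_fc, s2_work, df_resid, v)
    p_adj = bh_adjust(eb["p"])
    table = pd.DataFrame(
        {
            "feature_id": list(features),
            "log_fc": log_fc,
            "ave_expr": ave_expr,
            "s2": s2,
            "s2_post": eb["s2_post"],
            "t_mod": eb["t_mod"],
            "p": eb["p"],
            "p_adj": p_adj,
        }
    )
    return ModeratedResult(table, eb["d0"], eb["s0_sq"], eb["df_total"])
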