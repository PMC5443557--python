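"""Per-study differential-expression statistics between two phenotypes.

For every probe the module computes two effect sizes on the log2 scale — the
mean-based log fold change (logFC) and the robust median-ratio log fold
change (logFC_m, the log2 of the median of all cross-group linear expression
ratios) — the median absolute deviation (MAD) of the cross-pair log ratios
(the reproducibility penalty used by the gene score), a moderated t with an
empirical-Bayes shrunken variance, and the B statistic, the log posterior
odds of differential expression of the standard empirical-Bayes linear-model
framework for microarrays (Smyth 2004). An ANOVA/FDR prefilter discards
probes with no evidence of any group effect before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .studies import ExpressionStudy

__all__ = [
    "compute_logfc",
    "compute_logfc_m",
    "compute_mad",
    "bh_adjust",
    "anova_prefilter",
    "moderated_stats",
    "probe_stats",
    "ModeratedResult",
]


# ---------------------------------------------------------------------------
# effect sizes


def _as_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def compute_logfc(values_a, values_b) -> float:
    """Mean-based log2 fold change: mean(A) − mean(B)."""
    a = _as_vector(values_a, "values_a")
    b = _as_vector(values_b, "values_b")
    return float(a.mean() - b.mean())


def _pair_log_ratios(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All |A|×|B| cross-group log2 ratios a − b, flattened."""
    return (a[:, None] - b[None, :]).ravel()


def compute_logfc_m(values_a, values_b) -> float:
    """Median-ratio log2 fold change.

    Forms every cross-group linear ratio 2**(a−b), takes the median of those
    linear ratios, and returns its log2. The median of an even count is the
    linear-scale midpoint, so this is not in general the median of the log
    ratios.
    """
    a = _as_vector(values_a, "values_a")
    b = _as_vector(values_b, "values_b")
    ratios = np.exp2(_pair_log_ratios(a, b))
    return float(np.log2(np.median(ratios)))


def compute_mad(values_a, values_b) -> float:
    """Unscaled MAD of the cross-pair log2 ratios.

    No 1.4826 consistency constant is applied: the raw median absolute
    deviation is the smaller, more conservative penalty.
    """
    a = _as_vector(values_a, "values_a")
    b = _as_vector(values_b, "values_b")
    lr = _pair_log_ratios(a, b)
    return float(np.median(np.abs(lr - np.median(lr))))


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# ANOVA prefilter


def _two_group_f(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way equal-variance F statistic per probe (two groups).

    For two groups F equals the square of the pooled-variance t statistic.
    """
    ma, mb = study.group_matrices()
    na, nb = ma.shape[1], mb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"study {study.study_id!r}: a phenotype group has fewer than 2 samples; "
            "the equal-variance ANOVA prefilter is undefined — rerun with "
            "skip_prefilter=True"
        )
    a = ma.to_numpy(float)
    b = mb.to_numpy(float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        f = diff**2 / (s2 * (1.0 / na + 1.0 / nb))
    # probes with zero within-group variance: F = 0 when the means agree too
    # (no effect), infinite otherwise (certain effect)
    f = np.where(s2 == 0, np.where(diff == 0, 0.0, np.inf), f)
    p = stats.f.sf(f, 1, df)
    return f, p


def anova_prefilter(study: ExpressionStudy, fdr: float = 0.05) -> ExpressionStudy:
    """Drop probes whose two-group ANOVA BH-FDR exceeds ``fdr``."""
    _, p = _two_group_f(study)
    keep = bh_adjust(p) <= fdr
    return ExpressionStudy(
        study_id=study.study_id,
        species=study.species,
        matrix=study.matrix.loc[keep],
        groups=study.groups,
        probe_map=study.probe_map,
        comparison=study.comparison,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderated statistics


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for sample variances.

    Returns (d0, s0_sq): prior degrees of freedom and prior variance. Falls
    back to d0 = 4, s0² = median(s²) when the log-variance curvature is not
    positive (tiny or near-degenerate fixtures).
    """
    if np.all(s2 <= 0):
        raise ValueError("all probe variances are zero: hyperparameter fit impossible")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n > 1:
        evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    else:
        evar = -1.0
    if np.isfinite(evar) and evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = 4.0
        s0_sq = float(np.median(s2))
        if s0_sq <= 0:
            raise ValueError("cannot fit variance prior: median probe variance is zero")
    return d0, s0_sq


def _var_prior(
    tstat: np.ndarray, stdev_unscaled: float, df_total: np.ndarray, proportion: float
) -> float:
    """Estimate the prior variance of the coefficient for DE probes.

    Moment-matches the top |t| order statistics against the t quantiles of a
    two-component mixture with DE proportion ``proportion`` (the var.prior
    step of the empirical-Bayes framework).
    """
    ngenes = tstat.size
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return float(stdev_unscaled**2)
    p = max(ntarget / ngenes, proportion)
    t_abs = np.abs(tstat)
    max_df = float(np.max(df_total))
    order = np.argsort(-t_abs)[:ntarget]
    ttarget = t_abs[order]
    v1 = stdev_unscaled**2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(ttarget, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1 * ((ttarget[pos] / qtarget) ** 2 - 1.0)
    return float(np.mean(v0))


@dataclass
class ModeratedResult:
    """Per-probe moderated statistics plus the fitted hyperparameters."""

    table: pd.DataFrame  # columns: t, p, adj_p, B
    d0: float
    s0_sq: float
    var_prior: float
    proportion: float


def moderated_stats(
    study: ExpressionStudy,
    proportion: float = 0.01,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedResult:
    """Moderated t, p, BH-adjusted p and B per probe.

    The pooled two-group residual variance s² (df = n−2) is shrunk toward a
    prior s0² with d0 prior df fitted by the method of moments on log s²;
    the moderated t uses the posterior variance (d0·s0² + df·s²)/(d0+df) and
    is referenced to a t distribution with d0+df degrees of freedom. B is
    the log posterior odds that the probe is differentially expressed, with
    prior DE proportion ``proportion``.

    ``d0``/``s0_sq`` may be forced (e.g. d0=0 reproduces the ordinary t;
    d0=inf gives the fully shrunk limit).
    """
    ma, mb = study.group_matrices()
    na, nb = ma.shape[1], mb.shape[1]
    df_resid = na + nb - 2
    if df_resid < 1:
        raise ValueError("need at least 3 samples across the two groups")
    if ma.shape[0] == 0:
        empty = pd.DataFrame(columns=["t", "p", "adj_p", "B"], index=ma.index, dtype=float)
        return ModeratedResult(table=empty, d0=float("nan"), s0_sq=float("nan"),
                               var_prior=float("nan"), proportion=proportion)
    a = ma.to_numpy(float)
    b = mb.to_numpy(float)
    coef = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    su = math.sqrt(1.0 / na + 1.0 / nb)  # unscaled stdev of the coefficient

    if d0 is None or s0_sq is None:
        d0_fit, s0_fit = _fit_f_dist(s2, float(df_resid))
        d0 = d0_fit if d0 is None else d0
        s0_sq = s0_fit if s0_sq is None else s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full(s2.size, float(df_resid * s2.size))
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = np.full(s2.size, min(d0 + df_resid, float(df_resid * s2.size)))
    if np.any(s2_post <= 0):
        raise ValueError("non-positive posterior variance: degenerate expression matrix")

    t = coef / (su * np.sqrt(s2_post))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj_p = bh_adjust(p)

    v0 = _var_prior(t, su, df_total, proportion)
    v1 = su**2
    r = (v1 + max(v0, 0.0)) / v1
    t2 = t**2
    if np.all(df_total > 1e6):  # normal-limit kernel
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    lods = math.log(proportion / (1.0 - proportion)) - math.log(r) / 2.0 + kernel

    table = pd.DataFrame(
        {"t": t, "p": p, "adj_p": adj_p, "B": lods}, index=ma.index
    )
    return ModeratedResult(table=table, d0=float(d0), s0_sq=float(s0_sq),
                           var_prior=float(v0), proportion=proportion)


# ---------------------------------------------------------------------------
# per-study probe table


def probe_stats(study: ExpressionStudy, proportion: float = 0.01) -> pd.DataFrame:
    """Full per-probe statistics table for one study.

    Columns: logFC, logFC_m, MAD, variance (of every sample of both
    phenotypes, used for probe collapse), t, p, adj_p, B.
    """
    ma, mb = study.group_matrices()
    if ma.shape[0] == 0:
        cols = ["logFC", "logFC_m", "MAD", "variance", "t", "p", "adj_p", "B"]
        empty = pd.DataFrame(columns=cols, index=ma.index, dtype=float)
        empty.index.name = "probe_id"
        return empty
    a = ma.to_numpy(float)
    b = mb.to_numpy(float)
    # cross-pair log ratios, probes × (|A|·|B|)
    lr = (a[:, :, None] - b[:, None, :]).reshape(a.shape[0], -1)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    logfc_m = np.log2(np.median(np.exp2(lr), axis=1))
    med = np.median(lr, axis=1, keepdims=True)
    mad = np.median(np.abs(lr - med), axis=1)
    both = np.concatenate([a, b], axis=1)
    variance = both.var(axis=1, ddof=1)
    mod = moderated_stats(study, proportion=proportion)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "logFC_m": logfc_m,
            "MAD": mad,
            "variance": variance,
            "t": mod.table["t"],
            "p": mod.table["p"],
            "adj_p": mod.table["adj_p"],
            "B": mod.table["B"],
        },
        index=ma.index,
    )
    out.index.name = "probe_id"
    return out
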