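"""Per-study gene scores from probe-level statistics.

The score of a gene in one study weights its normalized robust effect size
by a signal-to-(signal+noise) reliability factor and gates it on statistical
significance:

    s_raw = n * r * gate
    n     = logFC_m normalized per study to [0,1] (up) / [−1,0] (down)
    r     = |logFC_m| / (|logFC_m| + c·MAD)          (0 when logFC_m = 0)
    gate  = 1 iff adj_p ≤ alpha and B > 0, else 0

Probes are collapsed to genes by keeping, for each gene, the probe with the
greatest variance across all samples of the two phenotypes; raw scores are
then standardized within the study by the maximum absolute score so that
every study contributes on the same [−1,1] scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_effect_sizes",
    "probe_score",
    "collapse_probes_to_genes",
    "standardize_scores",
    "score_study",
]


def normalize_effect_sizes(logfc_m) -> np.ndarray:
    """Scale positive values by the max positive, negatives by |min negative|.

    Maps each study's effect sizes onto [−1,1] so that expression-ratio
    magnitudes are comparable across platforms; zeros stay zero, and a side
    with no values leaves the other side untouched.
    """
    v = np.asarray(logfc_m, dtype=float)
    if v.size == 0:
        raise ValueError("effect-size vector must be non-empty")
    out = v.astype(float).copy()
    pos = v > 0
    neg = v < 0
    if pos.any():
        out[pos] = v[pos] / v[pos].max()
    if neg.any():
        out[neg] = v[neg] / abs(v[neg].min())
    return out


def probe_score(
    n_ij: float,
    logfc_m_ij: float,
    mad_ij: float,
    adj_p: float,
    b: float,
    alpha: float = 0.05,
    c: float = 1.0,
) -> float:
    """Raw (pre-standardization) score of one probe/gene in one study."""
    if logfc_m_ij == 0:
        r = 0.0
    else:
        r = abs(logfc_m_ij) / (abs(logfc_m_ij) + c * mad_ij)
    gate = 1.0 if (adj_p <= alpha and b > 0) else 0.0
    return float(n_ij * r * gate)


def _raw_scores(
    table: pd.DataFrame, alpha: float, c: float
) -> pd.DataFrame:
    """Vectorized probe_score over a stats table (adds n, gate, s_raw)."""
    n = normalize_effect_sizes(table["logFC_m"].to_numpy())
    lfm = table["logFC_m"].to_numpy(float)
    mad = table["MAD"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(lfm == 0, 0.0, np.abs(lfm) / (np.abs(lfm) + c * mad))
    gate = ((table["adj_p"].to_numpy(float) <= alpha) & (table["B"].to_numpy(float) > 0)).astype(
        float
    )
    out = table.copy()
    out["n"] = n
    out["gate"] = gate
    out["s_raw"] = n * r * gate
    return out


def collapse_probes_to_genes(stats: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """One row per gene: the probe with maximal all-sample variance.

    Probes without a map entry are dropped (count logged). Variance ties are
    broken by the lexicographically smallest probe ID for determinism.
    """
    mapped = stats.index.intersection(probe_map.index)
    dropped = stats.shape[0] - mapped.size
    if mapped.size == 0:
        raise ValueError("no probe in the stats table has a probe-map entry")
    if dropped:
        logger.info("collapse: dropped %d unmapped probes", dropped)
    tab = stats.loc[mapped].copy()
    tab["gene_id"] = probe_map.loc[mapped].to_numpy()
    tab = tab.sort_index()  # lexicographic probe order for tie-breaks
    best = tab.sort_values("variance", kind="stable", ascending=False)
    best = best[~best["gene_id"].duplicated(keep="first")]
    out = best.reset_index(names="probe_id").set_index("gene_id").sort_index()
    return out


def standardize_scores(raw) -> np.ndarray:
    """Divide by the maximum absolute raw score; all-zero input unchanged."""
    v = np.asarray(raw, dtype=float)
    if v.size == 0:
        raise ValueError("score vector must be non-empty")
    m = np.abs(v).max()
    if m == 0:
        return v.copy()
    return v / m


def score_study(
    stats: pd.DataFrame,
    probe_map: pd.Series,
    alpha: float = 0.05,
    c: float = 1.0,
) -> pd.DataFrame:
    """Probe stats -> per-gene score table for one study.

    Scores are computed at probe level (normalization over the study's probe
    universe), probes are collapsed onto genes by the max-variance rule, and
    the collapsed raw scores are range-standardized within the study.

    Returns a gene-indexed table with columns probe_id, logFC, logFC_m, MAD,
    variance, adj_p, B, n, gate, s_raw, s_std.
    """
    cols = ["probe_id", "logFC", "logFC_m", "MAD", "variance", "adj_p", "B", "n", "gate", "s_raw", "s_std"]
    if stats.empty:  # e.g. every probe removed by the prefilter
        out = pd.DataFrame(columns=cols, dtype=float)
        out.index.name = "gene_id"
        return out
    scored = _raw_scores(stats, alpha=alpha, c=c)
    genes = collapse_probes_to_genes(scored, probe_map)
    genes["s_std"] = standardize_scores(genes["s_raw"].to_numpy())
    return genes[cols]
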