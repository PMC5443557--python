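"""Combine per-study gene scores into a final ranked signature.

Human study scores are summed per gene; the mouse study (mapped onto human
gene IDs through an ortholog table) is added only when its score sign agrees
with the human sum and the human sum is non-null — genes exclusive to the
mouse are ignored. Cross-study effect sizes are medians, with the mouse
value included only under the same sign-agreement rule. Per gene, the
Bhattacharyya-distance (BD) ratio measures how unevenly the represented
studies contribute to the final score. Two final screens produce the
signature: a sign-consistency screen (score sign must match the median
logFC sign) and a top/bottom-decile cut with an absolute-logFC floor.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "map_orthologs",
    "combine_scores",
    "median_effect_sizes",
    "bd_ratio",
    "consistency_screen",
    "final_signature_filter",
    "integrate_studies",
]


def map_orthologs(mouse_table: pd.DataFrame, ortholog_map: pd.Series) -> pd.DataFrame:
    """Re-key a mouse gene-score table onto human gene IDs.

    ``ortholog_map``: mouse gene ID -> human gene ID (many mouse genes may
    map to one human gene; the row with the greatest all-sample variance is
    kept, mirroring the probe-collapse rule). Unmapped mouse genes are
    dropped with a logged count.
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")
    mapped = mouse_table.index.intersection(ortholog_map.index)
    dropped = mouse_table.shape[0] - mapped.size
    if dropped:
        logger.info("ortholog mapping: dropped %d unmapped mouse genes", dropped)
    tab = mouse_table.loc[mapped].copy()
    tab["human_gene_id"] = ortholog_map.loc[mapped].to_numpy()
    tab = tab.sort_index()
    best = tab.sort_values("variance", kind="stable", ascending=False)
    best = best[~best["human_gene_id"].duplicated(keep="first")]
    out = best.reset_index(names="mouse_gene_id").set_index("human_gene_id").sort_index()
    out.index.name = "gene_id"
    return out


def combine_scores(
    human_tables: list[pd.DataFrame],
    mouse_table: pd.DataFrame | None = None,
    mouse_weight: float = 1.0,
) -> pd.DataFrame:
    """Sum standardized per-study scores into the final score s_i.

    Returns a gene-indexed frame with columns ``score``, ``studies`` (count
    of studies in which the gene is represented, mouse counted only when
    included) and ``mouse`` (0/1 inclusion flag). Genes present only in the
    mouse study are absent from the output.
    """
    if not human_tables:
        raise ValueError("at least one human study table is required")
    scores = pd.concat(
        [t["s_std"].rename(i) for i, t in enumerate(human_tables)], axis=1
    )
    s_human = scores.sum(axis=1, skipna=True)
    n_studies = scores.notna().sum(axis=1)

    out = pd.DataFrame({"score": s_human, "studies": n_studies, "mouse": 0})
    if mouse_table is not None:
        ms = mouse_table["s_std"].reindex(out.index)
        include = (
            ms.notna()
            & (out["score"] != 0)
            & (np.sign(ms) == np.sign(out["score"]))
            & (ms != 0)
        )
        out.loc[include, "score"] = out.loc[include, "score"] + mouse_weight * ms[include]
        out.loc[include, "studies"] += 1
        out.loc[include, "mouse"] = 1
    out.index.name = "gene_id"
    return out.sort_index()


def median_effect_sizes(
    human_values: list[float], mouse_value: float | None = None
) -> float:
    """Median effect size across studies with the mouse sign rule.

    The mouse value joins the median only when its sign equals the sign of
    the human median; otherwise (or when absent) the human median stands.
    """
    vals = [v for v in human_values if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("at least one human effect size is required")
    human_med = float(np.median(vals))
    if mouse_value is None or np.isnan(mouse_value):
        return human_med
    if np.sign(mouse_value) == np.sign(human_med) and human_med != 0:
        return float(np.median(vals + [float(mouse_value)]))
    return human_med


def bd_ratio(scores) -> float:
    """Bhattacharyya-distance ratio of one gene's per-study score mass.

    With p_j = |s_ij| / Σ|s_ij| over the n studies in which the gene is
    represented and q_j = 1/n the equal-contribution reference,
    BD = −ln Σ√(p_j q_j) and the ratio divides by the maximum possible
    BD = ½ ln n (all mass on a single study). A gene represented in a
    single study is assigned 0 by convention, as is a gene whose scores are
    all null.
    """
    s = np.abs(np.asarray(scores, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("bd_ratio needs at least one study score")
    if n == 1:
        return 0.0
    total = s.sum()
    if total == 0:
        return 0.0
    p = s / total
    bc = np.sqrt(p / n).sum()
    bd = -math.log(min(bc, 1.0))
    bd_max = 0.5 * math.log(n)
    return float(min(bd / bd_max, 1.0))


def consistency_screen(records: pd.DataFrame) -> pd.DataFrame:
    """Third filter: drop genes whose score sign contradicts the logFC sign.

    Null scores are also removed from signature candidacy.
    """
    score = records["score"].to_numpy(float)
    lfc = records["logFC"].to_numpy(float)
    keep = (score != 0) & (np.sign(score) == np.sign(lfc))
    return records.loc[keep]


def _take_decile(side: pd.DataFrame, top_frac: float, ascending: bool) -> pd.DataFrame:
    k = math.floor(top_frac * side.shape[0])
    if k == 0:
        return side.iloc[0:0]
    ordered = side.sort_values(
        by=["score", "abs_lfc", "gene_id"],
        ascending=[ascending, False, True],
        kind="stable",
    )
    return ordered.iloc[:k]


def final_signature_filter(
    records: pd.DataFrame,
    top_frac: float = 0.10,
    min_abs_logfc: float = 0.99,
) -> pd.DataFrame:
    """Fourth filter: decile-by-score cut plus absolute-logFC floor.

    Takes the top ``floor(top_frac·N₊)`` positive-score genes and the bottom
    ``floor(top_frac·N₋)`` negative-score genes (rank ties broken by |logFC|
    descending then gene ID), then retains those with |logFC| >
    ``min_abs_logfc``. Result sorted by score descending.
    """
    work = records.copy()
    if work.index.name == "gene_id":
        work = work.reset_index()
    work["abs_lfc"] = work["logFC"].abs()
    pos = _take_decile(work[work["score"] > 0], top_frac, ascending=False)
    neg = _take_decile(work[work["score"] < 0], top_frac, ascending=True)
    sig = pd.concat([pos, neg])
    sig = sig[sig["abs_lfc"] > min_abs_logfc]
    if sig.empty:
        logger.warning("final signature filter produced an empty signature")
    sig = sig.sort_values(by=["score", "gene_id"], ascending=[False, True], kind="stable")
    return sig.drop(columns=["abs_lfc"]).set_index("gene_id")


def integrate_studies(
    human_tables: list[pd.DataFrame],
    mouse_table: pd.DataFrame | None = None,
    mouse_weight: float = 1.0,
) -> pd.DataFrame:
    """Full unfiltered meta table: score, logFC, logFC_m, studies, mouse, bd_ratio.

    ``human_tables``/``mouse_table`` are gene-indexed per-study score tables
    as produced by :func:`nfmeta.scoring.score_study` (mouse already mapped
    to human IDs via :func:`map_orthologs`).
    """
    combined = combine_scores(human_tables, mouse_table, mouse_weight=mouse_weight)

    h_lfc = pd.concat([t["logFC"].rename(i) for i, t in enumerate(human_tables)], axis=1)
    h_lfm = pd.concat([t["logFC_m"].rename(i) for i, t in enumerate(human_tables)], axis=1)
    h_s = pd.concat([t["s_std"].rename(i) for i, t in enumerate(human_tables)], axis=1)
    h_lfc = h_lfc.reindex(combined.index)
    h_lfm = h_lfm.reindex(combined.index)
    h_s = h_s.reindex(combined.index)

    if mouse_table is not None:
        m_lfc = mouse_table["logFC"].reindex(combined.index)
        m_lfm = mouse_table["logFC_m"].reindex(combined.index)
        m_s = mouse_table["s_std"].reindex(combined.index)
    else:
        m_lfc = m_lfm = m_s = pd.Series(np.nan, index=combined.index)

    hl = h_lfc.to_numpy(float)
    hm = h_lfm.to_numpy(float)
    hs = h_s.to_numpy(float)
    ml = m_lfc.to_numpy(float)
    mm = m_lfm.to_numpy(float)
    ms = m_s.to_numpy(float)
    mouse_in = combined["mouse"].to_numpy() == 1

    logfc = np.empty(combined.shape[0])
    logfc_m = np.empty(combined.shape[0])
    ratios = np.empty(combined.shape[0])
    for k in range(combined.shape[0]):
        hvals = hl[k][~np.isnan(hl[k])].tolist()
        hvals_m = hm[k][~np.isnan(hm[k])].tolist()
        mv = None if np.isnan(ml[k]) else float(ml[k])
        mv_m = None if np.isnan(mm[k]) else float(mm[k])
        logfc[k] = median_effect_sizes(hvals, mv)
        logfc_m[k] = median_effect_sizes(hvals_m, mv_m)
        svals = hs[k][~np.isnan(hs[k])].tolist()
        if mouse_in[k]:
            svals.append(float(ms[k]))
        ratios[k] = bd_ratio(svals)

    out = combined.copy()
    out["logFC"] = logfc
    out["logFC_m"] = logfc_m
    out["bd_ratio"] = ratios
    return out[["score", "logFC", "logFC_m", "studies", "mouse", "bd_ratio"]]
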