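"""Chromosome-region enrichment and the promoter-hypermethylation filter.

Region enrichment asks whether signature genes pile up on particular
chromosome arms or cytogenetic bands: with p the fraction of the annotated
gene universe lying in a region and n the signature size, the upper binomial
tail P(X ≥ x) gives the probability of seeing at least the observed count x
by chance. Raw tails are reported (no cross-region correction) together
with the conventional star labels.

The silencing filter crosses a tumor expression meta-analysis with promoter
methylation statistics to nominate genes plausibly switched off by
hypermethylation during malignant transformation: downregulated in the
malignant-vs-benign comparison (negative score, logFC below a floor in both
tumor comparisons) with hypermethylated promoters (methylation logFC above,
adjusted p below, their thresholds) in the corresponding methylome
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "region_enrichment",
    "significance_stars",
    "methylation_silencing_filter",
    "MethylationThresholds",
]

MPNST_VS_NF = "MPNST_vs_NF"
MPNST_VS_CONTROL = "MPNST_vs_control"
NF_VS_CONTROL = "NF_vs_control"


def _region_labels(annotation: pd.DataFrame, level: str) -> pd.Series:
    chrom = annotation["chromosome"].astype(str)
    if level == "arm":
        lab = chrom + annotation["arm"].astype(str)
        # genes lacking arm annotation drop out of arm-level tests
        lab = lab.where(annotation["arm"].notna())
    elif level == "band":
        lab = chrom + annotation["band"].astype(str)
        lab = lab.where(annotation["band"].notna())
    else:
        raise ValueError(f"level must be 'arm' or 'band', got {level!r}")
    return lab


def region_enrichment(
    signature_genes, annotation: pd.DataFrame, level: str = "arm"
) -> pd.DataFrame:
    """Exact binomial upper-tail enrichment of signature genes per region.

    Parameters
    ----------
    signature_genes
        Iterable of gene IDs (genes missing from the annotation are dropped
        with a logged count).
    annotation
        Gene-indexed frame with columns ``chromosome``, ``arm``, ``band``.
    level
        ``"arm"`` (chromosome + p/q) or ``"band"`` (chromosome + band),
        with expected frequencies computed genome-wide in either case.

    Returns a frame indexed by region with columns observed, expected_freq,
    n, p_tail, stars, sorted by p_tail.
    """
    if annotation.empty:
        raise ValueError("annotation universe is empty")
    labels = _region_labels(annotation, level).dropna()
    universe_counts = labels.value_counts()
    universe_size = labels.size

    sig = pd.Index(pd.unique(pd.Series(list(signature_genes))))
    in_universe = sig.intersection(labels.index)
    dropped = sig.size - in_universe.size
    if dropped:
        logger.info("enrichment: dropped %d signature genes without annotation", dropped)
    n = in_universe.size
    sig_counts = labels.loc[in_universe].value_counts()

    regions = universe_counts.index
    x = sig_counts.reindex(regions, fill_value=0).to_numpy(int)
    p = (universe_counts / universe_size).to_numpy(float)
    p_tail = stats.binom.sf(x - 1, n, p) if n > 0 else np.ones_like(p)
    out = pd.DataFrame(
        {
            "observed": x,
            "expected_freq": p,
            "n": n,
            "p_tail": p_tail,
        },
        index=regions,
    )
    out["stars"] = [significance_stars(v) for v in out["p_tail"]]
    out.index.name = "region"
    return out.sort_values(["p_tail", "observed"], ascending=[True, False], kind="stable")


def significance_stars(p: float) -> str:
    """Map a binomial tail probability to its star label.

    ****: P < 0.0001, ***: 0.0001 < P < 0.001, **: 0.001 < P < 0.01,
    *: 0.01 < P < 0.05, otherwise empty. The intervals are open; a boundary
    value takes the less significant label.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("tail probability must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class MethylationThresholds:
    """Cutoffs of the hypermethylation silencing filter.

    ``expr_logfc_max``: tumor expression logFC must fall below this in both
    tumor comparisons (log2 units). ``meth_logfc_min`` / ``meth_adj_p_max``:
    promoter methylation evidence floor/ceiling. ``require_both``: demand
    the methylation evidence in both the malignant-vs-benign and
    malignant-vs-control methylome comparisons (default) or in either.
    """

    expr_logfc_max: float = -0.5
    meth_logfc_min: float = 1.5
    meth_adj_p_max: float = 0.1
    require_both: bool = True


def methylation_silencing_filter(
    expression: dict[str, pd.DataFrame],
    methylation: pd.DataFrame,
    thresholds: MethylationThresholds | None = None,
) -> pd.DataFrame:
    """Genes downregulated in tumors with hypermethylated promoters.

    Parameters
    ----------
    expression
        Mapping with keys ``"MPNST_vs_NF"`` and ``"MPNST_vs_control"``, each
        a gene-indexed meta table with at least ``score`` and ``logFC``.
    methylation
        Long table with columns ``gene_id``, ``comparison``, ``meth_logfc``,
        ``meth_adj_p``; comparisons named as the expression keys.
    thresholds
        See :class:`MethylationThresholds`.

    Returns the gene-indexed rows of the MPNST-vs-NF expression table that
    satisfy every condition, with the methylation statistics joined on.
    """
    th = thresholds or MethylationThresholds()
    for key in (MPNST_VS_NF, MPNST_VS_CONTROL):
        if key not in expression:
            raise ValueError(f"missing expression meta table for comparison {key!r}")
    nf = expression[MPNST_VS_NF]
    ctrl = expression[MPNST_VS_CONTROL]

    if np.any((methylation["meth_adj_p"] < 0) | (methylation["meth_adj_p"] > 1)):
        raise ValueError("methylation adjusted p-values must lie in [0, 1]")

    expr_ok = (
        (nf["score"] < 0)
        & (nf["logFC"] < th.expr_logfc_max)
        & (ctrl["logFC"].reindex(nf.index) < th.expr_logfc_max)
    )
    candidates = nf.index[expr_ok.fillna(False)]

    meth_ok = {}
    for comp in (MPNST_VS_NF, MPNST_VS_CONTROL):
        sub = methylation[methylation["comparison"] == comp].set_index("gene_id")
        ok = (sub["meth_logfc"] > th.meth_logfc_min) & (sub["meth_adj_p"] < th.meth_adj_p_max)
        meth_ok[comp] = ok.reindex(candidates).fillna(False)
    if th.require_both:
        meth_pass = meth_ok[MPNST_VS_NF] & meth_ok[MPNST_VS_CONTROL]
    else:
        meth_pass = meth_ok[MPNST_VS_NF] | meth_ok[MPNST_VS_CONTROL]

    selected = candidates[meth_pass.to_numpy()]
    out = nf.loc[selected].copy()
    for comp, col in ((MPNST_VS_NF, "nf"), (MPNST_VS_CONTROL, "ctrl")):
        sub = methylation[methylation["comparison"] == comp].set_index("gene_id")
        out[f"meth_logfc_{col}"] = sub["meth_logfc"].reindex(selected)
        out[f"meth_adj_p_{col}"] = sub["meth_adj_p"].reindex(selected)
    return out
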