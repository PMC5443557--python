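"""Bundled reference tables.

The hypermethylation panel is the published 10-gene set of MPNST-vs-NF
signature genes potentially silenced by promoter hypermethylation:
nerve-tumor expression meta-analysis statistics (score and median logFC for
the MPNST-vs-NF and MPNST-vs-control comparisons) together with the
promoter-methylation differential statistics (edgeR logFC and adjusted p)
derived from the GSE21714 MeDIP-seq methylome of pooled MPNST, neurofibroma
and normal Schwann cell samples. It is a worked-example input for the
silencing filter, not an output of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genomics import MPNST_VS_CONTROL, MPNST_VS_NF

__all__ = ["load_hypermethylation_panel", "panel_as_filter_inputs"]


def load_hypermethylation_panel() -> pd.DataFrame:
    """The 10-gene hypermethylated-biomarker panel, gene-indexed."""
    ref = resources.files("nfmeta.data") / "mpnst_hypermethylation_panel.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="gene_id")


def panel_as_filter_inputs(
    panel: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Re-shape the panel into silencing-filter inputs.

    Returns ``(expression, methylation)``: the per-comparison expression
    meta tables (columns ``score``, ``logFC``) and the long-format promoter
    methylation table.
    """
    p = panel if panel is not None else load_hypermethylation_panel()
    expression = {
        MPNST_VS_NF: pd.DataFrame(
            {"score": p["score_mpnst_vs_nf"], "logFC": p["logfc_mpnst_vs_nf"]}
        ),
        MPNST_VS_CONTROL: pd.DataFrame(
            {"score": p["score_mpnst_vs_control"], "logFC": p["logfc_mpnst_vs_control"]}
        ),
    }
    rows = []
    for comp, col in ((MPNST_VS_NF, "nf"), (MPNST_VS_CONTROL, "control")):
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": p.index,
                    "comparison": comp,
                    "meth_logfc": p[f"meth_logfc_mpnst_vs_{col}"].to_numpy(),
                    "meth_adj_p": p[f"meth_adj_p_mpnst_vs_{col}"].to_numpy(),
                }
            )
        )
    methylation = pd.concat(rows, ignore_index=True)
    return expression, methylation
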