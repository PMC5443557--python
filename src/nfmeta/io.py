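"""TSV readers and writers for every pipeline table.

All tables are tab-separated with one header row; missing values are
written as ``NA``. The formats are deliberately spreadsheet-trivial:

* expression matrix — first column ``probe_id``, remaining columns samples
* sample sheet — ``sample_id``, ``group``
* probe map — ``probe_id``, ``gene_id``
* ortholog map — ``mouse_gene_id``, ``human_gene_id``
* genome annotation — ``gene_id``, ``chromosome``, ``arm``, ``band``
* methylation — ``gene_id``, ``comparison``, ``meth_logfc``, ``meth_adj_p``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .studies import ExpressionStudy

NA_REP = "NA"

__all__ = [
    "read_expression_study",
    "write_expression_study",
    "read_probe_map",
    "read_ortholog_map",
    "read_annotation",
    "read_methylation",
    "read_table",
    "write_table",
    "render_report_table",
]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA_REP])


def _read_two_column(path, key: str, value: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}, found {list(df.columns)}")
    s = df.set_index(key)[value]
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate {key} {dup!r}")
    return s


def read_probe_map(path) -> pd.Series:
    return _read_two_column(path, "probe_id", "gene_id")


def read_ortholog_map(path) -> pd.Series:
    return _read_two_column(path, "mouse_gene_id", "human_gene_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_REP]).set_index("gene_id")
    missing = {"chromosome", "arm", "band"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene IDs in annotation")
    return df


def read_methylation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    missing = {"gene_id", "comparison", "meth_logfc", "meth_adj_p"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: methylation table lacks columns {sorted(missing)}")
    return df


def read_expression_study(
    matrix_path,
    sample_sheet_path,
    probe_map_path,
    species: str,
    study_id: str | None = None,
    comparison: tuple[str, str] | None = None,
) -> ExpressionStudy:
    """Read and validate one study from its three files."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=[NA_REP])
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{matrix_path}: duplicated probe row {dup!r}")
    try:
        matrix = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{matrix_path}: non-numeric expression values") from exc

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ValueError(f"{sample_sheet_path}: expected column {col!r}")
    groups = sheet.set_index("sample_id")["group"]
    extra = [s for s in groups.index if s not in matrix.columns]
    if extra:
        raise ValueError(f"{sample_sheet_path}: samples absent from matrix: {extra}")

    probe_map = read_probe_map(probe_map_path)
    sid = study_id or Path(matrix_path).stem
    return ExpressionStudy(
        study_id=sid,
        species=species,
        matrix=matrix,
        groups=groups,
        probe_map=probe_map,
        comparison=comparison,
    )


def write_expression_study(study: ExpressionStudy, out_dir) -> dict[str, Path]:
    """Write matrix, sample sheet and probe map; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{study.study_id}_matrix.tsv",
        "samples": out / f"{study.study_id}_samples.tsv",
        "probe_map": out / f"{study.study_id}_probe_map.tsv",
    }
    m = study.matrix.copy()
    m.index.name = "probe_id"
    write_table(m, paths["matrix"])
    sheet = pd.DataFrame({"sample_id": study.groups.index, "group": study.groups.to_numpy()})
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    pm = pd.DataFrame({"probe_id": study.probe_map.index, "gene_id": study.probe_map.to_numpy()})
    pm.to_csv(paths["probe_map"], sep="\t", index=False)
    return paths


def render_report_table(meta: pd.DataFrame, bd_percent: bool = True) -> str:
    """Human-readable signature table: 2-decimal floats, BD ratio in percent.

    Machine outputs keep full precision; this rendering matches the
    conventional published precision.
    """
    view = meta.copy()
    if bd_percent and "bd_ratio" in view.columns:
        view["bd_ratio"] = 100.0 * view["bd_ratio"]
    floats = view.select_dtypes(include="float").columns
    view[floats] = view[floats].map(lambda v: f"{v:.2f}")
    return view.to_string()
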