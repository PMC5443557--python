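"""End-to-end orchestration: studies in, ranked signature out.

Stage order: ANOVA/FDR prefilter -> per-probe statistics -> probe scoring ->
probe-to-gene collapse -> within-study standardization -> ortholog mapping
(mouse) -> cross-study score combination -> effect-size medians -> BD ratio
-> sign-consistency screen -> top/bottom-decile signature filter ->
chromosome-region enrichment (-> hypermethylation silencing filter when a
methylation table is supplied). A run log records per-stage counts, which
are monotone non-increasing along the filter chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import destats, genomics, io, metaintegrate, scoring
from .studies import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "StudyEntry",
    "PipelineConfig",
    "RunLog",
    "MetaResult",
    "run_meta_analysis",
    "run_pipeline",
]


@dataclass
class AnalysisParams:
    """Thresholds and weights of the analysis stages."""

    prefilter_fdr: float = 0.05
    skip_prefilter: bool = False
    alpha: float = 0.05  # BH-adjusted significance gate of the score
    penalty_c: float = 1.0  # weight of the MAD penalty in the reliability factor
    prior_proportion: float = 0.01  # prior DE proportion of the B statistic
    mouse_weight: float = 1.0
    top_frac: float = 0.10
    min_abs_logfc: float = 0.99
    enrichment_level: str = "arm"
    methylation: genomics.MethylationThresholds = field(
        default_factory=genomics.MethylationThresholds
    )


@dataclass
class StudyEntry:
    """File locations of one study in a pipeline config."""

    study_id: str
    species: str
    matrix: str
    samples: str
    probe_map: str


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (YAML-compatible)."""

    studies: list[StudyEntry]
    comparison: tuple[str, str] = ("MPNST", "NF")
    ortholog_map: str | None = None
    annotation: str | None = None
    methylation: str | None = None
    out_dir: str = "results"
    seed: int = 0
    report_bd_percent: bool = True
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        paths = [p for e in self.studies for p in (e.matrix, e.samples, e.probe_map)]
        if len(set(paths)) != len(paths):
            raise ValueError("study file paths must be distinct")
        n_mouse = sum(e.species == "mouse" for e in self.studies)
        if n_mouse > 1:
            raise ValueError("at most one mouse study is supported")
        if n_mouse == 1 and not self.ortholog_map:
            raise ValueError("a mouse study requires an ortholog_map")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        studies = [StudyEntry(**e) for e in raw.pop("studies")]
        params = AnalysisParams(**raw.pop("params", {}))
        meth = raw.pop("methylation_thresholds", None)
        if meth:
            params.methylation = genomics.MethylationThresholds(**meth)
        if "comparison" in raw:
            raw["comparison"] = tuple(raw["comparison"])
        return cls(studies=studies, params=params, **raw)


@dataclass
class RunLog:
    """Per-stage counts, warnings and the configuration echo of one run."""

    seed: int = 0
    config: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "config": self.config,
                    "counts": self.counts,
                    "warnings": self.warnings,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class MetaResult:
    """Everything one pipeline run produces."""

    meta_table: pd.DataFrame  # unfiltered per-gene meta records
    signature: pd.DataFrame  # final ranked signature (score descending)
    study_scores: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame | None
    methylation_candidates: pd.DataFrame | None
    runlog: RunLog


def _score_one_study(
    study: ExpressionStudy, params: AnalysisParams, log: RunLog
) -> pd.DataFrame:
    sid = study.study_id
    log.counts[f"{sid}.probes_read"] = study.n_probes
    if not params.skip_prefilter:
        study = destats.anova_prefilter(study, fdr=params.prefilter_fdr)
    log.counts[f"{sid}.probes_after_prefilter"] = study.n_probes
    stats = destats.probe_stats(study, proportion=params.prior_proportion)
    genes = scoring.score_study(
        stats, study.probe_map, alpha=params.alpha, c=params.penalty_c
    )
    log.counts[f"{sid}.genes_after_collapse"] = genes.shape[0]
    return genes


def run_meta_analysis(
    studies: list[ExpressionStudy],
    ortholog_map: pd.Series | None = None,
    annotation: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    control_meta: pd.DataFrame | None = None,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> MetaResult:
    """Run the full meta-analysis on in-memory studies.

    ``control_meta`` optionally supplies the MPNST-vs-control expression
    meta table required by the methylation silencing filter; when absent the
    MPNST-vs-NF table is reused for that condition with a logged warning.
    """
    params = params or AnalysisParams()
    log = RunLog(seed=seed)
    if not studies:
        raise ValueError("at least one study is required")

    human_tables: list[pd.DataFrame] = []
    mouse_table: pd.DataFrame | None = None
    study_scores: dict[str, pd.DataFrame] = {}
    for study in studies:
        try:
            genes = _score_one_study(study, params, log)
        except Exception as exc:
            raise RuntimeError(f"stage scoring[{study.study_id}]: {exc}") from exc
        study_scores[study.study_id] = genes
        if study.species == "mouse":
            if mouse_table is not None:
                raise ValueError("at most one mouse study is supported")
            if ortholog_map is None or ortholog_map.empty:
                raise ValueError("a mouse study requires a non-empty ortholog map")
            mouse_table = metaintegrate.map_orthologs(genes, ortholog_map)
            log.counts[f"{study.study_id}.genes_after_ortholog_map"] = mouse_table.shape[0]
        else:
            human_tables.append(genes)
    if not human_tables:
        raise ValueError("at least one human study is required")

    meta = metaintegrate.integrate_studies(
        human_tables, mouse_table, mouse_weight=params.mouse_weight
    )
    log.counts["genes_meta"] = meta.shape[0]
    log.counts["genes_nonnull_score"] = int((meta["score"] != 0).sum())

    candidates = metaintegrate.consistency_screen(meta)
    log.counts["genes_after_consistency"] = candidates.shape[0]
    signature = metaintegrate.final_signature_filter(
        candidates, top_frac=params.top_frac, min_abs_logfc=params.min_abs_logfc
    )
    log.counts["signature_size"] = signature.shape[0]
    log.counts["signature_up"] = int((signature["score"] > 0).sum())
    log.counts["signature_down"] = int((signature["score"] < 0).sum())
    if signature.empty:
        log.warn("empty signature")

    if annotation is not None:
        ann_cols = annotation[["chromosome", "arm", "band"]]
        meta = meta.join(ann_cols, how="left")
        signature = signature.join(ann_cols, how="left")

    enrichment = None
    if annotation is not None and not signature.empty:
        enrichment = genomics.region_enrichment(
            signature.index, annotation, level=params.enrichment_level
        )

    meth_candidates = None
    if methylation is not None:
        if control_meta is None:
            log.warn(
                "no MPNST-vs-control meta table supplied; reusing the MPNST-vs-NF "
                "table for the control-comparison expression condition"
            )
            control_meta = meta
        meth_candidates = genomics.methylation_silencing_filter(
            {genomics.MPNST_VS_NF: meta, genomics.MPNST_VS_CONTROL: control_meta},
            methylation,
            thresholds=params.methylation,
        )
        log.counts["methylation_candidates"] = meth_candidates.shape[0]

    return MetaResult(
        meta_table=meta,
        signature=signature,
        study_scores=study_scores,
        enrichment=enrichment,
        methylation_candidates=meth_candidates,
        runlog=log,
    )


def run_pipeline(config: PipelineConfig) -> MetaResult:
    """File-based front end of :func:`run_meta_analysis`.

    Reads every input named in ``config``, runs the analysis, and writes
    the unfiltered meta table, the signature, per-study score tables, the
    enrichment table, methylation candidates and the run log under
    ``config.out_dir``. Fixed seed and inputs give bit-identical outputs.
    """
    studies = [
        io.read_expression_study(
            e.matrix,
            e.samples,
            e.probe_map,
            species=e.species,
            study_id=e.study_id,
            comparison=config.comparison,
        )
        for e in config.studies
    ]
    ortholog = io.read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
    annotation = io.read_annotation(config.annotation) if config.annotation else None
    methylation = io.read_methylation(config.methylation) if config.methylation else None

    result = run_meta_analysis(
        studies,
        ortholog_map=ortholog,
        annotation=annotation,
        methylation=methylation,
        params=config.params,
        seed=config.seed,
    )
    result.runlog.config = {
        "studies": [e.__dict__ for e in config.studies],
        "comparison": list(config.comparison),
        "out_dir": str(config.out_dir),
    }

    out = Path(config.out_dir)
    io.write_table(result.meta_table, out / "meta_table.tsv")
    io.write_table(result.signature, out / "signature.tsv")
    for sid, tab in result.study_scores.items():
        io.write_table(tab, out / f"study_scores_{sid}.tsv")
    if result.enrichment is not None:
        io.write_table(result.enrichment, out / "enrichment.tsv")
    if result.methylation_candidates is not None:
        io.write_table(result.methylation_candidates, out / "methylation_candidates.tsv")
    (out / "signature_report.txt").write_text(
        io.render_report_table(result.signature, bd_percent=config.report_bd_percent) + "\n"
    )
    result.runlog.to_yaml(out / "run_log.yaml")
    return result
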