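"""Synthetic multi-study, multi-species expression inputs with known truth.

The generator emulates the statistical structure the meta-analysis assumes:
several studies on different "platforms" (each covering its own random
subset of a shared gene universe, with one to a few probes per gene), two
phenotype groups whose means differ by a planted log2 effect for a chosen
fraction of genes, i.i.d. Gaussian replicate noise on the log2 scale, and
an optional mouse study connected through an ortholog map in which a
configurable fraction of the planted effects have their sign flipped —
the cross-species discordance the integration rules must reject. Matching
chromosome annotation and promoter-methylation tables can be generated so a
full pipeline run needs no external input, and a truth ledger records every
planted effect for recovery scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import MPNST_VS_CONTROL, MPNST_VS_NF, NF_VS_CONTROL
from .studies import ExpressionStudy

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_study_set",
    "generate_genome_annotation",
    "generate_methylation_table",
]

GROUP_A = "MPNST"
GROUP_B = "NF"

#: log2 s.d. of the probe-specific additive offset shared by both groups
PROBE_OFFSET_SD = 0.3


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the reference desk-scale cohort: four human studies
    plus one mouse study over a 1000-gene universe, 10% of genes planted as
    differential with |log2 effects| in [2, 4], five replicates per
    phenotype group, replicate noise of 0.5 on the log2 scale, and 10% of
    planted effects sign-flipped in the mouse.
    """

    n_genes: int = 1000
    n_studies_human: int = 4
    include_mouse: bool = True
    probes_per_gene_range: tuple[int, int] = (1, 3)
    platform_coverage: float = 0.8
    n_replicates_per_group: int = 5
    frac_de: float = 0.10
    effect_size_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.5
    mouse_signflip_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("platform_coverage", "frac_de", "mouse_signflip_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_studies_human", "n_replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.probes_per_gene_range
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene_range must satisfy 1 <= lo <= hi")
        lo, hi = self.effect_size_range
        if not (0.0 < lo <= hi):
            raise ValueError("effect_size_range lower bound must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frac_de > 0 and round(self.frac_de * self.n_genes) == 0:
            raise ValueError(
                f"frac_de={self.frac_de} with n_genes={self.n_genes} plants no "
                "differential genes; increase n_genes or frac_de"
            )

    @property
    def n_de(self) -> int:
        return round(self.frac_de * self.n_genes)


@dataclass
class PlantedTruth:
    """Ground-truth ledger: one row per gene of the human universe.

    Columns of ``table`` (gene-indexed): ``status`` (up/down/null),
    ``effect_human``, ``effect_mouse`` (signed log2 effects),
    ``sign_flipped_in_mouse``, ``mouse_gene_id``.
    """

    table: pd.DataFrame
    config: SyntheticConfig = field(repr=False)

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["status"] != "null"]

    @property
    def down_genes(self) -> pd.Index:
        return self.table.index[self.table["status"] == "down"]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_study(
    rng: np.random.Generator,
    study_id: str,
    species: str,
    gene_ids: np.ndarray,
    effects: pd.Series,
    baselines: pd.Series,
    cfg: SyntheticConfig,
) -> ExpressionStudy:
    n_cov = max(1, round(cfg.platform_coverage * gene_ids.size))
    covered = np.sort(rng.choice(gene_ids, size=n_cov, replace=False))
    lo, hi = cfg.probes_per_gene_range
    n_probes = rng.integers(lo, hi + 1, size=n_cov)

    probe_gene = np.repeat(covered, n_probes)
    probe_ids = [f"{study_id}_P{i:06d}" for i in range(1, probe_gene.size + 1)]
    offsets = rng.normal(0.0, PROBE_OFFSET_SD, size=probe_gene.size)

    base = baselines.loc[probe_gene].to_numpy() + offsets
    eff = effects.loc[probe_gene].to_numpy()
    nrep = cfg.n_replicates_per_group
    mean_a = base + eff  # group A carries the planted effect
    mean_b = base
    mat = np.concatenate(
        [
            np.repeat(mean_a[:, None], nrep, axis=1),
            np.repeat(mean_b[:, None], nrep, axis=1),
        ],
        axis=1,
    )
    if cfg.noise_sd > 0:
        mat = mat + rng.normal(0.0, cfg.noise_sd, size=mat.shape)
    samples = [f"{study_id}_{GROUP_A}_{k}" for k in range(1, nrep + 1)] + [
        f"{study_id}_{GROUP_B}_{k}" for k in range(1, nrep + 1)
    ]
    groups = pd.Series([GROUP_A] * nrep + [GROUP_B] * nrep, index=samples)
    matrix = pd.DataFrame(mat, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"), name="gene_id")
    return ExpressionStudy(
        study_id=study_id,
        species=species,
        matrix=matrix,
        groups=groups,
        probe_map=probe_map,
        comparison=(GROUP_A, GROUP_B),
    )


def generate_study_set(
    config: SyntheticConfig,
) -> tuple[list[ExpressionStudy], PlantedTruth, pd.Series]:
    """Generate the human studies, optional mouse study, truth and ortholog map.

    Returns ``(studies, truth, ortholog_map)`` where the mouse study, when
    present, is the last element of ``studies`` and ``ortholog_map`` maps
    mouse gene IDs to human gene IDs (empty Series when no mouse study).
    Identical configs (same seed) give bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_ids(cfg.n_genes))
    mouse_genes = np.array([g.replace("G", "mG", 1) for g in genes])
    ortholog_map = pd.Series(
        genes, index=pd.Index(mouse_genes, name="mouse_gene_id"), name="human_gene_id"
    )

    status = np.array(["null"] * cfg.n_genes, dtype=object)
    effect_h = np.zeros(cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=cfg.n_de)
    lo, hi = cfg.effect_size_range
    mags = rng.uniform(lo, hi, size=cfg.n_de)
    effect_h[de_idx] = signs * mags
    status[de_idx] = np.where(signs > 0, "up", "down")

    flipped = np.zeros(cfg.n_genes, dtype=bool)
    n_flip = round(cfg.mouse_signflip_frac * cfg.n_de)
    if n_flip > 0:
        flip_idx = rng.choice(de_idx, size=n_flip, replace=False)
        flipped[flip_idx] = True
    effect_m = np.where(flipped, -effect_h, effect_h)

    truth_table = pd.DataFrame(
        {
            "status": status,
            "effect_human": effect_h,
            "effect_mouse": effect_m,
            "sign_flipped_in_mouse": flipped,
            "mouse_gene_id": mouse_genes,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = PlantedTruth(table=truth_table, config=cfg)

    baselines = pd.Series(rng.uniform(5.0, 10.0, size=cfg.n_genes), index=genes)
    eff_h = pd.Series(effect_h, index=genes)

    studies: list[ExpressionStudy] = []
    for j in range(1, cfg.n_studies_human + 1):
        studies.append(
            _simulate_study(rng, f"HS{j}", "human", genes, eff_h, baselines, cfg)
        )
    if cfg.include_mouse:
        eff_m = pd.Series(effect_m, index=mouse_genes)
        base_m = pd.Series(baselines.to_numpy(), index=mouse_genes)
        studies.append(
            _simulate_study(rng, "MS1", "mouse", mouse_genes, eff_m, base_m, cfg)
        )
    if not cfg.include_mouse:
        ortholog_map = ortholog_map.iloc[0:0]
    return studies, truth, ortholog_map


def generate_genome_annotation(
    genes,
    n_chromosomes: int = 22,
    seed: int = 0,
    focus_genes=None,
    focus_region: str | None = None,
    focus_fraction: float = 1.0,
) -> pd.DataFrame:
    """Random gene -> (chromosome, arm, band) table.

    Bands are labelled cytogenetically (e.g. ``q21.3``), so band implies arm
    implies chromosome. ``focus_genes``/``focus_region`` optionally force a
    fraction of the given genes onto one region (e.g. ``"5q"`` or
    ``"5q21.3"``) to inject a planted enrichment signal.
    """
    gene_arr = np.asarray(list(genes), dtype=object)
    if gene_arr.size == 0:
        raise ValueError("gene list must be non-empty")
    if pd.Index(gene_arr).has_duplicates:
        raise ValueError("duplicate gene IDs in annotation input")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = rng.integers(1, n_chromosomes + 1, size=gene_arr.size).astype(str)
    arm = rng.choice(["p", "q"], size=gene_arr.size)
    major = rng.integers(1, 4, size=gene_arr.size)
    minor = rng.integers(1, 4, size=gene_arr.size)
    band = np.array([f"{a}{mj}.{mn}" for a, mj, mn in zip(arm, major, minor)], dtype=object)
    out = pd.DataFrame(
        {"chromosome": chrom, "arm": arm, "band": band},
        index=pd.Index(gene_arr, name="gene_id"),
    )
    if focus_genes is not None and focus_region is not None:
        focus = [g for g in focus_genes if g in out.index]
        n_place = round(focus_fraction * len(focus))
        placed = rng.choice(np.asarray(focus, dtype=object), size=n_place, replace=False)
        m = re.match(r"^([0-9XY]+)([pq].*)$", focus_region)
        if m is None:
            raise ValueError(f"cannot parse focus_region {focus_region!r}")
        f_chrom, rest = m.group(1), m.group(2)
        f_arm = rest[0]
        f_band = rest if len(rest) > 1 else f"{f_arm}1.1"
        out.loc[placed, ["chromosome", "arm", "band"]] = [f_chrom, f_arm, f_band]
    return out


def generate_methylation_table(
    truth: PlantedTruth,
    frac_hypermethylated_of_down: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Promoter methylation statistics emulating a MeDIP-seq comparison table.

    A stated fraction of the planted-down genes receive hypermethylation
    evidence (methylation logFC > 1.5 at adjusted p < 0.1) in both the
    malignant-vs-benign and malignant-vs-control comparisons; every other
    gene/comparison receives null-like values. Long format: gene_id,
    comparison, meth_logfc, meth_adj_p.
    """
    if not 0.0 <= frac_hypermethylated_of_down <= 1.0:
        raise ValueError("frac_hypermethylated_of_down must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.table.index.to_numpy()
    down = truth.down_genes.to_numpy()
    n_hyper = round(frac_hypermethylated_of_down * down.size)
    hyper = set(rng.choice(down, size=n_hyper, replace=False)) if n_hyper else set()

    rows = []
    for comp in (MPNST_VS_NF, MPNST_VS_CONTROL, NF_VS_CONTROL):
        is_hyper = np.array([g in hyper for g in genes]) if comp != NF_VS_CONTROL else np.zeros(
            genes.size, dtype=bool
        )
        lfc = np.where(
            is_hyper,
            rng.uniform(2.0, 4.0, size=genes.size),
            rng.normal(0.0, 0.5, size=genes.size),
        )
        adj_p = np.where(
            is_hyper,
            rng.uniform(1e-6, 0.09, size=genes.size),
            rng.uniform(0.15, 1.0, size=genes.size),
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "comparison": comp,
                    "meth_logfc": lfc,
                    "meth_adj_p": adj_p,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
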