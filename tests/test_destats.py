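"""Effect sizes, MAD penalty, BH adjustment, ANOVA prefilter, moderated stats."""

import math
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nfmeta.destats import (
    anova_prefilter,
    bh_adjust,
    compute_logfc,
    compute_logfc_m,
    compute_mad,
    moderated_stats,
    probe_stats,
)
from conftest import make_study

finite_logs = st.lists(
    st.floats(min_value=-8, max_value=8, allow_nan=False), min_size=1, max_size=6
)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([3, 5], [1, 1], 3.0),
        ([2, 2], [2, 2], 0.0),
        ([1.5], [0.5], 1.0),
    ],
)
def test_logfc_is_mean_difference(a, b, expected):
    assert compute_logfc(a, b) == pytest.approx(expected)


def test_logfc_random_case_matches_arithmetic_oracle():
    rng = np.random.default_rng(3)
    a, b = rng.normal(7, 1, 4), rng.normal(6, 1, 4)
    assert compute_logfc(a, b) == pytest.approx(sum(a) / 4 - sum(b) / 4)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        # pair log-ratios {1,1,3,3} -> linear {2,2,8,8} -> median 5
        ([2, 4], [1, 1], math.log2(5)),
        ([3], [1], 2.0),
        ([4, 4], [4, 4], 0.0),
    ],
)
def test_logfc_m_is_log2_of_median_linear_ratio(a, b, expected):
    assert compute_logfc_m(a, b) == pytest.approx(expected)


def test_logfc_m_enumeration_oracle():
    rng = np.random.default_rng(5)
    a, b = rng.normal(8, 1, 3), rng.normal(6, 1, 4)
    ratios = sorted(2 ** (x - y) for x in a for y in b)
    assert compute_logfc_m(a, b) == pytest.approx(math.log2(np.median(ratios)))


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([2, 4], [1, 1], 1.0),  # log ratios {1,1,3,3}: deviations all 1
        ([5, 5], [2, 2], 0.0),  # constant ratios
        ([3], [1], 0.0),  # single pair
    ],
)
def test_mad_of_cross_pair_ratios(a, b, expected):
    assert compute_mad(a, b) == pytest.approx(expected)


@pytest.mark.parametrize("func", [compute_logfc, compute_logfc_m, compute_mad])
def test_empty_vector_rejected(func):
    with pytest.raises(ValueError):
        func([], [1.0])


@settings(deadline=None, max_examples=60)
@given(a=finite_logs, b=finite_logs, shift=st.floats(-5, 5, allow_nan=False))
def test_effect_sizes_negate_under_swap_and_mad_is_shift_invariant(a, b, shift):
    assert compute_logfc(b, a) == pytest.approx(-compute_logfc(a, b), abs=1e-9)
    if (len(a) * len(b)) % 2 == 1:
        # the linear-scale midpoint of an even pair count is not exactly
        # antisymmetric (median of reciprocals != reciprocal of the midpoint)
        assert compute_logfc_m(b, a) == pytest.approx(-compute_logfc_m(a, b), abs=1e-9)
    a2 = [x + shift for x in a]
    b2 = [x + shift for x in b]
    assert compute_mad(a2, b2) == pytest.approx(compute_mad(a, b), abs=1e-9)


@settings(deadline=None, max_examples=30)
@given(a=st.floats(-8, 8, allow_nan=False), b=st.floats(-8, 8, allow_nan=False))
def test_logfc_m_equals_logfc_for_single_samples(a, b):
    assert compute_logfc_m([a], [b]) == pytest.approx(compute_logfc([a], [b]))


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_matches_hand_computation():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_adjusted_never_below_raw(random_study):
    tab = probe_stats(random_study)
    assert (tab["adj_p"] >= tab["p"] - 1e-12).all()
    assert tab["p"].between(0, 1).all() and tab["adj_p"].between(0, 1).all()


# ---------------------------------------------------------------------------
# ANOVA prefilter


def test_f_equals_t_squared(random_study):
    from nfmeta.destats import _two_group_f

    f, p = _two_group_f(random_study)
    a, b = random_study.group_matrices()
    t, pt = sps.ttest_ind(a.to_numpy(), b.to_numpy(), axis=1)
    np.testing.assert_allclose(f, t**2, rtol=1e-10)
    np.testing.assert_allclose(p, pt, rtol=1e-10)


def test_prefilter_keeps_effect_drops_flat():
    rng = np.random.default_rng(0)
    mat = np.full((40, 10), 6.0) + rng.normal(0, 0.1, (40, 10))
    mat[0, :5] += 3.0  # planted effect 3 at noise 0.1
    mat[1] = 6.0  # identical in every sample
    study = make_study(mat, 5, 5)
    kept = anova_prefilter(study, fdr=0.05).matrix.index
    assert "P000" in kept
    assert "P001" not in kept


def test_prefilter_requires_replicates():
    study = make_study(np.random.default_rng(1).normal(6, 1, (5, 3)), 1, 2)
    with pytest.raises(ValueError, match="skip_prefilter"):
        anova_prefilter(study)


# ---------------------------------------------------------------------------
# moderated statistics


def test_unmoderated_limit_equals_ordinary_t(random_study):
    res = moderated_stats(random_study, d0=0.0, s0_sq=1.0)
    a, b = random_study.group_matrices()
    t, p = sps.ttest_ind(a.to_numpy(), b.to_numpy(), axis=1)
    np.testing.assert_allclose(res.table["t"], t, rtol=1e-10)
    np.testing.assert_allclose(res.table["p"], p, rtol=1e-10)


def test_fully_shrunk_limit_scales_by_prior_sd(random_study):
    s0_sq = 0.4
    res = moderated_stats(random_study, d0=math.inf, s0_sq=s0_sq)
    a, b = random_study.group_matrices()
    coef = a.to_numpy().mean(axis=1) - b.to_numpy().mean(axis=1)
    su = math.sqrt(1 / a.shape[1] + 1 / b.shape[1])
    np.testing.assert_allclose(res.table["t"], coef / (su * math.sqrt(s0_sq)), rtol=1e-12)


def test_all_constant_matrix_rejected():
    study = make_study(np.full((10, 8), 5.0), 4, 4)
    with pytest.raises(ValueError):
        moderated_stats(study)


def test_b_statistic_matches_direct_formula_transcription():
    """Six-probe worked case: scalar re-evaluation of the log-odds formula."""
    rng = np.random.default_rng(9)
    mat = rng.normal(7, 1, (6, 8))
    mat[0, :4] += 3
    study = make_study(mat, 4, 4)
    res = moderated_stats(study)
    a, b = study.group_matrices()
    na, nb = 4, 4
    su2 = 1 / na + 1 / nb
    for i, probe in enumerate(res.table.index):
        row = mat[i]
        s2 = (np.var(row[:4], ddof=1) * (na - 1) + np.var(row[4:], ddof=1) * (nb - 1)) / (
            na + nb - 2
        )
        s2_post = (res.d0 * res.s0_sq + (na + nb - 2) * s2) / (res.d0 + na + nb - 2)
        t = (row[:4].mean() - row[4:].mean()) / math.sqrt(su2 * s2_post)
        df = res.d0 + na + nb - 2
        r = (su2 + res.var_prior) / su2
        kernel = (1 + df) / 2 * math.log((t**2 + df) / (t**2 / r + df))
        lods = math.log(res.proportion / (1 - res.proportion)) - math.log(r) / 2 + kernel
        assert res.table.loc[probe, "B"] == pytest.approx(lods, rel=1e-10)
        assert res.table.loc[probe, "t"] == pytest.approx(t, rel=1e-10)


def test_moderated_stats_match_limma_reference(tmp_path):
    """Independent oracle: limma's eBayes on the same matrix via Rscript."""
    rng = np.random.default_rng(42)
    n, na, nb = 120, 4, 4
    mat = rng.uniform(5, 10, (n, 1)) + rng.normal(
        0, rng.uniform(0.2, 1.0, n)[:, None], (n, na + nb)
    )
    mat[:12, :na] += 2.0
    study = make_study(mat, na, nb)
    fixture = tmp_path / "m.tsv"
    study.matrix.to_csv(fixture, sep="\t")
    rfile = tmp_path / "oracle.R"
    rfile.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{fixture}", row.names=1))
            design <- cbind(Intercept=1, A=c(rep(1,{na}), rep(0,{nb})))
            fit <- eBayes(lmFit(x, design), proportion=0.01)
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], B=fit$lods[,2])
            write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
            """
        )
    )
    subprocess.run(
        ["Rscript", str(rfile)], check=True, capture_output=True, text=True
    )
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
    res = moderated_stats(study)
    for col in ("t", "p", "B"):
        np.testing.assert_allclose(res.table[col], ref[col], rtol=1e-6, atol=1e-8)


def test_probe_stats_antisymmetric_under_phenotype_swap(random_study):
    fwd = probe_stats(random_study)
    rev = probe_stats(random_study.swapped())
    for col in ("logFC", "logFC_m", "t"):
        np.testing.assert_allclose(rev[col], -fwd[col], atol=1e-10)
    np.testing.assert_allclose(rev["p"], fwd["p"], atol=1e-12)
    np.testing.assert_allclose(rev["MAD"], fwd["MAD"], atol=1e-12)
    np.testing.assert_allclose(rev["variance"], fwd["variance"], atol=1e-12)
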