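"""Score combination, effect-size medians, BD ratio, final filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfmeta.metaintegrate import (
    bd_ratio,
    combine_scores,
    consistency_screen,
    final_signature_filter,
    integrate_studies,
    map_orthologs,
    median_effect_sizes,
)


def _score_table(scores: dict, variance: float | dict = 1.0, **extra) -> pd.DataFrame:
    idx = pd.Index(list(scores), name="gene_id")
    var = [variance[g] if isinstance(variance, dict) else variance for g in idx]
    df = pd.DataFrame({"s_std": list(scores.values()), "variance": var}, index=idx)
    for col, vals in extra.items():
        df[col] = [vals[g] for g in idx]
    return df


# ---------------------------------------------------------------------------
# ortholog mapping


def test_one_to_one_map_preserves_rows():
    tab = _score_table({"mG1": 0.5, "mG2": -0.3})
    out = map_orthologs(tab, pd.Series({"mG1": "G1", "mG2": "G2"}))
    assert sorted(out.index) == ["G1", "G2"]
    assert out.loc["G1", "s_std"] == 0.5


def test_unmapped_mouse_genes_dropped():
    tab = _score_table({"mG1": 0.5, "mGX": 0.9})
    out = map_orthologs(tab, pd.Series({"mG1": "G1"}))
    assert list(out.index) == ["G1"]


def test_many_to_one_resolved_by_variance():
    tab = _score_table({"mG1": 0.5, "mG2": -0.3}, variance={"mG1": 1.0, "mG2": 4.0})
    out = map_orthologs(tab, pd.Series({"mG1": "G1", "mG2": "G1"}))
    assert out.loc["G1", "mouse_gene_id"] == "mG2"


def test_empty_map_rejected():
    with pytest.raises(ValueError):
        map_orthologs(_score_table({"mG1": 0.5}), pd.Series(dtype=object))


# ---------------------------------------------------------------------------
# score combination


def test_mouse_added_when_signs_agree():
    human = [_score_table({"G1": s}) for s in (0.6, 0.7, 0.5, 0.8)]
    mouse = _score_table({"G1": 0.4})
    out = combine_scores(human, mouse)
    assert out.loc["G1", "score"] == pytest.approx(3.0)
    assert out.loc["G1", "studies"] == 5
    assert out.loc["G1", "mouse"] == 1


def test_mouse_discarded_on_sign_disagreement():
    human = [_score_table({"G1": s}) for s in (0.6, 0.7, 0.5, 0.8)]
    mouse = _score_table({"G1": -0.4})
    out = combine_scores(human, mouse)
    assert out.loc["G1", "score"] == pytest.approx(2.6)
    assert out.loc["G1", "mouse"] == 0
    assert out.loc["G1", "studies"] == 4


def test_mouse_excluded_when_human_score_null():
    human = [_score_table({"G1": 0.0})]
    mouse = _score_table({"G1": 0.4})
    out = combine_scores(human, mouse)
    assert out.loc["G1", "score"] == 0.0
    assert out.loc["G1", "mouse"] == 0


def test_mouse_only_genes_ignored():
    human = [_score_table({"G1": 0.5})]
    mouse = _score_table({"G2": 0.9})
    out = combine_scores(human, mouse)
    assert "G2" not in out.index


def test_mouse_weight_applies_to_mouse_term_only():
    human = [_score_table({"G1": 1.0})]
    mouse = _score_table({"G1": 0.5})
    out = combine_scores(human, mouse, mouse_weight=0.5)
    assert out.loc["G1", "score"] == pytest.approx(1.25)


def test_no_human_tables_rejected():
    with pytest.raises(ValueError):
        combine_scores([])


# ---------------------------------------------------------------------------
# effect-size medians


@pytest.mark.parametrize(
    "human, mouse, expected",
    [
        ([1.0, 2.0, 3.0], None, 2.0),
        ([1.0, 2.0, 3.0], -1.5, 2.0),  # sign conflict: mouse ignored
        ([1.0, 3.0], 2.0, 2.0),  # sign agrees: median of {1,3,2}
        ([-1.0, -3.0], -2.0, -2.0),
    ],
)
def test_median_effect_sizes_with_mouse_rule(human, mouse, expected):
    assert median_effect_sizes(human, mouse) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# BD ratio


def _bd_oracle(scores) -> float:
    """Direct Bhattacharyya-coefficient summation."""
    s = [abs(x) for x in scores]
    n = len(s)
    if n == 1 or sum(s) == 0:
        return 0.0
    total = sum(s)
    bc = sum(math.sqrt((x / total) * (1.0 / n)) for x in s)
    return -math.log(bc) / (0.5 * math.log(n))


@pytest.mark.parametrize(
    "scores, expected",
    [
        ([1, 1, 1, 1], 0.0),  # equal contributions
        ([1, 0, 0], 1.0),  # all mass on one study = maximal disparity
        ([0.5, 0.5, 0], 0.3690702464285425),
        ([0.7], 0.0),  # single-study convention
        ([0, 0, 0], 0.0),  # all-null convention
    ],
)
def test_bd_ratio_examples(scores, expected):
    assert bd_ratio(scores) == pytest.approx(expected, abs=1e-12)


def test_bd_ratio_equals_brute_force_on_grid():
    """All score compositions over a small grid for n <= 5 studies."""
    grid = [0.0, 0.2, 0.5, 1.0]
    for n in range(1, 6):
        for combo in itertools.product(grid, repeat=n):
            assert bd_ratio(combo) == pytest.approx(_bd_oracle(combo), abs=1e-12)


@settings(deadline=None, max_examples=80)
@given(
    scores=st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=5),
    scale=st.floats(0.01, 100, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_bd_ratio_invariances(scores, scale, seed):
    base = bd_ratio(scores)
    perm = np.random.default_rng(seed).permutation(scores)
    assert bd_ratio(perm) == pytest.approx(base, abs=1e-12)
    assert bd_ratio([scale * s for s in scores]) == pytest.approx(base, abs=1e-10)
    assert 0.0 <= base <= 1.0


def test_bd_ratio_empty_rejected():
    with pytest.raises(ValueError):
        bd_ratio([])


# ---------------------------------------------------------------------------
# final filters


def _records(score, logfc) -> pd.DataFrame:
    idx = pd.Index([f"G{i:04d}" for i in range(len(score))], name="gene_id")
    return pd.DataFrame({"score": score, "logFC": logfc}, index=idx)


def test_consistency_screen_removes_sign_conflicts_and_nulls():
    rec = _records([1.2, 1.2, 0.0, -0.5], [-0.3, 2.0, 1.0, -1.0])
    out = consistency_screen(rec)
    assert list(out.index) == ["G0001", "G0003"]


def test_decile_cut_takes_exactly_ten_percent():
    rng = np.random.default_rng(1)
    rec = _records(rng.uniform(0.1, 3, 500), np.full(500, 2.0))
    sig = final_signature_filter(rec)
    assert sig.shape[0] == 50
    # the retained are exactly the 50 highest scores
    assert sig["score"].min() >= rec["score"].sort_values(ascending=False).iloc[49]


def test_low_logfc_excluded_even_in_top_decile():
    score = np.linspace(3, 0.1, 100)
    logfc = np.full(100, 2.0)
    logfc[0] = 0.5  # top-ranked gene with small median logFC
    sig = final_signature_filter(_records(score, logfc))
    assert "G0000" not in sig.index
    assert sig.shape[0] == 9


def test_all_small_logfc_gives_empty_signature():
    rec = _records([2.0, -2.0], [0.9, -0.9])
    assert final_signature_filter(rec).empty


def test_signature_respects_size_bound_and_order():
    rng = np.random.default_rng(3)
    score = np.concatenate([rng.uniform(0.1, 3, 137), -rng.uniform(0.1, 3, 83)])
    logfc = np.sign(score) * rng.uniform(0.2, 4, 220)
    sig = final_signature_filter(_records(score, logfc))
    n_pos = math.ceil(0.1 * 137)
    n_neg = math.ceil(0.1 * 83)
    assert sig.shape[0] <= n_pos + n_neg
    assert (sig["score"].to_numpy() == np.sort(sig["score"].to_numpy())[::-1]).all()
    assert (sig["logFC"].abs() > 0.99).all()
    assert (np.sign(sig["score"]) == np.sign(sig["logFC"])).all()


# ---------------------------------------------------------------------------
# integrate_studies


def test_integrate_studies_assembles_meta_columns():
    human = [
        _score_table({"G1": 0.5, "G2": -0.4}, logFC={"G1": 2.0, "G2": -1.0},
                     logFC_m={"G1": 2.2, "G2": -1.1}),
        _score_table({"G1": 1.0}, logFC={"G1": 3.0}, logFC_m={"G1": 3.1}),
    ]
    mouse = _score_table({"G1": 0.5}, logFC={"G1": 1.0}, logFC_m={"G1": 1.2})
    meta = integrate_studies(human, mouse)
    assert meta.loc["G1", "score"] == pytest.approx(2.0)
    assert meta.loc["G1", "studies"] == 3
    assert meta.loc["G1", "mouse"] == 1
    assert meta.loc["G1", "logFC"] == pytest.approx(2.0)  # median of {2,3,1}
    assert meta.loc["G1", "bd_ratio"] == pytest.approx(_bd_oracle([0.5, 1.0, 0.5]))
    # G2: single study -> forced 0
    assert meta.loc["G2", "bd_ratio"] == 0.0
    assert meta.loc["G2", "studies"] == 1


def test_single_nonnull_among_represented_studies_gives_ratio_one():
    human = [
        _score_table({"G1": 0.8}, logFC={"G1": 2.0}, logFC_m={"G1": 2.0}),
        _score_table({"G1": 0.0}, logFC={"G1": 0.1}, logFC_m={"G1": 0.1}),
        _score_table({"G1": 0.0}, logFC={"G1": 0.2}, logFC_m={"G1": 0.2}),
    ]
    meta = integrate_studies(human)
    assert meta.loc["G1", "studies"] == 3
    assert meta.loc["G1", "bd_ratio"] == pytest.approx(1.0)
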