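"""Activity models: ratiometric rule, background regression, FDR, rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from starrcall.activity import (
    DegenerateDesignError,
    activity_table,
    anova_groups,
    bh_adjust,
    empirical_fdr,
    fisher_2x2,
    fit_background_model,
    ratiometric_summary,
    score_activity,
    select_training_set,
    wilcoxon_rank_sum,
)
from starrcall.catalog import AmpliconCatalog
from starrcall.qc import compute_proportions


def _sheet(n_reps=2):
    rows = [(f"DNA_{r}", "DNA", r, "") for r in range(1, n_reps + 1)]
    rows += [(f"RNA_{r}", "RNA", r, "") for r in range(1, n_reps + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "kind", "replicate", "technical_of"])


# ---------------------------------------------------------------------------
# ratiometric model
# ---------------------------------------------------------------------------

def test_ratiometric_identical_rna_dna_not_called():
    counts = pd.DataFrame(
        {"DNA_1": [100, 200], "DNA_2": [50, 75], "RNA_1": [100, 200], "RNA_2": [50, 75]},
        index=["a1", "a2"],
    )
    ratios, summary = ratiometric_summary(counts, _sheet(2))
    assert np.allclose(ratios, 1.0)
    assert (summary["ratio_sd"] == 0).all()
    assert not summary["ratiometric_call"].any()


def test_ratiometric_call_rule():
    # constant ratio 1.6 across replicates: call; sd >= mean: no call
    summary = pd.DataFrame({"ratio_mean": [1.6, 1.6], "ratio_sd": [0.0, 1.7]})
    call = (summary["ratio_mean"] > 1.5) & (summary["ratio_sd"] < summary["ratio_mean"])
    assert call.tolist() == [True, False]


def test_ratiometric_stabilizer_damps_low_counts():
    """The 1000-count stabilizer pulls low-count ratios toward 1."""
    counts = pd.DataFrame(
        {"DNA_1": [10, 100_000, 1_000_000], "RNA_1": [40, 400_000, 1_000_000],
         "DNA_2": [10, 100_000, 1_000_000], "RNA_2": [40, 400_000, 1_000_000]},
        index=["low", "high", "filler"],
    )
    _, summary = ratiometric_summary(counts, _sheet(2))
    # raw ratio is 4x for both, but only the abundant amplicon keeps it
    assert summary.loc["low", "ratio_mean"] < 1.5
    assert summary.loc["high", "ratio_mean"] > 3.0


def test_ratiometric_excludes_technical_replicate():
    counts = pd.DataFrame(
        {"DNA_1": [1000], "RNA_1": [4000], "DNA_2": [1000], "RNA_2": [4000],
         "RNA_2_tech": [0]},
        index=["a1"],
    )
    sheet = _sheet(2)
    sheet = pd.concat(
        [sheet, pd.DataFrame([("RNA_2_tech", "RNA", 2, "RNA_2")], columns=sheet.columns)],
        ignore_index=True,
    )
    ratios, _ = ratiometric_summary(counts, sheet)
    assert list(ratios.columns) == ["rep1", "rep2"]


@pytest.mark.parametrize("n,expected", [(10, 8), (308, 248), (247, 199)])
def test_training_set_floor_rule(n, expected):
    s = pd.Series(np.arange(n, dtype=float), index=[f"a{i:04d}" for i in range(n)])
    assert len(select_training_set(s)) == expected


def test_training_set_zero_trim_is_identity():
    s = pd.Series(np.arange(20, dtype=float), index=[f"a{i}" for i in range(20)])
    assert set(select_training_set(s, trim_fraction=0.0)) == set(s.index)


def test_training_set_tie_break_deterministic():
    s = pd.Series(1.0, index=[f"a{i}" for i in range(20)])
    assert list(select_training_set(s)) == list(select_training_set(s.iloc[::-1]))


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

def _activity_frame(log2_dna, gc, log2_rna):
    ids = [f"a{i:03d}" for i in range(len(gc))]
    table = pd.DataFrame(
        {
            "amplicon_id": ids,
            "chrom": "chr1",
            "start": np.arange(len(gc)) * 1000,
            "end": np.arange(len(gc)) * 1000 + 900,
            "group": "GWAS",
            "gc": gc,
            "ascertained_enhancer": False,
        }
    )
    catalog = AmpliconCatalog(table)
    act = pd.DataFrame(
        {"mean_dna_prop": np.exp2(log2_dna), "mean_rna_prop": np.exp2(log2_rna)},
        index=pd.Index(ids),
    )
    return catalog, act


def test_ols_recovers_noiseless_coefficients(rng):
    x = rng.normal(-11, 1.0, 80)
    gc = rng.uniform(0.3, 0.7, 80)
    y = 0.9 * x + 0.5 * gc + 0.1
    catalog, act = _activity_frame(x, gc, y)
    fit = fit_background_model(act, catalog, act.index)
    assert fit.slope_dna == pytest.approx(0.9, abs=1e-9)
    assert fit.coeff_gc == pytest.approx(0.5, abs=1e-9)
    assert fit.intercept == pytest.approx(0.1, abs=1e-9)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)


def test_constant_gc_is_degenerate(rng):
    x = rng.normal(-11, 1.0, 40)
    catalog, act = _activity_frame(x, np.full(40, 0.5), x)
    with pytest.raises(DegenerateDesignError):
        fit_background_model(act, catalog, act.index)


def test_score_activity_z_to_p(rng):
    x = rng.normal(-11, 1.0, 200)
    gc = rng.uniform(0.3, 0.7, 200)
    y = 0.9 * x + 0.5 * gc + rng.normal(0, 0.3, 200)
    catalog, act = _activity_frame(x, gc, y)
    fit = fit_background_model(act, catalog, act.index)
    scores = score_activity(fit, act, catalog)
    assert np.isclose(scores["z"].mean(), 0, atol=1e-9)
    assert np.isclose(scores["z"].std(ddof=1), 1, atol=1e-9)
    # p is the upper-tail normal probability of z
    assert scores["p_model"].to_numpy() == pytest.approx(
        stats.norm.sf(scores["z"].to_numpy())
    )
    near_zero = scores.iloc[(scores["z"].abs()).argsort()[:1]]
    assert abs(near_zero["p_model"].iloc[0] - 0.5) < 0.1


def test_identical_counts_get_identical_scores():
    counts = pd.DataFrame(
        {
            "DNA_1": [1000] * 2 + list(range(300, 330)),
            "DNA_2": [1000] * 2 + list(range(300, 330)),
            "RNA_1": [1500] * 2 + list(range(280, 340, 2)),
            "RNA_2": [1500] * 2 + list(range(280, 340, 2)),
        },
        index=["dup1", "dup2"] + [f"x{i}" for i in range(30)],
    )
    gc = np.linspace(0.3, 0.7, 32)
    table = pd.DataFrame(
        {
            "amplicon_id": counts.index,
            "chrom": "chr1",
            "start": np.arange(32) * 1000,
            "end": np.arange(32) * 1000 + 900,
            "group": "GWAS",
            "gc": np.r_[0.5, 0.5, gc[2:]],
            "ascertained_enhancer": False,
        }
    )
    catalog = AmpliconCatalog(table)
    result, _ = activity_table(counts, _sheet(2), catalog)
    r = result.set_index("amplicon_id")
    for col in ("ratio_mean", "residual", "z", "p_model", "q_model", "p_wilcoxon"):
        assert r.loc["dup1", col] == r.loc["dup2", col]


# ---------------------------------------------------------------------------
# empirical tail-area FDR
# ---------------------------------------------------------------------------

def test_empirical_fdr_outlier_example():
    """One z=3 among 100 standard-normal grid placeholders."""
    placeholders = stats.norm.ppf((np.arange(100) + 0.5) / 100)
    z = np.concatenate([placeholders, [3.0]])
    q = empirical_fdr(z)
    # independent evaluation of the stated estimator
    neg = z[z <= 0]
    sigma = math.sqrt(np.mean(neg ** 2))
    expected = min(1.0, 101 * stats.norm.sf(3.0 / sigma) / 1)
    assert q[-1] == pytest.approx(expected)
    # and, at the stated sigma-hat = 1, approximately 101*(1-Phi(3))
    assert q[-1] == pytest.approx(101 * stats.norm.sf(3.0), rel=0.1)


def test_empirical_fdr_monotone_and_bounded(rng):
    z = rng.normal(0, 1, 500)
    q = empirical_fdr(z)
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(z)
    assert (np.diff(q[order]) <= 1e-12).all()


def test_empirical_fdr_null_control(rng):
    """On null z-scores, few amplicons fall below q<0.1."""
    z = rng.standard_normal(2000)
    q = empirical_fdr(z)
    assert (q < 0.1).mean() <= 0.1 * 1.1


def test_empirical_fdr_needs_enough_values():
    with pytest.raises(ValueError):
        empirical_fdr(np.zeros(5))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dna,rna,expected",
    [([1, 2], [3, 4], 1 / 6), ([1, 2, 3, 4], [5, 6, 7, 8], 1 / 70)],
)
def test_wilcoxon_separated_examples(dna, rna, expected):
    assert wilcoxon_rank_sum(dna, rna).p_value == pytest.approx(expected)


def test_wilcoxon_identical_groups_uninformative():
    res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value >= 0.5
    assert not res.shift_positive


def _enumeration_oracle(dna, rna):
    combined = np.concatenate([dna, rna])
    ranks = stats.rankdata(combined)
    obs = ranks[len(dna):].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), len(rna)):
        total += 1
        if ranks[list(idx)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


@settings(deadline=None, max_examples=60)
@given(
    st.lists(st.integers(0, 6), min_size=2, max_size=5),
    st.lists(st.integers(0, 6), min_size=2, max_size=5),
)
def test_wilcoxon_matches_enumeration_with_ties(dna, rna):
    p = wilcoxon_rank_sum(dna, rna).p_value
    assert p == pytest.approx(_enumeration_oracle(np.array(dna, float), np.array(rna, float)))


def test_wilcoxon_shift_bound_positive_for_strong_separation():
    res = wilcoxon_rank_sum([1, 2, 3, 4, 5, 6], [11, 12, 13, 14, 15, 16])
    assert res.shift_positive and res.shift_lower_bound > 0


def test_wilcoxon_large_sample_close_to_exact():
    rng = np.random.default_rng(0)
    dna = rng.normal(0, 1, 7)
    rna = rng.normal(1.0, 1, 7)  # combined n = 14 > 12: normal approximation
    p_norm = wilcoxon_rank_sum(dna, rna).p_value
    p_exact = _enumeration_oracle(dna, rna)
    assert p_norm == pytest.approx(p_exact, abs=0.02)


# ---------------------------------------------------------------------------
# BH, ANOVA, Fisher
# ---------------------------------------------------------------------------

def test_bh_examples():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


@settings(deadline=None, max_examples=40)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_order_invariant(p):
    q = bh_adjust(p)
    perm = np.random.RandomState(0).permutation(len(p))
    q_perm = bh_adjust(np.asarray(p)[perm])
    assert q_perm == pytest.approx(q[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_anova_closed_form_example():
    f, p = anova_groups([1, 2, 3, 4], ["g1", "g1", "g2", "g2"])
    assert f == pytest.approx(8.0)
    assert p == pytest.approx(stats.f.sf(8.0, 1, 2))
    f0, p0 = anova_groups([1, 2, 1, 2], ["g1", "g1", "g2", "g2"])
    assert f0 == pytest.approx(0.0) and p0 == pytest.approx(1.0)
    f_shift, _ = anova_groups([11, 12, 13, 14], ["g1", "g1", "g2", "g2"])
    assert f_shift == pytest.approx(8.0)


def test_anova_rejects_singleton_group():
    with pytest.raises(ValueError):
        anova_groups([1, 2, 3], ["a", "a", "b"])


def test_fisher_ascertainment_tables():
    """The two enhancer-ascertainment contingency tables and their one-tailed tests."""
    odds, p = fisher_2x2(20, 106, 21, 161)
    assert odds == pytest.approx(1.45, abs=0.005)
    assert p == pytest.approx(0.176, abs=0.001)
    odds2, p2 = fisher_2x2(12, 114, 5, 177)
    assert odds2 == pytest.approx(3.73, abs=0.005)
    assert p2 == pytest.approx(0.011, abs=0.001)


def test_fisher_small_table_and_zero_margin():
    odds, p = fisher_2x2(1, 1, 1, 1)
    assert odds == pytest.approx(1.0) and p == pytest.approx(5 / 6)
    odds_inf, p_inf = fisher_2x2(3, 0, 1, 5)
    assert math.isinf(odds_inf) and 0 < p_inf <= 1


# ---------------------------------------------------------------------------
# model concordance on spiked simulations
# ---------------------------------------------------------------------------

def test_residual_and_ratio_rankings_agree_in_top_decile(small_dataset):
    _, catalog, _, counts, samples = small_dataset
    table, _ = activity_table(counts, samples, catalog)
    k = len(table) // 10
    top_z = set(table.nlargest(k, "z")["amplicon_id"])
    top_ratio = set(
        table.assign(lr=np.log2(table["ratio_mean"])).nlargest(k, "lr")["amplicon_id"]
    )
    assert len(top_z & top_ratio) / k >= 0.9
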