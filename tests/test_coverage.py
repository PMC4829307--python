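"""Coverage medians, normalization, regressions, speed classes — checked
against independent brute-force/closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from splicestep import coverage as cov
from splicestep.synthetic import SimulationConfig, emit_read_pairs, simulate_gene, simulate_transcripts


# ---- independent oracles --------------------------------------------------


def sort_median(values):
    """Brute-force median: sort, take central value or mean of central pair."""
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def ols_closed_form(x, y):
    """Textbook least-squares slope/intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return b, y.mean() - b * x.mean()


def pearson_formula(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))


# ---- median ---------------------------------------------------------------


@pytest.mark.parametrize(
    "depths,expected",
    [([0, 0, 10, 20, 30], 10), ([4, 6], 5), ([7], 7), ([0, 0, 0, 5], 0)],
)
def test_median_conventions(depths, expected):
    assert cov.median_feature_coverage(np.array(depths)) == expected


def test_median_matches_sort_oracle_large():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 500, 10_000)
    assert abs(cov.median_feature_coverage(vals) - sort_median(vals)) < 1e-10


def test_fully_masked_feature_errors():
    with pytest.raises(cov.CoverageError, match="no coverage basis"):
        cov.median_feature_coverage(np.array([]))


# ---- normalization --------------------------------------------------------


def _table(exon_medians, intron_medians):
    rows = [
        {"feature": "exon", "index": i + 1, "fully_masked": False, "raw_median": v}
        for i, v in enumerate(exon_medians)
    ] + [
        {"feature": "intron", "index": i + 1, "fully_masked": False, "raw_median": v}
        for i, v in enumerate(intron_medians)
    ]
    return pd.DataFrame(rows)


def test_normalization_worked_example():
    # sample A: exon mean 200; sample B: exon mean 50 -> grand mean 125
    # normalized(A, intron) = 180 * 125/200
    tabs = {"A": _table([200, 200], [180]), "B": _table([50, 50], [40])}
    norm = cov.normalize_coverage(tabs)
    a = norm[(norm.sample_id == "A") & (norm.feature == "intron")].normalized_median.iloc[0]
    assert a == pytest.approx(180 * 125 / 200)


def test_single_sample_normalization_is_identity():
    tabs = {"only": _table([100, 120], [80, 90])}
    norm = cov.normalize_coverage(tabs)
    got = norm[norm.feature == "intron"].normalized_median.tolist()
    assert got == pytest.approx([80, 90])


@given(scale=st.floats(0.25, 8.0))
@settings(deadline=None, max_examples=25)
def test_normalization_scale_invariance(scale):
    """Multiplying one sample's depths by a constant leaves its normalized
    medians unchanged (reference depth pinned); with the default reference
    the same rescaling only moves the common unit, never the ratios."""
    base_e, base_i = [100.0, 140.0], [80.0, 200.0, 95.0]
    tabs = {
        "ref": _table([90.0, 110.0], [70.0, 150.0, 100.0]),
        "s": _table(base_e, base_i),
    }
    tabs_scaled = {
        "ref": tabs["ref"],
        "s": _table([v * scale for v in base_e], [v * scale for v in base_i]),
    }
    n1 = cov.normalize_coverage(tabs, reference_depth=100.0)
    n2 = cov.normalize_coverage(tabs_scaled, reference_depth=100.0)
    for norm in (n1, n2):
        norm.sort_values(["sample_id", "feature", "index"], inplace=True)
    v1 = n1[n1.sample_id == "s"].normalized_median.values
    v2 = n2[n2.sample_id == "s"].normalized_median.values
    assert np.allclose(v1, v2)
    # default (grand-mean) reference: a rescaled sample shifts every value by
    # one common factor, so all cross-feature ratios are unchanged
    d1 = cov.normalize_coverage(tabs).sort_values(["sample_id", "feature", "index"])
    d2 = cov.normalize_coverage(tabs_scaled).sort_values(["sample_id", "feature", "index"])
    ratio = d2.normalized_median.values / d1.normalized_median.values
    assert np.allclose(ratio, ratio[0])


def test_samples_at_two_depths_normalize_identically():
    """Two samples whose depths differ by an exact factor 2 from the same
    truth get identical normalized values."""
    truth_e, truth_i = [100.0, 140.0], [80.0, 200.0, 95.0]
    tabs = {
        "x1": _table(truth_e, truth_i),
        "x2": _table([2 * v for v in truth_e], [2 * v for v in truth_i]),
    }
    norm = cov.normalize_coverage(tabs)
    a = norm[norm.sample_id == "x1"].sort_values(["feature", "index"]).normalized_median.values
    b = norm[norm.sample_id == "x2"].sort_values(["feature", "index"]).normalized_median.values
    assert np.allclose(a, b)


def test_zero_exon_coverage_sample_rejected():
    with pytest.raises(cov.CoverageError, match="rejected"):
        cov.normalize_coverage({"bad": _table([0.0, 0.0], [10.0])})


# ---- regressions ----------------------------------------------------------


def test_gc_regression_flat_and_planted():
    gc = np.linspace(0.3, 0.6, 40)
    flat = cov.gc_bias_regression(gc, np.full(40, 100.0))
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(1)
    y = 100 + 50 * gc + rng.normal(0, 1.0, 40)
    reg = cov.gc_bias_regression(gc, y)
    b_oracle, a_oracle = ols_closed_form(gc, y)
    assert reg.slope == pytest.approx(b_oracle, abs=1e-10)
    assert reg.intercept == pytest.approx(a_oracle, abs=1e-10)
    # planted slope inside the OLS confidence interval
    se = stats.linregress(gc, y).stderr
    assert abs(reg.slope - 50) < 3 * se


def test_degenerate_regressions():
    assert cov.gc_bias_regression(np.array([0.4, 0.5]), np.array([1.0, 2.0])).degenerate
    assert cov.gc_bias_regression(np.full(10, 0.5), np.arange(10.0)).degenerate


def test_positional_bias_monotone_and_flat():
    flat = cov.positional_bias_regression(np.full(30, 100.0))
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    dec = cov.positional_bias_regression(np.linspace(200, 100, 30))
    assert dec.slope < 0 and dec.p_value < 1e-6


def test_post_transcriptional_model_gives_negative_positional_slope(tmp_path):
    """With splicing switched off, nascent steady-state transcription alone
    leaves more copies of 5' introns than 3' introns: the per-intron medians
    must trend down along the gene."""
    cfg = SimulationConfig(
        n_introns=12, intron_length_range=(1500, 3000), removal_rates=1e-9,
        depth=60, n_molecules=800, extra_time=0.0, seed=31,
    )
    rng = np.random.default_rng(cfg.seed)
    model, _ = simulate_gene(cfg, rng)
    molecules = simulate_transcripts(model, cfg, rng)
    sam, _ = emit_read_pairs(molecules, model, cfg, rng)
    p = tmp_path / "post.sam"
    p.write_text(sam)
    depth = cov.depth_from_alignments(str(p), model)
    medians = [
        cov.median_feature_coverage(cov.feature_depths(depth, i, model))
        for i in model.introns
    ]
    reg = cov.positional_bias_regression(np.array(medians))
    assert reg.slope < 0 and reg.p_value < 0.01


# ---- speed classes and windows -------------------------------------------


@pytest.mark.parametrize(
    "value,expected",
    [(85, "fast"), (135, "slow"), (110, "intermediate"), (90, "intermediate"), (130, "intermediate")],
)
def test_speed_cutoffs(value, expected):
    assert cov.classify_intron_speed([value]) == [expected]


def test_window_count_78_introns():
    reports = cov.window_reports(np.arange(78.0), window=5, step=3)
    assert len(reports) == 26
    assert reports[-1]["members"][-1] == 78  # final partial window reaches the end


def test_window_ranking_orders_members():
    reports = cov.window_reports([50.0, 10.0, 30.0, 20.0, 40.0], window=5, step=3)
    assert reports[0]["ranked"] == [2, 4, 3, 5, 1]


# ---- replicate correlation and outliers ----------------------------------


def test_replicate_correlation_matches_formula_oracle():
    rng = np.random.default_rng(7)
    x = rng.lognormal(4, 0.5, 78)
    y = x * rng.lognormal(0, 0.1, 78)
    r, p = cov.replicate_correlation(x, y, log=True)
    assert r == pytest.approx(pearson_formula(np.log(x), np.log(y)), abs=1e-10)
    assert r > 0.9 and p < 1e-10


def test_outlier_spike_detection(toy_model):
    s, _ = toy_model.span
    depth = np.full(toy_model.span_length, 20, dtype=np.int64)
    intr2 = toy_model.intron(2)
    depth[intr2.start - s + 50 : intr2.start - s + 90] = 500  # local UTR-like spike
    assert cov.detect_coverage_outliers(depth, toy_model) == [2]


def test_slower_removal_means_higher_coverage(tmp_path):
    """Kinetic link between removal rate and intron coverage (rank r > 0.8)."""
    rates = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 0.07, 0.3, 1.0, 0.15]
    cfg = SimulationConfig(
        n_introns=10, intron_length_range=(1000, 2500), removal_rates=rates,
        depth=60, n_molecules=1200, seed=33,
    )
    rng = np.random.default_rng(cfg.seed)
    model, _ = simulate_gene(cfg, rng)
    molecules = simulate_transcripts(model, cfg, rng)
    sam, _ = emit_read_pairs(molecules, model, cfg, rng)
    p = tmp_path / "kin.sam"
    p.write_text(sam)
    depth = cov.depth_from_alignments(str(p), model)
    medians = [
        cov.median_feature_coverage(cov.feature_depths(depth, i, model))
        for i in model.introns
    ]
    rho = stats.spearmanr([1 / r for r in rates], medians).statistic
    assert rho > 0.8
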