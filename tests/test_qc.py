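"""dLRsd, GC correction, aberration calling, ROC and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import fragmatch as fm

from conftest import exhaustive_interval_calls


def make_table(values, chrom="chr1", spacing=2100, gc=None):
    n = len(values)
    starts = np.arange(n) * spacing
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 60,
            "probe_id": [f"{chrom}_p{i}" for i in range(n)],
            "log2ratio": np.asarray(values, dtype=float),
        }
    )
    if gc is not None:
        df["gc"] = gc
    return df


# --------------------------------------------------------------------- dlrsd


def test_dlrsd_zero_for_arithmetic_ramp_and_constant():
    assert fm.dlrsd(make_table(np.linspace(0, 5, 100))).dlrsd == pytest.approx(
        0.0, abs=1e-12
    )
    assert fm.dlrsd(make_table(np.full(50, 0.2))).dlrsd == 0.0


def test_dlrsd_estimates_gaussian_noise_sd():
    rng = np.random.default_rng(1)
    res = fm.dlrsd(make_table(rng.normal(0, 0.16, 50_000)))
    assert res.dlrsd == pytest.approx(0.16, abs=0.005)
    assert res.n_diffs == 49_999
    assert res.pass_03


def test_dlrsd_diffs_do_not_cross_chromosomes():
    # a huge offset between chromosomes must not contribute a difference
    df1 = make_table(np.zeros(50), chrom="chr1")
    df2 = make_table(np.full(50, 100.0), chrom="chr2")
    res = fm.dlrsd(pd.concat([df1, df2], ignore_index=True))
    assert res.dlrsd == 0.0
    assert res.n_diffs == 98


def test_dlrsd_insufficient_data():
    with pytest.raises(fm.InsufficientDataError):
        fm.dlrsd(make_table([0.1]))


def test_dlrsd_robust_to_few_breakpoints():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 0.16, 50_000)
    res0 = fm.dlrsd(make_table(base))
    shifted = base.copy()
    for lo, hi in ((5_000, 9_000), (15_000, 16_500), (30_000, 50_000)):
        shifted[lo:hi] += 0.8  # 5 step edges (the last segment runs to the end)
    res1 = fm.dlrsd(make_table(shifted))
    assert abs(res1.dlrsd - res0.dlrsd) / res0.dlrsd < 0.03


@settings(max_examples=50, derandomize=True)
@given(c=st.floats(-5, 5), seed=st.integers(0, 1000))
def test_dlrsd_scale_equivariance(c, seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.2, 500)
    base = fm.dlrsd(make_table(vals)).dlrsd
    scaled = fm.dlrsd(make_table(c * vals)).dlrsd
    assert scaled == pytest.approx(abs(c) * base, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------- gc_correct


def test_gc_correct_noop_when_signal_independent_of_gc():
    rng = np.random.default_rng(3)
    df = make_table(rng.normal(0, 0.16, 20_000), gc=rng.uniform(0.3, 0.7, 20_000))
    out = fm.gc_correct(df)
    rms = np.sqrt(np.mean((out["log2ratio"] - df["log2ratio"]) ** 2))
    assert rms < 0.01


def test_gc_correct_removes_injected_linear_wave():
    cfg = fm.HybridizationConfig(
        680, 680, n_probes=20_000, seed=7, gc_effect=1.0,
        constants=fm.NoiseConstants(sigma0=1e-9),
    )
    probes = fm.simulate_hybridization(cfg)
    assert abs(np.corrcoef(probes["log2ratio"], probes["gc"])[0, 1]) > 0.99
    out = fm.gc_correct(probes)
    assert abs(np.corrcoef(out["log2ratio"], out["gc"])[0, 1]) < 0.05


def test_gc_correct_preserves_constant_shift_and_median():
    rng = np.random.default_rng(4)
    df = make_table(rng.normal(0, 0.1, 10_000) + 0.2, gc=rng.uniform(0.3, 0.7, 10_000))
    out = fm.gc_correct(df)
    assert np.median(out["log2ratio"]) == pytest.approx(
        np.median(df["log2ratio"]), abs=1e-9
    )
    assert out["log2ratio"].mean() == pytest.approx(0.2, abs=0.01)


def test_gc_correct_requires_gc():
    df = make_table(np.zeros(100))
    with pytest.raises(fm.ValidationError, match="gc"):
        fm.gc_correct(df)


# ------------------------------------------------------------------- calling


def test_caller_empty_on_all_zero_ratios():
    with pytest.raises(fm.DegenerateNoiseError):
        fm.call_aberrations(make_table(np.zeros(100)))
    # with an explicit noise scale, an all-zero table yields no calls
    assert fm.call_aberrations(make_table(np.zeros(100)), sigma=0.1) == []


def test_caller_empty_table():
    assert fm.call_aberrations(make_table([])) == []


def test_caller_detects_implanted_segment_and_filters_short_one():
    cfg = fm.HybridizationConfig(
        400, 400, n_probes=2_000, seed=3, cn_profile=(("chr1", (500, 520), 0.8),)
    )
    calls = fm.call_aberrations(fm.simulate_hybridization(cfg))
    assert len(calls) == 1
    call = calls[0]
    assert call.direction == "gain"
    # overlaps the implant (probe indices 500..519 at 2.1 kb spacing)
    assert call.start < 520 * 2100 and call.end > 500 * 2100
    assert call.score >= 6.0 and call.n_probes >= 6

    cfg4 = fm.HybridizationConfig(
        400, 400, n_probes=2_000, seed=3, cn_profile=(("chr1", (500, 504), 0.8),)
    )
    assert fm.call_aberrations(fm.simulate_hybridization(cfg4)) == []


def test_caller_loss_direction():
    cfg = fm.HybridizationConfig(
        400, 400, n_probes=1_000, seed=8, cn_profile=(("chr1", (100, 130), -0.9),)
    )
    calls = fm.call_aberrations(fm.simulate_hybridization(cfg))
    assert len(calls) == 1 and calls[0].direction == "loss"


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_caller_matches_exhaustive_scan_oracle(seed):
    """Greedy recursive extraction equals the brute-force interval scan."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.16, 400)
    # implant a couple of segments of varying strength
    vals[50:70] += 0.6
    vals[200:204] += 0.9
    vals[300:340] -= 0.5
    sigma = 0.16
    got = fm.call_aberrations(make_table(vals), sigma=sigma)
    expected = exhaustive_interval_calls(vals, sigma, 6.0, 6, 0.3)
    assert len(got) == len(expected)
    for call, (i, j, score) in zip(got, sorted(expected)):
        assert call.start == i * 2100
        assert call.end == (j - 1) * 2100 + 60
        assert call.score == pytest.approx(score, rel=1e-9)


def test_calls_are_non_overlapping():
    rng = np.random.default_rng(9)
    vals = rng.normal(0, 0.16, 1_000)
    vals[100:150] += 0.7
    vals[160:220] += 0.5
    vals[400:450] -= 0.6
    calls = fm.call_aberrations(make_table(vals), sigma=0.16)
    calls = sorted(calls, key=lambda c: c.start)
    for a, b in zip(calls, calls[1:]):
        assert a.end <= b.start


# ----------------------------------------------------------------------- roc


def test_roc_perfect_separation():
    res = fm.roc_probe_level([1.0, 1.1, 1.2], [0.0, 0.1, 0.2], "gain")
    assert res.auc == 1.0
    assert res.fpr == 0.0 and res.fnr == 0.0


def test_roc_exchangeable_distributions_auc_half():
    rng = np.random.default_rng(6)
    res = fm.roc_probe_level(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
    assert res.auc == pytest.approx(0.5, abs=0.02)


def test_roc_gaussian_single_copy_gain_auc():
    """Single-copy-gain shift 0.58 over sd 0.2 noise: AUC = Phi(0.58/(0.2*sqrt2))."""
    rng = np.random.default_rng(5)
    ab = rng.normal(0.58, 0.2, 50_000)
    ne = rng.normal(0.0, 0.2, 50_000)
    res = fm.roc_probe_level(ab, ne, "gain")
    assert res.auc == pytest.approx(norm.cdf(0.58 / (0.2 * np.sqrt(2))), abs=0.003)
    assert 0 < res.fpr < 0.2 and 0 < res.fnr < 0.2


def test_roc_auc_equals_mannwhitney_normalization():
    rng = np.random.default_rng(7)
    ab = rng.normal(0.3, 0.25, 400)
    ne = rng.normal(0.0, 0.25, 300)
    res = fm.roc_probe_level(ab, ne, "gain")
    # independent cross-check: direct pairwise comparison count
    wins = (ab[:, None] > ne[None, :]).sum() + 0.5 * (ab[:, None] == ne[None, :]).sum()
    assert res.auc == pytest.approx(wins / (len(ab) * len(ne)), abs=1e-12)


def test_roc_loss_direction_mirrors_gain():
    rng = np.random.default_rng(8)
    ab = rng.normal(-0.5, 0.2, 2_000)
    ne = rng.normal(0.0, 0.2, 2_000)
    res = fm.roc_probe_level(ab, ne, "loss")
    assert res.auc > 0.9
    assert res.optimal_threshold < 0


def test_roc_empty_input_errors():
    with pytest.raises(fm.DomainError):
        fm.roc_probe_level([], [0.1])


# --------------------------------------------------------------- concordance


def _call(chrom, start, end, sign=1.0):
    return fm.AberrationCall(
        chrom, start, end, 10, sign * 0.5, 8.0, "gain" if sign > 0 else "loss"
    )


def test_concordance_identical_and_disjoint():
    ref = [_call("chr1", 0, 1000), _call("chr2", 500, 900)]
    assert fm.concordance(ref, list(ref)) == 1.0
    qry = [_call("chr3", 0, 1000), _call("chr4", 500, 900)]
    assert fm.concordance(ref, qry) == 0.0


def test_concordance_26_of_27():
    """27 reference aberrations, 26 overlapped: ~96% concordance."""
    ref = [_call("chr1", i * 10_000, i * 10_000 + 5_000) for i in range(27)]
    qry = [_call("chr1", i * 10_000 + 1_000, i * 10_000 + 4_000) for i in range(26)]
    assert fm.concordance(ref, qry) == pytest.approx(26 / 27)


def test_concordance_requires_one_shared_base():
    ref = [_call("chr1", 0, 1000)]
    assert fm.concordance(ref, [_call("chr1", 1000, 2000)]) == 0.0  # abutting
    assert fm.concordance(ref, [_call("chr1", 999, 2000)]) == 1.0


def test_concordance_empty_reference_errors():
    with pytest.raises(fm.DomainError):
        fm.concordance([], [_call("chr1", 0, 10)])
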