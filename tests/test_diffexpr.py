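"""TMM normalization, the NB exact test, dispersion estimation, DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trideg.diffexpr import (
    ContrastResult,
    DegThresholds,
    bh_adjust,
    call_degs,
    cpm,
    estimate_dispersion,
    nb_exact_test,
    run_contrast,
    run_triplet,
    signed_fc,
    tmm_factors,
)
from trideg.simdata import SimConfig, simulate_counts


def _df(arr, samples=None):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_columns_give_unit_factors():
    col = np.array([5, 10, 50, 100, 500, 1000])
    f = tmm_factors(_df(np.column_stack([col, col])))
    assert np.allclose(f, 1.0)


def test_tmm_pure_depth_difference_absorbed_by_library_size():
    col = np.array([5, 10, 50, 100, 500, 1000])
    f = tmm_factors(_df(np.column_stack([col, 2 * col])))
    assert np.allclose(f, 1.0)
    assert abs(np.exp(np.log(f).mean()) - 1.0) < 1e-9


def _tmm_oracle(counts, ref_j, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step trimmed weighted mean of M-values."""
    y = counts.astype(float)
    lib = y.sum(axis=0)
    log_f = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_j:
            continue
        rows = [
            (
                np.log2((y[g, j] / lib[j]) / (y[g, ref_j] / lib[ref_j])),
                0.5 * np.log2((y[g, j] / lib[j]) * (y[g, ref_j] / lib[ref_j])),
                (lib[j] - y[g, j]) / (lib[j] * y[g, j])
                + (lib[ref_j] - y[g, ref_j]) / (lib[ref_j] * y[g, ref_j]),
            )
            for g in range(y.shape[0])
            if y[g, j] > 0 and y[g, ref_j] > 0
        ]
        n = len(rows)
        m_rank = stats.rankdata([r[0] for r in rows])
        a_rank = stats.rankdata([r[1] for r in rows])
        num = den = 0.0
        for (m, a, w), rm, ra in zip(rows, m_rank, a_rank):
            if (
                np.floor(n * trim_m) + 1 <= rm <= n - np.floor(n * trim_m)
                and np.floor(n * trim_a) + 1 <= ra <= n - np.floor(n * trim_a)
            ):
                num += w * m
                den += w
        if den > 0:
            log_f[j] = num / den
    log_f -= log_f.mean()
    return 2.0 ** log_f


def test_tmm_matches_hand_computation_on_toy():
    """6-gene, 3-sample toy with one 10-fold-inflated gene: factors equal an
    independent spreadsheet-style computation of the trimmed weighted mean."""
    counts = np.array(
        [
            [100, 110, 95],
            [200, 190, 210],
            [50, 500, 55],  # inflated in sample 1
            [400, 420, 380],
            [800, 790, 805],
            [30, 35, 28],
        ]
    )
    df = _df(counts)
    f = tmm_factors(df, reference="s0")
    expected = _tmm_oracle(counts, ref_j=0)
    assert np.allclose(f.to_numpy(), expected, rtol=1e-12)
    assert abs(np.exp(np.log(f).mean()) - 1.0) < 1e-9


def test_tmm_rejects_all_zero_sample():
    df = _df(np.array([[1, 0], [2, 0]]))
    with pytest.raises(ValueError, match="s1"):
        tmm_factors(df)


def test_tmm_geometric_mean_one_on_simulated_data(small_sim):
    _, counts, _, _ = small_sim
    f = tmm_factors(counts)
    assert abs(np.exp(np.log(f).mean()) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# exact NB test


def _enumeration_oracle(s_a, total, n_a, n_b, phi):
    """Full conditional enumeration of the split distribution."""
    mu = total / (n_a + n_b)
    if phi == 0:
        f_a = stats.poisson(n_a * mu)
        f_b = stats.poisson(n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        f_a = stats.nbinom(r_a, r_a / (r_a + n_a * mu))
        f_b = stats.nbinom(r_b, r_b / (r_b + n_b * mu))
    ks = np.arange(total + 1)
    pmf = f_a.pmf(ks) * f_b.pmf(total - ks)
    pmf = pmf / pmf.sum()
    return float(pmf[pmf <= pmf[s_a] * (1 + 1e-7)].sum())


def _p(sa, sb, na=1, nb=1, phi=0.1):
    lib = np.full(na + nb, 1e6)
    a = np.full(na, sa / na)
    b = np.full(nb, sb / nb)
    return nb_exact_test(a, b, lib[:na], lib[na:], phi)


def test_exact_test_symmetric_split_gives_p_one():
    assert _p(10, 10) == 1.0
    assert _p(0, 0) == 1.0


def test_exact_test_poisson_limit_equals_binomial_test():
    for sa, sb in [(18, 2), (7, 13), (0, 9)]:
        p = _p(sa, sb, phi=0.0)
        expected = stats.binomtest(sa, sa + sb, 0.5).pvalue
        assert p == pytest.approx(expected, abs=1e-12)


def test_exact_test_matches_full_enumeration():
    """Agreement with explicit conditional enumeration for totals <= 200."""
    cases = [
        (18, 2, 1, 1, 0.1),
        (18, 2, 4, 4, 0.1),
        (150, 50, 4, 4, 0.2),
        (100, 100, 3, 5, 0.05),
        (60, 20, 2, 6, 0.3),
        (0, 30, 4, 4, 0.1),
    ]
    for sa, sb, na, nb, phi in cases:
        got = _p(sa, sb, na, nb, phi)
        want = _enumeration_oracle(sa, sa + sb, na, nb, phi)
        assert got == pytest.approx(want, abs=1e-10), (sa, sb, na, nb, phi)


def test_exact_test_large_total_windowing_consistent():
    """The windowed evaluation for large totals matches the full range."""
    sa, sb = 5200, 4300
    got = _p(sa, sb, 4, 4, 0.1)
    want = _enumeration_oracle(sa, sa + sb, 4, 4, 0.1)
    assert got == pytest.approx(want, rel=1e-9)


def test_exact_test_rejects_negative_dispersion():
    with pytest.raises(ValueError, match="dispersion"):
        _p(5, 5, phi=-0.5)


def test_exact_test_library_equalization():
    """A pure depth difference is no evidence of differential expression."""
    p = nb_exact_test(
        np.array([200.0]), np.array([100.0]),
        np.array([2e6]), np.array([1e6]), 0.1,
    )
    assert p == 1.0


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_zero_for_constant_counts():
    counts = _df(np.tile([[100], [50], [10]], (1, 6)))
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
    assert estimate_dispersion(counts, groups) == 0.0


def test_dispersion_near_zero_for_poisson_counts():
    rng = np.random.default_rng(0)
    counts = _df(rng.poisson(np.geomspace(10, 2000, 2000)[:, None], size=(2000, 8)))
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
    assert 0.0 <= estimate_dispersion(counts, groups) <= 0.05


def test_dispersion_recovers_planted_value():
    rng = np.random.default_rng(1)
    mu = np.geomspace(20, 2000, 2000)[:, None]
    phi = 0.2
    r = 1 / phi
    counts = _df(rng.negative_binomial(r, r / (r + mu), size=(2000, 8)))
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
    assert estimate_dispersion(counts, groups) == pytest.approx(phi, abs=0.1)


def test_dispersion_requires_replicates():
    counts = _df(np.array([[1, 2], [3, 4]]))
    groups = pd.Series(["a", "b"], index=counts.columns)
    with pytest.raises(ValueError, match="replicates"):
        estimate_dispersion(counts, groups)


# ---------------------------------------------------------------------------
# BH, DEG rule, display convention


def test_bh_matches_hand_step_up():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    # step-up by hand: p_(i) * n / i = .04, .04, .04, .04; running min from
    # the largest rank leaves all at 0.04
    assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])
    p = np.array([0.005, 0.04, 0.5])
    assert np.allclose(bh_adjust(p), [0.015, 0.06, 0.5])


def test_bh_identity_cases():
    assert np.allclose(bh_adjust(np.array([0.2, 0.2, 0.2])), 0.2)
    assert np.allclose(bh_adjust(np.array([0.031])), 0.031)
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.0, 0.5]))


def test_signed_fc_display_convention():
    assert signed_fc(1.0) == pytest.approx(2.0)
    assert signed_fc(0.0) == pytest.approx(1.0)
    # a 2^7.1175-fold down-regulation prints as approximately -138.86
    assert signed_fc(-7.1175) == pytest.approx(-138.86, abs=0.01)


def _result_from(signed, p):
    arr = np.asarray(signed, dtype=float)
    log2fc = np.sign(arr) * np.log2(np.abs(arr))
    t = pd.DataFrame(
        {
            "log2FC": log2fc,
            "signed_FC": signed,
            "mean_CPM": 100.0,
            "p_value": p,
            "FDR": bh_adjust(np.asarray(p)),
        },
        index=[f"g{i}" for i in range(len(signed))],
    )
    t["is_DEG"] = (t["signed_FC"].abs() > 1.5) & (t["p_value"] < 0.05)
    return ContrastResult("M1", "L3vNT", t)


def test_call_degs_rule_and_boundary():
    res = _result_from(
        signed=[1.5, 1.6, -1.6, 2.0, 5.0, -3.0, 1.2, 8.0, -2.5, 1.9],
        p=[0.001, 0.001, 0.001, 0.5, 0.01, 0.02, 0.001, 0.04, 0.9, 0.049],
    )
    degs = call_degs(res)
    # FC exactly 1.5 is excluded (strictly more than 1.5-fold)
    assert "g0" not in degs
    assert degs == {"g1", "g2", "g4", "g5", "g7", "g9"}


def test_call_degs_all_p_one_is_empty():
    res = _result_from(signed=[3.0, -4.0], p=[1.0, 1.0])
    assert call_degs(res) == set()


@given(
    fc_thresh=st.floats(1.1, 6.0),
    p_thresh=st.floats(0.001, 0.5),
)
@settings(max_examples=50, derandomize=True)
def test_deg_count_monotone_in_thresholds(fc_thresh, p_thresh):
    rng = np.random.default_rng(99)
    signed = np.concatenate([rng.uniform(1, 10, 30), -rng.uniform(1, 10, 30)])
    res = _result_from(signed=signed, p=rng.uniform(0.0001, 1, 60))
    base = len(call_degs(res, fc_thresh, p_thresh))
    stricter_fc = len(call_degs(res, fc_thresh + 0.5, p_thresh))
    stricter_p = len(call_degs(res, fc_thresh, p_thresh / 2))
    assert stricter_fc <= base and stricter_p <= base


# ---------------------------------------------------------------------------
# run_contrast / run_triplet


def test_run_contrast_identical_means_is_flat(small_sim):
    _, counts, design, _ = small_sim
    res = run_contrast(counts, design, ("M1", "IFNL3"), ("M1", "NT"))
    t = res.table
    # display invariant: signed FC and log2FC agree everywhere
    assert np.allclose(np.abs(t["signed_FC"]), 2.0 ** np.abs(t["log2FC"]))
    assert ((t["p_value"] > 0) & (t["p_value"] <= 1)).all()


def test_run_contrast_unknown_group_raises(small_sim):
    _, counts, design, _ = small_sim
    with pytest.raises(ValueError, match="no samples"):
        run_contrast(counts, design, ("M3", "IFNL3"), ("M1", "NT"))


def test_run_triplet_shares_gene_order(small_sim):
    _, counts, design, _ = small_sim
    trip = run_triplet(counts, design, "M1")
    idx = trip.results["L3vNT"].table.index
    assert trip.results["L4vNT"].table.index.equals(idx)
    assert trip.results["L4vL3"].table.index.equals(idx)
    flat = trip.to_classify_input()
    assert list(flat.columns) == [
        "signed_fc_l3", "p_l3", "signed_fc_l4", "p_l4",
        "signed_fc_l4vl3", "p_l4vl3",
    ]


def test_run_contrast_power_on_planted_effects():
    """Genes planted at |log2FC| = 2 with low dispersion are nearly always
    recovered as DEGs with the correct sign."""
    cfg = SimConfig(
        n_genes=300, dispersion=0.05, seed=3,
        archetype_mix={"null": 0.5, "l3_only": 0.5},
    )
    counts, design, truth = simulate_counts(cfg)
    res = run_contrast(counts, design, ("M1", "IFNL3"), ("M1", "NT"), dispersion=0.05)
    tr = truth[truth["cell_type"] == "M1"].set_index("gene")
    planted = tr.index[tr["planted_lfc_l3"] != 0].intersection(res.table.index)
    sub = res.table.loc[planted]
    assert sub["is_DEG"].mean() >= 0.95
    signs_match = np.sign(sub["log2FC"]) == np.sign(tr.loc[planted, "planted_lfc_l3"])
    assert signs_match.mean() >= 0.95
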