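"""TMM, common dispersion, NB exact test, fold changes, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom

import evcargo as ev
from evcargo.de import Contrast


def _cm(arr, n_bio="miRNA", samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(arr, columns=samples,
                          index=[f"f{i}" for i in range(arr.shape[0])])
    bio = pd.Series(n_bio, index=counts.index)
    return ev.CountMatrix(counts, bio)


# ---------------------------------------------------------------- TMM

def test_tmm_identical_columns_give_unit_factors():
    cm = _cm(np.tile([[10], [20], [30], [40]], (1, 4)))
    assert np.allclose(ev.tmm_factors(cm), 1.0)


def test_tmm_scaled_column_absorbed_into_library_size():
    rng = np.random.default_rng(0)
    base = rng.poisson(50, size=(300, 1))
    cm = _cm(np.hstack([base, 2 * base, base]))
    f = ev.tmm_factors(cm)
    assert f.iloc[1] / f.iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_tmm_composition_outlier_gets_factor_below_one():
    rng = np.random.default_rng(1)
    y = rng.poisson(100, size=(200, 4))
    y[0, 3] = y[:, 3].sum()  # one feature now ~50% of sample 3's reads
    cm = _cm(y)
    f = ev.tmm_factors(cm)
    assert f.iloc[3] < 1.0
    assert f.iloc[3] < f.iloc[:3].min()


# ------------------------------------------------- common dispersion

def test_dispersion_identical_replicates_hit_lower_bound():
    col = np.array([[10], [50], [200], [7]])
    cm = _cm(np.hstack([col, col]))
    phi = ev.estimate_common_dispersion(cm, {"g": ["s0", "s1"]})
    assert phi == pytest.approx(1e-4, rel=0.1)


def test_dispersion_poisson_data_estimates_near_zero():
    cfg = ev.SimulationConfig(n_hc=0, n_responders=8, n_nonresponders=8,
                              timepoints=("Dg",), dispersion=0.0,
                              library_size_mean=5e4, seed=2,
                              n_features_per_biotype={b: 50 for b in
                                                      ev.BIOTYPES})
    ds = ev.simulate_cohort(cfg)
    phi = ev.estimate_common_dispersion(
        ds.counts, {"R": ds.sample_ids(group="R"),
                    "NR": ds.sample_ids(group="NR")})
    assert phi <= 0.02


def test_dispersion_without_replication_warns_and_falls_back():
    cm = _cm([[10, 20], [5, 8]])
    with pytest.warns(UserWarning, match="no replicated group"):
        phi = ev.estimate_common_dispersion(cm, {"a": ["s0"], "b": ["s1"]},
                                            fallback=0.25)
    assert phi == 0.25


# ---------------------------------------------------- NB exact test

def test_exact_test_symmetric_split_is_exactly_one():
    assert ev.nb_exact_test(25, 25, 4, 4, 0.3) == 1.0
    assert ev.nb_exact_test(0, 0, 3, 5, 0.3) == 1.0


def test_exact_test_swapping_groups_preserves_p():
    for phi in (0.0, 0.1, 1.0):
        p_ab = ev.nb_exact_test(40, 7, 5, 3, phi)
        p_ba = ev.nb_exact_test(7, 40, 3, 5, phi)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)


def test_exact_test_matches_conditional_enumeration():
    """Independent oracle: scipy beta-binomial pmf enumerated over all splits."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        n_a, n_b = rng.integers(2, 9, size=2)
        t = int(rng.integers(1, 51))
        a = int(rng.integers(0, t + 1))
        phi = float(rng.uniform(0.02, 3.0))
        pmf = betabinom(t, n_a / phi, n_b / phi).pmf(np.arange(t + 1))
        oracle = pmf[pmf <= pmf[a] * (1 + 1e-7)].sum()
        assert ev.nb_exact_test(a, t - a, n_a, n_b, phi) == \
            pytest.approx(min(1.0, oracle), rel=1e-8)


def test_exact_test_rejects_negative_dispersion():
    with pytest.raises(ValueError):
        ev.nb_exact_test(5, 5, 2, 2, -0.1)


# ------------------------------------------------------ fold change

def test_log2_fold_change_examples():
    # equal column totals so that raw CPM comparisons are exact:
    # f0 equal means -> 0; f1 4x -> ~2; f2 absent in b -> large finite
    cm = _cm([[100, 100, 100, 100],
              [400, 400, 100, 100],
              [300, 300, 0, 0],
              [0, 0, 600, 600]])      # filler balancing the totals
    c = Contrast(["s0", "s1"], ["s2", "s3"])
    lfc = ev.log2_fold_change(cm, c, prior=0.01)
    assert lfc["f0"] == pytest.approx(0.0, abs=1e-6)
    assert lfc["f1"] == pytest.approx(2.0, abs=0.05)
    cpm_a = 300 / 800 * 1e6
    expected = np.log2((cpm_a + 0.1) / 0.1)
    lfc2 = ev.log2_fold_change(cm, c, prior=0.1)
    assert np.isfinite(lfc2["f2"])
    assert lfc2["f2"] == pytest.approx(expected, rel=1e-6)


# ------------------------------------------------------------- BH

def test_bh_hand_computed_values():
    assert ev.bh_adjust([0.2]) == pytest.approx([0.2])
    assert ev.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03] * 3)
    assert ev.bh_adjust([0.03, 0.01, 0.02]) == pytest.approx([0.03] * 3)


def test_bh_matches_statsmodels_and_is_equivariant():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.random(rng.integers(1, 200))
        adj = ev.bh_adjust(p)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, sm_adj)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        perm = rng.permutation(len(p))
        assert np.allclose(ev.bh_adjust(p[perm]), adj[perm])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=80))
def test_bh_is_valid_adjustment_for_any_pvector(p):
    adj = ev.bh_adjust(p)
    p = np.asarray(p)
    assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
    # monotone in the p-value ranks
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_rejects_invalid_input():
    with pytest.raises(ValueError):
        ev.bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        ev.bh_adjust([-0.1])


# ------------------------------------------------------------ run_de

def test_run_de_swap_symmetry(small_cohort):
    ds = small_cohort
    nr = ds.sample_ids(group="NR", timepoint="Dg")
    r = ds.sample_ids(group="R", timepoint="Dg")
    fwd = ev.run_de(ds.counts, Contrast(nr, r), dispersion=0.3)
    rev = ev.run_de(ds.counts, Contrast(r, nr), dispersion=0.3)
    assert np.allclose(fwd.table["p_value"], rev.table["p_value"], rtol=1e-9)
    assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-9)
    assert (fwd.table["adj_p"] >= fwd.table["p_value"] - 1e-15).all()


def test_run_de_balanced_rescaling_leaves_pvalues_unchanged(small_cohort):
    """Scaling one column up and another down by the same factor cancels in
    normalization, so exact-test p-values are unchanged."""
    ds = small_cohort
    nr = ds.sample_ids(group="NR", timepoint="Dg")
    r = ds.sample_ids(group="R", timepoint="Dg")
    base = ds.counts.subset_samples(nr + r)
    doubled = base.counts * 2  # make halving integral
    cm1 = ev.CountMatrix(doubled, base.biotype)
    scaled = doubled.copy()
    scaled[nr[0]] = scaled[nr[0]] * 2
    scaled[r[0]] = scaled[r[0]] // 2
    cm2 = ev.CountMatrix(scaled, base.biotype)
    p1 = ev.run_de(cm1, Contrast(nr, r), dispersion=0.3).table["p_value"]
    p2 = ev.run_de(cm2, Contrast(nr, r), dispersion=0.3).table["p_value"]
    assert np.allclose(p1, p2, atol=1e-6)


def test_run_de_extreme_thresholds_flag_nothing(small_cohort):
    ds = small_cohort
    res = ev.run_de(ds.counts,
                    Contrast(ds.sample_ids(group="NR", timepoint="Dg"),
                             ds.sample_ids(group="R", timepoint="Dg")),
                    dispersion=0.3, lfc_threshold=np.inf, alpha=0.0)
    assert not res.table["significant"].any()


def test_run_de_detects_strong_planted_effect():
    hits = 0
    for seed in range(5):
        m = ev.PlantedMarker("mk", "miRNA", carrier_groups=("NR",),
                             carrier_fraction=1.0, expression_log2fc=8.0,
                             active_timepoints=("Dg",))
        cfg = ev.SimulationConfig(n_hc=0, timepoints=("Dg",),
                                  library_size_mean=5e4, seed=seed,
                                  n_features_per_biotype={b: 50 for b in
                                                          ev.BIOTYPES},
                                  planted_markers=[m])
        ds = ev.simulate_cohort(cfg)
        res = ev.run_de(ds.counts,
                        Contrast(ds.sample_ids(group="NR"),
                                 ds.sample_ids(group="R")))
        hits += "mk" in res.up_in_a()
    assert hits == 5


def test_run_de_null_cohort_controls_false_flags():
    flagged = total = 0
    for seed in range(8):
        cfg = ev.SimulationConfig(n_hc=0, timepoints=("Dg",),
                                  library_size_mean=5e4, seed=100 + seed,
                                  n_features_per_biotype={b: 50 for b in
                                                          ev.BIOTYPES})
        ds = ev.simulate_cohort(cfg)
        res = ev.run_de(ds.counts,
                        Contrast(ds.sample_ids(group="NR"),
                                 ds.sample_ids(group="R")),
                        dispersion=0.3)
        flagged += int(res.table["significant"].sum())
        total += len(res.table)
    assert flagged / total <= 0.05


def test_contrast_validation():
    with pytest.raises(ValueError):
        Contrast([], ["s1"])
    with pytest.raises(ValueError):
        Contrast(["s1"], ["s1", "s2"])
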