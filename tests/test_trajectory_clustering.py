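"""Change filter and Up/Nc/Dn pattern classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import stresstraj as st
from stresstraj.trajectory_clustering import classify_trajectories

from conftest import make_ratio_table


# ---------------------------------------------------------------------------
# pattern enumeration
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, expected", [(2, 3), (4, 27), (5, 81)])
def test_pattern_count(n, expected):
    codes = st.enumerate_patterns(n)
    assert len(codes) == expected
    assert len(set(codes)) == expected


def test_pattern_enumeration_order_and_errors():
    assert st.enumerate_patterns(2) == ["Up", "Nc", "Dn"]
    # brute-force cartesian-product oracle
    oracle = ["".join(p) for p in itertools.product(("Up", "Nc", "Dn"), repeat=3)]
    assert st.enumerate_patterns(4) == oracle
    with pytest.raises(ValueError):
        st.enumerate_patterns(1)


# ---------------------------------------------------------------------------
# transition classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "prev, nxt, label",
    [
        (1.0, 1.2, "Up"),
        (1.0, 0.8, "Dn"),
        (1.0, 1.19, "Nc"),
        (1.2, 1.0, "Nc"),  # a 16.7% drop: asymmetry of the relative change
        (1.0, 1.0, "Nc"),
    ],
)
def test_transition_boundaries_at_20_percent(prev, nxt, label):
    assert st.classify_transition(prev, nxt) == label


def test_transition_classification_matches_sign_magnitude_oracle():
    rng = np.random.default_rng(42)
    prev = rng.uniform(0.1, 5.0, size=100_000)
    nxt = rng.uniform(0.1, 5.0, size=100_000)
    table = make_ratio_table(
        {f"g{i}": (prev[i], nxt[i]) for i in range(len(prev))}, timepoints=("a", "b")
    )
    got = classify_trajectories(table, transition_threshold=0.2).to_numpy()
    rel = (nxt - prev) / prev
    oracle = np.where(rel >= 0.2, "Up", np.where(rel <= -0.2, "Dn", "Nc"))
    # the float guard may only matter within 1e-12 of the boundary; none here
    assert (np.abs(np.abs(rel) - 0.2) > 1e-9).all()
    np.testing.assert_array_equal(got, oracle)


@settings(derandomize=True, max_examples=200)
@given(
    a=hs.floats(0.05, 20.0),
    b=hs.floats(0.05, 20.0),
    c=hs.floats(0.01, 100.0),
)
def test_transition_scale_invariance(a, b, c):
    rel = (b - a) / a
    if min(abs(rel - 0.2), abs(rel + 0.2)) < 1e-6:
        return  # stay off the threshold boundary where float noise decides
    assert st.classify_transition(c * a, c * b) == st.classify_transition(a, b)


def test_log_symmetric_variant_is_direction_symmetric():
    assert st.classify_transition(1.0, 1.2, log_scale=True) == "Up"
    assert st.classify_transition(1.2, 1.0, log_scale=True) == "Dn"
    assert st.classify_transition(1.0, 1.19, log_scale=True) == "Nc"


# ---------------------------------------------------------------------------
# 40% filter
# ---------------------------------------------------------------------------


def test_filter_examples_and_boundary():
    table = make_ratio_table(
        {
            "flat": (1.0, 1.0, 1.0, 1.0),
            "late": (1.0, 1.0, 1.0, 1.4),  # exactly 40%: retained (>= convention)
            "just_below": (1.0, 1.0, 1.0, 1.39),
        }
    )
    out = st.filter_by_change(table, 0.40)
    assert not out.loc["flat", "passed"]
    assert out.loc["late", "passed"]
    assert not out.loc["just_below", "passed"]


def test_filter_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    trajs = {f"g{i}": tuple(rng.uniform(0.3, 3.0, size=4)) for i in range(10)}
    out = st.filter_by_change(make_ratio_table(trajs), 0.40)
    for gene, r in trajs.items():
        expected = any(abs(rt - r[0]) / r[0] >= 0.40 for rt in r[1:])
        assert out.loc[gene, "passed"] == expected


# ---------------------------------------------------------------------------
# pattern assignment
# ---------------------------------------------------------------------------


def test_worked_example_up_nc_dn():
    """Rises >=20%, then flat, then falls >=20% -> UpNcDn."""
    table = make_ratio_table({"g": (1.0, 1.5, 1.6, 1.1)})
    result = st.assign_patterns(table)
    assert result.patterns["g"] == "UpNcDn"


def test_noiseless_planted_patterns_recovered_exactly():
    design = st.SyntheticDesign(
        n_genes=200, noise_sd_log2=0.0, pattern_weights={"NcNcUp": 1.0}, seed=2
    )
    truth = st.generate_truth(design)
    result = st.assign_patterns(truth.ratio_table())
    assert (result.patterns == "NcNcUp").all()
    assert result.n_filtered == 200


def test_pattern_agrees_with_brute_force_three_comparisons(small_design):
    truth = st.generate_truth(small_design)
    table = truth.ratio_table()
    result = st.assign_patterns(table)
    for gene in result.patterns.index[:50]:
        r = table.ratios.loc[gene].to_numpy()
        code = "".join(
            st.classify_transition(r[t], r[t + 1]) for t in range(3)
        )
        assert result.patterns[gene] == code


def test_partition_property(small_design):
    truth = st.generate_truth(small_design)
    result = st.assign_patterns(truth.ratio_table())
    members = [g for code in st.enumerate_patterns(4) for g in result.members(code)]
    assert sorted(members) == sorted(result.patterns.index)
    assert result.occupancy.sum() == result.n_filtered


def test_gene_scale_invariance_of_filter_and_pattern(small_design):
    truth = st.generate_truth(small_design)
    table = truth.ratio_table()
    scaled = st.RatioTable(ratios=table.ratios * 3.7)
    a = st.assign_patterns(table)
    b = st.assign_patterns(scaled)
    pd.testing.assert_series_equal(a.patterns, b.patterns)
    pd.testing.assert_series_equal(
        a.filter_table["passed"], b.filter_table["passed"]
    )


def test_threshold_monotonicity(small_design):
    """Raising thresholds can only add Nc labels / shrink the filtered set."""
    truth = st.generate_truth(small_design)
    table = truth.ratio_table()
    lo = st.assign_patterns(table, transition_threshold=0.2)
    hi = st.assign_patterns(table, transition_threshold=0.3)
    assert (hi.patterns.str.count("Nc") >= lo.patterns.str.count("Nc")).all()
    f_lo = st.filter_by_change(table, 0.40)["passed"]
    f_hi = st.filter_by_change(table, 0.50)["passed"]
    assert not (f_hi & ~f_lo).any()


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------


def test_sensitivity_scan_limits_and_monotonicity(small_design):
    truth = st.generate_truth(small_design)
    table = truth.ratio_table()
    scan = st.sensitivity_scan(table, [0.0, 0.2, 0.3, 1e9])
    assert scan.nc_monotone
    # threshold 0: Nc only where consecutive ratios are exactly equal
    pats0 = scan.patterns[0.0]
    vals = table.ratios.loc[pats0.index].to_numpy()
    any_equal = (vals[:, :-1] == vals[:, 1:]).any(axis=1)
    has_nc = pats0.str.contains("Nc").to_numpy()
    assert not (has_nc & ~any_equal).any()
    # threshold -> infinity: everything NcNcNc
    assert (scan.patterns[1e9] == "NcNcNc").all()


def test_sensitivity_scan_changes_only_near_threshold_transitions(small_design):
    truth = st.generate_truth(small_design)
    table = truth.ratio_table()
    scan = st.sensitivity_scan(table, [0.2, 0.3])
    vals = table.ratios.loc[scan.patterns[0.2].index].to_numpy()
    rel = np.abs(np.diff(vals, axis=1) / vals[:, :-1])
    for i, gene in enumerate(scan.patterns[0.2].index):
        p_lo, p_hi = scan.patterns[0.2][gene], scan.patterns[0.3][gene]
        for t in range(3):
            lo_lab, hi_lab = p_lo[2 * t : 2 * t + 2], p_hi[2 * t : 2 * t + 2]
            if lo_lab != hi_lab:
                assert 0.2 <= rel[i, t] < 0.3


def test_sensitivity_scan_rejects_negative_threshold(small_design):
    truth = st.generate_truth(small_design)
    with pytest.raises(ValueError):
        st.sensitivity_scan(truth.ratio_table(), [-0.1])
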