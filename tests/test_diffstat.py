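"""S0 statistic, permutation FDR and regulation classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import subproteo as sp
from subproteo.diffstat import _tstat_matrix, permutation_fdr

from conftest import toy_quant_table


# --- log transform --------------------------------------------------------


def test_log_transform_values():
    table = toy_quant_table(
        [
            ("p1", "168", "control", "cytosolic", 1, 8.0, 3),
            ("p2", "168", "control", "cytosolic", 1, 1.0, 3),
        ]
    )
    log2 = sp.log_transform(table)
    assert list(log2["intensity"]) == [3.0, 0.0]
    assert log2.attrs["is_log2"]


def test_log_transform_inverse(rng):
    x = rng.uniform(-5, 30, size=50)
    table = toy_quant_table(
        [(f"p{i}", "168", "control", "cytosolic", 1, 2.0**v, 3) for i, v in enumerate(x)]
    )
    assert np.allclose(sp.log_transform(table)["intensity"], x)


def test_log_transform_pre_logged_skipped():
    table = toy_quant_table([("p1", "168", "control", "cytosolic", 1, 25.0, 3)])
    table.attrs["is_log2"] = True
    out = sp.log_transform(table)
    assert out["intensity"].iloc[0] == 25.0


def test_log_transform_nonpositive_error():
    table = toy_quant_table([("p1", "168", "control", "cytosolic", 1, -1.0, 3)])
    with pytest.raises(ValueError):
        sp.log_transform(table)


# --- mean difference ------------------------------------------------------


@pytest.mark.parametrize(
    "induced,control,expected",
    [([4, 4, 4], [4, 4, 4], 0.0), ([5, 6], [3, 4, 5], 1.5)],
)
def test_mean_difference(induced, control, expected):
    assert sp.mean_difference(induced, control) == pytest.approx(expected)


def test_mean_difference_undefined():
    with pytest.raises(sp.UndefinedDifferenceError):
        sp.mean_difference([], [1, 2, 3])


# --- S0 statistic ---------------------------------------------------------


def test_s0_tstat_identical_groups_zero():
    assert sp.s0_tstat([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 0.0


def test_s0_zero_equals_classical_t(rng):
    """With s0=0 the statistic must match the textbook pooled two-sample t."""
    for _ in range(20):
        a = rng.normal(0, 1, size=rng.integers(2, 6))
        b = rng.normal(0.5, 2, size=rng.integers(2, 6))
        expected = stats.ttest_ind(a, b, equal_var=True).statistic
        assert sp.s0_tstat(a, b, s0=0.0) == pytest.approx(expected, rel=1e-12)


def test_s0_monotone_damping(rng):
    a = rng.normal(1, 1, size=3)
    b = rng.normal(0, 1, size=3)
    grid = [0.0, 0.1, 0.5, 1.0, 5.0, 50.0]
    vals = [abs(sp.s0_tstat(a, b, s0=s)) for s in grid]
    assert all(x > y for x, y in zip(vals, vals[1:]))
    assert vals[-1] < 0.1 * vals[0]


def test_s0_tstat_antisymmetric(rng):
    a = rng.normal(0, 1, size=4)
    b = rng.normal(1, 1, size=3)
    assert sp.s0_tstat(a, b) == pytest.approx(-sp.s0_tstat(b, a))


def test_s0_tstat_small_group_rejected():
    with pytest.raises(ValueError):
        sp.s0_tstat([1.0], [1.0, 2.0])


def test_welch_variant_differs_with_unequal_sizes(rng):
    a = rng.normal(0, 1, size=5)
    b = rng.normal(0, 3, size=2)
    assert sp.s0_tstat(a, b, welch=True) != pytest.approx(sp.s0_tstat(a, b, welch=False))


# --- permutation FDR ------------------------------------------------------


def _toy_block(rng, n=30, effect=0.0, n_signal=0, sd=0.5):
    A = rng.normal(25, sd, size=(n, 3))
    B = rng.normal(25, sd, size=(n, 3))
    A[:n_signal] += effect
    return A, B


def test_exhaustive_mode_triggers_for_3v3(rng):
    A, B = _toy_block(rng)
    res = permutation_fdr(A, B, sp.TestConfig(seed=0))
    assert res.exhaustive
    assert res.n_permutations == 18  # C(6,3) minus the observed split + mirror


def test_spiked_proteins_flagged(rng):
    A, B = _toy_block(rng, n=40, effect=5.0, n_signal=2, sd=0.2)
    res = permutation_fdr(A, B, sp.TestConfig(seed=0))
    assert res.significant[:2].all()
    # FDR 0.05 admits the occasional borderline null
    assert res.significant[2:].sum() <= 1


def test_antisymmetry_under_label_swap(rng):
    A, B = _toy_block(rng, n=25, effect=2.0, n_signal=5)
    cfg = sp.TestConfig(seed=1)
    r1 = permutation_fdr(A, B, cfg)
    r2 = permutation_fdr(B, A, cfg)
    assert np.allclose(r1.t, -r2.t, equal_nan=True)
    assert np.allclose(r1.p, r2.p, equal_nan=True)
    assert np.allclose(r1.q, r2.q, equal_nan=True)
    assert (r1.significant == r2.significant).all()


def test_significant_sets_nest_across_fdr_levels(rng):
    A, B = _toy_block(rng, n=60, effect=1.5, n_signal=12)
    strict = permutation_fdr(A, B, sp.TestConfig(fdr=0.01, seed=2))
    loose = permutation_fdr(A, B, sp.TestConfig(fdr=0.05, seed=2))
    assert set(np.nonzero(strict.significant)[0]) <= set(
        np.nonzero(loose.significant)[0]
    )


def test_sampled_permutations_converge_to_exhaustive(rng):
    """Sampling many randomizations approaches the exhaustive estimate."""
    A = rng.normal(25, 0.5, size=(20, 6))
    B = rng.normal(25, 0.5, size=(20, 6))
    A[:4] += 2.0
    exh = permutation_fdr(A, B, sp.TestConfig(n_randomizations=924, seed=3))
    assert exh.exhaustive and exh.n_permutations == 922
    sampled = permutation_fdr(A, B, sp.TestConfig(n_randomizations=900, seed=3))
    assert not sampled.exhaustive
    assert np.allclose(exh.q, sampled.q, atol=0.1, equal_nan=True)
    assert (exh.significant == sampled.significant).mean() >= 0.9


def test_constant_intensities_nothing_significant():
    A = np.full((10, 3), 20.0)
    B = np.full((10, 3), 20.0)
    res = permutation_fdr(A, B, sp.TestConfig(seed=0))
    assert res.significant.sum() == 0


def test_missing_replicates_handled(rng):
    A, B = _toy_block(rng, n=30, effect=4.0, n_signal=3, sd=0.3)
    A[5, 0] = np.nan  # 2-of-3 detection still testable
    res = permutation_fdr(A, B, sp.TestConfig(seed=0))
    assert np.isfinite(res.t[5])
    assert res.significant[:3].all()


# --- classification -------------------------------------------------------


def _classed(diff_rows, presence_rows):
    diff = pd.DataFrame(
        diff_rows,
        columns=["strain", "fraction", "protein", "difference", "significant"],
    )
    diff["t_s0"] = np.nan
    diff["p"] = np.nan
    diff["neglog10_p"] = np.nan
    diff["q"] = np.nan
    presence = pd.DataFrame(
        presence_rows, columns=["strain", "fraction", "protein", "call"]
    )
    return sp.classify_regulation(diff, presence)


def test_classification_rules():
    out = _classed(
        [
            ("m", "cytosolic", "rnc", 0.82, True),
            ("m", "cytosolic", "ffh", 0.286, False),
            ("m", "cytosolic", "ftsY", -0.394, True),
            ("m", "cytosolic", "htrB", np.nan, False),
        ],
        [
            ("m", "cytosolic", "rnc", "both"),
            ("m", "cytosolic", "ffh", "both"),
            ("m", "cytosolic", "ftsY", "both"),
            ("m", "cytosolic", "htrB", "OFF"),
        ],
    )
    cls = out.set_index("protein")["class"]
    assert cls["rnc"] == "up"
    assert cls["ffh"] == "unchanged"
    assert cls["ftsY"] == "down"
    assert cls["htrB"] == "OFF"


def test_presence_overrides_significance():
    out = _classed(
        [("m", "cytosolic", "p1", 3.0, True)],
        [("m", "cytosolic", "p1", "ON")],
    )
    assert out["class"].iloc[0] == "ON"


def test_conflicting_keys_rejected():
    with pytest.raises(ValueError, match="conflicting"):
        _classed(
            [
                ("m", "cytosolic", "p1", 1.0, True),
                ("m", "cytosolic", "p1", 2.0, True),
            ],
            [("m", "cytosolic", "p1", "both")],
        )


def test_differential_analysis_full_block(small_dataset, small_pipeline):
    """End-to-end: classes are consistent with signs and presence calls."""
    _, _, classed = small_pipeline
    up = classed[classed["class"] == "up"]
    down = classed[classed["class"] == "down"]
    assert (up["difference"] > 0).all()
    assert (down["difference"] < 0).all()
    onoff = classed[classed["class"].isin(["ON", "OFF"])]
    assert onoff["difference"].isna().all()
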