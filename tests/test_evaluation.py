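import numpy as np
import pytest

from selsmm import (FvcMap, PlotRecord, r_squared_and_regression, read_plots,
                    rmse, sample_estimates_at_plots, write_plots)


def _fvc_map(values, mask=None, geotransform=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    cat = np.zeros(values.shape, dtype=np.int8)
    return FvcMap(fvc=np.where(mask, np.nan, values), category=cat, mask=mask,
                  geotransform=geotransform)


# ---------------------------------------------------------------------------
# rmse


def test_identical_vectors_give_zero():
    assert rmse([(0.3, 0.3), (0.7, 0.7)]) == 0.0


def test_antisymmetric_unit_errors_give_one():
    assert rmse([(0.0, 1.0), (1.0, 0.0)]) == pytest.approx(1.0, abs=0)


def test_matches_direct_formula_on_random_pairs():
    rng = np.random.default_rng(50)
    est, meas = rng.random(50), rng.random(50)
    pairs = list(zip(est, meas))
    expected = np.sqrt(np.mean((est - meas) ** 2))
    assert rmse(pairs) == pytest.approx(expected, abs=1e-12)


def test_rmse_invariant_to_order_and_linear_in_errors():
    rng = np.random.default_rng(51)
    meas = rng.random(20)
    err = rng.normal(0, 0.1, 20)
    pairs = list(zip(meas + err, meas))
    shuffled = [pairs[i] for i in rng.permutation(20)]
    assert rmse(shuffled) == pytest.approx(rmse(pairs), abs=1e-14)
    doubled = list(zip(meas + 2 * err, meas))
    assert rmse(doubled) == pytest.approx(2 * rmse(pairs), abs=1e-12)


def test_empty_pairs_rejected():
    with pytest.raises(ValueError, match="no pairs"):
        rmse([])


# ---------------------------------------------------------------------------
# r-squared and regression


def test_identity_fit_is_perfect():
    vals = np.linspace(0.1, 0.9, 10)
    res = r_squared_and_regression(list(zip(vals, vals)))
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.slope == pytest.approx(1.0, abs=1e-12)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.rmse == pytest.approx(0.0, abs=1e-12)


def test_constant_estimates_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        r_squared_and_regression([(0.5, 0.1), (0.5, 0.4), (0.5, 0.9)])


def test_r_squared_matches_squared_pearson():
    rng = np.random.default_rng(52)
    meas = rng.uniform(0, 1, 40)
    est = 0.8 * meas + 0.05 + rng.normal(0, 0.05, 40)
    res = r_squared_and_regression(list(zip(est, meas)))
    expected = np.corrcoef(est, meas)[0, 1] ** 2
    assert res.r_squared == pytest.approx(expected, abs=1e-12)
    assert 0.0 <= res.r_squared <= 1.0
    assert res.p_value < 0.05


def test_r_squared_invariant_to_affine_transforms():
    rng = np.random.default_rng(53)
    meas = rng.uniform(0, 1, 30)
    est = 0.6 * meas + rng.normal(0, 0.08, 30)
    base = r_squared_and_regression(list(zip(est, meas))).r_squared
    scaled = r_squared_and_regression(
        list(zip(0.2 * est + 0.4, meas))).r_squared
    assert scaled == pytest.approx(base, abs=1e-12)


def test_adding_collinear_pair_keeps_perfect_fit():
    vals = [0.1, 0.4, 0.7]
    pairs = list(zip(vals, vals))
    r1 = r_squared_and_regression(pairs).r_squared
    r2 = r_squared_and_regression(pairs + [(0.9, 0.9)]).r_squared
    assert r1 == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# plot sampling


def test_plot_paired_with_containing_pixel():
    fm = _fvc_map(np.arange(20).reshape(4, 5) / 20.0)
    # default geotransform: pixel (r, c) covers x in [c, c+1), y in [r, r+1)
    plots = [PlotRecord(id="p1", x=5 * 0.0 + 0.5 + 5 - 5, y=3.5,
                        measured_fvc=0.4)]
    plots = [PlotRecord(id="p1", x=2.5, y=3.5, measured_fvc=0.4)]
    pairs, excluded = sample_estimates_at_plots(fm, plots)
    assert excluded == []
    assert pairs[0] == (pytest.approx((3 * 5 + 2) / 20.0), 0.4)


def test_plot_outside_extent_excluded_with_named_warning():
    fm = _fvc_map(np.full((3, 3), 0.5))
    plots = [PlotRecord(id="far_plot", x=-1.0, y=1.5, measured_fvc=0.2),
             PlotRecord(id="in", x=0.5, y=0.5, measured_fvc=0.5)]
    with pytest.warns(UserWarning, match="far_plot"):
        pairs, excluded = sample_estimates_at_plots(fm, plots)
    assert excluded == ["far_plot"]
    assert len(pairs) == 1


def test_plot_on_nodata_pixel_excluded():
    mask = np.zeros((3, 3), bool)
    mask[1, 1] = True
    fm = _fvc_map(np.full((3, 3), 0.5), mask=mask)
    plots = [PlotRecord(id="wet", x=1.5, y=1.5, measured_fvc=0.2)]
    with pytest.warns(UserWarning, match="nodata"):
        pairs, excluded = sample_estimates_at_plots(fm, plots)
    assert excluded == ["wet"]
    assert pairs == []


def test_all_plots_inside_yield_pairs_in_input_order():
    rng = np.random.default_rng(54)
    fm = _fvc_map(rng.random((10, 10)),
                  geotransform=(1000.0, 30.0, 0.0, 2000.0, 0.0, 30.0))
    plots = []
    for i in range(30):
        r, c = rng.integers(0, 10), rng.integers(0, 10)
        plots.append(PlotRecord(id=f"p{i}", x=1000.0 + (c + 0.5) * 30.0,
                                y=2000.0 + (r + 0.5) * 30.0,
                                measured_fvc=float(rng.random())))
    pairs, excluded = sample_estimates_at_plots(fm, plots)
    assert len(pairs) == 30 and excluded == []
    for (est, meas), p in zip(pairs, plots):
        assert meas == p.measured_fvc


def test_plots_csv_round_trip(tmp_path):
    plots = [PlotRecord(id="a", x=1.0, y=2.0, measured_fvc=0.3),
             PlotRecord(id="b", x=4.0, y=5.0, measured_fvc=0.8)]
    path = write_plots(plots, tmp_path / "plots.csv")
    back = read_plots(path)
    assert [p.id for p in back] == ["a", "b"]
    assert back[1].measured_fvc == pytest.approx(0.8)


def test_plot_record_validation():
    with pytest.raises(ValueError, match="measured_fvc"):
        PlotRecord(id="x", x=0.0, y=0.0, measured_fvc=1.2)
    with pytest.raises(ValueError, match="finite"):
        PlotRecord(id="x", x=np.nan, y=0.0, measured_fvc=0.5)
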