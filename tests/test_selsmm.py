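import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selsmm import (SelsmmConfig, SpectralLibrary, UndefinedResponseError,
                    response_coefficient, select_endmembers,
                    unmix_image_lsmm, unmix_image_selsmm)

from oracles import pearson_reference, selection_reference


# ---------------------------------------------------------------------------
# response coefficient


def test_perfect_linear_relations():
    assert response_coefficient([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)
    assert response_coefficient([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)


def test_matches_textbook_pearson():
    a = np.array([0.10, 0.20, 0.40, 0.50])
    b = np.array([0.30, 0.10, 0.50, 0.20])
    assert response_coefficient(a, b) == pytest.approx(
        pearson_reference(a, b), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=8),
       st.lists(st.floats(0.0, 1.0), min_size=4, max_size=8))
def test_symmetric_and_bounded(a, b):
    m = min(len(a), len(b))
    a, b = np.array(a[:m]), np.array(b[:m])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        with pytest.raises(UndefinedResponseError):
            response_coefficient(a, b)
        return
    r = response_coefficient(a, b)
    assert -1.0 <= r <= 1.0
    assert r == pytest.approx(response_coefficient(b, a), abs=1e-14)


def test_zero_variance_raises():
    with pytest.raises(UndefinedResponseError):
        response_coefficient([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# selection


def test_single_positive_endmember_selected(tm6_library):
    lib = tm6_library.subset([0])
    trace = select_endmembers(lib.spectra[0] * 0.8, lib)
    assert trace.selected == [0]
    assert not trace.fallback_full_library


def test_anticorrelated_member_gets_zero_weight():
    veg = np.array([0.05, 0.08, 0.05, 0.45, 0.23, 0.12])
    lib = SpectralLibrary(names=["A", "B"], vis_class=["vegetation", "other"],
                          spectra=np.vstack([veg, veg[::-1]]))
    trace = select_endmembers(veg, lib)
    first = trace.iterations[0]
    assert first.endmember == 0
    assert first.r_max == pytest.approx(1.0)
    # B's negative response is clamped, so A carries the full weight
    assert first.x_max == pytest.approx(1.0)


def test_trace_matches_straight_line_reference(default_scene):
    """The iteration log is reproduced step by step by an independent
    re-implementation of the response/subtract/stop loop."""
    lib = default_scene.library
    data = default_scene.cube.data.reshape(-1, lib.n_bands)
    rng = np.random.default_rng(17)
    cfg = SelsmmConfig(eta=0.35, delta_tol=1e-4)
    for i in rng.choice(len(data), size=50, replace=False):
        trace = select_endmembers(data[i], lib, cfg)
        choices, x_maxes, r_maxes, residuals, selected, stop = \
            selection_reference(data[i], lib.spectra, cfg.eta, cfg.delta_tol)
        assert [it.endmember for it in trace.iterations] == choices
        assert trace.selected == selected
        assert trace.stop_reason == stop
        for it, x, r, res in zip(trace.iterations, x_maxes, r_maxes, residuals):
            assert it.x_max == pytest.approx(x, abs=1e-12)
            assert it.r_max == pytest.approx(r, abs=1e-12)
            assert np.allclose(it.residual_after, res, atol=1e-12)


def test_residual_change_equals_damped_contribution(default_scene):
    """||dR||_inf of consecutive residuals is exactly eta*X_max*||A_max||_inf."""
    lib = default_scene.library
    C = lib.endmember_matrix()
    px = default_scene.cube.data[5, 9]
    cfg = SelsmmConfig(eta=0.65)
    trace = select_endmembers(px, lib, cfg)
    prev = px
    assert len(trace.iterations) >= 1
    for it in trace.iterations:
        delta = prev - it.residual_after
        expected = cfg.eta * it.x_max * C[:, it.endmember]
        assert np.allclose(delta, expected, atol=1e-12)
        prev = it.residual_after


def test_pure_pixel_gets_unit_abundance(noiseless_scene):
    lib = noiseless_scene.library
    px = lib.spectra[1]
    from selsmm import ImageCube
    cube = ImageCube(data=np.tile(px, (2, 2, 1)))
    abund, _ = unmix_image_selsmm(cube, lib)
    assert abund.fractions[0, 0, 1] == pytest.approx(1.0, abs=1e-6)


def test_flat_pixel_falls_back_to_full_library(tm6_library):
    trace = select_endmembers(np.full(6, 0.25), tm6_library)
    assert trace.fallback_full_library
    assert trace.selected == list(range(4))
    assert trace.stop_reason == "no_positive_response"


def test_selected_set_nonempty_and_distinct(default_scene):
    lib = default_scene.library
    data = default_scene.cube.data.reshape(-1, lib.n_bands)
    for i in range(0, 4096, 97):
        trace = select_endmembers(data[i], lib, SelsmmConfig(eta=0.8))
        assert len(trace.selected) >= 1
        assert len(set(trace.selected)) == len(trace.selected)
        assert len(trace.iterations) <= lib.n_endmembers


def test_larger_eta_selects_fewer_endmembers(default_scene):
    lib = default_scene.library
    data = default_scene.cube.data.reshape(-1, lib.n_bands)
    idx = np.random.default_rng(3).choice(len(data), 60, replace=False)
    means = []
    for eta in (0.1, 0.35, 0.65, 0.9):
        sizes = [len(select_endmembers(data[i], lib,
                                       SelsmmConfig(eta=eta)).selected)
                 for i in idx]
        means.append(np.mean(sizes))
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_config_validation():
    with pytest.raises(ValueError, match="eta"):
        SelsmmConfig(eta=1.5)
    with pytest.raises(ValueError, match="delta_tol"):
        SelsmmConfig(delta_tol=0.0)


def test_include_final_endmember_toggle():
    veg = np.array([0.05, 0.08, 0.05, 0.45, 0.23, 0.12])
    soil = np.array([0.10, 0.15, 0.20, 0.26, 0.33, 0.36])
    lib = SpectralLibrary(names=["veg", "soil"],
                          vis_class=["vegetation", "soil"],
                          spectra=np.vstack([veg, soil]))
    px = 0.5 * veg + 0.5 * soil
    keep = select_endmembers(px, lib, SelsmmConfig(eta=0.9))
    drop = select_endmembers(px, lib, SelsmmConfig(
        eta=0.9, include_final_endmember=False))
    if keep.stop_reason in ("negative_component", "small_delta"):
        assert len(drop.selected) == max(1, len(keep.selected) - 1)


# ---------------------------------------------------------------------------
# image-level


def test_full_selection_reduces_to_lsmm(default_scene):
    """Whenever selection keeps the whole library, the selective model and
    the plain fully constrained model coincide."""
    cube, lib = default_scene.cube, default_scene.library
    abund_s, summary = unmix_image_selsmm(cube, lib, SelsmmConfig(eta=0.35))
    abund_l = unmix_image_lsmm(cube, lib)
    full = summary.n_selected == lib.n_endmembers
    assert full.any()
    diff = np.abs(abund_s.fractions - abund_l.fractions)[full]
    assert np.nanmax(diff) < 1e-9


def test_unselected_endmembers_have_zero_abundance(default_scene):
    cube, lib = default_scene.cube, default_scene.library
    abund, summary = unmix_image_selsmm(cube, lib, SelsmmConfig(eta=0.9))
    unsel = ~abund.selected_mask & ~np.isnan(abund.fractions)
    assert np.all(abund.fractions[unsel] == 0.0)
    valid = ~cube.mask
    sums = np.nansum(abund.fractions, axis=2)[valid]
    assert np.allclose(sums, 1.0, atol=1e-6)


def test_trace_records_roundtrip(default_scene):
    cube, lib = default_scene.cube, default_scene.library
    sub = cube.data[:4, :4]
    from selsmm import ImageCube
    small = ImageCube(data=sub)
    _, summary = unmix_image_selsmm(small, lib, keep_traces=True)
    records = summary.trace_records()
    assert len(records) > 0
    assert {"row", "col", "iteration", "endmember", "r_max", "x_max",
            "stop_reason"} <= set(records[0])
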