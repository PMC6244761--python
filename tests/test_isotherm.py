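"""Isotherm container, file dialect, canonicalization, interpolation, smoothing."""
import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import monofilm as mf
from monofilm.errors import (
    DegenerateIsothermError,
    IsothermFormatError,
    OutOfRangeError,
    ParameterError,
)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def test_read_isotherm_parses_points_and_metadata(tmp_path):
    f = tmp_path / "run.txt"
    f.write_text(
        "# temperature_C: 20\n# subphase: DS40\n# operator: xy\n"
        "90, 0.1\n60, 5.0\n40, 30.0\n"
    )
    iso = mf.read_isotherm(f)
    assert iso.n == 3
    np.testing.assert_allclose(iso.area, [90, 60, 40])
    np.testing.assert_allclose(iso.pressure, [0.1, 5.0, 30.0])
    assert iso.meta.temperature_C == 20
    assert iso.meta.subphase == "DS40"
    assert iso.meta.extra["operator"] == "xy"  # unknown keys preserved


def test_read_isotherm_parses_components(tmp_path):
    f = tmp_path / "mix.txt"
    f.write_text(
        "# components: DPPC=0.7, cholesterol=0.3\n90 0.1\n60 5.0\n40 30.0\n"
    )
    iso = mf.read_isotherm(f)
    assert iso.meta.components == [("DPPC", 0.7), ("cholesterol", 0.3)]
    assert sum(f for _, f in iso.meta.components) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "body, match",
    [
        ("90, 0.1\n60, 5.0\n40, abc\n", "line 3"),
        ("90\n60\n", "two columns"),
        ("", "no data rows"),
    ],
)
def test_read_isotherm_rejects_malformed_files(tmp_path, body, match):
    f = tmp_path / "bad.txt"
    f.write_text(body)
    with pytest.raises(IsothermFormatError, match=match):
        mf.read_isotherm(f)


@st.composite
def isotherm_arrays(draw):
    n = draw(st.integers(4, 16))
    areas = draw(
        st.lists(st.floats(1.0, 500.0), min_size=n, max_size=n, unique=True)
    )
    pressures = draw(st.lists(st.floats(0.0, 70.0), min_size=n, max_size=n))
    return np.sort(np.asarray(areas))[::-1].copy(), np.asarray(pressures)


@given(isotherm_arrays())
@settings(
    max_examples=40,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
def test_file_roundtrip_preserves_points_and_metadata(tmp_path, data):
    areas, pressures = data
    meta = mf.IsothermMeta(
        components=[("sterol", 0.25), ("lipid", 0.75)],
        subphase="DS40+Ca2+",
        temperature_C=20.0,
        barrier_speed=20.0,
        extra={"note": "fixture"},
    )
    iso = mf.Isotherm(areas, pressures, meta)
    path = tmp_path / "roundtrip.txt"
    mf.write_isotherm(iso, path)
    back = mf.read_isotherm(path)
    np.testing.assert_allclose(back.area, iso.area, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(back.pressure, iso.pressure, rtol=1e-10, atol=1e-12)
    assert back.meta.components == meta.components
    assert back.meta.subphase == meta.subphase
    assert back.meta.barrier_speed == meta.barrier_speed
    assert back.meta.extra["note"] == "fixture"


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _sweep_oracle(areas, pressures, tol):
    """Independent cumulative-maximum sweep over area-sorted points."""
    order = np.argsort(-np.asarray(areas), kind="stable")
    a = np.asarray(areas)[order]
    p = np.asarray(pressures)[order]
    keep = [0]
    last = p[0]
    for i in range(1, len(a)):
        if p[i] > last + tol:
            keep.append(i)
            last = p[i]
    idx = np.array(keep)
    return a[idx], p[idx]


def test_canonicalize_identity_on_strictly_monotone(make_linear_isotherm):
    iso = make_linear_isotherm()
    out, report = mf.canonicalize(iso)
    np.testing.assert_array_equal(out.area, iso.area)
    np.testing.assert_array_equal(out.pressure, iso.pressure)
    assert report.n_dropped == 0
    assert not report.reversed


def test_canonicalize_resorts_increasing_area_input(make_linear_isotherm):
    iso = make_linear_isotherm()
    rev = mf.Isotherm(iso.area[::-1].copy(), iso.pressure[::-1].copy(), iso.meta)
    out, report = mf.canonicalize(rev)
    assert report.reversed
    assert out.is_canonical
    np.testing.assert_allclose(out.area, iso.area)


def test_canonicalize_plateau_segment_matches_sweep_oracle():
    # plateau pressures {5.00, 5.01, 4.99, 5.00, 5.02} embedded in a run
    areas = np.array([90.0, 85, 80, 75, 70, 65, 60, 55, 50, 45, 40])
    press = np.array([1.0, 2, 3, 5.00, 5.01, 4.99, 5.00, 5.02, 6, 7, 8])
    iso = mf.Isotherm(areas, press)
    out, report = mf.canonicalize(iso, pressure_tolerance=0.05)
    oa, op = _sweep_oracle(areas, press, 0.05)
    np.testing.assert_array_equal(out.area, oa)
    np.testing.assert_array_equal(out.pressure, op)
    # the first (largest-area) point of the plateau level survives
    assert 75.0 in out.area
    assert report.n_dropped == len(areas) - out.n
    # largest backward excursion among dropped points: 5.00 (kept) - 4.99
    assert report.max_pressure_violation == pytest.approx(0.01, abs=1e-9)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_canonicalize_matches_oracle_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    n = 60
    areas = np.linspace(100.0, 40.0, n)
    pressures = np.cumsum(rng.uniform(-0.02, 0.2, n))  # drifting, noisy walk
    iso = mf.Isotherm(areas, pressures - pressures.min() + 0.1)
    tol = 0.03
    out, _ = mf.canonicalize(iso, pressure_tolerance=tol)
    oa, op = _sweep_oracle(iso.area, iso.pressure, tol)
    np.testing.assert_array_equal(out.area, oa)
    np.testing.assert_array_equal(out.pressure, op)
    twice, rep2 = mf.canonicalize(out, pressure_tolerance=tol)
    assert rep2.n_dropped == 0
    np.testing.assert_array_equal(twice.area, out.area)
    assert out.is_canonical or tol > 0  # strictly monotone for tol >= 0


def test_canonicalize_degenerate_raises():
    iso = mf.Isotherm([90.0, 80, 70, 60], [5.0, 4.0, 3.0, 2.0])  # falling pi
    with pytest.raises(DegenerateIsothermError):
        mf.canonicalize(iso)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def test_area_at_pressure_nodes_and_midpoint():
    iso = mf.Isotherm([90.0, 60, 40, 30], [0.1, 5.0, 30.0, 40.0])
    assert mf.area_at_pressure(iso, 5.0) == pytest.approx(60.0)
    # hand linear interpolation between (60, 5) and (40, 30): 17.5 -> 50
    assert mf.area_at_pressure(iso, 17.5) == pytest.approx(50.0)


@pytest.mark.parametrize("pi", [0.05, 50.0])
def test_area_at_pressure_out_of_range(pi):
    iso = mf.Isotherm([90.0, 60, 40, 30], [0.1, 5.0, 30.0, 40.0])
    with pytest.raises(OutOfRangeError):
        mf.area_at_pressure(iso, pi)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_area_at_pressure_is_monotone_decreasing(seed):
    rng = np.random.default_rng(seed)
    areas = np.sort(rng.uniform(30, 120, 30))[::-1].copy()
    pressures = np.sort(rng.uniform(0.1, 50, 30))
    iso = mf.Isotherm(areas, pressures)
    assert iso.is_canonical
    q = np.sort(rng.uniform(pressures[0], pressures[-1], 20))
    a = mf.area_at_pressure(iso, q)
    assert np.all(np.diff(a) <= 1e-12)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("poly_order", [1, 2, 3])
def test_smooth_reproduces_polynomial_exactly(poly_order):
    n = 101
    x = np.arange(n, dtype=float)
    pressures = 1.0 + 0.3 * x  # linear in index (degree 1 <= every order)
    areas = np.linspace(90, 40, n)
    iso = mf.Isotherm(areas, pressures)
    out = mf.smooth(iso, window_points=11, poly_order=poly_order)
    np.testing.assert_allclose(out.pressure, pressures, atol=1e-9)
    np.testing.assert_array_equal(out.area, areas)


def test_smooth_reduces_noise_rms(make_linear_isotherm):
    iso = make_linear_isotherm(n=301, noise=0.05, seed=3)
    canon, _ = mf.canonicalize(iso)
    out = mf.smooth(canon, window_points=11, poly_order=2)
    true = lambda a: 230.0 - 5.0 * a
    rms_in = np.sqrt(np.mean((canon.pressure - true(canon.area)) ** 2))
    rms_out = np.sqrt(np.mean((out.pressure - true(out.area)) ** 2))
    assert rms_out < rms_in


def test_smooth_accepts_raw_unsorted_input(make_linear_isotherm):
    iso = make_linear_isotherm(n=101)
    raw = mf.Isotherm(iso.area[::-1].copy(), iso.pressure[::-1].copy())
    out = mf.smooth(raw, window_points=11, poly_order=1)
    assert out.is_canonical
    np.testing.assert_allclose(out.pressure, np.sort(iso.pressure), atol=1e-9)


@pytest.mark.parametrize(
    "window, order",
    [(10, 2), (202, 2), (201, 2), (3, 3)],
)
def test_smooth_rejects_bad_windows(make_linear_isotherm, window, order):
    iso = make_linear_isotherm(n=201)
    with pytest.raises(ParameterError):
        mf.smooth(iso, window_points=window, poly_order=order)
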