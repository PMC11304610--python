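"""Signal-processing and statistics tests for the tensile analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aortamimic import synth, tensile
from aortamimic.tensile import (
    SpecimenGeometry,
    StressStrainCurve,
    TensileRecord,
    TensileSummary,
)

GEOM = SpecimenGeometry(
    width=2.0, thickness_measurements=(1.0,) * 5, gauge_length=10.0
)

NOISELESS = synth.NoiseModel(load_noise_sd_n=0.0, inter_sample_cov=0.0)


def _linear_record(E=2.0, n=2000, gauge=10.0, area_geom=GEOM):
    """Noiseless record of a linear material sigma = E * eps."""
    t = np.arange(n) / 100.0
    disp = np.linspace(0.0, gauge, n)
    strain = disp / gauge
    load = E * strain * area_geom.area
    return TensileRecord(time=t, load=load, displacement=disp, geometry=area_geom)


# ---------------------------------------------------------------------------
# Geometry and stress/strain
# ---------------------------------------------------------------------------


def test_specimen_geometry_averages_five_thicknesses():
    g = SpecimenGeometry(
        width=10.0,
        thickness_measurements=(2.5, 2.6, 2.7, 2.6, 2.6),
        gauge_length=25.0,
    )
    assert g.thickness == pytest.approx(2.6)
    assert g.area == pytest.approx(26.0)
    with pytest.raises(ValueError):
        SpecimenGeometry(width=10.0, thickness_measurements=(2.6,) * 4,
                         gauge_length=25.0)


def test_stress_strain_arithmetic():
    """1 N over 2 mm^2 is 0.5 MPa; displacement = gauge is 100% strain."""
    rec = TensileRecord(
        time=np.array([0.0, 0.01]),
        load=np.array([0.0, 1.0]),
        displacement=np.array([0.0, 10.0]),
        geometry=GEOM,
    )
    curve = tensile.compute_stress_strain(rec)
    assert curve.stress[-1] == pytest.approx(0.5)
    assert curve.strain[-1] == pytest.approx(1.0)


@given(scale=st.floats(0.1, 10.0))
def test_stress_strain_linear_in_load_and_displacement(scale):
    rec = _linear_record()
    scaled = TensileRecord(
        time=rec.time,
        load=rec.load * scale,
        displacement=rec.displacement * scale,
        geometry=rec.geometry,
    )
    base = tensile.compute_stress_strain(rec)
    out = tensile.compute_stress_strain(scaled)
    assert np.allclose(out.stress, base.stress * scale)
    assert np.allclose(out.strain, base.strain * scale)


def test_conditioning_cycles_trimmed_to_final_ramp():
    rec = synth.generate_record(
        synth.tissue_model(), noise=NOISELESS, seed=0, conditioning=True
    )
    curve = tensile.compute_stress_strain(rec)
    assert curve.strain[0] == 0.0
    assert np.all(np.diff(curve.strain) >= 0)
    # The analysed ramp covers the full strain range of the material.
    assert curve.strain[-1] == pytest.approx(1.0, abs=0.01)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def test_align_equalizes_vector_sizes():
    """Curves of different durations map onto the median raw length."""
    a = StressStrainCurve(np.linspace(0, 1, 600), np.linspace(0, 2, 600))
    b = StressStrainCurve(np.linspace(0, 1, 900), np.linspace(0, 2, 900))
    out = tensile.align_curves([a, b])
    assert len(out[0]) == len(out[1]) == 750
    # Linear data is reproduced exactly by linear interpolation.
    assert np.allclose(out[0].stress, out[1].stress, atol=1e-9)
    for c in out:
        assert c.strain[0] == 0.0 and c.strain[-1] == pytest.approx(1.0)


def test_align_quadratic_interpolation_bound():
    """Interpolation error on f = x^2 is bounded by h^2 max|f''| / 8."""
    x_fine = np.linspace(0, 1, 101)
    x_coarse = np.linspace(0, 1, 51)
    a = StressStrainCurve(x_fine, x_fine**2)
    b = StressStrainCurve(x_coarse, x_coarse**2)
    out = tensile.align_curves([a, b])
    grid = np.linspace(0, 1, len(out[1]))
    err = np.max(np.abs(out[1].stress - grid**2))
    h = 1.0 / 50.0
    assert err <= h**2 * 2.0 / 8.0 + 1e-12


def test_align_rejects_tiny_curves():
    a = StressStrainCurve(np.linspace(0, 1, 5), np.linspace(0, 1, 5))
    b = StressStrainCurve(np.linspace(0, 1, 50), np.linspace(0, 1, 50))
    with pytest.raises(ValueError):
        tensile.align_curves([a, b])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def test_filter_preserves_constant_signal():
    c = StressStrainCurve(np.linspace(0, 1, 3000), np.full(3000, 0.7))
    out = tensile.filter_pipeline([c, c])
    assert len(out) == 300
    assert np.allclose(out.stress, 0.7, atol=1e-9)


def test_filter_attenuates_above_cutoff():
    """A 1 Hz unit sinusoid (10x cutoff) comes out below 0.03 amplitude."""
    t = np.arange(6000) / 100.0
    c = StressStrainCurve(strain=t / t[-1], stress=np.sin(2 * np.pi * 1.0 * t))
    out = tensile.filter_pipeline([c, c])
    mid = slice(len(out) // 3, 2 * len(out) // 3)
    assert np.max(np.abs(out.stress[mid])) < 0.03
    # Theoretical double-pass Butterworth gain at 10x cutoff.
    gain = 1.0 / (1.0 + 10.0**4)
    assert gain < 0.03


def test_filter_rejects_cutoff_at_nyquist():
    c = StressStrainCurve(np.linspace(0, 1, 1000), np.linspace(0, 1, 1000))
    with pytest.raises(ValueError):
        tensile.filter_pipeline([c], cutoff_hz=5.0)


# ---------------------------------------------------------------------------
# Incremental and secant modulus
# ---------------------------------------------------------------------------


def test_incremental_modulus_linear_material():
    """Full pipeline on noiseless sigma = 2*eps returns E_inc = 2 within 2%."""
    recs = [_linear_record(E=2.0, n=6000) for _ in range(3)]
    raw = [tensile.compute_stress_strain(r) for r in recs]
    avg = tensile.filter_pipeline(tensile.align_curves(raw))
    einc = tensile.incremental_modulus(avg)
    assert np.nanmax(np.abs(einc.modulus - 2.0) / 2.0) < 0.02
    # The window restricts to 15-90% of the test duration.
    assert einc.strain[0] >= 0.14 and einc.strain[-1] <= 0.91


def test_incremental_modulus_tracks_tissue_exponential():
    model = synth.tissue_model(A=0.05, B=3.0)
    recs = [synth.generate_record(model, noise=NOISELESS, seed=i) for i in range(3)]
    raw = [tensile.compute_stress_strain(r) for r in recs]
    avg = tensile.filter_pipeline(tensile.align_curves(raw))
    einc = tensile.incremental_modulus(avg)
    true = synth.incremental_modulus_true(model, einc.strain)
    n = len(true)
    interior = slice(n // 10, n - n // 10)
    rel = np.abs(einc.modulus - true) / true
    assert np.nanmax(rel[interior]) < 0.05


def test_einc_monotonicity_tissue_up_polymer_down():
    """Tissue stiffens with strain; the polymer softens (qualitative shapes)."""
    for model, sign in ((synth.tissue_model(), 1), (synth.polymer_model(), -1)):
        recs = [synth.generate_record(model, noise=NOISELESS, seed=i) for i in range(2)]
        raw = [tensile.compute_stress_strain(r) for r in recs]
        avg = tensile.filter_pipeline(tensile.align_curves(raw))
        einc = tensile.incremental_modulus(avg)
        m = einc.modulus[~np.isnan(einc.modulus)]
        interior = m[len(m) // 10 : -len(m) // 10]
        assert np.all(sign * np.diff(interior) > 0)


def test_secant_modulus_values_and_convexity():
    lin = StressStrainCurve(np.linspace(0.001, 1, 500), 3 * np.linspace(0.001, 1, 500))
    assert tensile.secant_modulus(lin, 0.4) == pytest.approx(3.0)
    x = np.linspace(0, 1, 2001)
    quad = StressStrainCurve(x, x**2)
    assert tensile.secant_modulus(quad, 0.5) == pytest.approx(0.5, rel=1e-4)
    # Convex curve: secant modulus non-decreasing in the evaluation strain.
    secants = [tensile.secant_modulus(quad, e) for e in np.linspace(0.1, 0.9, 9)]
    assert np.all(np.diff(secants) >= 0)
    with pytest.raises(ZeroDivisionError):
        tensile.secant_modulus(quad, 0.0)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def test_summarize_single_curve():
    c = StressStrainCurve(np.linspace(0, 1.0, 100), np.linspace(0, 0.7, 100))
    s = tensile.summarize([c], "m")
    assert s.max_stress_mean == pytest.approx(0.7)
    assert s.strain_at_max_mean_pct == pytest.approx(100.0)
    assert np.isnan(s.max_stress_sd)  # dispersion undefined at n = 1


def test_summarize_zero_dispersion():
    c = StressStrainCurve(np.linspace(0, 1, 50), np.linspace(0, 0.5, 50))
    s = tensile.summarize([c, c, c], "m")
    assert s.max_stress_mean == pytest.approx(0.5)
    assert s.max_stress_sd == 0.0
    assert s.cov_stress == 0.0


def test_summarize_ties_resolve_to_first_peak():
    strain = np.linspace(0, 1, 101)
    stress = np.minimum(strain * 2, 1.0)  # plateau at 1.0 from strain 0.5
    s = tensile.summarize([StressStrainCurve(strain, stress)], "m")
    assert s.strain_at_max_mean_pct == pytest.approx(50.0)


def test_summaries_invariant_to_filter_settings():
    """Max stress/strain come from raw curves, untouched by filtering."""
    model = synth.tissue_model()
    recs = synth.generate_batch(model, n=4, seed=3)
    raw = [tensile.compute_stress_strain(r) for r in recs]
    s1 = tensile.summarize(raw, "m")
    # Filtering with a different cutoff cannot change the summary inputs.
    tensile.filter_pipeline(tensile.align_curves(raw), cutoff_hz=0.02)
    s2 = tensile.summarize(raw, "m")
    assert s1 == s2


# ---------------------------------------------------------------------------
# Welch tests and relation classification
# ---------------------------------------------------------------------------


def _summary(mu, sd, n=6):
    return TensileSummary("s", n, mu, sd, 100.0, 5.0)


def test_welch_matches_textbook_formula():
    a, b = _summary(1.0, 0.1), _summary(0.9, 0.1)
    res = tensile.one_tailed_t_test(a, b, "greater")
    assert res.t == pytest.approx(0.1 / (0.1 * np.sqrt(2.0 / 6.0)))
    assert res.df == pytest.approx(10.0)
    assert res.p == pytest.approx(stats.t.sf(res.t, res.df))


def test_welch_matches_bruteforce_two_sample():
    """Summary-based Welch equals scipy on samples with matching moments."""
    rng = np.random.default_rng(7)
    xa = rng.normal(1.0, 0.2, 8)
    xb = rng.normal(0.8, 0.1, 6)
    a = _summary(xa.mean(), xa.std(ddof=1), len(xa))
    b = _summary(xb.mean(), xb.std(ddof=1), len(xb))
    ours = tensile.one_tailed_t_test(a, b, "greater")
    ref = stats.ttest_ind(xa, xb, equal_var=False, alternative="greater")
    assert ours.t == pytest.approx(ref.statistic)
    assert ours.p == pytest.approx(ref.pvalue)


def test_identical_summaries_do_not_reject():
    a = _summary(0.5, 0.05)
    res = tensile.one_tailed_t_test(a, a, "greater")
    assert res.t == 0.0 and not res.reject
    assert tensile.classify_relation(a, a) == "equal"


@given(
    mu1=st.floats(0.2, 2.0), mu2=st.floats(0.2, 2.0),
    sd=st.floats(0.01, 0.3),
)
def test_relation_antisymmetry(mu1, mu2, sd):
    a, b = _summary(mu1, sd), _summary(mu2, sd)
    rel_ab = tensile.classify_relation(a, b)
    rel_ba = tensile.classify_relation(b, a)
    flip = {"greater": "smaller", "smaller": "greater", "equal": "equal"}
    assert rel_ba == flip[rel_ab]


def test_missing_dispersion_raises():
    a = _summary(1.0, float("nan"), 1)
    with pytest.raises(ValueError):
        tensile.one_tailed_t_test(a, _summary(1.0, 0.1), "greater")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def test_csv_roundtrip(tmp_path):
    rec = synth.generate_record(synth.tissue_model(), seed=4, model_id="Tissue_X")
    path = tensile.write_tensile_csv(rec, tmp_path / "r.csv")
    back = tensile.read_tensile_csv(path)[0]
    assert back.model_id == "Tissue_X"
    assert np.allclose(back.time, rec.time)
    assert np.allclose(back.load, rec.load)
    assert np.allclose(back.displacement, rec.displacement)
    assert back.geometry.area == pytest.approx(rec.geometry.area)


def test_csv_tiny_file(tmp_path):
    p = tmp_path / "tiny.csv"
    p.write_text(
        "# model_id: t\n# width_mm: 2\n# thickness_mm: 1,1,1,1,1\n"
        "# gauge_length_mm: 10\n"
        "time_s,load_N,displacement_mm\n0,0,0\n0.01,0.1,0.0167\n0.02,0.2,0.0333\n"
    )
    recs = tensile.read_tensile_csv(p)
    assert len(recs) == 1 and len(recs[0].time) == 3


def test_csv_off_nominal_rate_resampled(tmp_path):
    p = tmp_path / "r99.csv"
    t = np.arange(50) / 99.0
    lines = "\n".join(f"{ti:.9f},{ti:.3f},{ti:.3f}" for ti in t)
    p.write_text(
        "# width_mm: 2\n# thickness_mm: 1,1,1,1,1\n# gauge_length_mm: 10\n"
        "time_s,load_N,displacement_mm\n" + lines + "\n"
    )
    with pytest.warns(UserWarning):
        rec = tensile.read_tensile_csv(p)[0]
    assert rec.sampling_hz == pytest.approx(100.0)


def test_csv_missing_geometry_is_hard_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("time_s,load_N,displacement_mm\n0,0,0\n")
    with pytest.raises(ValueError):
        tensile.read_tensile_csv(p)
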