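import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcpi import (
    DistributionSummary,
    IndexConstants,
    RegionRecord,
    attenuation,
    attenuation_width_for,
    biomass_barrier,
    enrich_records,
    mcpi_score,
    ndvi_pixel,
    summarize,
)


# -- attenuation ------------------------------------------------------------


def test_attenuation_anchor_values():
    assert attenuation(0.0) == 0.0
    assert attenuation(2.0) == pytest.approx(1 - math.exp(-0.58), abs=1e-12)
    assert attenuation(2.0) == pytest.approx(0.440102, abs=5e-6)


def test_attenuation_rejects_negative_width():
    with pytest.raises(ValueError):
        attenuation(-0.1)


def test_half_attenuation_width_matches_closed_form():
    assert attenuation_width_for(0.5) == pytest.approx(math.log(2) / 0.29, abs=1e-9)
    # a different rate constant scales the half-width inversely
    assert attenuation_width_for(0.5, rate=0.58) == pytest.approx(math.log(2) / 0.58, abs=1e-9)


@settings(deadline=None, max_examples=50)
@given(st.floats(0.0, 30.0), st.floats(0.0, 30.0))
def test_attenuation_monotone(w1, w2):
    lo, hi = sorted((w1, w2))
    assert attenuation(lo) <= attenuation(hi) < 1.0


# -- biomass barrier --------------------------------------------------------


def test_barrier_cap_and_values():
    assert biomass_barrier(10.0) == 1.0
    assert biomass_barrier(28.36) == 1.0  # tallest observed stands still cap at 1
    assert biomass_barrier(5.0) == pytest.approx(0.5**2.55, abs=1e-12)
    assert biomass_barrier(5.0) == pytest.approx(0.170755, abs=5e-6)


def test_barrier_continuous_at_cap_and_flat_above():
    eps = 1e-9
    assert biomass_barrier(10.0 - eps) == pytest.approx(1.0, abs=1e-6)
    assert biomass_barrier(12.0) == biomass_barrier(15.0) == 1.0


def test_barrier_rejects_negative_height():
    with pytest.raises(ValueError):
        biomass_barrier(-1.0)


# -- NDVI -------------------------------------------------------------------


def test_ndvi_pixel_values():
    assert ndvi_pixel(0.3, 0.3) == 0.0
    assert ndvi_pixel(0.5, 0.1) == pytest.approx(2.0 / 3.0, abs=1e-12)
    assert ndvi_pixel(0.4, 0.0) == 1.0
    assert math.isnan(ndvi_pixel(0.0, 0.0))  # undefined -> nodata


def test_ndvi_rejects_out_of_range_reflectance():
    with pytest.raises(ValueError):
        ndvi_pixel(1.2, 0.1)


# -- composition ------------------------------------------------------------


def test_mcpi_product_and_annihilation():
    assert mcpi_score(0.38, 0.74, 0.71) == pytest.approx(199.65, abs=0.01)
    assert mcpi_score(0.0, 1.0, 1.0) == 0.0
    assert mcpi_score(0.5, 0.0, 1.0) == 0.0
    # negative NDVI clips to zero rather than producing a negative index
    assert mcpi_score(0.5, 0.5, -0.2) == 0.0


def test_mcpi_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 0.999, 200)
    b = rng.uniform(0, 1, 200)
    v = rng.uniform(-0.5, 1, 200)
    scores = mcpi_score(a, b, v)
    assert ((scores >= 0) & (scores <= 1000)).all()
    # increasing any factor never decreases the index
    assert mcpi_score(0.6, 0.5, 0.5) >= mcpi_score(0.4, 0.5, 0.5)
    assert mcpi_score(0.4, 0.8, 0.5) >= mcpi_score(0.4, 0.5, 0.5)


def test_saturation_above_height_cap():
    # d(MCPI)/d(height) = 0 beyond the 10 m cap: tall stands are indistinguishable
    base = dict(region_id=0, epoch=2019, amw_m=1500.0, ndvi=0.7, m=5, n=5)
    tall = RegionRecord(ach_m=12.0, **base)
    taller = RegionRecord(ach_m=25.0, **base)
    at_cap = RegionRecord(ach_m=10.0, **base)
    out = enrich_records([tall, taller, at_cap])
    assert out[0].mcpi == out[1].mcpi == out[2].mcpi


def test_enrich_fills_factors_and_is_idempotent():
    rec = RegionRecord(0, 2019, amw_m=2000.0, ach_m=5.0, ndvi=0.6, m=4, n=4)
    (out,) = enrich_records([rec])
    assert out.a == pytest.approx(attenuation(2.0))
    assert out.b == pytest.approx(biomass_barrier(5.0))
    assert out.mcpi == pytest.approx(out.a * out.b * 0.6 * 1000)
    (again,) = enrich_records([out])
    assert again.mcpi == out.mcpi


def test_enrich_zero_width_gives_zero_index():
    rec = RegionRecord(0, 2019, amw_m=0.0, ach_m=5.0, ndvi=0.6, m=4, n=4)
    (out,) = enrich_records([rec])
    assert out.a == 0.0 and out.mcpi == 0.0


def test_minmax_ndvi_switch_rescales_across_records():
    recs = [
        RegionRecord(i, 2019, amw_m=1000.0, ach_m=5.0, ndvi=v, m=3, n=3)
        for i, v in enumerate([0.4, 0.6, 0.8])
    ]
    out = enrich_records(recs, IndexConstants(minmax_ndvi=True))
    a, b = attenuation(1.0), biomass_barrier(5.0)
    assert out[0].mcpi == 0.0
    assert out[1].mcpi == pytest.approx(a * b * 0.5 * 1000)
    assert out[2].mcpi == pytest.approx(a * b * 1.0 * 1000)


# -- distribution summaries -------------------------------------------------


def test_summary_basics():
    s = summarize([1, 2, 3, 4, 5])
    assert (s.median, s.mean, s.maximum) == (3, 3, 5)
    c = summarize([7.0] * 10)
    assert c.sd == 0.0 and c.q1 == c.q3 == 7.0


def test_summary_matches_textbook_formulas_on_lognormal_draws():
    rng = np.random.default_rng(42)
    v = np.sort(rng.lognormal(0.0, 0.8, 10_000))
    s = summarize(v)

    def quantile(p):  # linear interpolation on sorted data, textbook form
        h = (v.size - 1) * p
        lo = int(math.floor(h))
        return v[lo] + (h - lo) * (v[min(lo + 1, v.size - 1)] - v[lo])

    mean = v.sum() / v.size
    sd = math.sqrt(((v - mean) ** 2).sum() / (v.size - 1))
    assert s.q1 == pytest.approx(quantile(0.25), abs=1e-9)
    assert s.median == pytest.approx(quantile(0.5), abs=1e-9)
    assert s.q3 == pytest.approx(quantile(0.75), abs=1e-9)
    assert s.mean == pytest.approx(mean, abs=1e-9)
    assert s.sd == pytest.approx(sd, abs=1e-9)
    assert s.maximum == v[-1]


def test_summary_rejects_empty_and_orders_quartiles():
    with pytest.raises(ValueError):
        summarize([])
    with pytest.raises(ValueError):
        DistributionSummary(q1=2, median=1, q3=3, mean=2, sd=1, maximum=3)
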