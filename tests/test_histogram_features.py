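"""First-order histogram features: conventions, naive oracle, invariances."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nacradiomics.histogram_features import (
    PERCENTILES,
    STAT_NAMES,
    EmptyVoiError,
    VoiMask,
    extract_features,
    feature_table,
    percentile,
)
from nacradiomics.param_maps import ParameterMap


def pmap_from_values(values, name="T2SI"):
    """Pack a 1D multiset into a one-row 3D map."""
    vals = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return ParameterMap(name, vals)


def full_mask(pmap):
    return np.ones(pmap.values.shape, dtype=bool)


def naive_features(values, bins=64):
    """Direct-formula reimplementation used as an independent oracle."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    out = {}
    for p in PERCENTILES:
        rank = (n - 1) * p / 100.0
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        out[f"p{p}"] = x[lo] + (rank - lo) * (x[hi] - x[lo])
    out["max"], out["min"] = x[-1], x[0]
    out["range"] = x[-1] - x[0]
    mu = sum(x) / n
    out["mean"] = mu
    out["median"] = out["p50"]
    out["sd"] = (sum((v - mu) ** 2 for v in x) / (n - 1)) ** 0.5 if n > 1 else 0.0
    m2 = sum((v - mu) ** 2 for v in x) / n
    if m2 == 0:
        out["skewness"] = out["kurtosis"] = float("nan")
    else:
        m3 = sum((v - mu) ** 3 for v in x) / n
        m4 = sum((v - mu) ** 4 for v in x) / n
        out["skewness"] = m3 / m2**1.5
        out["kurtosis"] = m4 / m2**2 - 3.0
    uniq, counts = np.unique(x, return_counts=True)
    if uniq.size == 1:
        out["mode"] = uniq[0]
    elif uniq.size <= bins:
        out["mode"] = uniq[np.argmax(counts)]
    else:
        width = (x[-1] - x[0]) / bins
        idx = np.minimum(((x - x[0]) / width).astype(int), bins - 1)
        best = np.argmax(np.bincount(idx, minlength=bins))
        out["mode"] = x[0] + (best + 0.5) * width
    out["n_voxels"] = n
    return out


class TestPercentile:
    @pytest.mark.parametrize("values, p, expected", [
        ((1, 2, 3, 4, 5), 50, 3.0),
        ((1, 2, 3, 4, 5), 75, 4.0),  # rank (n-1)*p/100 = 3.0 exactly
        ((7,), 0, 7.0),
        ((7,), 50, 7.0),
        ((7,), 100, 7.0),
    ])
    def test_examples(self, values, p, expected):
        assert percentile(np.array(values, float), p) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            percentile(np.array([]), 50)


class TestExtractFeatures:
    def test_hand_arithmetic(self):
        rec = extract_features(pmap_from_values([1, 1, 2]),
                               full_mask(pmap_from_values([1, 1, 2])))
        assert rec.mean == pytest.approx(4 / 3)
        assert rec.median == 1.0
        assert rec.mode == 1.0
        assert (rec.min, rec.max, rec.range) == (1.0, 2.0, 1.0)
        assert rec.n_voxels == 3

    def test_symmetric_sample_has_zero_skewness(self):
        rec = extract_features(pmap_from_values([1, 2, 3]),
                               np.ones((1, 1, 3), bool))
        assert rec.skewness == pytest.approx(0.0, abs=1e-12)

    def test_large_normal_sample_moments(self, rng):
        vals = rng.standard_normal(10_000)
        rec = extract_features(pmap_from_values(vals), np.ones((1, 1, 10_000), bool))
        assert abs(rec.skewness) < 0.1
        assert abs(rec.kurtosis) < 0.2

    def test_constant_voi_flags_undefined_shape_stats(self):
        rec = extract_features(pmap_from_values([5.0] * 8),
                               np.ones((1, 1, 8), bool))
        assert rec.sd == 0.0 and rec.range == 0.0 and rec.mode == 5.0
        assert np.isnan(rec.skewness) and np.isnan(rec.kurtosis)

    def test_empty_voi_error_names_the_map(self):
        pmap = ParameterMap("ADC", np.full((1, 1, 2), np.nan))
        with pytest.raises(EmptyVoiError, match="ADC.*lesion7"):
            extract_features(pmap, np.ones((1, 1, 2), bool), lesion_id="lesion7")

    def test_matches_naive_oracle_on_small_vois(self, rng):
        for trial in range(30):
            n = int(rng.integers(2, 101))
            if trial % 3 == 0:  # heavy ties -> exact-mode path
                vals = rng.integers(0, 6, size=n).astype(float)
            else:  # continuous -> binned-mode path for n > 64
                vals = rng.normal(size=n) * rng.uniform(0.5, 200)
            rec = extract_features(pmap_from_values(vals),
                                   np.ones((1, 1, n), bool))
            expected = naive_features(vals)
            got = {k.split("_", 1)[1]: v for k, v in rec.to_dict().items()}
            for stat in STAT_NAMES:
                a, b = got[stat], expected[stat]
                if isinstance(b, float) and np.isnan(b):
                    assert np.isnan(a), stat
                else:
                    npt.assert_allclose(a, b, rtol=1e-12, atol=1e-12,
                                        err_msg=f"{stat} (n={n})")

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=60),
           st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_equivariance(self, values, a, b):
        vals = np.asarray(values)
        r1 = extract_features(pmap_from_values(vals),
                              np.ones((1, 1, vals.size), bool))
        r2 = extract_features(pmap_from_values(a * vals + b),
                              np.ones((1, 1, vals.size), bool))
        scale = max(1.0, abs(a) * float(np.max(np.abs(vals))) + abs(b))
        for p in PERCENTILES:
            npt.assert_allclose(r2.percentiles[p], a * r1.percentiles[p] + b,
                                rtol=1e-9, atol=1e-9 * scale)
        npt.assert_allclose(r2.mean, a * r1.mean + b, rtol=1e-9,
                            atol=1e-9 * scale)
        npt.assert_allclose(r2.sd, a * r1.sd, rtol=1e-9, atol=1e-9 * scale)
        npt.assert_allclose(r2.range, a * r1.range, rtol=1e-9,
                            atol=1e-9 * scale)
        if not np.isnan(r1.skewness):
            npt.assert_allclose(r2.skewness, r1.skewness, rtol=1e-6, atol=1e-7)
            npt.assert_allclose(r2.kurtosis, r1.kurtosis, rtol=1e-6, atol=1e-7)

    def test_permutation_and_shape_invariance(self, rng):
        vals = rng.normal(size=24)
        flat = pmap_from_values(vals)
        rec1 = extract_features(flat, np.ones((1, 1, 24), bool))
        # same multiset scattered over a different-shaped grid
        grid = np.full((4, 3, 4), np.nan)
        grid.ravel()[rng.permutation(48)[:24]] = rng.permutation(vals)
        pmap = ParameterMap("T2SI", grid)
        rec2 = extract_features(pmap, np.ones((4, 3, 4), bool))
        d1, d2 = rec1.to_dict(), rec2.to_dict()
        assert d1.keys() == d2.keys()
        for k in d1:  # summation order may differ -> allow rounding noise
            npt.assert_allclose(d1[k], d2[k], rtol=1e-12, atol=1e-12,
                                err_msg=k)

    def test_adding_supremum_voxel_grows_max_not_min(self, rng):
        vals = rng.normal(size=20)
        rec1 = extract_features(pmap_from_values(vals), np.ones((1, 1, 20), bool))
        vals2 = np.append(vals, rec1.max + 1.0)
        rec2 = extract_features(pmap_from_values(vals2), np.ones((1, 1, 21), bool))
        assert rec2.max > rec1.max
        assert rec2.range > rec1.range
        assert rec2.min == rec1.min


class TestFeatureTable:
    def _patients(self, rng, n=2):
        maps, masks = {}, {}
        for i in range(n):
            vals = rng.normal(size=(3, 3, 3))
            maps[f"P{i}"] = {name: ParameterMap(name, vals * (j + 1))
                             for j, name in enumerate(
                                 ("ADC", "T2SI", "PEAK", "AUC_ENH", "TME",
                                  "WASHIN", "WASHOUT"))}
            masks[f"P{i}"] = np.ones((3, 3, 3), bool)
        return maps, masks

    def test_dimensions_7_maps_23_stats(self, rng):
        maps, masks = self._patients(rng)
        table = feature_table(maps, masks)
        assert table.shape == (2, 161)
        assert "WASHOUT_p20" in table.columns
        assert "AUC_ENH_max" in table.columns
        assert "TME_p75" in table.columns

    def test_row_order_follows_patient_order(self, rng):
        maps, masks = self._patients(rng, n=3)
        t1 = feature_table(maps, masks)
        rev = dict(reversed(list(maps.items())))
        t2 = feature_table(rev, {k: masks[k] for k in rev})
        assert list(t2.index) == list(reversed(t1.index))
        npt.assert_allclose(t2.loc["P0"].to_numpy(dtype=float),
                            t1.loc["P0"].to_numpy(dtype=float))

    def test_missing_map_yields_nan_row_cells(self, rng, caplog):
        maps, masks = self._patients(rng)
        del maps["P1"]["ADC"]
        table = feature_table(maps, masks)
        assert table.loc["P1", "ADC_mean"] != table.loc["P1", "ADC_mean"]  # NaN
        assert np.isfinite(table.loc["P1", "T2SI_mean"])

    def test_voi_mask_type_validation(self):
        with pytest.raises(ValueError):
            VoiMask(np.zeros((2, 2, 2), bool))
        assert VoiMask(np.ones((2, 2, 2), bool)).n_voxels == 8
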