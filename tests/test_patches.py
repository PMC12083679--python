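"""Tiling, percentile scaling, and QC flagging of the patch pipeline."""

import numpy as np
import pytest

from imcpatch import (
    ConfigurationError,
    StateError,
    analysis_view,
    extract_patches,
    flag_low_signal,
    flag_outliers,
    scale_patches,
)
from imcpatch.patches import PatchTable
from conftest import make_image


def _const_image(rows, cols, value=5.0, **kw):
    arr = np.full((rows, cols), value)
    return make_image(arr, arr, arr, **kw)


@pytest.mark.parametrize(
    "rows, cols, pitch, patch_um, expected",
    [
        (100, 100, 1.0, 50.0, 4),    # 2x2 grid
        (120, 120, 1.0, 50.0, 4),    # 20 px margins dropped
        (100, 100, 0.5, 50.0, 1),    # 100 px patch side at 0.5 um/px
        (37, 91, 1.0, 10.0, 3 * 9),
        (49, 49, 1.0, 50.0, 0),      # patch larger than image
    ],
)
def test_tiling_count_formula(rows, cols, pitch, patch_um, expected):
    img = _const_image(rows, cols, pixel_size_um=pitch)
    table = extract_patches(img, patch_size_um=patch_um)
    p = round(patch_um / pitch)
    assert len(table) == (rows // p) * (cols // p) == expected


def test_constant_channel_patch_means_exact():
    table = extract_patches(_const_image(100, 100, value=7.25))
    assert (table.raw("DNA") == 7.25).all()
    assert (table.raw("TGFb") == 7.25).all()


def test_patch_means_match_manual_tiles(rng):
    img = make_image(*[rng.poisson(3.0, (60, 40)) for _ in range(3)], pixel_size_um=1.0)
    table = extract_patches(img, patch_size_um=20)
    row = table.df[(table.df.patch_row == 2) & (table.df.patch_col == 1)].iloc[0]
    expected = img.channel("Shh")[40:60, 20:40].mean()
    assert row["raw_Shh"] == pytest.approx(expected, abs=1e-12)


def test_patch_below_pixel_pitch_rejected():
    with pytest.raises(ConfigurationError):
        extract_patches(_const_image(10, 10, pixel_size_um=3.0), patch_size_um=1.0)


def test_scaling_constant_sample_gives_one():
    table = scale_patches(extract_patches(_const_image(100, 100, value=5.0)))
    assert np.allclose(table.scaled("Shh"), 1.0)
    refs = table.scaling_refs
    assert (refs["reference"] == 5.0).all()


def test_percentile_reference_matches_interpolation_rule():
    """1..100 patch means: reference from the declared linear-interpolation rule."""
    vals = np.arange(1.0, 101.0)
    # image whose 10x10 grid of 10px patches has means exactly 1..100
    tile_vals = vals.reshape(10, 10)
    img_arr = np.kron(tile_vals, np.ones((10, 10)))
    img = make_image(img_arr, img_arr, img_arr)
    table = scale_patches(extract_patches(img, patch_size_um=10))
    # hand-computed linear interpolation: position (n-1)*q = 99*0.99 = 98.01
    lo, hi = vals[98], vals[99]
    expected_ref = lo + 0.01 * (hi - lo)
    ref = float(table.scaling_refs.query("marker=='Shh'")["reference"].iloc[0])
    assert ref == pytest.approx(expected_ref, abs=1e-9)
    assert table.scaled("Shh").max() > 1.0
    assert table.scaled("Shh").max() == pytest.approx(100.0 / expected_ref)


def test_percentile_100_bounds_scaled_at_one(rng):
    img = make_image(*[rng.poisson(4.0, (100, 100)) for _ in range(3)])
    table = scale_patches(extract_patches(img), percentile=100)
    for m in ("DNA", "Shh", "TGFb"):
        assert table.scaled(m).max() <= 1.0 + 1e-12


def test_scaling_equivariance_under_sample_rescaling(rng):
    """Multiplying one sample's channel by k leaves scaled values unchanged."""
    base = rng.poisson(4.0, (100, 100)).astype(float)
    t1 = scale_patches(extract_patches(make_image(base, base, base)))
    t2 = scale_patches(extract_patches(make_image(base, 3.7 * base, base)))
    np.testing.assert_allclose(t1.scaled("Shh"), t2.scaled("Shh"), rtol=1e-12)


def test_zero_reference_yields_zeros(caplog):
    img = make_image(np.zeros((100, 100)), np.ones((100, 100)), np.ones((100, 100)))
    with caplog.at_level("WARNING"):
        table = scale_patches(extract_patches(img))
    assert (table.scaled("DNA") == 0).all()
    assert "zero" in caplog.text.lower()


def test_unknown_marker_rejected(rng):
    img = make_image(*[rng.poisson(4.0, (100, 100)) for _ in range(3)])
    with pytest.raises(ConfigurationError, match="unknown markers"):
        scale_patches(extract_patches(img), markers=("DNA", "CD45"))


def test_flagging_requires_scaled_table():
    table = extract_patches(_const_image(100, 100))
    with pytest.raises(StateError):
        flag_outliers(table)
    with pytest.raises(StateError):
        flag_low_signal(table)


def test_outlier_boundary_inclusive(rng):
    """scaled == 1.0 is not an outlier; only strictly above the reference is."""
    img = make_image(*[rng.poisson(4.0, (100, 100)) for _ in range(3)])
    table = scale_patches(extract_patches(img), percentile=100)  # max-normalized: all <= 1
    flagged = flag_outliers(table)
    assert (flagged.df["qc_flags"] == "").all()


def test_hot_pixel_patch_flagged(rng):
    arr = rng.poisson(4.0, (100, 100)).astype(float)
    hot = arr.copy()
    hot[10, 10] = 50000.0  # one hot pixel dominates its patch mean
    table = scale_patches(extract_patches(make_image(arr, hot, arr)))
    flagged = flag_outliers(table)
    row = flagged.df[(flagged.df.patch_row == 0) & (flagged.df.patch_col == 0)].iloc[0]
    assert "outlier" in row["qc_flags"]


def test_outlier_rate_near_one_percent(rng):
    """~1% of patches exceed their own 99th-percentile reference by construction."""
    img = make_image(*[rng.normal(100.0, 10.0, (495, 495)).clip(min=0) for _ in range(3)],
                     pixel_size_um=1.0)
    table = flag_outliers(scale_patches(extract_patches(img, patch_size_um=15)))
    n = len(table)  # 33*33 = 1089 patches
    per_marker = [
        (table.scaled(m) > 1.0).mean() for m in ("DNA", "Shh", "TGFb")
    ]
    for rate in per_marker:
        # binomial 99.7% band around 0.01 with n=1089
        assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n)


def test_low_signal_threshold_validation(rng):
    img = make_image(*[rng.poisson(4.0, (100, 100)) for _ in range(3)])
    table = scale_patches(extract_patches(img))
    with pytest.raises(ConfigurationError):
        flag_low_signal(table, dna_threshold=1.5)


def test_low_signal_blank_regions_flagged():
    """Blank (zero-DNA) tissue regions are flagged; covered regions are not."""
    dna = np.ones((100, 100)) * 8.0
    dna[:, 50:] = 0.0  # right half blank
    other = np.ones((100, 100))
    table = flag_low_signal(scale_patches(extract_patches(make_image(dna, other, other))))
    flags = table.df.sort_values(["patch_row", "patch_col"])["qc_flags"].tolist()
    assert flags == ["", "low_signal", "", "low_signal"]


def test_low_signal_fraction_grows_with_blank_area_and_threshold():
    def flagged_fraction(blank_cols, thr=0.05):
        dna = np.full((100, 200), 8.0)
        if blank_cols:
            dna[:, -blank_cols:] = 0.0
        other = np.ones_like(dna)
        t = flag_low_signal(scale_patches(extract_patches(make_image(dna, other, other))), thr)
        return (t.df["qc_flags"] != "").mean()

    fractions = [flagged_fraction(b) for b in (0, 50, 100, 150)]
    assert fractions == sorted(fractions) and fractions[0] < fractions[-1]
    assert flagged_fraction(50, thr=0.0) <= flagged_fraction(50, thr=0.05)


def test_qc_flags_commute(rng):
    arr = rng.poisson(4.0, (200, 200)).astype(float)
    dna = arr.copy()
    dna[:, :50] = 0.0
    shh = arr.copy()
    shh[5, 5] = 1e5
    table = scale_patches(extract_patches(make_image(dna, shh, arr)))
    ab = flag_low_signal(flag_outliers(table))
    ba = flag_outliers(flag_low_signal(table))
    assert (ab.df["qc_flags"] == ba.df["qc_flags"]).all()
    assert set(ab.df["qc_flags"]) >= {"", "low_signal"}


def test_analysis_view_counts_and_monotonicity(rng):
    arr = rng.poisson(4.0, (200, 200)).astype(float)
    dna = arr.copy()
    dna[:, :50] = 0.0
    table = scale_patches(extract_patches(make_image(dna, arr, arr)))
    view0, counts0 = analysis_view(table)
    assert counts0["total_removed"] == 0 and len(view0) == len(table)
    t1 = flag_low_signal(table)
    view1, counts1 = analysis_view(t1)
    assert len(view1) == len(table) - counts1["total_removed"]
    t2 = flag_outliers(t1)
    view2, counts2 = analysis_view(t2)
    assert len(view2) <= len(view1)  # more flagging never adds records back
    assert counts2["low_signal"] == counts1["low_signal"]


def test_analysis_view_all_flagged_empty(caplog):
    dna = np.zeros((100, 100))
    one = np.ones((100, 100))
    table = flag_low_signal(scale_patches(extract_patches(make_image(dna, one, one))))
    with caplog.at_level("WARNING"):
        view, counts = analysis_view(table)
    assert len(view) == 0
    assert counts["total_removed"] == 4


def test_patch_table_csv_roundtrip(tmp_path, rng):
    img = make_image(*[rng.poisson(4.0, (100, 100)) for _ in range(3)])
    table = flag_outliers(scale_patches(extract_patches(img)))
    table.to_csv(tmp_path / "patches.csv", refs_path=tmp_path / "refs.csv")
    back = PatchTable.from_csv(tmp_path / "patches.csv", patch_size_um=50.0,
                               refs_path=tmp_path / "refs.csv")
    assert back.markers == table.markers
    np.testing.assert_allclose(back.scaled("TGFb"), table.scaled("TGFb"), rtol=1e-12)
    assert (back.df["qc_flags"] == table.df["qc_flags"]).all()
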