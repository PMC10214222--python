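"""Image metrics: segmentation, N:C ratios, fat:cyto, Alizarin, maps, 4PL."""

import dataclasses

import numpy as np
import pytest

from nichefab.errors import (
    ConfigurationError,
    GeometryError,
    UndefinedRatioError,
    ValidationError,
)
from nichefab.quantify import (
    LabeledVolume,
    alizarin_score,
    fat_cyto,
    fit_sigmoid,
    map_expression,
    nc_ratio,
    region_stats,
    segment_nuclei_simple,
)
from nichefab.synth import ImageSceneParams, gen_dose_response, gen_niche_image


def _toy_volume(nuclear_value=200.0, cyto_value=100.0):
    """One cell: a 3x3x3 nucleus inside a cytoplasm shell, no noise."""
    shape = (9, 15, 15)
    labels = np.zeros(shape, dtype=np.int32)
    labels[3:6, 6:9, 6:9] = 1
    cyto = np.zeros(shape, dtype=bool)
    cyto[2:7, 4:11, 4:11] = True
    img = np.zeros(shape)
    img[cyto] = cyto_value
    img[labels == 1] = nuclear_value
    cyto_mask = cyto | (labels > 0)
    return LabeledVolume(
        channels={"marker": img}, nuclear_labels=labels, cytoplasm_mask=cyto_mask
    )


class TestSegmentation:
    def test_separated_spheres_counted_exactly(self):
        vol, truth = gen_niche_image(
            ImageSceneParams(n_cells=10, poisson_noise=False, read_noise_sd=0.0,
                             seed=1),
            niche_geometry=(120.0, 60.0),
        )
        labels = segment_nuclei_simple(vol.channels["nuclei"])
        assert labels.max() == 10

    def test_blank_image_zero_labels_with_warning(self):
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_nuclei_simple(np.zeros((8, 32, 32)))
        assert labels.max() == 0

    def test_touching_spheres_split_by_watershed(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        img[(yy - 20) ** 2 + (xx - 14) ** 2 <= 64] = 200.0
        img[(yy - 20) ** 2 + (xx - 27) ** 2 <= 64] = 200.0
        labels = segment_nuclei_simple(img, min_distance=4)
        assert labels.max() == 2


class TestNCRatio:
    def test_constructed_ratio_of_two(self):
        vol = _toy_volume(nuclear_value=200.0, cyto_value=100.0)
        cells, report = nc_ratio(vol, "marker")
        assert report["n_dropped"] == 0
        assert len(cells) == 1
        assert cells[0].nc_ratio == pytest.approx(2.0, rel=1e-12)

    def test_uniform_intensity_gives_unity(self):
        vol = _toy_volume(nuclear_value=77.0, cyto_value=77.0)
        cells, _ = nc_ratio(vol, "marker")
        assert cells[0].nc_ratio == pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance(self):
        vol = _toy_volume()
        base = nc_ratio(vol, "marker")[0][0].nc_ratio
        vol.channels["marker"] = vol.channels["marker"] * 17.3
        scaled = nc_ratio(vol, "marker")[0][0].nc_ratio
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_missing_channel_raises_key_error(self):
        with pytest.raises(KeyError):
            nc_ratio(_toy_volume(), "absent")

    @pytest.mark.parametrize("level", [0.5, 1.0, 2.0, 4.0])
    def test_population_recovery_with_poisson_noise(self, level):
        vol, truth = gen_niche_image(
            ImageSceneParams(n_cells=25, nc_levels=(level,), seed=int(level * 7)),
            niche_geometry=(160.0, 160.0),
        )
        cells, _ = nc_ratio(vol, "marker")
        med = np.median([c.nc_ratio for c in cells])
        assert abs(med - level) / level <= 0.10


class TestFatCyto:
    def test_no_lipid_is_zero(self):
        vol = _toy_volume()
        vol.channels["lipid"] = np.zeros_like(vol.channels["marker"])
        ratio, _ = fat_cyto(vol, "lipid")
        assert ratio == 0.0

    def test_constructed_thirty_percent(self):
        vol = _toy_volume()
        cyto_idx = np.argwhere(vol.cytoplasm_mask)
        n = len(cyto_idx)
        k = int(round(0.30 * n))
        lipid = np.zeros_like(vol.channels["marker"])
        for z, y, x in cyto_idx[:k]:
            lipid[z, y, x] = 300.0
        vol.channels["lipid"] = lipid
        ratio, _ = fat_cyto(vol, "lipid", threshold=150.0)
        assert ratio == pytest.approx(k / n, abs=1e-12)

    def test_empty_cytoplasm_raises(self):
        vol = _toy_volume()
        vol.cytoplasm_mask = np.zeros_like(vol.cytoplasm_mask)
        with pytest.raises(UndefinedRatioError):
            fat_cyto(vol, "marker")

    @pytest.mark.parametrize("frac", [0.05, 0.15, 0.35])
    def test_droplet_field_recovery(self, frac):
        vol, truth = gen_niche_image(
            ImageSceneParams(n_cells=16, lipid_fraction=frac, seed=int(frac * 100)),
            niche_geometry=(140.0, 140.0),
        )
        ratio, _ = fat_cyto(vol, "lipid")
        assert abs(ratio - truth["lipid_fraction"]) / truth["lipid_fraction"] <= 0.10


class TestAlizarin:
    def test_pure_red_scores_one(self):
        img = np.zeros((20, 20, 3))
        img[..., 0] = 200.0
        roi = [(2, 2), (17, 2), (17, 17), (2, 17)]
        assert alizarin_score(img, roi) == pytest.approx(1.0)

    def test_achromatic_scores_exactly_one_third(self):
        img = np.full((20, 20, 3), 85.0)
        roi = [(2, 2), (17, 2), (17, 17), (2, 17)]
        assert alizarin_score(img, roi) == 1.0 / 3.0

    def test_known_channel_means(self):
        img = np.zeros((20, 20, 3))
        img[..., 0], img[..., 1], img[..., 2] = 120.0, 60.0, 60.0
        roi = [(2, 2), (17, 2), (17, 17), (2, 17)]
        assert alizarin_score(img, roi) == pytest.approx(0.5, rel=1e-12)

    def test_roi_outside_image_raises(self):
        img = np.zeros((20, 20, 3))
        with pytest.raises(GeometryError):
            alizarin_score(img, [(2, 2), (30, 2), (30, 17)])


class TestMapExpression:
    def _cells(self, seed=3, n=25, level=2.0):
        vol, _ = gen_niche_image(
            ImageSceneParams(n_cells=n, nc_levels=(level,), seed=seed),
            niche_geometry=(160.0, 160.0),
        )
        return nc_ratio(vol, "marker")[0]

    def test_identity_transform_preserves_coordinates(self):
        cells = self._cells()
        nm = map_expression([(cells, np.eye(3))], (160.0, 160.0), bin_um=20.0)
        xy = nm.cells[["x", "y"]].to_numpy()
        expected = np.array([(c.centroid[2], c.centroid[1]) for c in cells])
        assert np.allclose(xy, expected)

    def test_offset_replicates_coincide_after_mapping(self):
        cells = self._cells()
        shifted = [
            dataclasses.replace(
                c, centroid=(c.centroid[0], c.centroid[1], c.centroid[2] + 100.0)
            )
            for c in cells
        ]
        t_back = np.eye(3)
        t_back[0, 2] = -100.0
        nm = map_expression(
            [(cells, np.eye(3)), (shifted, t_back)], (160.0, 160.0), bin_um=20.0
        )
        a = nm.cells[nm.cells.replicate_id == 0][["x", "y"]].to_numpy()
        b = nm.cells[nm.cells.replicate_id == 1][["x", "y"]].to_numpy()
        assert np.abs(a - b).mean() < 1.0  # < 1 voxel (1 µm voxels)

    def test_cell_count_conservation(self):
        c1, c2 = self._cells(seed=3), self._cells(seed=4, n=20)
        nm = map_expression([(c1, np.eye(3)), (c2, np.eye(3))], (160.0, 160.0))
        assert nm.n_pooled + nm.n_excluded == len(c1) + len(c2)
        assert nm.n_excluded == 0

    def test_missing_transform_raises(self):
        with pytest.raises(ConfigurationError):
            map_expression([(self._cells(), None)], (160.0, 160.0))

    def test_gradient_yields_monotone_binned_means(self):
        vol, _ = gen_niche_image(
            ImageSceneParams(
                n_cells=24, gradient=(0.5, 4.0), poisson_noise=False,
                read_noise_sd=0.0, seed=5,
            ),
            niche_geometry=(240.0, 100.0),
        )
        cells, _ = nc_ratio(vol, "marker")
        nm = map_expression(
            [(cells, np.eye(3))], (240.0, 100.0), bin_um=40.0,
            normalization="minmax",
        )
        col_means = np.nanmean(nm.surface, axis=0)
        col_means = col_means[np.isfinite(col_means)]
        assert np.all(np.diff(col_means) > 0)

    def test_region_summaries(self):
        cells = self._cells()
        nm = map_expression(
            [(cells, np.eye(3))], (160.0, 160.0),
            property_regions={"left": (0, 0, 80, 160), "right": (80, 0, 80, 160)},
        )
        assert set(nm.region_summaries) == {"left", "right"}
        total = sum(v["n"] for v in nm.region_summaries.values())
        assert total >= nm.n_pooled  # boundary cells may count in both


class TestSigmoid:
    def test_noise_free_self_consistency(self):
        doses = np.array([0.1, 0.3, 0.6, 1.0, 2.0, 4.0, 8.0, 16.0])
        df, truth = gen_dose_response((1.0, 3.0, 2.0, 2.0), doses, noise_sd=0.0)
        fit = fit_sigmoid(df["dose"], df["response"])
        assert fit.bottom == pytest.approx(1.0, rel=1e-3)
        assert fit.top == pytest.approx(3.0, rel=1e-3)
        assert fit.ec50 == pytest.approx(2.0, rel=1e-3)
        assert fit.hill == pytest.approx(2.0, rel=1e-3)

    def test_constant_response_flagged(self):
        doses = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fit = fit_sigmoid(doses, np.full(5, 1.5))
        assert fit.degenerate
        assert fit.top == fit.bottom == 1.5

    def test_ec50_recovery_under_noise(self):
        doses = np.repeat([0.25, 0.5, 1.0, 2.0, 4.0, 8.0], 3)
        errs = []
        for seed in range(10):
            df, _ = gen_dose_response((1.0, 3.0, 2.0, 2.0), doses, 0.05, seed=seed)
            fit = fit_sigmoid(df["dose"], df["response"])
            errs.append(abs(fit.ec50 - 2.0) / 2.0)
        assert np.median(errs) <= 0.15

    def test_decreasing_response_keeps_top_above_bottom(self):
        doses = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        # bottom 3 at low dose falling to 1 at high dose (hill > 0, top < bottom
        # in the generator's parameterization)
        df, _ = gen_dose_response((3.0, 1.0, 2.0, 2.0), doses, noise_sd=0.0)
        assert df["response"].is_monotonic_decreasing
        fit = fit_sigmoid(df["dose"], df["response"])
        assert fit.top >= fit.bottom
        assert fit.hill < 0
        assert fit.top == pytest.approx(3.0, rel=1e-3)
        assert fit.bottom == pytest.approx(1.0, rel=1e-3)

    def test_too_few_doses_raise(self):
        with pytest.raises(ValidationError):
            fit_sigmoid([1, 2, 3, 4], [1, 2, 3, 4])


def test_region_stats_wrapper_discriminates_groups():
    rng = np.random.default_rng(0)
    stats = region_stats(
        {
            "soft": rng.normal(1.0, 0.1, 30),
            "stiff": rng.normal(2.0, 0.1, 30),
        }
    )
    assert stats["anova_p"] < 1e-6
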