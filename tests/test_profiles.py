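"""Along-vessel binning, decile ranking, radial profiles, densities."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_distance
from vesseltau.geometry import Centerline, VesselRecord
from vesseltau.io import RunConfig
from vesseltau.objects import ObjectRecord
from vesseltau.profiles import (
    bin_along_vessel,
    heatmap_table,
    layer_summaries,
    locate_objects,
    object_density,
    percent_nft_by_decile,
    radial_profile,
    rank_deciles,
)
from vesseltau.volumes import ImageVolume, LayerVolume


def straight_vessel(length_um=95.0, radius=3.0, shape=(16, 16, 110), donor="d1"):
    """Hand-built straight vessel along x with an exact analytic centerline."""
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    c = shape[0] / 2
    x0 = 5.0
    mask = (
        ((z + 0.5 - c) ** 2 + (y + 0.5 - c) ** 2 <= radius**2)
        & (x + 0.5 >= x0)
        & (x + 0.5 <= x0 + length_um)
    )
    n = int(length_um) + 1
    nodes = np.stack(
        [np.full(n, c), np.full(n, c), x0 + np.linspace(0, length_um, n)], axis=1
    )
    cl = Centerline(nodes, np.linspace(0, length_um, n))
    from vesseltau.geometry import compute_distance_field

    field = compute_distance_field(mask, (1, 1, 1), max_distance_um=100)
    return VesselRecord(0, donor, mask, (1.0, 1.0, 1.0), cl, field, 2 * radius)


@pytest.fixture(scope="module")
def vessel():
    return straight_vessel()


@pytest.fixture
def config():
    return RunConfig()


class TestBinAlongVessel:
    def test_uniform_intensity_gives_uniform_bins(self, vessel, config):
        vol = ImageVolume(np.full(vessel.mask.shape, 5.0), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config, donor_id="d1")
        assert np.allclose(bins["mean_surface_intensity"], 5.0)

    def test_bin_partition_and_trailing_partial(self, vessel, config):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config)
        assert len(bins) == 10
        assert bins["arc_start_um"].tolist() == [10.0 * k for k in range(10)]
        assert bins["arc_end_um"].iloc[-1] == pytest.approx(95.0)
        assert bins["partial"].tolist() == [False] * 9 + [True]

    def test_too_short_vessel_rejected(self, config):
        v = straight_vessel(length_um=6.0, shape=(16, 16, 20))
        vol = ImageVolume(np.ones(v.mask.shape), (1, 1, 1))
        with pytest.raises(ValueError, match="shorter than one bin"):
            bin_along_vessel(vol, v, config)

    def test_surface_voxel_conservation(self, vessel, config):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config)
        expected = (vessel.distance_field.values <= config.surface_band_um).sum()
        assert bins["n_surface_voxels"].sum() == expected

    def test_matches_brute_force_groupby(self, config, rng):
        v = straight_vessel(length_um=24.0, radius=2.5, shape=(12, 12, 32))
        data = rng.random(v.mask.shape) * 50
        vol = ImageVolume(data, (1, 1, 1))
        bins = bin_along_vessel(vol, v, config)
        # oracle: brute-force distances + exhaustive nearest node, groupby
        d = brute_force_distance(v.mask, (1, 1, 1))
        idx = np.argwhere(np.ones_like(v.mask))
        pts = idx + 0.5
        nearest = np.argmin(
            np.linalg.norm(pts[:, None, :] - v.centerline.nodes[None], axis=2), axis=1
        )
        arc = v.centerline.cumulative_arclength[nearest].reshape(v.mask.shape)
        surf = d <= config.surface_band_um
        n_bins = len(bins)
        k = np.clip((arc / 10.0).astype(int), 0, n_bins - 1)
        for b in range(n_bins):
            sel = surf & (k == b)
            assert bins["mean_surface_intensity"].iloc[b] == pytest.approx(
                data[sel].mean()
            )
            assert bins["n_surface_voxels"].iloc[b] == sel.sum()
            vol_sel = (d <= config.density_radius_um) & (k == b)
            assert bins["neighborhood_volume_mm3"].iloc[b] == pytest.approx(
                vol_sel.sum() / 1e9
            )

    def test_modal_layer_assignment(self, vessel, config):
        labels = np.zeros(vessel.mask.shape, int)
        labels[:, :, :55] = 2
        labels[:, :, 55:] = 5
        layers = LayerVolume(labels, (1, 1, 1))
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config, layers=layers)
        assert bins["layer"].iloc[0] == 2
        assert bins["layer"].iloc[-1] == 5


class TestRankDeciles:
    def _bins(self, values, donor="d1"):
        return pd.DataFrame(
            {
                "donor_id": donor,
                "vessel_id": 0,
                "bin_index": np.arange(len(values)),
                "mean_surface_intensity": values,
            }
        )

    def test_strictly_increasing_ten_bins(self, config):
        out = rank_deciles(self._bins(np.arange(10.0)), config)
        assert out["decile"].tolist() == list(range(1, 11))

    def test_all_ties_share_one_decile(self, config):
        out = rank_deciles(self._bins(np.full(20, 7.0)), config)
        assert out["decile"].nunique() == 1

    def test_thousand_random_bins_balanced(self, config, rng):
        vals = rng.random(1000)
        out = rank_deciles(self._bins(vals), config)
        counts = out["decile"].value_counts()
        assert sorted(counts.index) == list(range(1, 11))
        assert all(counts == 100)
        # sort-based oracle: k-th hundred of the sorted values → decile k+1
        order = np.argsort(vals)
        oracle = np.empty(1000, int)
        for k in range(10):
            oracle[order[100 * k : 100 * (k + 1)]] = k + 1
        assert out["decile"].tolist() == oracle.tolist()

    def test_decile_means_nondecreasing(self, config, rng):
        out = rank_deciles(self._bins(rng.random(300)), config)
        means = out.groupby("decile")["mean_surface_intensity"].mean()
        assert means.is_monotonic_increasing

    def test_too_few_bins_rejected(self, config):
        with pytest.raises(ValueError, match="fewer"):
            rank_deciles(self._bins(np.arange(5.0)), config)

    def test_donor_pooling_is_default(self, config):
        a = self._bins(np.arange(10.0), donor="d1")
        b = self._bins(np.arange(10.0) + 100, donor="d2")
        out = rank_deciles(pd.concat([a, b], ignore_index=True), config)
        # each donor ranked separately → both spans 1..10
        for donor in ("d1", "d2"):
            assert out.loc[out.donor_id == donor, "decile"].tolist() == list(range(1, 11))


class TestRadialProfile:
    def test_uniform_image_zero_percent_everywhere(self, vessel, config):
        vol = ImageVolume(np.full(vessel.mask.shape, 9.0), (1, 1, 1))
        bins = rank_deciles(bin_along_vessel(vol, vessel, config, donor_id="d1"), config)
        prof = radial_profile(vol, [vessel], bins, config, donor_id="d1")
        assert len(prof) > 0
        assert np.allclose(prof["pct_change"], 0.0)

    def test_distance_bands_partition_export_radius(self, vessel, config):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = rank_deciles(bin_along_vessel(vol, vessel, config, donor_id="d1"), config)
        prof = radial_profile(vol, [vessel], bins, config, donor_id="d1")
        assert prof["r_inner_um"].min() == 0.0
        assert prof["r_outer_um"].max() <= config.export_radius_um
        assert (prof["r_outer_um"] - prof["r_inner_um"]).max() == config.radial_step_um
        # interior voxels (d = 0) are excluded from radial bands
        n_annulus = ((vessel.distance_field.values > 0)
                     & (vessel.distance_field.values <= config.export_radius_um)).sum()
        assert prof["n_voxels"].sum() == n_annulus


class TestObjectDensity:
    def _objs(self, vessel):
        recs = [
            ObjectRecord(1, "neuron", np.array([8.0, 11.5, 30.5]), 20),  # d≈1.6, arc 25
            ObjectRecord(2, "tangle", np.array([8.0, 8.0, 50.0]), 10),
            ObjectRecord(3, "neuron", np.array([8.0, 8.0, 104.0]), 20),  # beyond end
        ]
        return locate_objects(recs, [vessel], RunConfig())

    def test_single_neuron_lands_in_bin_2(self, vessel, config):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config, donor_id="")
        recs = self._objs(vessel)
        assert recs[0].distance_um <= config.density_radius_um
        out = object_density(bins, recs[:1], config)
        assert out["neuron_count"].iloc[2] == 1  # arc 25 → interval [20, 30)
        assert out["neuron_count"].sum() == 1
        assert out["neuron_density_per_mm3"].iloc[2] == pytest.approx(
            1.0 / out["neighborhood_volume_mm3"].iloc[2]
        )

    def test_no_objects_all_zero(self, vessel, config):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config)
        out = object_density(bins, [], config)
        assert out["neuron_count"].sum() == 0
        assert np.allclose(out["neuron_density_per_mm3"], 0.0)

    def test_counts_match_brute_force(self, vessel, config, rng):
        vol = ImageVolume(np.ones(vessel.mask.shape), (1, 1, 1))
        bins = bin_along_vessel(vol, vessel, config)
        recs = [
            ObjectRecord(i, "neuron" if i % 2 else "tangle",
                         rng.uniform([0, 0, 0], [16, 16, 110]), 5)
            for i in range(60)
        ]
        locate_objects(recs, [vessel], config)
        out = object_density(bins, recs, config)
        for b in range(len(bins)):
            lo, hi = 10.0 * b, 10.0 * (b + 1)
            expect = {"neuron": 0, "tangle": 0}
            for r in recs:
                if r.distance_um is None or r.distance_um > config.density_radius_um:
                    continue
                arc = min(max(r.arc_um, 0.0), 94.999)
                k = min(int(arc // 10), len(bins) - 1)
                if k == b:
                    expect[r.object_class] += 1
            assert out["neuron_count"].iloc[b] == expect["neuron"]
            assert out["tangle_count"].iloc[b] == expect["tangle"]


class TestSummaries:
    def _bins_with_counts(self):
        return pd.DataFrame(
            {
                "donor_id": ["d1"] * 4,
                "vessel_id": [0, 0, 0, 0],
                "bin_index": [0, 1, 2, 3],
                "mean_surface_intensity": [1.0, 2.0, 3.0, 4.0],
                "n_surface_voxels": [10, 10, 20, 0],
                "neighborhood_volume_mm3": [1e-5] * 4,
                "layer": [1, 1, 2, 0],
                "decile": [1, 5, 10, 5],
                "neuron_count": [4, 0, 2, 0],
                "nft_neuron_count": [2, 0, 2, 0],
                "tangle_count": [1, 0, 0, 0],
            }
        )

    def test_percent_nft_pooled_within_decile(self):
        t = percent_nft_by_decile(self._bins_with_counts())
        assert t.loc["d1", "decile_1"] == pytest.approx(50.0)
        assert t.loc["d1", "decile_10"] == pytest.approx(100.0)
        assert np.isnan(t.loc["d1", "decile_5"])  # zero neurons → missing, not 0
        assert np.isnan(t.loc["d1", "decile_2"])

    def test_percent_nft_extremes(self):
        bins = self._bins_with_counts()
        bins["nft_neuron_count"] = bins["neuron_count"]
        assert (percent_nft_by_decile(bins).stack() == 100.0).all()
        bins["nft_neuron_count"] = 0
        assert (percent_nft_by_decile(bins).stack() == 0.0).all()

    def test_layer_summary_weighted_means(self):
        out = layer_summaries(self._bins_with_counts()).set_index("layer")
        assert out.loc[1, "mean_surface_intensity"] == pytest.approx(1.5)
        assert out.loc[2, "mean_surface_intensity"] == pytest.approx(3.0)
        assert out.loc[1, "neuron_density_per_mm3"] == pytest.approx(4 / 2e-5)
        assert 0 in out.index  # layer 0 reported separately, not merged

    def test_heatmap_log_normalization(self):
        bins = self._bins_with_counts()
        out = heatmap_table(bins, image_mean=2.0).set_index(["donor_id", "vessel_id"])
        row = out.loc[("d1", 0)]
        assert row["bin_1"] == 0.0  # equals image mean → log ratio 0
        assert row["bin_3"] == pytest.approx(np.log10(2.0))
        assert row.tolist() == sorted(row.tolist())  # monotone in, monotone out
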