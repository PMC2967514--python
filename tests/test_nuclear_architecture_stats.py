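"""Radial positioning, shell binning and the paper-style statistical tests."""

import math

import numpy as np
import pytest

from conftest import fast_config
from nucleoscape.nuclear_architecture_stats import (
    OutsideNucleus,
    RadialRecord,
    compare_counts,
    compare_means,
    ks_compare,
    radial_fraction,
    shell_histogram,
    shell_index,
    summarize_condition,
)
from nucleoscape.object_quantification import segment_nuclei
from nucleoscape.pipeline import quantify_stacks
from nucleoscape.synthetic_microscopy import (
    VoxelGrid,
    condition_config,
    generate_nuclei_dataset,
)

import pandas as pd

VOX = (0.2, 0.2, 0.25)


def spherical_mask(radius=4.0, vox=VOX, pad=1.0):
    ext = radius + pad
    shape = (
        int(2 * ext / vox[2]) + 1,
        int(2 * ext / vox[1]) + 1,
        int(2 * ext / vox[0]) + 1,
    )
    img = np.zeros(shape)
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * vox[2],
        (np.arange(shape[1]) + 0.5) * vox[1],
        (np.arange(shape[2]) + 0.5) * vox[0],
        indexing="ij",
    )
    c = (shape[2] * vox[0] / 2, shape[1] * vox[1] / 2, shape[0] * vox[2] / 2)
    inside = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius**2
    img[inside] = 200.0
    grid = VoxelGrid(img, vox, "dapi")
    return segment_nuclei(grid)[0], np.array(c), radius


class TestShellConvention:
    def test_one_per_shell(self):
        counts, _ = shell_histogram([0.1, 0.3, 0.5, 0.7, 0.9])
        assert counts.tolist() == [1, 1, 1, 1, 1]

    def test_edge_conventions(self):
        assert shell_index(0.2) == 2
        assert shell_index(1.0) == 5
        assert shell_index(0.0) == 1
        assert shell_index(0.6) == 4

    def test_empty_histogram_is_valid(self):
        counts, cum = shell_histogram([])
        assert counts.tolist() == [0, 0, 0, 0, 0]
        assert len(cum) == 0

    def test_counts_sum_and_ecdf_monotone(self, rng):
        fracs = rng.random(137)
        counts, cum = shell_histogram(fracs)
        assert counts.sum() == 137
        assert (np.diff(cum.ecdf) >= 0).all()
        assert cum.ecdf.iloc[-1] == pytest.approx(1.0)

    def test_records_api(self):
        recs = [RadialRecord(0, i, f, shell_index(f)) for i, f in
                enumerate([0.05, 0.95])]
        counts, _ = shell_histogram(recs)
        assert counts.tolist() == [1, 0, 0, 0, 1]


class TestRadialFraction:
    def test_center_is_zero(self):
        mask, _, _ = spherical_mask()
        assert radial_fraction(mask.center_um, mask) == 0.0

    @pytest.mark.parametrize("direction", [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                                           (1, 1, 1)])
    def test_known_fraction_on_sphere(self, direction):
        mask, c, R = spherical_mask()
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        f = radial_fraction(c + 0.45 * R * u, mask)
        assert f == pytest.approx(0.45, abs=0.03)

    def test_outermost_voxel_is_peripheral(self):
        mask, c, R = spherical_mask()
        # the outermost mask voxel centre along +x sits at distance R
        f = radial_fraction(c + np.array([R, 0, 0]), mask)
        assert f >= 0.95

    def test_signal_outside_mask_rejected(self):
        mask, c, R = spherical_mask()
        with pytest.raises(OutsideNucleus):
            radial_fraction(c + np.array([R + 0.5, 0, 0]), mask)

    def test_invariant_under_isotropic_scaling(self):
        mask, c, R = spherical_mask()
        scaled = type(mask)(
            nucleus_id=mask.nucleus_id,
            mask=mask.mask,
            voxel_size=tuple(2 * d for d in mask.voxel_size),
            volume_um3=mask.volume_um3 * 8,
            center_um=tuple(2 * x for x in mask.center_um),
        )
        p = c + np.array([0.3 * R, 0.2 * R, 0.1 * R])
        f1 = radial_fraction(p, mask)
        f2 = radial_fraction(2 * p, scaled)
        assert f1 == pytest.approx(f2, abs=1e-6)


class TestKS:
    def test_identical_samples(self):
        d, p = ks_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_compare([0.1, 0.2], [0.8, 0.9])
        assert d == 1.0

    def test_d_matches_bruteforce(self, rng):
        for _ in range(20):
            a = rng.random(10)
            b = rng.random(10)
            d, _ = ks_compare(a, b)
            # O(n^2) oracle: evaluate both ECDFs at every pooled point
            brute = max(
                abs((a <= x).mean() - (b <= x).mean())
                for x in np.concatenate([a, b])
            )
            assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [0.5])


class TestCompareCounts:
    def test_identical_rates(self):
        z, p = compare_counts([3, 4, 5], [5, 4, 3])
        assert z == 0.0 and p == 1.0

    def test_pooled_z_closed_form(self):
        # group A: 120 objects / 10 nuclei, group B: 60 / 10
        # z = (12-6)/sqrt(9*(1/10+1/10)) = 4.47213595; p frozen from
        # an independent evaluation of 2*pnorm(-z)
        a = [12] * 10
        b = [6] * 10
        z, p = compare_counts(a, b)
        assert z == pytest.approx(4.47213595, abs=1e-8)
        assert p == pytest.approx(7.744216431e-06, rel=1e-6)

    def test_extreme_separation(self, rng):
        a = rng.poisson(10, 50)
        b = rng.poisson(1, 50)
        _, p = compare_counts(a, b)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_counts([], [1, 2])


class TestCompareMeans:
    def test_identical_samples(self):
        t, p = compare_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_against_reference_welch(self):
        # frozen from an independent Welch t implementation (R t.test)
        t, p = compare_means([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert t == pytest.approx(-1.8973665961, abs=1e-9)
        assert p == pytest.approx(0.1075311949, abs=1e-9)

    def test_power_at_condition_set_points(self, rng):
        a = rng.normal(8.0, 2.4, 500)
        b = rng.normal(6.0, 1.8, 500)
        _, p = compare_means(a, b)
        assert p < 0.05

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_means([1.0], [1.0, 2.0])


class TestSummaries:
    def make_tables(self):
        objects = pd.DataFrame(
            {
                "nucleus_id": [0, 0],
                "channel": ["centromere"] * 2,
                "volume_um3": [3.0, 5.0],
                "mean_intensity": [100.0, 120.0],
                "condition": ["control"] * 2,
            }
        )
        nuclei = pd.DataFrame(
            {"nucleus_id": [0], "volume_um3": [250.0], "condition": ["control"]}
        )
        return objects, nuclei

    def test_mean_and_se(self):
        objects, nuclei = self.make_tables()
        s = summarize_condition(objects, nuclei, "control")
        assert s.mean_volume_um3 == 4.0
        assert s.se_volume_um3 == pytest.approx(1.0)
        assert s.mean_count == 2.0

    def test_empty_objects_flagged_missing(self):
        objects, nuclei = self.make_tables()
        s = summarize_condition(objects.iloc[0:0], nuclei, "control")
        assert s.n_objects == 0
        assert math.isnan(s.mean_volume_um3)
        assert s.mean_count == 0.0

    def test_absent_condition_rejected(self):
        objects, nuclei = self.make_tables()
        with pytest.raises(ValueError):
            summarize_condition(objects, nuclei, "antibody")


class TestDisaggregationSignature:
    def test_more_smaller_chromocenters_unchanged_nucleus(self):
        """Splitting conserved heterochromatin into more, smaller pieces must
        be read out as higher count, lower mean volume, same nuclear volume."""
        frames = {}
        for cond in ("control", "hgf"):
            cfg = condition_config(cond, n_nuclei=12, seed=77)
            stacks, _ = generate_nuclei_dataset(cfg)
            objects, nuclei = quantify_stacks(stacks, channels=("centromere",))
            objects["condition"] = cond
            nuclei["condition"] = cond
            frames[cond] = (objects, nuclei)
        ctrl = summarize_condition(*frames["control"], "control")
        hgf = summarize_condition(*frames["hgf"], "hgf")
        assert hgf.mean_count > ctrl.mean_count
        assert hgf.mean_volume_um3 < ctrl.mean_volume_um3
        assert hgf.mean_nuclear_volume_um3 == pytest.approx(
            ctrl.mean_nuclear_volume_um3, rel=0.10
        )
        _, p_count = compare_counts(hgf.counts_per_nucleus,
                                    ctrl.counts_per_nucleus)
        _, p_vol = compare_means(
            frames["hgf"][0].volume_um3, frames["control"][0].volume_um3
        )
        assert p_count < 0.05 and p_vol < 0.05
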