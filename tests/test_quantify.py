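"""Condensate detection, photobleach correction, partition ratio, and
spatial metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from pyrecond import make_chloroplast, make_periodic_square
from pyrecond import quantify
from pyrecond.synthetic_data import DropletSpec, droplet_profile


def flood_fill_label(binary, periodic, connectivity8=True):
    """Brute-force BFS labeling, independent of scipy's implementation."""
    ny, nx = binary.shape
    labels = np.zeros_like(binary, dtype=int)
    nxt = 0
    if connectivity8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for i0 in range(ny):
        for j0 in range(nx):
            if binary[i0, j0] and labels[i0, j0] == 0:
                nxt += 1
                stack = [(i0, j0)]
                labels[i0, j0] = nxt
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        ii, jj = i + di, j + dj
                        if periodic:
                            ii %= ny
                            jj %= nx
                        elif not (0 <= ii < ny and 0 <= jj < nx):
                            continue
                        if binary[ii, jj] and labels[ii, jj] == 0:
                            labels[ii, jj] = nxt
                            stack.append((ii, jj))
    return labels, nxt


class TestDetect:
    def test_empty_field(self):
        tab = quantify.detect(np.zeros((32, 32)), threshold=0.5)
        assert len(tab) == 0
        assert quantify.condensed_fraction(np.zeros((32, 32)), threshold=0.5) == 0.0

    def test_two_droplets_areas(self):
        geo = make_periodic_square(64.0, 128)
        spec = DropletSpec(droplets=[((-16.0, 0.0), 5.0), ((16.0, 0.0), 5.0)],
                           phi_plus=0.9, phi_minus=0.01, interface_width=0.7)
        field = droplet_profile(geo, spec)
        tab = quantify.detect(field, threshold=(0.9 + 0.01) / 2, periodic=True,
                              grid_spacing=geo.h)
        assert len(tab) == 2
        for vol in tab["volume"]:
            assert vol == pytest.approx(np.pi * 25.0, rel=0.10)

    def test_periodic_wrap_counts_once(self):
        geo = make_periodic_square(32.0, 64)
        # droplet centered on the domain corner: wraps all four edges
        spec = DropletSpec(droplets=[((-16.0, -16.0), 4.0)], phi_plus=1.0,
                           phi_minus=0.0)
        field = droplet_profile(geo, spec)
        tab_p = quantify.detect(field, threshold=0.5, periodic=True)
        assert len(tab_p) == 1
        # brute-force check: rolling the field must not change the count
        rolled = np.roll(np.roll(field, 13, axis=0), 7, axis=1)
        tab_r = quantify.detect(rolled, threshold=0.5, periodic=True)
        assert len(tab_r) == 1
        assert tab_r["size"].iloc[0] == tab_p["size"].iloc[0]
        # without periodic awareness the same field splits into pieces
        tab_np = quantify.detect(field, threshold=0.5, periodic=False)
        assert len(tab_np) > 1

    def test_min_size_filter(self):
        field = np.zeros((32, 32))
        field[4, 4] = 1.0                     # single voxel: filtered
        field[10:14, 10:14] = 1.0             # 16 voxels: kept
        tab = quantify.detect(field, threshold=0.5, min_size=4)
        assert len(tab) == 1
        assert tab["size"].iloc[0] == 16

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            quantify.detect(np.zeros((8, 8)), mask=np.zeros((8, 8), bool))

    @pytest.mark.parametrize("periodic", [False, True])
    def test_labeling_agrees_with_flood_fill(self, periodic):
        rng = np.random.default_rng(7)
        for _ in range(60):
            binary = rng.random((24, 24)) < 0.35
            lab, n = quantify.label_condensates(binary, periodic=periodic)
            _, n_bf = flood_fill_label(binary, periodic)
            assert n == n_bf

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        field = ndimage.gaussian_filter(rng.random((64, 64)), 3)
        fracs, areas = [], []
        for thr in np.quantile(field, [0.3, 0.5, 0.7, 0.9]):
            fracs.append(quantify.condensed_fraction(field, threshold=thr,
                                                     min_size=1))
            tab = quantify.detect(field, threshold=thr, min_size=1)
            areas.append(tab["size"].max() if len(tab) else 0.0)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestCondensedFraction:
    def test_full_and_empty(self):
        mask = np.ones((16, 16), bool)
        assert quantify.condensed_fraction(np.full((16, 16), 0.9), mask,
                                           threshold=0.5) == 1.0

    def test_known_droplet_area(self):
        geo = make_periodic_square(64.0, 256)
        spec = DropletSpec(droplets=[((0.0, 0.0), 8.0)], phi_plus=0.9,
                           phi_minus=0.0, interface_width=0.5)
        field = droplet_profile(geo, spec)
        frac = quantify.condensed_fraction(field, threshold=0.45, periodic=True)
        assert frac == pytest.approx(np.pi * 64.0 / 64.0**2, rel=0.05)


class TestBleachCorrect:
    def make_stack(self, beta, frames=6, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random((16, 16)) + 0.5
        return np.stack([base * np.exp(-beta * t) for t in range(frames)])

    def test_no_bleaching_identity(self):
        stack = self.make_stack(0.0)
        assert np.allclose(quantify.bleach_correct(stack), stack)

    def test_recovers_exponential_factors(self):
        stack = self.make_stack(0.13)
        factors = quantify.bleach_factors(stack)
        t = np.arange(6)
        assert np.allclose(factors, np.exp(0.13 * t), rtol=1e-10)
        corrected = quantify.bleach_correct(stack)
        totals = corrected.reshape(6, -1).sum(axis=1)
        assert np.allclose(totals, totals[0], rtol=1e-12)

    def test_idempotent(self):
        stack = self.make_stack(0.2)
        once = quantify.bleach_correct(stack)
        twice = quantify.bleach_correct(once)
        assert np.allclose(once, twice)

    def test_zero_total_frame_raises(self):
        stack = self.make_stack(0.1)
        stack[3] = 0.0
        with pytest.raises(ValueError):
            quantify.bleach_correct(stack)


class TestPartitionRatio:
    def test_uniform_signal_is_unity(self):
        sig = np.full((20, 20), 3.3)
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        assert quantify.partition_ratio(sig, mask) == pytest.approx(1.0)

    def test_two_to_one(self):
        sig = np.ones((20, 20))
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        sig[mask] = 2.0
        assert quantify.partition_ratio(sig, mask) == pytest.approx(2.0)

    def test_blur_moves_ratio_toward_unity(self):
        sig = np.zeros((40, 40)) + 1.0
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        sig[mask] = 5.0
        sharp = quantify.partition_ratio(sig, mask)
        blurred = quantify.partition_ratio(ndimage.gaussian_filter(sig, 2), mask)
        assert 1.0 < blurred < sharp

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            quantify.partition_ratio(np.ones((8, 8)), np.ones((8, 8), bool))


class TestSpatialMetrics:
    def test_centering_zero_at_canonical(self):
        geo = make_chloroplast(N=96)
        ci, cj = quantify.canonical_position(geo)
        tab = pd.DataFrame([{"size": 10.0, "centroid_0": ci, "centroid_1": cj}])
        assert quantify.centering_metric(tab, geo) < geo.h

    def test_canonical_matches_brute_force_clearance(self):
        # independent oracle: per-cell min distance to any outside cell
        geo = make_chloroplast(N=48)
        inside = np.argwhere(geo.mask)
        outside = np.argwhere(~geo.mask)
        best_d, best_cell = -1.0, None
        for (i, j) in inside:
            d = np.sqrt(((outside - (i, j)) ** 2).sum(axis=1)).min()
            if d > best_d:
                best_d, best_cell = d, (i, j)
        ci, cj = quantify.canonical_position(geo)
        d_at_canon = np.sqrt(((outside - (ci, cj)) ** 2).sum(axis=1)).min()
        assert d_at_canon >= best_d - 1.0   # within one cell of the optimum

    def test_pairwise_separation_exact(self):
        geo = make_periodic_square(32.0, 64)
        tab = pd.DataFrame([
            {"size": 5.0, "centroid_0": 10.0, "centroid_1": 10.0},
            {"size": 5.0, "centroid_0": 10.0, "centroid_1": 30.0},
        ])
        assert quantify.pairwise_separation(tab, geo) == pytest.approx(20.0 * geo.h)

    def test_pairwise_separation_periodic_metric(self):
        geo = make_periodic_square(32.0, 64)
        tab = pd.DataFrame([
            {"size": 5.0, "centroid_0": 2.0, "centroid_1": 2.0},
            {"size": 5.0, "centroid_0": 62.0, "centroid_1": 62.0},
        ])
        # wrap distance: 4 cells along each axis, not 60
        assert quantify.pairwise_separation(tab, geo) == pytest.approx(
            np.hypot(4.0, 4.0) * geo.h)

    def test_three_symmetric_droplets(self):
        geo = make_periodic_square(30.0, 60)
        tab = pd.DataFrame([
            {"size": 1.0, "centroid_0": 30.0, "centroid_1": 10.0},
            {"size": 1.0, "centroid_0": 30.0, "centroid_1": 30.0},
            {"size": 1.0, "centroid_0": 30.0, "centroid_1": 50.0},
        ])
        assert quantify.pairwise_separation(tab, geo) == pytest.approx(20.0 * geo.h)

    def test_requires_enough_condensates(self):
        geo = make_periodic_square(32.0, 64)
        with pytest.raises(ValueError):
            quantify.pairwise_separation(pd.DataFrame(), geo)
        with pytest.raises(ValueError):
            quantify.centering_metric(pd.DataFrame(), geo)
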