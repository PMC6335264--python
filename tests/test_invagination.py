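"""Lamin partition, invaginated fraction, depth scoring and classification."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import nucleomorph as nm
from nucleomorph.errors import InputError, NoLaminSignalError, ParameterError
from nucleomorph.invagination import LaminPartition

from conftest import render_single_nucleus


def _disk_mask(radius_px, shape=(101, 101)):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    c = (shape[0] // 2, shape[1] // 2)
    return (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius_px**2


def _score_truth(field, **cfg):
    """Score a rendered field on its exact truth mask (no segmentation)."""
    config = nm.ScoringConfig(**cfg) if cfg else nm.ScoringConfig()
    return nm.score_field(field.truth_nuclei, field.channels["lamin"], config)[0]


class TestPartition:
    def test_pure_rim_gives_empty_interior(self):
        field = render_single_nucleus()
        p = nm.partition_lamin(field.truth_nuclei, 1, field.channels["lamin"])
        assert len(p.interior[0]) == 0
        assert len(p.boundary[0]) > 0

    def test_planted_fold_populates_interior(self):
        inv = nm.InvaginationSpec(entry_angle=1.2, depth_um=4.0, width_um=0.8)
        field = render_single_nucleus([inv])
        p = nm.partition_lamin(field.truth_nuclei, 1, field.channels["lamin"])
        assert len(p.interior[0]) > 0
        assert len(p.boundary[0]) > 0

    def test_rim_band_wider_than_nucleus_swallows_everything(self):
        inv = nm.InvaginationSpec(entry_angle=1.2, depth_um=4.0, width_um=0.8)
        field = render_single_nucleus([inv])
        p = nm.partition_lamin(
            field.truth_nuclei, 1, field.channels["lamin"], rim_width_um=10.0
        )
        assert len(p.interior[0]) == 0

    def test_no_lamin_signal_raises(self):
        field = render_single_nucleus()
        with pytest.raises(NoLaminSignalError):
            nm.partition_lamin(
                field.truth_nuclei, 1, np.zeros(field.truth_nuclei.shape)
            )

    def test_partition_masks_disjoint_and_conserving(self, mixed_field, mixed_segmentation):
        lam = mixed_field.channels["lamin"]
        for nid in map(int, mixed_segmentation.ids):
            p = nm.partition_lamin(mixed_segmentation, nid, lam)
            b = set(zip(*p.boundary))
            i = set(zip(*p.interior))
            assert not b & i
            # conservation: boundary + interior intensities equal the total
            # thresholded lamin intensity, exactly (float64 accumulation of
            # float32 pixels is exact at these magnitudes)
            total = lam[tuple(np.array(sorted(b | i)).T)].sum(dtype=np.float64)
            assert (
                lam[p.boundary].sum(dtype=np.float64)
                + lam[p.interior].sum(dtype=np.float64)
                == total
            )

    def test_invalid_rim_width_rejected(self, mixed_segmentation, mixed_field):
        with pytest.raises(ParameterError):
            nm.partition_lamin(
                mixed_segmentation, 1, mixed_field.channels["lamin"], rim_width_um=0.0
            )


class TestFraction:
    def _partition(self, boundary, interior):
        return LaminPartition(1, boundary, interior, 0.0, 0.5)

    def test_empty_interior_is_zero(self):
        lam = np.ones((10, 10))
        p = self._partition((np.array([1, 2]), np.array([1, 2])), (np.array([], int),) * 2)
        assert nm.invaginated_fraction(p, lam) == 0.0

    def test_empty_boundary_is_one(self):
        lam = np.ones((10, 10))
        p = self._partition((np.array([], int),) * 2, (np.array([5]), np.array([5])))
        assert nm.invaginated_fraction(p, lam) == 1.0

    def test_equal_planted_intensities_give_half(self):
        # 10 boundary px at 20 and 5 interior px at 40: equal totals -> 0.5
        lam = np.zeros((20, 20))
        brow, bcol = np.arange(10), np.zeros(10, int)
        irow, icol = np.arange(5), np.full(5, 10)
        lam[brow, bcol] = 20.0
        lam[irow, icol] = 40.0
        p = self._partition((brow, bcol), (irow, icol))
        assert nm.invaginated_fraction(p, lam, "intensity") == pytest.approx(0.5)
        assert nm.invaginated_fraction(p, lam, "area") == pytest.approx(5 / 15)

    def test_empty_union_signals_no_lamin(self):
        p = self._partition((np.array([], int),) * 2, (np.array([], int),) * 2)
        with pytest.raises(NoLaminSignalError):
            nm.invaginated_fraction(p, np.zeros((5, 5)))


class TestClassifiers:
    @pytest.mark.parametrize("f,expected", [(0.30, False), (0.31, True), (0.0, False)])
    def test_fraction_rule_is_strict(self, f, expected):
        assert nm.classify_by_fraction(f) is expected

    @pytest.mark.parametrize("d,expected", [(3.0, True), (2.99, False), (0.0, False)])
    def test_depth_rule_is_inclusive(self, d, expected):
        assert nm.classify_by_depth(d) is expected

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            nm.classify_by_fraction(1.2)


class TestDepth:
    def test_empty_interior_is_zero(self, mixed_segmentation):
        d = nm.max_invagination_depth(
            mixed_segmentation, 1, (np.array([], int), np.array([], int))
        )
        assert d == 0.0

    def test_unit_conversion_at_known_edt(self):
        # pick a pixel whose EDT is exactly 35 px; at 0.1 um/px -> 3.5 um
        mask = np.zeros((101, 101), dtype=np.int32)
        mask[_disk_mask(45)] = 1
        lm = nm.LabelMask(mask, 0.1)
        edt = ndi.distance_transform_edt(mask > 0)
        r, c = np.argwhere(edt == 35.0)[0]
        d = nm.max_invagination_depth(lm, 1, (np.array([r]), np.array([c])))
        assert d == pytest.approx(3.5)

    def test_matches_brute_force_distance_oracle(self):
        # irregular small masks: EDT-based depth must agree with an
        # exhaustive min-distance-to-background search within one pixel
        # diagonal
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = np.zeros((64, 64), dtype=np.int32)
            rr, cc = np.ogrid[:64, :64]
            for _k in range(3):
                r0, c0 = rng.integers(20, 44, 2)
                rad = rng.integers(8, 16)
                mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = 1
            mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = 0
            lm = nm.LabelMask(mask, 0.1)
            inside = np.argwhere(mask > 0)
            pick = inside[rng.choice(len(inside), size=20, replace=False)]
            bg = np.argwhere(mask == 0)
            brute = max(
                np.sqrt(((bg - p) ** 2).sum(axis=1)).min() for p in pick
            ) * 0.1
            d = nm.max_invagination_depth(lm, 1, (pick[:, 0], pick[:, 1]))
            assert abs(d - brute) <= np.sqrt(2) * 0.1

    def test_invalid_pixel_size_rejected(self, mixed_segmentation):
        with pytest.raises(ParameterError):
            nm.max_invagination_depth(
                mixed_segmentation, 1, (np.array([5]), np.array([5])), pixel_size_um=0.0
            )


class TestSummaries:
    def _measurement(self, frac):
        return nm.NucleusMeasurement(
            1, 80.0, frac, 0.0, nm.classify_by_fraction(frac), False
        )

    def test_no_positives_gives_zero_percent(self):
        s = nm.summarize_field([self._measurement(0.0)] * 10, "fraction")
        assert s.percent_positive == 0.0

    def test_mixed_fractions_apply_strict_rule(self):
        ms = [self._measurement(f) for f in (0.1, 0.29, 0.3, 0.31, 0.9)]
        s = nm.summarize_field(ms, "fraction")
        assert (s.n_positive, s.percent_positive) == (2, 40.0)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            nm.summarize_field([], "fraction")


class TestGeometricProperties:
    def test_fraction_and_depth_monotone_in_planted_depth(self):
        # deepening a single fold (all else fixed, zero noise) never
        # decreases the measured invaginated fraction or maximum depth
        fracs, depths = [], []
        for depth in (0.8, 1.5, 2.5, 3.5, 4.2):
            inv = nm.InvaginationSpec(entry_angle=0.9, depth_um=depth, width_um=0.8)
            field = render_single_nucleus([inv])
            (m,) = _score_truth(field)
            fracs.append(m.invaginated_fraction)
            depths.append(m.max_depth_um)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert all(b >= a for a, b in zip(depths, depths[1:]))

    def test_rotation_changes_fraction_by_less_than_002(self):
        invs = [
            nm.InvaginationSpec(entry_angle=0.9, depth_um=3.8, width_um=0.9),
            nm.InvaginationSpec(entry_angle=3.5, depth_um=3.2, width_um=0.8, curvature=0.3),
        ]
        (m0,) = _score_truth(render_single_nucleus(invs, orientation=0.0))
        (m90,) = _score_truth(render_single_nucleus(invs, orientation=np.pi / 2))
        assert abs(m0.invaginated_fraction - m90.invaginated_fraction) < 0.02
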