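"""Generator contracts: population sampling, rendering geometry, noise."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import nucleomorph as nm
from nucleomorph.errors import GeometryError, InputError, ParameterError

from conftest import render_single_nucleus


class TestSamplePopulation:
    @pytest.mark.parametrize("prevalence,check", [
        (0.0, lambda specs: all(len(s.invaginations) == 0 for s in specs)),
        (1.0, lambda specs: all(len(s.invaginations) >= 1 for s in specs)),
    ])
    def test_degenerate_prevalence(self, prevalence, check):
        specs = nm.sample_population(50, prevalence, rng_seed=0)
        assert len(specs) == 50
        assert check(specs)

    def test_planted_count_is_binomial(self):
        # prevalence 0.4, n=10000: the positive count should sit within
        # 3 binomial standard deviations of the expectation
        specs = nm.sample_population(10_000, 0.4, rng_seed=123)
        n_pos = sum(len(s.invaginations) > 0 for s in specs)
        sd = np.sqrt(10_000 * 0.4 * 0.6)
        assert abs(n_pos - 4000) <= 3 * sd

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ParameterError):
            nm.sample_population(10, 1.5)
        with pytest.raises(ParameterError):
            nm.sample_population(0, 0.5)

    def test_reproducible_given_seed(self):
        a = nm.sample_population(20, 0.5, rng_seed=7)
        b = nm.sample_population(20, 0.5, rng_seed=7)
        assert a == b

    def test_depth_clamped_below_minor_axis(self):
        specs = nm.sample_population(200, 1.0, rng_seed=2)
        for s in specs:
            for inv in s.invaginations:
                assert inv.depth_um < s.semi_axes_um[1]


class TestAddNoise:
    def test_noiseless_limit_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 100, (50, 50)).astype(np.float32)
        out = nm.add_noise(img, nm.NoiseParams.none(), rng_seed=1)
        np.testing.assert_array_equal(out, img)

    def test_same_seed_bit_identical(self):
        img = np.full((64, 64), 30.0)
        a = nm.add_noise(img, nm.NoiseParams(), rng_seed=5)
        b = nm.add_noise(img, nm.NoiseParams(), rng_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_moments_of_stated_model(self):
        # constant image v: sample mean ~ v + background within 3 SEs
        v, gain, sd, bg = 50.0, 1.0, 2.0, 10.0
        img = np.full((400, 400), v)
        out = nm.add_noise(img, nm.NoiseParams(gain, sd, bg), rng_seed=3)
        se = np.sqrt(v / gain + sd**2) / 400
        assert abs(out.mean() - (v + bg)) < 3 * se

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            nm.NoiseParams(poisson_gain=-1)
        with pytest.raises(InputError):
            nm.add_noise(np.array([[-1.0]]), nm.NoiseParams(), 0)


class TestRenderField:
    def test_rim_only_nucleus_lamin_within_band(self):
        field = render_single_nucleus()
        nuc = field.truth_nuclei.labels > 0
        edt_um = ndi.distance_transform_edt(nuc) * 0.1
        positive = field.channels["lamin"] > 100
        assert positive.any()
        assert np.all(edt_um[positive] <= 0.5)
        assert field.truth_table["planted_fraction"].iloc[0] == 0.0

    def test_planted_depth_matches_geometry_oracle(self):
        # one 4 um fold at 0.1 um/px: deepest lamin pixel must sit at an
        # EDT distance of 4.0 +- 0.2 um from the nuclear boundary
        inv = nm.InvaginationSpec(entry_angle=0.7, depth_um=4.0, width_um=0.8)
        field = render_single_nucleus([inv])
        nuc = field.truth_nuclei.labels > 0
        edt_um = ndi.distance_transform_edt(nuc) * 0.1
        positive = (field.channels["lamin"] > 100) & nuc
        oracle_depth = edt_um[positive].max()
        assert oracle_depth == pytest.approx(4.0, abs=0.2)
        assert field.truth_table["planted_depth_um"].iloc[0] == pytest.approx(
            oracle_depth, abs=1e-9
        )

    def test_fully_mixed_reporters_equalize(self):
        field = render_single_nucleus(delta=1.0)
        nuc = field.truth_nuclei.labels > 0
        cyto = (field.truth_cells.labels > 0) & ~nuc
        nes = field.channels["nes_gfp"]
        assert nes[nuc].mean() == pytest.approx(nes[cyto].mean())

    def test_bit_identical_given_same_spec(self):
        pop = nm.sample_population(4, 0.5, rng_seed=9)
        spec = nm.make_field_spec(pop, rng_seed=9)
        a = nm.render_field(spec)
        b = nm.render_field(spec)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        np.testing.assert_array_equal(a.truth_nuclei.labels, b.truth_nuclei.labels)

    def test_truth_labels_partition_and_table_agree(self, mixed_field):
        ids_mask = set(map(int, mixed_field.truth_nuclei.ids))
        ids_table = set(map(int, mixed_field.truth_table["nucleus_id"]))
        assert ids_mask == ids_table
        # every cell contains its nucleus and shares its id
        nuc = mixed_field.truth_nuclei.labels
        cells = mixed_field.truth_cells.labels
        assert np.array_equal(cells[nuc > 0], nuc[nuc > 0])

    def test_overlapping_nuclei_rejected(self):
        a = nm.NucleusSpec(center=(60.0, 60.0), semi_axes_um=(5.0, 4.0))
        b = nm.NucleusSpec(center=(65.0, 60.0), semi_axes_um=(5.0, 4.0))
        spec = nm.FieldSpec((120, 120), 0.1, [a, b], noise=nm.NoiseParams.none())
        with pytest.raises(GeometryError):
            nm.render_field(spec)

    def test_invagination_deeper_than_nucleus_rejected(self):
        with pytest.raises(ParameterError):
            nm.NucleusSpec(
                center=(50.0, 50.0),
                semi_axes_um=(6.0, 4.0),
                invaginations=[nm.InvaginationSpec(0.0, depth_um=4.5, width_um=0.5)],
            )
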