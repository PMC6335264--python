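import numpy as np
import pytest

import nucleomorph as nm


def render_single_nucleus(
    invaginations=(),
    noise=None,
    orientation=0.0,
    semi_axes_um=(6.0, 5.0),
    harmonics=(),
    rng_seed=0,
    delta=0.0,
):
    """One nucleus centred in a small field; noiseless by default."""
    if noise is None:
        noise = nm.NoiseParams.none()
    spec = nm.NucleusSpec(
        center=(110.0, 110.0),
        semi_axes_um=semi_axes_um,
        orientation=orientation,
        invaginations=list(invaginations),
        boundary_harmonics=tuple(harmonics),
    )
    fspec = nm.FieldSpec(
        image_shape=(220, 220),
        pixel_size_um=0.1,
        nuclei=[spec],
        transport_defect_delta=delta,
        noise=noise,
        rng_seed=rng_seed,
    )
    return nm.render_field(fspec)


@pytest.fixture(scope="session")
def mixed_field():
    """Nine nuclei, half carrying planted invaginations, realistic noise."""
    pop = nm.sample_population(9, 0.5, rng_seed=1)
    return nm.render_field(nm.make_field_spec(pop, rng_seed=1))


@pytest.fixture(scope="session")
def mixed_segmentation(mixed_field):
    return nm.segment_nuclei(mixed_field.channels["dapi"], 0.1)


@pytest.fixture(scope="session")
def transport_sweep():
    """Small populations rendered at five transport-defect levels."""
    fields = {}
    for delta in (0.0, 0.25, 0.5, 0.75, 1.0):
        pop = nm.sample_population(12, 0.0, rng_seed=3)
        fields[delta] = nm.render_field(
            nm.make_field_spec(pop, transport_defect_delta=delta, rng_seed=3)
        )
    return fields
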