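import pytest
from hypothesis import settings

from sonolens import (
    BUILTIN_MEDIA,
    FocusTarget,
    LensSpec,
    RunConfig,
    SkullLayer,
    bilateral_ds_config,
    design_lens,
    find_foci,
    simulate_field,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FREQ = 3e6


@pytest.fixture(scope="session")
def water():
    return BUILTIN_MEDIA["water"]


@pytest.fixture(scope="session")
def lens_resin():
    return BUILTIN_MEDIA["lens"]


@pytest.fixture(scope="session")
def skull_medium():
    return BUILTIN_MEDIA["skull"]


@pytest.fixture(scope="session")
def lens_spec():
    return LensSpec()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down single-focus configuration for fast end-to-end tests:
    5 mm aperture (20x20 pixels), point-focus recording, coarse volume."""
    media = dict(BUILTIN_MEDIA)
    lens = LensSpec(
        aperture=(5e-3, 5e-3),
        lens_medium=media["lens"],
        outer_medium=media["water"],
    )
    return RunConfig(
        frequency=FREQ,
        media=media,
        lens=lens,
        skull=SkullLayer(medium=media["skull"], thickness=250e-6, z_entry=0.5e-3),
        targets=[FocusTarget(center=(0.0, 0.0, 3.0e-3), n_sources=1)],
        jitter_radius=0.0,
        seed=3,
        volume_bounds=((-1.5e-3, 1.5e-3), (-0.5e-3, 0.5e-3), (2.0e-3, 4.0e-3)),
        volume_spacing=0.25e-3,
        scan_step=10e-6,
    )


@pytest.fixture(scope="session")
def ds_config():
    """The full bilateral dorsal-striatum study configuration."""
    return bilateral_ds_config(seed=7)


@pytest.fixture(scope="session")
def ds_height_map(ds_config):
    return design_lens(ds_config)


@pytest.fixture(scope="session")
def ds_field(ds_config, ds_height_map):
    """Forward field of the designed lens through the 250 um skull."""
    return simulate_field(
        ds_height_map, ds_config.skull, ds_config.volume_grid(), ds_config.frequency
    )


@pytest.fixture(scope="session")
def ds_report(ds_field):
    return find_foci(ds_field, 2)
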