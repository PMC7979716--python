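import numpy as np
import pytest

from ngi.pipeline import run_sample
from ngi.simulate import SlideConfig, generate_slide
from ngi.stains import StainBasis


@pytest.fixture(scope="session")
def basis():
    return StainBasis.dab_hematoxylin()


@pytest.fixture(scope="session")
def small_config():
    """Compact slide (256 µm square) that still exercises every stage."""
    return SlideConfig(
        image_height_px=512, image_width_px=512, pixel_size_um=0.5,
        tumour_nests=((80.0, 80.0, 50.0), (180.0, 170.0, 55.0)),
        n_cells_per_phenotype={"CD8_T": 60, "CD4_T": 40, "Treg": 15,
                               "CD3_only": 18, "other": 30, "tumour": None},
        noise_sd_od=0.02, seed=1,
    )


@pytest.fixture(scope="session")
def small_slide(small_config):
    return generate_slide(small_config)


@pytest.fixture(scope="session")
def small_result(small_slide):
    rounds, _ = small_slide
    return run_sample(rounds)


@pytest.fixture(scope="session")
def clean_slide(small_config):
    """Noise-free render of the same slide (exact forward-model checks)."""
    import dataclasses
    cfg = dataclasses.replace(small_config, noise_sd_od=0.0)
    return generate_slide(cfg)
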