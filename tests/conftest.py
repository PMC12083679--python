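import numpy as np
import pytest

from imcpatch import MarkerImage, MarkerPanel, PipelineConfig, SyntheticConfig, generate_cohort

PANEL = MarkerPanel.from_markers(("DNA", "Shh", "TGFb"))


def make_image(dna, shh, tgfb, pixel_size_um=1.0, sample_id="S0", grade="G0", is_case=False):
    """MarkerImage from three 2-D channel arrays."""
    return MarkerImage(
        pixels=np.stack([np.asarray(dna, float), np.asarray(shh, float), np.asarray(tgfb, float)]),
        panel=PANEL,
        pixel_size_um=pixel_size_um,
        sample_id=sample_id,
        grade=grade,
        is_case=is_case,
    )


@pytest.fixture(scope="session")
def small_synth_config():
    """Small but non-degenerate generator settings for fast cohort tests."""
    return SyntheticConfig(image_size_px=(200, 200), n_per_grade=1, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_synth_config):
    cohort, truths = generate_cohort(small_synth_config)
    return cohort, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
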