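"""Shared synthetic-section fixtures.

Sections are generated once per session; every quantification test scores
the pipeline against the ground truth carried by these fixtures.
"""

import pytest

from myosen import SectionSpec, generate_section, generate_zstack

NOISE_SD = 8.0


@pytest.fixture(scope="session")
def taf_noiseless():
    """TAF panel, noise off, planted CNFs: the exact-recovery substrate."""
    spec = SectionSpec(seed=31, marker_panel="TAF", noise_model=None,
                       cnf_fraction=0.3, coloc_fraction=0.4,
                       foci_per_nucleus_distribution={"poisson": 2.0})
    return generate_section(spec)


@pytest.fixture(scope="session")
def taf_snr5():
    """TAF panel at SNR 5 (focus amplitude = 5 x noise SD), fine pixels."""
    spec = SectionSpec(seed=11, marker_panel="TAF", focus_amplitude=5 * NOISE_SD,
                       pixel_size_um=0.5, field_size_px=(768, 768),
                       noise_model={"gaussian_sd": NOISE_SD}, coloc_fraction=0.4,
                       foci_per_nucleus_distribution={"poisson": 6.0})
    return generate_section(spec)


@pytest.fixture(scope="session")
def hmgb1_section():
    spec = SectionSpec(seed=21, marker_panel="HMGB1", noise_model=None,
                       intensity_contrast_sd=6.0, positive_fraction=0.3)
    return generate_section(spec)


@pytest.fixture(scope="session")
def laminb1_section():
    spec = SectionSpec(seed=22, marker_panel="LaminB1", noise_model=None,
                       intensity_contrast_sd=6.0, positive_fraction=0.3)
    return generate_section(spec)


@pytest.fixture(scope="session")
def p16_section():
    spec = SectionSpec(seed=23, marker_panel="p16", noise_model=None,
                       foci_per_nucleus_distribution={"pmf": [0.6, 0.25, 0.1, 0.05]})
    return generate_section(spec)


@pytest.fixture(scope="session")
def taf_zstack():
    spec = SectionSpec(seed=41, marker_panel="TAF", pixel_size_um=0.5,
                       field_size_px=(384, 384), coloc_fraction=0.4,
                       foci_per_nucleus_distribution={"poisson": 3.0},
                       noise_model=None)
    return generate_zstack(spec, 8)
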