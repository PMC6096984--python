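import pytest

from membud.synthetic import (
    DeformationConfig,
    ElutionConfig,
    PopulationConfig,
    gen_budded_population,
    gen_deformation_series,
    gen_elution_trace,
)


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free 10-vesicle budded population at m_true = 0.4 µm⁻¹, κ'/κ = 0."""
    cfg = PopulationConfig(n=10, m_true=0.4, kappa_ratio=0.0, radius_noise=0.0)
    return gen_budded_population(cfg, seed=11)


@pytest.fixture(scope="session")
def noisefree_series():
    """Noise-free electrodeformation series with ΔA_max = 0.046."""
    return gen_deformation_series(DeformationConfig(delta_A_max=0.046), seed=5)


@pytest.fixture(scope="session")
def noisy_series():
    """Same experiment with 0.5% multiplicative frame noise."""
    return gen_deformation_series(
        DeformationConfig(delta_A_max=0.046, frame_noise=0.005), seed=5
    )


@pytest.fixture(scope="session")
def default_trace():
    """Three-Gaussian elution trace with 0.74% incorporated share."""
    return gen_elution_trace(ElutionConfig(), seed=7)
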