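import numpy as np
import pytest

from occlusim.synthimg import MonolayerSpec, generate_field


@pytest.fixture(scope="session")
def noiseless_field():
    """A 40-cell noiseless field with full junction integrity."""
    spec = MonolayerSpec(n_cells=40, noise_sd=0.0, seed=3)
    images, truth = generate_field(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def noisy_field():
    """A default (noisy, 64-cell) field."""
    spec = MonolayerSpec(seed=11)
    images, truth = generate_field(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def demo_compound_params():
    from occlusim.lungpbpk import CompoundParams

    return CompoundParams(
        solubility_cs_um=50.0,
        diffusion_d_cm2_per_s=6e-6,
        diffusion_layer_h_cm=30e-4,
        particle_density_g_per_ml=1.2,
        initial_particle_radius_um=1.5,
        permeability_p_tb_cm_per_s=1e-6,
        molecular_weight_g_per_mol=450.0,
        fu_plasma=0.1,
        fu_tissue=0.2,
        kp_epithelium=5.0,
        kp_subepithelium=5.0,
        k_in_per_h=1.0,
        k_out_per_h=0.5,
        cl_ml_per_h=1500.0,
        vss_ml=2000.0,
    )
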