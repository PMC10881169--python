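import numpy as np
import pytest

from flimcyte import (AcquisitionParams, DecaySpec, PhantomSpec,
                      FreeNADHReference, PipelineConfig, single_exp_phasor)


@pytest.fixture(scope="session")
def acq():
    """Default acquisition: 80 MHz, 256 bins, 256x256, 6 planes at 3 um."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_small():
    """Reduced acquisition for fast unit tests."""
    return AcquisitionParams(n_time_bins=64, frame_shape=(64, 64), n_z=3)


@pytest.fixture(scope="session")
def acq_fast_pipeline():
    """Reduced acquisition sized for many end-to-end runs."""
    return AcquisitionParams(n_time_bins=64, frame_shape=(128, 128), n_z=6)


@pytest.fixture(scope="session")
def fast_phantom():
    """50-cell phantom that fits the reduced acquisition frame."""
    return PhantomSpec(n_cells=50, cell_radius=4.5, min_gap=4.0,
                       mito_density=6.0, mito_radius=1.2, seed=0)


@pytest.fixture(scope="session")
def fast_config(acq_fast_pipeline):
    """Analysis settings scaled to the reduced phantom: the blur matches
    the ~4.5 px cell radius (the default 2 px suits ~10 px cells)."""
    from dataclasses import replace
    cfg = PipelineConfig(acquisition=acq_fast_pipeline)
    return replace(cfg, segmentation=replace(cfg.segmentation,
                                             blur_sigma=1.0, min_area=25))


@pytest.fixture(scope="session")
def free_ref(acq):
    return FreeNADHReference.from_lifetime(0.4, acq.omega)


@pytest.fixture(scope="session")
def free_ref_small(acq_small):
    return FreeNADHReference.from_lifetime(0.4, acq_small.omega)


@pytest.fixture(scope="session")
def chord_length(acq, free_ref):
    """Analytic distance between pure free (0.4 ns) and bound (3.2 ns) phasors."""
    gb, sb = single_exp_phasor(3.2e-9, acq.omega)
    return float(np.hypot(gb - free_ref.g_free, sb - free_ref.s_free))
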