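import numpy as np
import pytest

from petph.core_io import GatedPetSeries, to_suv
from petph.phantom import PhantomSpec, make_thorax


@pytest.fixture(scope="session")
def thorax():
    """One noise-free default thorax phantom shared across tests."""
    spec = PhantomSpec(seed=11)
    series, ct, truth = make_thorax(spec)
    return spec, series, ct, truth


@pytest.fixture(scope="session")
def thorax_suv(thorax):
    """SUV-converted gated series + static (frame-averaged) SUV image."""
    spec, series, ct, truth = thorax
    frames = [to_suv(f, spec.injected_dose_mbq, spec.body_weight_kg)
              for f in series.frames]
    suv_series = GatedPetSeries(frames, spec.injected_dose_mbq,
                                spec.body_weight_kg, spec.uptake_time_min)
    static = frames[0].with_values(np.mean([f.values for f in frames], axis=0))
    return suv_series, static
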