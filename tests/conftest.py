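import numpy as np
import pytest

import hybridflair as hf


@pytest.fixture(scope="session")
def flair_seq() -> hf.SequenceParams:
    return hf.SequenceParams()  # TR 10000, TI 2800, TE 120, flip 90


@pytest.fixture(scope="session")
def small_phantom():
    """Clean 6-slice phantom (no noise, no mismatch) with its physics image."""
    spec = hf.default_phantom_spec(shape=(6, 128, 128), noise_sigma=0.0,
                                   lesion_mismatch=1.0,
                                   unmodeled_tissue_factors={})
    labels, maps = hf.make_phantom(spec)
    phys = hf.synthesize_flair(maps, hf.SequenceParams())
    return spec, labels, maps, phys


@pytest.fixture(scope="session")
def mismatch_phantom():
    """Default study conditions: lambda 1.8, MT attenuation, 2% noise."""
    spec = hf.default_phantom_spec(shape=(4, 224, 224))
    labels, maps = hf.make_phantom(spec)
    seq = hf.SequenceParams()
    phys = hf.synthesize_flair(maps, seq)
    conv = hf.simulate_conventional_flair(maps, labels, seq, spec)
    mask = hf.extract_brain_mask(np.abs(phys), 0.5)
    return spec, labels, phys, conv, mask
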