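import numpy as np
import pytest

import siribruise as sb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def bruised_spec():
    """Default bruised phantom: centered-ish elliptical bruise, pits, noise."""
    return sb.PhantomSpec(
        seed=42, bruise=sb.BruiseSpec(center=(60, 70), semi_axes=(17, 21))
    )


@pytest.fixture(scope="session")
def bruised_sample(bruised_spec):
    return sb.render_phantom(bruised_spec, 0.10, 700.0)


@pytest.fixture(scope="session")
def normal_sample():
    return sb.render_phantom(sb.PhantomSpec(seed=7), 0.10, 700.0)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Clean phantom: no noise, no pits, no vignetting, no bruise."""
    return sb.PhantomSpec(seed=0, noise_sigma=0.0, n_dark_spots=0, vignette_strength=0.0)


def make_triplet(pixel_fields, f=0.10, wavelength=700.0, pitch=0.5):
    """Assemble a PhaseTriplet from three pixel arrays."""
    return sb.PhaseTriplet(
        tuple(
            sb.RawPatternImage(
                pixels=p,
                phase_offset=theta,
                spatial_frequency=f,
                wavelength=wavelength,
                pixel_pitch=pitch,
            )
            for p, theta in zip(pixel_fields, sb.PHASE_OFFSETS)
        )
    )


@pytest.fixture
def triplet_factory():
    return make_triplet
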