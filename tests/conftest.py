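import numpy as np
import pytest

from nirsconn import Channel, EventMarker, IntensityRecording, ProbeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20230442)


def build_geometry(n_pairs=2, rng=None, separation=3.0):
    """Random montage with two wavelength channels per source-detector pair."""
    rng = rng or np.random.default_rng(0)
    sources = rng.normal(size=(n_pairs, 3)) * 5
    u = rng.standard_normal((n_pairs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    detectors = sources + separation * u
    channels = []
    for p in range(n_pairs):
        channels.append(Channel(p, p, 760.0))
        channels.append(Channel(p, p, 850.0))
    return ProbeGeometry(sources, detectors, channels)


def build_recording(geometry, n_samples=500, fs=10.2, rng=None, condition="barefoot"):
    rng = rng or np.random.default_rng(1)
    L = geometry.n_channels
    intens = 1.0 + 0.05 * rng.standard_normal((L, n_samples))
    intens = np.abs(intens) + 0.1
    markers = [EventMarker(5.0, 10.0, condition)]
    return IntensityRecording(
        intensities=intens,
        fs=fs,
        wavelengths=np.array([c.wavelength for c in geometry.channels]),
        run_condition=condition,
        event_markers=markers,
    )


@pytest.fixture
def small_geometry(rng):
    return build_geometry(n_pairs=3, rng=rng)


@pytest.fixture
def small_recording(small_geometry, rng):
    return build_recording(small_geometry, rng=rng)
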