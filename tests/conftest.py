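import numpy as np
import pytest

from ivfc.core import Kymograph, ScanMetadata
from ivfc.simulate import SimulationParams


@pytest.fixture
def small_metadata() -> ScanMetadata:
    return ScanMetadata(scan_rate_hz=750.0, pixel_size_um=0.6,
                        n_lines=200, n_pixels=64)


@pytest.fixture
def fast_params() -> SimulationParams:
    """Short, coarse record for quick pipeline tests (~1 s of scanning)."""
    return SimulationParams(
        seed=11, T_s=5.0, scan_rate_hz=650.0, n_pixels=64, pixel_size_um=0.8,
        concentration_per_ml=2.0e6,  # dense enough for a handful of events
    )


@pytest.fixture
def two_color_params(fast_params) -> SimulationParams:
    import dataclasses
    return dataclasses.replace(fast_params, two_color=True,
                               positive_fraction=0.5)


def make_kymograph(pixels: np.ndarray, scan_rate_hz=750.0, pixel_size_um=0.6,
                   channel_names=None) -> Kymograph:
    """Wrap a raw (lines, px[, ch]) array in a consistent Kymograph."""
    arr = np.asarray(pixels, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    names = channel_names or tuple(f"ch{i}" for i in range(arr.shape[2]))
    md = ScanMetadata(scan_rate_hz=scan_rate_hz, pixel_size_um=pixel_size_um,
                      n_lines=arr.shape[0], n_pixels=arr.shape[1],
                      channel_names=tuple(names))
    return Kymograph(pixels=arr, metadata=md)
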