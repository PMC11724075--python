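import numpy as np
import pytest

from dimerscreen import synthetic as syn


@pytest.fixture(scope="session")
def small_screen():
    """Two 384-well plates with gradients, edge depression and 2% spikes."""
    spec = syn.PlateEffectSpec(seed=11)
    plates, truth = syn.simulate_screen(spec, n_plates=2)
    return spec, plates, truth


@pytest.fixture(scope="session")
def planted_library():
    """2,000-compound library, 10% pharmacophore carriers, clean labels."""
    spec = syn.LibrarySpec(n_compounds=2000, active_fraction=0.1, label_noise=0.0, seed=5)
    lib, truth = syn.generate_library(spec)
    return spec, lib, truth


@pytest.fixture(scope="session")
def cell_image():
    """One default two-channel synthetic micrograph with truth."""
    spec = syn.CellImageSpec(seed=4)
    image, truth = syn.render_cell_image(spec)
    return spec, image, truth


def erode4(mask: np.ndarray) -> np.ndarray:
    """Brute-force 4-connected binary erosion (out-of-bounds treated as 0)."""
    out = mask.copy()
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.zeros_like(mask)
        if shift == 1:
            if axis == 0:
                shifted[1:, :] = mask[:-1, :]
            else:
                shifted[:, 1:] = mask[:, :-1]
        else:
            if axis == 0:
                shifted[:-1, :] = mask[1:, :]
            else:
                shifted[:, :-1] = mask[:, 1:]
        out &= shifted
    return out


def dilate4(mask: np.ndarray) -> np.ndarray:
    """Brute-force 4-connected binary dilation."""
    out = mask.copy()
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.zeros_like(mask)
        if shift == 1:
            if axis == 0:
                shifted[1:, :] = mask[:-1, :]
            else:
                shifted[:, 1:] = mask[:, :-1]
        else:
            if axis == 0:
                shifted[:-1, :] = mask[1:, :]
            else:
                shifted[:, :-1] = mask[:, 1:]
        out |= shifted
    return out
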