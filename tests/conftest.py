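import numpy as np
import pytest
from hypothesis import settings

import ki67calib as k
from ki67calib.synthetic import (SyntheticSpot, place_nuclei, true_li,
                                 tumour_mask_for)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

EASY_SEEDS = (3, 4, 5)
EASY_LIS = (20.0, 35.0, 50.0)


def easy_spec(seed: int, li: float) -> "k.SpotSpec":
    """Easy DIA regime: sparse spots, nuclei comfortably above the size
    minimum, and staining intensities that sit strictly inside their bins
    (negatives never dip below the weak 1+ threshold)."""
    return k.SpotSpec(spot_diameter_um=500.0, cell_density_per_mm2=800.0,
                      true_li_percent=li, seed=seed,
                      nucleus_radius_um=k.NormalClip(5.5, 0.4, lo=4.5),
                      negative_intensity=k.NormalClip(219.0, 3.5, lo=212.0,
                                                      hi=228.0))


@pytest.fixture(scope="session")
def easy_spots():
    return [k.generate_spot(easy_spec(s, li))
            for s, li in zip(EASY_SEEDS, EASY_LIS)]


@pytest.fixture(scope="session")
def default_spot():
    """One spot at the default study conditions (1-mm core, 2000 cells/mm2)."""
    return k.generate_spot(k.SpotSpec(seed=11))


def truth_only_spot(spec) -> SyntheticSpot:
    """Spot with truth and mask but no rendered raster (counting-only tests)."""
    truth = tuple(place_nuclei(spec))
    return SyntheticSpot(image=np.zeros((1, 1, 3), dtype=np.uint8),
                         tumour_mask=tumour_mask_for(spec), truth=truth,
                         true_li_percent=true_li(truth), spec=spec)
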