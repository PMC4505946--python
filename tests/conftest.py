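import numpy as np
import pytest

from vtmorph import geometry as geo
from vtmorph import synthetic as sv
from vtmorph.containers import AreaFunction


def tube_profile(length: float = 60.0, area: float = 100.0) -> AreaFunction:
    """Constant-area tube with the standard lower-VT annotations."""
    pos = np.linspace(0.0, length, int(length) + 1)
    return AreaFunction(
        pos,
        np.full_like(pos, area),
        {
            "glottis": 0.0,
            "fold_min": sv.S_FOLD_MIN,
            "closure_top": sv.S_CLOSURE_TOP,
            "vallecula_inferior": sv.S_VALLECULA,
            "lips": length,
        },
    )


@pytest.fixture(scope="session")
def speech_profile() -> AreaFunction:
    return sv.make_area_profile(sv.SyntheticVTParams(mode="speech_like"))


@pytest.fixture(scope="session")
def singing_profile() -> AreaFunction:
    return sv.make_area_profile(sv.SyntheticVTParams(mode="singing"))


@pytest.fixture(scope="session")
def straight_tube():
    """Voxelized straight constant-area tube plus its landmark set."""
    vol, lm = sv.voxelize(tube_profile(), bend=sv.BendSpec(angle_deg=0),
                          voxel_size=0.5)
    return vol, lm


@pytest.fixture(scope="session")
def bent_tube():
    vol, lm = sv.voxelize(tube_profile(),
                          bend=sv.BendSpec(angle_deg=90, radius_mm=25, start_mm=20),
                          voxel_size=0.5)
    return vol, lm


@pytest.fixture(scope="session")
def straight_centerline(straight_tube):
    vol, lm = straight_tube
    return geo.build_centerline(vol, lm)


@pytest.fixture(scope="session")
def default_cohort():
    return sv.make_cohort(seed=11)
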