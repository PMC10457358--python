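import datetime

import numpy as np
import pytest

import bloomtrace as bt

DATE = datetime.date(2021, 7, 10)


@pytest.fixture
def s2():
    return bt.get_sensor("s2-like")


@pytest.fixture
def modis():
    return bt.get_sensor("modis-like")


def make_fai(values, valid=None, level="low_sensitivity", date=DATE):
    """FAIGrid from a raw array; full validity unless given."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return bt.FAIGrid(values=values, valid_mask=valid, date=date, level=level)


def make_scene(red, nir, swir, sensor, level="low_sensitivity", date=DATE,
               water=None, cloud=None):
    red = np.asarray(red, dtype=float)
    shape = red.shape
    return bt.Scene(
        date=date, level=level, sensor=sensor,
        red=red, nir=np.asarray(nir, float), swir=np.asarray(swir, float),
        water_mask=np.ones(shape, bool) if water is None else water,
        cloud_mask=np.zeros(shape, bool) if cloud is None else cloud,
    )


@pytest.fixture
def default_pair():
    return bt.generate_scene_pair(bt.SceneGenConfig(seed=7))
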