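import datetime as dt

import numpy as np
import pytest

from magnav.geofield import FieldGrid, FieldStack, GridGeometry
from magnav.synthdata import fixture_scenario
from magnav.tracks import KM, Trajectory


@pytest.fixture(scope="session")
def smoke():
    return fixture_scenario("smoke")


@pytest.fixture(scope="session")
def recovery():
    return fixture_scenario("recovery-taxis")


@pytest.fixture(scope="session")
def study_scale():
    return fixture_scenario("study-scale")


@pytest.fixture
def small_geometry():
    return GridGeometry(0.0, 0.0, 10 * KM, 5, 5, "test-planar")


def make_grid(values, cue="F", cell=10 * KM, date=dt.date(2016, 9, 19)):
    values = np.asarray(values, dtype=float)
    geo = GridGeometry(0.0, 0.0, cell, values.shape[0], values.shape[1], "t")
    return FieldGrid(cue=cue, date=date, geometry=geo, values=values)


def make_stack(F, I, cell=10 * KM):
    Fg = make_grid(F, "F", cell)
    Ig = make_grid(I, "I", cell)
    H = Fg.values * np.cos(np.deg2rad(Ig.values))
    Hg = make_grid(np.clip(H, 0, None), "H", cell)
    return FieldStack({"F": Fg, "I": Ig, "H": Hg})


def hourly_track(animal_id, xy, t0="2016-09-19T00:00:00"):
    xy = np.asarray(xy, dtype=float)
    start = np.datetime64(t0, "s")
    times = start + np.arange(len(xy)) * np.timedelta64(3600, "s")
    return Trajectory(animal_id, times, xy[:, 0], xy[:, 1])
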