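import numpy as np
import pytest

from scrdesign.detectors import DetectorArray, HabitatMask
from scrdesign.histories import from_records


@pytest.fixture
def line_detectors():
    """Five detectors 1,500 m apart on one transect."""
    x = np.arange(5) * 1500.0
    return DetectorArray([f"d{i}" for i in range(5)], x, np.zeros(5),
                         ["t1"] * 5)


@pytest.fixture
def toy_mask():
    """A coarse 3 x 3 mask around the line detectors."""
    gx, gy = np.meshgrid([-1500.0, 1500.0, 4500.0], [-3000.0, 0.0, 3000.0])
    return HabitatMask(gx.ravel(), gy.ravel(), cell_area_km2=9.0)


@pytest.fixture
def toy_histories():
    """Three individuals, two occasions, with one spatial recapture."""
    recs = [("a", 1, "d0"), ("a", 2, "d1"),
            ("b", 1, "d3"), ("b", 2, "d3"),
            ("c", 2, "d2")]
    return from_records(recs, n_occasions=2, sex={"a": "F", "b": "M", "c": "U"})


def random_toy_instance(rng, max_detectors=3, max_occasions=2, max_mask=5):
    """A randomized tiny SCR instance for oracle comparisons."""
    K = int(rng.integers(1, max_detectors + 1))
    S = int(rng.integers(1, max_occasions + 1))
    M = int(rng.integers(1, max_mask + 1))
    det_xy = rng.uniform(0, 5000, (K, 2))
    mask_xy = rng.uniform(-2000, 7000, (M, 2))
    usage = (rng.random((K, S)) < 0.8).astype(float)
    usage[0, :] = 1.0
    n = int(rng.integers(1, 4))
    omega = np.zeros((n, S, K), dtype=int)
    for i in range(n):
        while omega[i].sum() == 0:
            omega[i] = ((rng.random((S, K)) < 0.4) * usage.T).astype(int)
    recs = [(f"i{i}", s + 1, f"d{k}")
            for i in range(n) for s in range(S) for k in range(K)
            if omega[i, s, k]]
    dets = DetectorArray([f"d{k}" for k in range(K)], det_xy[:, 0],
                         det_xy[:, 1], ["t1"] * K, usage=usage)
    hist = from_records(recs, S)
    mask = HabitatMask(mask_xy[:, 0], mask_xy[:, 1], cell_area_km2=2.25)
    return dets, hist, mask, usage
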