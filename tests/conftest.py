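import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", database=None, derandomize=True)
settings.load_profile("ci")

from bloomcount.density_targets import PointAnnotationSet
from bloomcount.synthetic_field import SyntheticFieldSpec
from bloomcount.trainer import Sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_field_spec():
    return SyntheticFieldSpec(image_height=96, image_width=96, bed_width=32,
                              road_width=8, plant_spacing=10,
                              flowering_fraction=0.6,
                              blob_radius_range=(3.0, 4.0), jitter_sd=0.5,
                              seed=7)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; used to check the fast paths)
# ---------------------------------------------------------------------------

def brute_force_density(points, shape, sigma, trunc=4.0,
                        legacy_prefactor=False):
    """Per-pixel kernel sum over all points, no windowing tricks."""
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    if legacy_prefactor:
        norm = 1.0 / (2.0 * math.pi * sigma)
    else:
        norm = 1.0 / (2.0 * math.pi * sigma * sigma)
    rad2 = (trunc * sigma) ** 2
    for i in range(h):
        for j in range(w):
            total = 0.0
            for r, c in points:
                d2 = (i - r) ** 2 + (j - c) ** 2
                if d2 <= rad2:
                    total += norm * math.exp(-d2 / (2.0 * sigma * sigma))
            out[i, j] = total
    return out


def brute_force_peaks(arr, gamma, delta):
    """Enumerate-sort-suppress peak oracle with plain Python loops.

    Candidates are local maxima of the gamma-thresholded map (plateaus
    collapse to their lexicographically smallest pixel), visited in
    descending value then ascending (row, col), accepting unless within
    Euclidean distance < delta of an accepted peak.
    """
    h, w = arr.shape
    z = [[arr[i][j] if arr[i][j] >= gamma else 0.0 for j in range(w)]
         for i in range(h)]

    def neighbors(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w:
                    yield ii, jj

    is_max = [[z[i][j] > 0
               and all(z[i][j] >= z[ii][jj] for ii, jj in neighbors(i, j))
               for j in range(w)] for i in range(h)]

    # collapse 8-connected equal-valued plateaus of passing pixels
    seen = [[False] * w for _ in range(h)]
    candidates = []
    for i in range(h):
        for j in range(w):
            if not is_max[i][j] or seen[i][j]:
                continue
            stack, comp = [(i, j)], []
            seen[i][j] = True
            while stack:
                a, b = stack.pop()
                comp.append((a, b))
                for ii, jj in neighbors(a, b):
                    if is_max[ii][jj] and not seen[ii][jj] \
                            and z[ii][jj] == z[a][b]:
                        seen[ii][jj] = True
                        stack.append((ii, jj))
            r, c = min(comp)
            candidates.append((r, c, z[r][c]))

    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    accepted = []
    for r, c, v in candidates:
        if all((r - ar) ** 2 + (c - ac) ** 2 >= delta * delta
               for ar, ac, _ in accepted):
            accepted.append((r, c, v))
    return accepted


@pytest.fixture
def brute_density_oracle():
    return brute_force_density


@pytest.fixture
def brute_peaks_oracle():
    return brute_force_peaks


# ---------------------------------------------------------------------------
# Tiny datasets for trainer-level tests
# ---------------------------------------------------------------------------

def make_samples(n, size, seed, fraction=0.5, spacing=10):
    from bloomcount.synthetic_field import generate_field

    ss = np.random.SeedSequence(seed)
    samples = []
    for i, child in enumerate(ss.spawn(n)):
        spec = SyntheticFieldSpec(image_height=size, image_width=size,
                                  bed_width=32, road_width=8,
                                  plant_spacing=spacing,
                                  flowering_fraction=fraction,
                                  blob_radius_range=(3.0, 4.0),
                                  jitter_sd=0.5,
                                  seed=int(child.generate_state(1)[0]))
        img, ann = generate_field(spec)
        sid = f"s{seed}_{i:03d}"
        samples.append(Sample(sid, img, PointAnnotationSet(sid, ann.points)))
    return samples


@pytest.fixture(scope="session")
def tiny_train_val():
    return make_samples(16, 64, seed=5), make_samples(4, 64, seed=6)


@pytest.fixture(scope="session")
def sample_factory():
    return make_samples
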