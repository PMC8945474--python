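import numpy as np
import pytest

from octamorph import ScanGeometry, SyntheticLesionSpec, generate_lesion_image


@pytest.fixture
def geometry():
    """Default 6 × 6 mm / 500 px scan geometry (12 µm per pixel)."""
    return ScanGeometry()


@pytest.fixture
def worked_groups():
    """Three tiny ordered groups with fully enumerable rank arithmetic."""
    return [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]


@pytest.fixture
def phantom(geometry):
    """One seeded mid-size synthetic lesion (image, mask, ground truth)."""
    return generate_lesion_image(SyntheticLesionSpec(seed=1), geometry)


def make_y_skeleton(size=61, arm=20):
    """Y-shaped skeleton: three arms meeting at the centre pixel."""
    sk = np.zeros((size, size), dtype=bool)
    c = size // 2
    for i in range(arm + 1):
        sk[c, c + i] = True          # east arm
        sk[c - i, c - i] = True      # north-west arm
        sk[c + i, c - i] = True      # south-west arm
    return sk


def make_diamond_loop(size=41, radius=12):
    """Closed 8-connected ring (|dr| + |dc| = radius): every pixel degree 2."""
    sk = np.zeros((size, size), dtype=bool)
    c = size // 2
    for dr in range(-radius, radius + 1):
        dc = radius - abs(dr)
        sk[c + dr, c + dc] = True
        sk[c + dr, c - dc] = True
    return sk


def make_grid_skeleton(n_lines=3, spacing=10, margin=5):
    """Full-span horizontal/vertical lines crossing n_lines² times."""
    size = 2 * margin + (n_lines - 1) * spacing + 1
    sk = np.zeros((size, size), dtype=bool)
    for i in range(n_lines):
        sk[margin + i * spacing, :] = True
        sk[:, margin + i * spacing] = True
    return sk
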