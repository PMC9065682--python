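import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyreco.model import ClusterBox

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_box(chr1="1", chr2="13", id=1, y=(0, 100), x=(0, 100), num=10):
    """Build a ClusterBox from y = (r_y, l_y) and x = (l_x, r_x) intervals."""
    return ClusterBox(chr1=str(chr1), chr2=str(chr2), id=id,
                      l_x=x[0], l_y=y[1], r_x=x[1], r_y=y[0], num=num)


def random_boxes(rng: np.random.Generator, n: int, chr2="13",
                 span=1500) -> list[ClusterBox]:
    """Random boxes on one reference chromosome, many partial y-overlaps."""
    boxes = []
    for i in range(n):
        y0 = int(rng.integers(0, span))
        y1 = y0 + int(rng.integers(1, span // 3))
        x0 = int(rng.integers(0, span))
        x1 = x0 + int(rng.integers(1, span // 3))
        boxes.append(make_box(chr1=str(int(rng.integers(1, 9))), chr2=chr2,
                              id=i + 1, y=(y0, y1), x=(x0, x1),
                              num=int(rng.integers(3, 50))))
    return boxes


@pytest.fixture
def grape13():
    from polyreco.examples import grape_chr13_regions
    return grape_chr13_regions()


@pytest.fixture
def arab3():
    from polyreco.examples import arabidopsis_chr3_regions
    return arabidopsis_chr3_regions()
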