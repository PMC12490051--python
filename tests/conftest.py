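import numpy as np
import pytest

from histoquant.image_io import SectionImage
from histoquant.segmentation import SegmentationConfig


def disk_pair_image(radius: float = 8.0, distance: float = 12.0, size: int = 64,
                    value: int = 200) -> SectionImage:
    """Two equal disks with given center distance on a dark background."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2.0
    c1, c2 = size / 2.0 - distance / 2.0, size / 2.0 + distance / 2.0
    mask = ((yy - cy) ** 2 + (xx - c1) ** 2 <= radius**2) | (
        (yy - cy) ** 2 + (xx - c2) ** 2 <= radius**2
    )
    return SectionImage((mask * value).astype(np.uint8), bit_depth=8)


@pytest.fixture
def binary_cfg() -> SegmentationConfig:
    """Config for synthetic binary shapes: fixed threshold, minimal blur."""
    return SegmentationConfig(binarize_method="fixed", fixed_threshold=100, blur_sigma_px=0.5)


@pytest.fixture
def default_cfg() -> SegmentationConfig:
    return SegmentationConfig()
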