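import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gastruquant import RuleSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rules() -> RuleSet:
    return RuleSet()


@pytest.fixture
def tiny_rules() -> RuleSet:
    """Small marker lists for fast hand-built count matrices."""
    return RuleSet(
        hox_genes=["Hoxa1", "Hoxb4"],
        brain_markers=["Otx2", "Six3", "Foxg1", "Emx2", "En1", "Pax6"],
        brain_min_markers=2,
        spinal_exclusion_gene="Fgfbp3",
        dv_modules={
            "dorsal": ["Pax3"],
            "midline": ["Shh"],
            "ventral": ["Nkx2-2", "Olig2"],
        },
    )


def rasterize_disk(radius_px: int) -> np.ndarray:
    n = 2 * radius_px + 21
    rr, cc = np.mgrid[0:n, 0:n]
    c = n // 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2


def rasterize_ellipse(a_px: float, b_px: float) -> np.ndarray:
    ny, nx = int(2 * b_px + 21), int(2 * a_px + 21)
    rr, cc = np.mgrid[0:ny, 0:nx]
    y = rr - (ny - 1) / 2
    x = cc - (nx - 1) / 2
    return (x / a_px) ** 2 + (y / b_px) ** 2 <= 1.0
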