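import numpy as np
import pytest

from spherotrack.phantom import PhantomConfig


@pytest.fixture
def quiet_config() -> PhantomConfig:
    """Noiseless phantom with a small field, fast to render."""
    return PhantomConfig(
        base_radius_um=70.0,
        growth_rate_per_day=0.25,
        r_max_um=280.0,
        invasion_rate_per_day=0.02,
        noise_sd=0.0,
        pixel_size_um=2.0,
        image_size_px=384,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def circle_polygon(radius: float, n: int = 360,
                   center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Regular n-gon approximating a circle, CCW, (x, y) vertices."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(theta),
                            center[1] + radius * np.sin(theta)])


def star_polygon(radius: float, amp: float, k: int = 8, n: int = 720,
                 phase: float = 0.3) -> np.ndarray:
    """Cosine-lobed star polygon for shape-metric oracles."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius * (1.0 + amp * np.cos(k * theta + phase))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
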