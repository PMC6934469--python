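import numpy as np
import pytest

import vesseltort as vt


def sinusoid(n_points=600, x_span=2 * np.pi, amplitude=1.0, half_periods=2):
    """Polyline samples of y = A*sin(pi*k*x/span) on [0, span]."""
    x = np.linspace(0.0, x_span, n_points)
    y = amplitude * np.sin(np.pi * half_periods * x / x_span)
    return np.column_stack([x, y])


def circle_arc(n_points=1000, start=0.0, stop=np.pi / 2, radius=1.0):
    th = np.linspace(start, stop, n_points)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def landmarks():
    return vt.LandmarkSet(od_center=(192.0, 384.0), od_radius=42.0,
                          fovea_center=(360.0, 384.0),
                          image_width=768, image_height=768)


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic retinas with zero-noise planted labels (session-cached)."""
    cfg = vt.GeneratorConfig(n_retinas=20)
    samples = vt.generate_cohort(cfg, seed=42)
    labels, threshold = vt.generate_labels(samples, cfg)
    return samples, labels, threshold, cfg


@pytest.fixture(scope="session")
def small_features(small_cohort):
    samples, _, _, _ = small_cohort
    return vt.CohortFeatures.from_cohort(samples)
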