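import numpy as np
import pytest

from cbfold.contour import Contour


def circle_contour(radius=1.0, n=2000, center=(0.0, 0.0), ccw=True):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if not ccw:
        theta = theta[::-1]
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Contour(pts, closed=True)


def polar_contour(r_of_theta, n=4000):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = r_of_theta(theta)
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]), closed=True)


def semicircle_arc(radius=200.0, n=1001):
    theta = np.linspace(0.0, np.pi, n)
    return Contour(np.column_stack([radius * np.cos(theta), radius * np.sin(theta)]))


@pytest.fixture(scope="session")
def section_eps03():
    from cbfold.synthetic import gen_section

    return gen_section(epsilon=0.3, seed=11)


@pytest.fixture(scope="session")
def section_eps0():
    from cbfold.synthetic import gen_section

    return gen_section(epsilon=0.0, seed=11)
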