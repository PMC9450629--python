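import dataclasses

import numpy as np
import pytest

from cochlen import COCHLEA25, CenterlineCurve, generate_centerline


def make_straight(length: float, n: int = 101) -> CenterlineCurve:
    t = np.linspace(0.0, length, n)
    return CenterlineCurve(np.column_stack([t, np.zeros(n), np.zeros(n)]))


def make_circle(radius: float, arc_span: float, n: int = 100001) -> CenterlineCurve:
    theta = np.linspace(0.0, arc_span / radius, n)
    return CenterlineCurve(
        np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
        )
    )


@pytest.fixture(scope="session")
def default_curve() -> CenterlineCurve:
    return generate_centerline(COCHLEA25, 20001)


@pytest.fixture(scope="session")
def straight10() -> CenterlineCurve:
    return make_straight(10.0)


@pytest.fixture
def spec_with(request):
    def factory(**kwargs):
        return dataclasses.replace(COCHLEA25, **kwargs)

    return factory
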