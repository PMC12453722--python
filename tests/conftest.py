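import pytest

from chainnoise import (
    demo_fixtures,
    make_figure_eight,
    make_line,
    make_ring_shape,
    make_square,
)


@pytest.fixture
def demo_f8():
    return demo_fixtures()[0]


@pytest.fixture
def demo_f4():
    return demo_fixtures()[1]


@pytest.fixture
def square100():
    return make_square(100)


@pytest.fixture
def line200():
    return make_line(200)


@pytest.fixture
def figure_eight():
    return make_figure_eight(8)


@pytest.fixture
def square_with_hole():
    # 24-step outer loop with one 6-step hole, comfortably clear of the loop.
    return make_ring_shape(24, [6], [(5, 5)])


class StubRNG:
    """Deterministic stand-in for the injector's RNG.

    ``random()`` returns 0.0 on the draw indices listed in ``fire_at``
    (firing the alteration) and 1.0 otherwise; ``integers(n)`` pops
    scripted values (default 0).
    """

    def __init__(self, fire_at=(), integer_script=()):
        self.fire_at = set(fire_at)
        self.integer_script = list(integer_script)
        self.draws = 0

    def random(self):
        fired = self.draws in self.fire_at
        self.draws += 1
        return 0.0 if fired else 1.0

    def integers(self, n):
        return self.integer_script.pop(0) if self.integer_script else 0


@pytest.fixture
def stub_rng_factory():
    return StubRNG
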