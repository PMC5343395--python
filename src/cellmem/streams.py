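"""Uniform random-variate streams.

Every stochastic kernel in this package draws nothing but uniform variates on
[0, 1), in a documented order (see :mod:`cellmem.evolution`).  That makes any
simulation step reproducible from a plain list of numbers: a
:class:`RecordedStream` can stand in for the random number generator, which is
how the hand-traceable oracle fixtures in the test suite work.

Seed handling goes through :func:`derive_seeds`, which spawns independent
child seeds from a master seed with :class:`numpy.random.SeedSequence`, so the
environment realization, the population initialization and the per-step loop
never share a stream.
"""

from __future__ import annotations

import numpy as np

from .errors import StreamExhausted

__all__ = [
    "UniformStream",
    "RandomStream",
    "RecordedStream",
    "derive_seeds",
]


class UniformStream:
    """Protocol: a source of i.i.d. Uniform[0, 1) variates."""

    def uniform(self, n: int | None = None):
        """Return one float (``n is None``) or an ndarray of ``n`` floats."""
        raise NotImplementedError


class RandomStream(UniformStream):
    """Uniform stream backed by :func:`numpy.random.default_rng`."""

    def __init__(self, seed) -> None:
        self._rng = np.random.default_rng(seed)

    def uniform(self, n: int | None = None):
        if n is None:
            return float(self._rng.random())
        return self._rng.random(int(n))


class RecordedStream(UniformStream):
    """Uniform stream that replays a fixed list of variates.

    Consuming past the end raises :class:`~cellmem.errors.StreamExhausted`;
    test fixtures are expected to be sized exactly.
    """

    def __init__(self, values) -> None:
        self._values = np.asarray(values, dtype=float)
        if self._values.ndim != 1:
            raise ValueError("recorded stream must be a flat sequence")
        if self._values.size and (
            self._values.min() < 0.0 or self._values.max() >= 1.0
        ):
            raise ValueError("recorded variates must lie in [0, 1)")
        self._cursor = 0

    @property
    def remaining(self) -> int:
        return self._values.size - self._cursor

    def uniform(self, n: int | None = None):
        k = 1 if n is None else int(n)
        if self._cursor + k > self._values.size:
            raise StreamExhausted(
                f"recorded stream exhausted: requested {k}, "
                f"remaining {self.remaining}"
            )
        out = self._values[self._cursor : self._cursor + k]
        self._cursor += k
        if n is None:
            return float(out[0])
        return out.copy()


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from ``base_seed``.

    Children come from ``SeedSequence(base_seed).spawn(n)``; each is reduced
    to a single 31-bit integer so it can be logged and replayed anywhere.
    """
    children = np.random.SeedSequence(base_seed).spawn(n)
    return [int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in children]
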