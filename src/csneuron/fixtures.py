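"""Synthetic point sets and series of analytically known correlation
dimension, used to validate the D2 estimators independently of any circuit
simulation.

Kinds and their exact dimensions:

* ``constant`` -- a constant ISI series: a single point, D2 = 0;
* ``uniform_segment`` -- points uniform on a line segment in [0,1]^W, D2 = 1;
* ``uniform_square`` -- points uniform on a 2-D patch in [0,1]^W, D2 = 2;
* ``two_frequency_quasiperiodic`` -- an ISI series driven by an irrational
  circle rotation (the beat phase of two incommensurate drive frequencies
  advances by a fixed irrational increment per spike), whose delay
  embedding is a closed curve: D2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaos import DEFAULT_W, EmbeddedSeries, normalize_and_embed

__all__ = ["FixtureSpec", "FIXTURE_KINDS", "make_fixture", "fixture_series", "fixture_points"]

FIXTURE_KINDS = {
    "constant": 0.0,
    "uniform_segment": 1.0,
    "uniform_square": 2.0,
    "two_frequency_quasiperiodic": 1.0,
}

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # irrational rotation increment


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_points: int = 10_000
    seed: int = 0
    w: int = DEFAULT_W

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def true_dimension(self) -> float:
        return FIXTURE_KINDS[self.kind]


def fixture_series(spec: FixtureSpec) -> np.ndarray:
    """ISI-like series for the series-valued fixture kinds."""
    if spec.kind == "constant":
        return np.full(spec.n_points + spec.w, 500, dtype=np.int64)
    if spec.kind == "two_frequency_quasiperiodic":
        rng = np.random.default_rng(spec.seed)
        phi0 = rng.random()
        k = np.arange(spec.n_points + spec.w - 1)
        theta = (phi0 + k * _GOLDEN) % 1.0
        return 900.0 + 60.0 * np.sin(2.0 * np.pi * theta)
    raise ValueError(f"{spec.kind!r} is a point-set fixture; use fixture_points")


def fixture_points(spec: FixtureSpec) -> EmbeddedSeries:
    """Point set in [0,1]^W with known correlation dimension."""
    rng = np.random.default_rng(spec.seed)
    w = spec.w
    if spec.kind == "uniform_segment":
        u = rng.random(spec.n_points)
        vectors = np.repeat(u[:, None], w, axis=1)
    elif spec.kind == "uniform_square":
        u = rng.random(spec.n_points)
        v = rng.random(spec.n_points)
        vectors = np.empty((spec.n_points, w))
        half = w // 2
        vectors[:, :half] = u[:, None]
        vectors[:, half:] = v[:, None]
    else:
        series = fixture_series(spec)
        return normalize_and_embed(series, w)
    return EmbeddedSeries(vectors=vectors, w=w, normalization_max=1.0)


def make_fixture(spec: FixtureSpec) -> EmbeddedSeries:
    """Embedded point set for any fixture kind."""
    return fixture_points(spec)
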