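"""Glorot and He weight initializers.

The scale of the initial weights is set by the layer's fan-in (and, for
the Glorot schemes, fan-out):

* glorot_normal: truncated normal, mean 0, std sqrt(2 / (n_in + n_out))
* he_normal:     truncated normal, mean 0, std sqrt(2 / n_in)
* glorot_uniform: Uniform(+-sqrt(6 / (n_in + n_out)))
* he_uniform:     Uniform(+-sqrt(6 / n_in))

The *_normal schemes truncate at two standard deviations (the de-facto
convention for these initializers): samples outside +-2 std are redrawn,
which shrinks the delivered variance by a known factor of about 0.774.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["make_initializer", "truncated_normal", "TRUNC_VAR_FACTOR"]

#: Variance of a standard normal truncated at +-2, relative to 1:
#: 1 - 4*phi(2) / (2*Phi(2) - 1).
TRUNC_VAR_FACTOR = 1.0 - 4.0 * math.exp(-2.0) / math.sqrt(2.0 * math.pi) / (
    math.erf(2.0 / math.sqrt(2.0))
)

SCHEMES = ("glorot_normal", "glorot_uniform", "he_normal", "he_uniform")


def truncated_normal(
    rng: np.random.Generator, std: float, shape, n_std: float = 2.0
) -> np.ndarray:
    """Normal(0, std) with out-of-bounds samples (|x| > n_std*std) redrawn."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > n_std * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > n_std * std
    return out


def make_initializer(scheme: str, fan_in: int, fan_out: int):
    """Return ``sampler(rng, shape) -> ndarray`` for the given scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown initializer {scheme!r}; options: {list(SCHEMES)}")
    if fan_in < 1 or fan_out < 1:
        raise ValueError(f"fan_in and fan_out must be >= 1, got {fan_in}, {fan_out}")

    if scheme == "glorot_normal":
        std = math.sqrt(2.0 / (fan_in + fan_out))
        return lambda rng, shape: truncated_normal(rng, std, shape)
    if scheme == "he_normal":
        std = math.sqrt(2.0 / fan_in)
        return lambda rng, shape: truncated_normal(rng, std, shape)
    if scheme == "glorot_uniform":
        limit = math.sqrt(6.0 / (fan_in + fan_out))
    else:  # he_uniform
        limit = math.sqrt(6.0 / fan_in)
    return lambda rng, shape: rng.uniform(-limit, limit, size=shape)
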