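"""Divisive normalization of value: closed forms and their predictions.

The normalization function rescales a vector of non-negative item values by
a contrast constant plus the summed value in context,

    z_n = v_n / (sigma + sum_m v_m),    sigma > 0,

so the valuation of a bundle, taken as the sum of its members' normalized
values, is v_bar / (sigma + v_bar) with v_bar the summed item value. Two
consequences drive everything downstream: the bundle value is strictly
concave in v_bar (sub-additivity), and the responsiveness of the code to a
change in one item's value, sigma / (sigma + v1 + v2)^2, shrinks as soon as
a second item is present — attenuation of the value code on bundle trials.

All functions accept an arbitrary number of items; the two-item case is the
canonical one.
"""

from __future__ import annotations

import numpy as np


def _validate(v: np.ndarray, sigma: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if np.any(v < 0):
        raise ValueError("item values must be non-negative")
    return v


def normalize_values(v, sigma: float) -> np.ndarray:
    """Divisively normalized values z_n = v_n / (sigma + sum v).

    Order-preserving; outputs lie in [0, 1).
    """
    v = _validate(v, sigma)
    return v / (sigma + v.sum())


def bundle_value_normalized(v, sigma: float) -> float:
    """Bundle value as the sum of normalized member values: v_bar/(sigma+v_bar)."""
    v = _validate(v, sigma)
    vbar = v.sum()
    return float(vbar / (sigma + vbar))


def responsiveness(v1: float, v2: float, sigma: float) -> float:
    """Derivative of the normalized code with respect to one item's value.

    Equals sigma / (sigma + v1 + v2)^2: maximal when the context holds a
    single item (v2 = 0) and strictly decreasing in the companion value —
    the attenuation prediction for bundles.
    """
    _validate(np.array([v1, v2]), sigma)
    return float(sigma / (sigma + v1 + v2) ** 2)


def bundle_second_derivative(v_bar: float, sigma: float) -> float:
    """Second derivative of bundle value in the summed item value.

    Equals -2*sigma / (sigma + v_bar)^3 < 0, hence concavity and
    sub-additive discounting that grows with the item values.
    """
    _validate(np.array([v_bar]), sigma)
    return float(-2.0 * sigma / (sigma + v_bar) ** 3)
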