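"""Unimodal curve families used for thermal performance curves.

Each family maps temperature to a non-negative performance value and is
unimodal for valid parameters.  Families are registered in :data:`FAMILIES`
by name; :func:`register_family` adds new ones (the catalog hook used by
tests and downstream configuration).

Built-in families
-----------------
``emg_peak``
    Exponentially modified Gaussian, oriented so the exponential (heavy)
    tail points to *lower* temperatures and the Gaussian (steep) flank to
    higher ones — the canonical thermal-performance asymmetry of a rapid
    decline above the optimum::

        f(T) = a * (lam/2) * exp(lam*(T - mu) + lam^2 sigma^2 / 2)
                 * erfc((T - mu + lam*sigma^2) / (sqrt(2)*sigma))

``asym_logistic_peak``
    Product of a powered logistic rise and a logistic fall, rescaled so the
    peak value equals ``a``.  With ``s = 1/(1 + exp(-(T - c)/b))``::

        f(T) = a * s^d * (1 - s) / (d^d / (d + 1)^(d + 1))

``gumbel_peak``
    Gumbel (extreme-value) density shape rescaled to peak value ``a`` at
    ``T = mu``, again with the heavy tail toward cold temperatures::

        f(T) = a * exp(-exp(-z) - z + 1),   z = (mu - T) / sigma

All three are strictly positive on the real line; clamping to the tolerance
interval is the caller's job (see :func:`thermoperf.tpc.clamped_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erfc

__all__ = [
    "CurveFamily",
    "FAMILIES",
    "register_family",
    "get_family",
]


@dataclass(frozen=True)
class CurveFamily:
    """A named, parameterized unimodal temperature-performance map.

    Parameters
    ----------
    name:
        Registry key.
    param_names:
        Ordered parameter names; ``n_params`` is their count.
    eval_fn:
        Vectorized ``f(T, params) -> performance`` (raw, unclamped).
    bounds_fn:
        ``(temps, perf, t_lo, t_hi) -> (lower, upper)`` arrays of per-parameter
        fitting bounds derived from the data and the tolerance anchors.
    """

    name: str
    param_names: tuple[str, ...]
    eval_fn: Callable[[np.ndarray, Sequence[float]], np.ndarray] = field(repr=False)
    bounds_fn: Callable[..., tuple[np.ndarray, np.ndarray]] = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, temps, params) -> np.ndarray:
        temps = np.asarray(temps, dtype=float)
        return self.eval_fn(temps, params)


def _emg_eval(temps: np.ndarray, params: Sequence[float]) -> np.ndarray:
    a, mu, sigma, lam = params
    arg = lam * (temps - mu) + 0.5 * lam**2 * sigma**2
    # guard the exponential: erfc decays as fast as exp grows, so evaluate
    # the product through the scaled complementary error function erfcx
    # when the plain form would overflow.
    z = (temps - mu + lam * sigma**2) / (np.sqrt(2.0) * sigma)
    with np.errstate(over="ignore", invalid="ignore"):
        out = a * 0.5 * lam * np.exp(arg) * erfc(z)
        bad = ~np.isfinite(out)
        if np.any(bad):
            from scipy.special import erfcx

            zb = z[bad] if z.ndim else z
            argb = arg[bad] if np.ndim(arg) else arg
            out_bad = a * 0.5 * lam * np.exp(argb - zb**2) * erfcx(zb)
            if out.ndim:
                out[bad] = out_bad
            else:
                out = out_bad
    return np.nan_to_num(out, nan=0.0, posinf=np.inf)


def _emg_bounds(temps, perf, t_lo, t_hi):
    pmax = float(np.max(perf))
    span = t_hi - t_lo
    lower = np.array([0.1 * pmax, t_lo, 0.3, 1e-3])
    upper = np.array([20.0 * pmax, t_hi, span, 2.0])
    return lower, upper


def _asym_logistic_eval(temps: np.ndarray, params: Sequence[float]) -> np.ndarray:
    a, b, c, d = params
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-(temps - c) / b))
    peak = d**d / (d + 1.0) ** (d + 1.0)
    with np.errstate(invalid="ignore"):
        out = a * np.power(s, d) * (1.0 - s) / peak
    return np.nan_to_num(out, nan=0.0)


def _asym_logistic_bounds(temps, perf, t_lo, t_hi):
    pmax = float(np.max(perf))
    span = t_hi - t_lo
    lower = np.array([0.2 * pmax, 0.3, t_lo, 0.05])
    upper = np.array([3.0 * pmax, span, t_hi, 50.0])
    return lower, upper


def _gumbel_eval(temps: np.ndarray, params: Sequence[float]) -> np.ndarray:
    a, mu, sigma = params
    z = (mu - temps) / sigma
    with np.errstate(over="ignore"):
        return a * np.exp(-np.exp(-z) - z + 1.0)


def _gumbel_bounds(temps, perf, t_lo, t_hi):
    pmax = float(np.max(perf))
    span = t_hi - t_lo
    lower = np.array([0.2 * pmax, t_lo, 0.3])
    upper = np.array([3.0 * pmax, t_hi, span])
    return lower, upper


FAMILIES: dict[str, CurveFamily] = {}


def register_family(family: CurveFamily) -> None:
    """Add (or replace) a family in the registry."""
    FAMILIES[family.name] = family


def get_family(name: str) -> CurveFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown curve family {name!r}; known: {sorted(FAMILIES)}"
        ) from None


register_family(
    CurveFamily(
        name="emg_peak",
        param_names=("a", "mu", "sigma", "lam"),
        eval_fn=_emg_eval,
        bounds_fn=_emg_bounds,
    )
)
register_family(
    CurveFamily(
        name="asym_logistic_peak",
        param_names=("a", "b", "c", "d"),
        eval_fn=_asym_logistic_eval,
        bounds_fn=_asym_logistic_bounds,
    )
)
register_family(
    CurveFamily(
        name="gumbel_peak",
        param_names=("a", "mu", "sigma"),
        eval_fn=_gumbel_eval,
        bounds_fn=_gumbel_bounds,
    )
)
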