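"""Input-function generators for extern model variables.

Physiological models are often driven through an extern input — an
inflowing concentration, a pacing waveform — selected at run time rather
than coded in the model.  The kinds here cover the usual menu: rectangular
pulses and pulse trains, sine and shaped-sawtooth signals, and the density
forms used for indicator-dilution boluses (exponential, Gaussian,
lognormal, gamma-variate).  Density kinds are normalized so their numeric
integral over the evaluation window ``[tmin, tmax]`` equals the requested
``area`` (default 1), which is what makes input/output mass comparisons
meaningful.  Experimental data curves can be bound directly as
interpolants.

All generators are pure functions of the domain variable and accept numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as _sci_integrate

__all__ = ["FuncSpec", "make_generator", "bind_data_curve", "parse_funcspec"]

_KINDS = ("pulse", "pulse_train", "sine", "sawtooth", "exponential",
          "gaussian", "lognormal", "gamma_variate", "data_curve")

#: kinds normalized to a prescribed area over the window
DENSITY_KINDS = ("exponential", "gaussian", "lognormal", "gamma_variate")


@dataclass
class FuncSpec:
    kind: str
    params: dict[str, float] = field(default_factory=dict)
    unit: str = "dimensionless"
    #: normalization window for density kinds (defaults to the model's
    #: time-domain extent when bound by the engines)
    window: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")


def _req(params: dict, name: str, default=None) -> float:
    if name in params:
        return float(params[name])
    if default is None:
        raise ValueError(f"missing generator parameter {name!r}")
    return float(default)


def _positive(value: float, name: str) -> float:
    if not value > 0:
        raise ValueError(f"generator parameter {name!r} must be > 0")
    return value


def make_generator(spec: FuncSpec):
    """Build an evaluable ``f(t)`` from a spec.

    Density kinds integrate to ``spec.params['area']`` over the window to a
    relative accuracy of 1e-6; signal kinds use their parameters directly.
    """
    p = spec.params
    kind = spec.kind

    if kind == "pulse":
        onset = _req(p, "onset", 0.0)
        dur = _positive(_req(p, "duration"), "duration")
        amp = _req(p, "amplitude", 1.0)
        return lambda t: np.where((np.asarray(t) >= onset)
                                  & (np.asarray(t) < onset + dur), amp, 0.0)

    if kind == "pulse_train":
        onset = _req(p, "onset", 0.0)
        dur = _positive(_req(p, "duration"), "duration")
        amp = _req(p, "amplitude", 1.0)
        period = _positive(_req(p, "period"), "period")
        n = int(_req(p, "n", np.inf)) if "n" in p else None
        if dur > period:
            raise ValueError("pulse_train duration must not exceed period")

        def train(t):
            t = np.asarray(t, dtype=float)
            rel = t - onset
            phase = np.mod(rel, period)
            k = np.floor(rel / period)
            on = (rel >= 0) & (phase < dur)
            if n is not None:
                on &= k < n
            return np.where(on, amp, 0.0)
        return train

    if kind == "sine":
        amp = _req(p, "amplitude", 1.0)
        period = _positive(_req(p, "period"), "period")
        phase = _req(p, "phase", 0.0)
        offset = _req(p, "offset", 0.0)
        w = 2 * np.pi / period
        return lambda t: offset + amp * np.sin(w * np.asarray(t) + phase)

    if kind == "sawtooth":
        # shaped (triangle) sawtooth: rise_fraction of the period rising
        # 0 -> amplitude, the rest falling back to 0
        amp = _req(p, "amplitude", 1.0)
        period = _positive(_req(p, "period"), "period")
        rise = _req(p, "rise_fraction", 0.5)
        if not 0 < rise < 1:
            raise ValueError("rise_fraction must lie in (0, 1)")
        onset = _req(p, "onset", 0.0)

        def saw(t):
            ph = np.mod(np.asarray(t, dtype=float) - onset, period) / period
            up = ph / rise
            down = (1.0 - ph) / (1.0 - rise)
            return amp * np.where(ph < rise, up, down)
        return saw

    if kind in DENSITY_KINDS:
        return _density(spec)

    if kind == "data_curve":
        raise ValueError("bind data curves with bind_data_curve()")

    raise ValueError(kind)  # pragma: no cover


def _density(spec: FuncSpec):
    p = spec.params
    area = _req(p, "area", 1.0)
    kind = spec.kind

    if kind == "exponential":
        onset = _req(p, "onset", 0.0)
        rate = _positive(_req(p, "rate"), "rate")

        def shape(t):
            t = np.asarray(t, dtype=float)
            return np.where(t >= onset, rate * np.exp(-rate * (t - onset)), 0.0)

    elif kind == "gaussian":
        mean = _req(p, "mean")
        sd = _positive(_req(p, "sd"), "sd")

        def shape(t):
            z = (np.asarray(t, dtype=float) - mean) / sd
            return np.exp(-0.5 * z * z) / (sd * np.sqrt(2 * np.pi))

    elif kind == "lognormal":
        # parameterized by the median exp(mu) and geometric sd exp(sigma)
        mu = np.log(_positive(_req(p, "median"), "median")) \
            if "median" in p else _req(p, "mu", 0.0)
        sigma = _positive(_req(p, "sigma"), "sigma")
        onset = _req(p, "onset", 0.0)

        def shape(t):
            t = np.asarray(t, dtype=float)
            tau = t - onset
            out = np.zeros_like(tau)
            ok = tau > 0
            z = (np.log(tau[ok]) - mu) / sigma
            out[ok] = np.exp(-0.5 * z * z) / (tau[ok] * sigma
                                              * np.sqrt(2 * np.pi))
            return out

    elif kind == "gamma_variate":
        # classic indicator-dilution form
        #   A (t - t0)^alpha exp(-(t - t0)/beta) / (Gamma(alpha+1) beta^(alpha+1))
        from scipy.special import gammaln
        t0 = _req(p, "onset", 0.0)
        alpha = _positive(_req(p, "shape"), "shape")
        beta = _positive(_req(p, "scale"), "scale")
        lognorm = gammaln(alpha + 1) + (alpha + 1) * np.log(beta)

        def shape(t):
            t = np.asarray(t, dtype=float)
            tau = t - t0
            out = np.zeros_like(tau)
            ok = tau > 0
            out[ok] = np.exp(alpha * np.log(tau[ok]) - tau[ok] / beta
                             - lognorm)
            return out
    else:  # pragma: no cover
        raise ValueError(kind)

    lo, hi = spec.window
    if np.isfinite(hi):
        total, _ = _sci_integrate.quad(lambda t: float(shape(t)), lo, hi,
                                       limit=400)
        if total <= 0:
            raise ValueError("density generator has zero mass in the window")
        k = area / total
    else:
        k = area  # analytic shapes already integrate to 1 on [0, inf)

    return lambda t, _k=k: _k * shape(t)


def bind_data_curve(samples, mode: str = "linear"):
    """Interpolant over a data curve (or bare (x, y) arrays).

    ``linear`` interpolates between samples; ``step`` holds the value of
    the sample at or left of t.  Outside the sampled range the function
    returns 0 — bolus-input semantics, not extrapolation.
    """
    if hasattr(samples, "domain") and hasattr(samples, "samples"):
        x = np.asarray(samples.domain, dtype=float)
        y = np.asarray(samples.samples, dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in samples)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("data curve needs at least two points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("data-curve abscissae must be strictly increasing")
    if x.shape != y.shape:
        raise ValueError("domain and sample lengths differ")
    if mode not in ("linear", "step"):
        raise ValueError(f"unknown interpolation mode {mode!r}")

    def f(t):
        t = np.asarray(t, dtype=float)
        if mode == "linear":
            out = np.interp(t, x, y)
        else:
            idx = np.clip(np.searchsorted(x, t, side="right") - 1, 0,
                          x.size - 1)
            out = y[idx]
        out = np.where((t < x[0]) | (t > x[-1]), 0.0, out)
        return out if out.ndim else float(out)
    return f


def parse_funcspec(text: str) -> FuncSpec:
    """Parse the CLI form ``kind(key=value, ..., area=1 mM*s)``.

    A trailing unit on a value is recorded as the spec's output unit.
    """
    import re
    m = re.fullmatch(r"\s*([a-z_]+)\s*\((.*)\)\s*", text)
    if not m:
        raise ValueError(f"malformed generator spec {text!r}")
    kind, body = m.group(1), m.group(2)
    params: dict[str, float] = {}
    unit = "dimensionless"
    if body.strip():
        for item in body.split(","):
            k, _, v = item.partition("=")
            k, v = k.strip(), v.strip()
            if not k or not v:
                raise ValueError(f"malformed generator parameter {item!r}")
            mv = re.fullmatch(r"([-+0-9.eE]+)\s*(.*)", v)
            if not mv:
                raise ValueError(f"malformed generator value {v!r}")
            params[k] = float(mv.group(1))
            if mv.group(2):
                unit = mv.group(2)
    return FuncSpec(kind=kind, params=params, unit=unit)
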