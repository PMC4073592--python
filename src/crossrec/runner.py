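"""Configuration validation and the method dispatcher.

A :class:`RunConfig` names one analysis method and its parameter block;
:func:`run` validates it (unknown keys and out-of-range values are
rejected *before* any computation) and dispatches to the corresponding
library call, returning a plain serializable dict with a provenance
block.  The CLI is a thin wrapper over this module, so CLI results are
bit-identical to direct library calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import categorical, optimize, profiles, simulate
from .errors import ValidationError
from .io import provenance
from .measures import MEASURE_ORDER
from .pipeline import crqa
from .series import TimeSeries

__all__ = ["RunConfig", "DEFAULTS", "validate_config", "run"]

#: allowed keys and defaults per method; None marks "required, no default"
DEFAULTS: dict[str, dict] = {
    "crqa": {"delay": 1, "embed": 1, "radius": 0.001, "tw": 0, "minline": 2,
             "normalize": "none", "rescale": "none", "datatype": "categorical"},
    "profile": {"W": 10, "radius": 0.001, "delay": 1, "embed": 1,
                "normalize": "none", "exclude_nonevent": None,
                "datatype": "categorical"},
    "window": {"window_size": None, "step": None, "lag_window": None,
               "radius": 0.001, "delay": 1, "embed": 1, "normalize": "none",
               "exclude_nonevent": None, "datatype": "categorical",
               "per_window": "rr", "minline": 2, "tw": 0},
    "ct": {"W": 10},
    "phi": {"W": 10, "state": None},
    "optimize": {"max_lag": 40, "bins": 10, "max_dim": 6, "target_lo": 2.0,
                 "target_hi": 5.0, "n_candidates": 20, "max_rounds": 3,
                 "normalize": "none"},
    "simulate": {"p_c": 0.25, "p_s": 0.05, "p_cc": 0.05, "p_ss": 0.05,
                 "p_sc": 0.33, "steps": 1000, "seed": None,
                 "coupling": "previous"},
}

_NEEDS_TWO_SERIES = {"crqa", "profile", "window", "ct", "phi", "optimize"}


@dataclass(frozen=True)
class RunConfig:
    method: str
    params: dict = field(default_factory=dict)


def validate_config(config: RunConfig) -> dict:
    """Fill defaults, reject unknown keys and invalid values."""
    if config.method not in DEFAULTS:
        raise ValidationError(
            f"unknown method {config.method!r}; choose from {sorted(DEFAULTS)}"
        )
    schema = DEFAULTS[config.method]
    unknown = set(config.params) - set(schema)
    if unknown:
        raise ValidationError(
            f"unknown parameter(s) for method {config.method!r}: {sorted(unknown)}"
        )
    params = {**schema, **config.params}
    missing = [k for k, v in params.items() if v is None and schema[k] is None
               and k not in ("seed", "exclude_nonevent")]
    if missing:
        raise ValidationError(
            f"missing required parameter(s) for {config.method!r}: {sorted(missing)}"
        )
    _check_ranges(config.method, params)
    return params


def _check_ranges(method: str, p: dict) -> None:
    def positive(*names):
        for nm in names:
            if p.get(nm) is not None and p[nm] < 1:
                raise ValidationError(f"{nm} must be >= 1, got {p[nm]}")

    def nonneg(*names):
        for nm in names:
            if p.get(nm) is not None and p[nm] < 0:
                raise ValidationError(f"{nm} must be >= 0, got {p[nm]}")

    positive(*(nm for nm in ("delay", "embed", "minline", "steps", "window_size",
                             "step", "max_lag", "max_dim", "bins", "n_candidates",
                             "max_rounds") if nm in p))
    nonneg(*(nm for nm in ("radius", "tw", "W", "lag_window") if nm in p))
    if method == "window" and p["lag_window"] >= p["window_size"]:
        raise ValidationError(
            "lag_window must be smaller than window_size: within a window, recurrence "
            "can only be computed for lags smaller than the window itself"
        )
    if method == "window" and p["per_window"] not in ("rr", "measures"):
        raise ValidationError("per_window must be 'rr' or 'measures'")
    if method == "optimize" and not p["target_lo"] < p["target_hi"]:
        raise ValidationError("target_lo must be below target_hi")


def run(config: RunConfig, x: TimeSeries | None = None,
        y: TimeSeries | None = None) -> dict:
    """Validate, dispatch, and return a JSON-ready result dict."""
    p = validate_config(config)
    if config.method in _NEEDS_TWO_SERIES and (x is None or y is None):
        raise ValidationError(f"method {config.method!r} needs two input series")
    out: dict = {"method": config.method}
    if config.method == "crqa":
        res = crqa(x, y, delay=p["delay"], embed=p["embed"], radius=p["radius"],
                   tw=p["tw"], minline=p["minline"], normalize=p["normalize"],
                   rescale=p["rescale"], datatype=p["datatype"])
        out["measures"] = {k: getattr(res.measures, k) for k in MEASURE_ORDER}
        out["n_recurrent"] = res.matrix.count
        out["dimensions"] = [res.matrix.n1, res.matrix.n2]
    elif config.method == "profile":
        prof = profiles.diagonal_recurrence_profile(
            x, y, W=p["W"], radius=p["radius"], delay=p["delay"], embed=p["embed"],
            normalize=p["normalize"], exclude_nonevent=p["exclude_nonevent"],
            datatype=p["datatype"])
        out.update(lags=prof.lags, rr=prof.rr, maxrec=prof.maxrec, maxlag=prof.maxlag)
    elif config.method == "window":
        common = dict(window_size=p["window_size"], step=p["step"],
                      radius=p["radius"], delay=p["delay"], embed=p["embed"],
                      normalize=p["normalize"], datatype=p["datatype"])
        if p["per_window"] == "rr":
            wp = profiles.windowed_diagonal_profile(
                x, y, lag_window=p["lag_window"],
                exclude_nonevent=p["exclude_nonevent"], **common)
            out.update(window_starts=wp.starts, values=wp.values)
        else:
            wp = profiles.windowed_full_crqa(x, y, minline=p["minline"],
                                             tw=p["tw"], **common)
            out.update(window_starts=wp.starts,
                       values=[{k: getattr(m, k) for k in MEASURE_ORDER}
                               for m in wp.values])
    elif config.method == "ct":
        stack = categorical.build_contingency_stack(x, y, W=p["W"])
        prof = categorical.rr_from_contingency(stack)
        out.update(states=list(stack.common_states), lags=prof.lags, rr=prof.rr,
                   maxrec=prof.maxrec, maxlag=prof.maxlag)
    elif config.method == "phi":
        stack = categorical.build_contingency_stack(x, y, W=p["W"])
        pp = categorical.phi_profile(stack, p["state"])
        out.update(state=pp.state, lags=pp.lags, phi=pp.phi,
                   n_undefined=pp.n_undefined)
    elif config.method == "optimize":
        opt = optimize.optimize_params(
            x, y, max_lag=p["max_lag"], bins=p["bins"], max_dim=p["max_dim"],
            target_rr=(p["target_lo"], p["target_hi"]),
            n_candidates=p["n_candidates"], max_rounds=p["max_rounds"],
            normalize=p["normalize"])
        out.update(delay=opt.delay, embed_dim=opt.embed_dim, radius=opt.radius,
                   achieved_rr=opt.achieved_rr,
                   diagnostics={
                       "ami_delays": list(opt.diagnostics["ami"]["delays"]),
                       "ami_curve_x": opt.diagnostics["ami"]["curve_x"],
                       "ami_curve_y": opt.diagnostics["ami"]["curve_y"],
                       "fnn_dims": list(opt.diagnostics["fnn"]["dims"]),
                       "fnn_fractions_x": opt.diagnostics["fnn"]["fractions_x"],
                       "fnn_fractions_y": opt.diagnostics["fnn"]["fractions_y"],
                       "radius_trace": opt.diagnostics["radius_trace"],
                   })
    elif config.method == "simulate":
        sp = simulate.SimParams(p_c=p["p_c"], p_s=p["p_s"], p_cc=p["p_cc"],
                                p_ss=p["p_ss"], p_sc=p["p_sc"], steps=p["steps"],
                                seed=p["seed"], coupling=p["coupling"])
        c, s = simulate.simulate_coupled_binary(sp)
        out.update(series_c=c.values, series_s=s.values)
    out["provenance"] = provenance(params=p, seed=p.get("seed"))
    return out
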