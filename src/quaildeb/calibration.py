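"""Loss function, goodness-of-fit statistics and derivative-free estimation.

Parameters are estimated by minimising the symmetric bounded loss with the
Nelder-Mead simplex, the approach customary for DEB models.  For each dataset
the squared residuals are scaled by the sum of the squared dataset means of
data and predictions, which bounds every dataset's contribution and makes the
loss symmetric under swapping data and predictions.  Fit quality is reported
as the mean relative error (MRE) and the symmetric mean squared error (SMSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .params import DEBParams

__all__ = ["CalibrationDataset", "symmetric_bounded_loss", "mre", "smse",
           "estimate", "FitResult"]


@dataclass
class CalibrationDataset:
    """Observed calibration data: scalar points and (x, y) curves.

    ``zero_variate``: list of ``(name, value, weight)``.
    ``uni_variate``: list of ``(name, x, y, weight)`` where ``weight`` is a
    scalar applied per point (default convention: 1/n per n-point curve).
    """

    zero_variate: list = field(default_factory=list)
    uni_variate: list = field(default_factory=list)

    def __post_init__(self):
        for name, _val, w in self.zero_variate:
            if w < 0:
                raise ValueError(f"negative weight for {name}")
        for name, x, y, w in self.uni_variate:
            if len(x) != len(y):
                raise ValueError(f"x/y length mismatch in {name}")
            if w < 0:
                raise ValueError(f"negative weight for {name}")

    def names(self) -> list[str]:
        return [n for n, *_ in self.zero_variate] + [n for n, *_ in self.uni_variate]


def _paired(data: CalibrationDataset, predictions: dict):
    """Yield (obs_array, pred_array, weight_array) per dataset."""
    for name, val, w in data.zero_variate:
        if name not in predictions:
            raise ValueError(f"missing prediction for {name!r}")
        yield (np.atleast_1d(float(val)),
               np.atleast_1d(float(predictions[name])),
               np.atleast_1d(float(w)))
    for name, x, y, w in data.uni_variate:
        if name not in predictions:
            raise ValueError(f"missing prediction for {name!r}")
        p = np.asarray(predictions[name], float)
        y = np.asarray(y, float)
        if p.shape != y.shape:
            raise ValueError(f"shape mismatch for {name!r}: {p.shape} vs {y.shape}")
        yield y, p, np.full_like(y, float(w))


def symmetric_bounded_loss(data: CalibrationDataset, predictions: dict) -> float:
    """Symmetric bounded loss: per dataset, weighted squared differences
    scaled by (mean of data)^2 + (mean of predictions)^2, then summed.

    Non-negative; zero iff predictions equal data; invariant under swapping
    data and predictions.
    """
    total = 0.0
    for d, p, w in _paired(data, predictions):
        scale = np.mean(d) ** 2 + np.mean(p) ** 2
        if scale == 0.0:
            continue
        total += float(np.sum(w * (d - p) ** 2) / scale)
    return total


def mre(data: CalibrationDataset, predictions: dict) -> float:
    """Mean relative error: weighted mean of |pred - obs| / |obs| per dataset,
    averaged over datasets.  Raises on a zero datum."""
    per_set = []
    for d, p, w in _paired(data, predictions):
        if np.any(d == 0):
            raise ValueError("MRE undefined for a zero datum")
        if np.sum(w) == 0:
            continue
        per_set.append(float(np.sum(w * np.abs(p - d) / np.abs(d)) / np.sum(w)))
    return float(np.mean(per_set)) if per_set else 0.0


def smse(data: CalibrationDataset, predictions: dict) -> float:
    """Symmetric mean squared error: per dataset
    sum w (d-p)^2 / sum w (d^2 + p^2), averaged over datasets, square-rooted.
    In [0, 1]; zero iff exact."""
    per_set = []
    for d, p, w in _paired(data, predictions):
        denom = float(np.sum(w * (d ** 2 + p ** 2)))
        if denom == 0:
            continue
        per_set.append(float(np.sum(w * (d - p) ** 2)) / denom)
    return math.sqrt(float(np.mean(per_set))) if per_set else 0.0


# ---------------------------------------------------------------------------
# Nelder-Mead estimation over a transformed (positivity / box) space


@dataclass
class FitResult:
    params: DEBParams
    loss: float
    trace: list          # (iteration, loss) at each improvement
    converged: bool
    message: str = ""


_LOGIT_PARAMS = {"kap", "kap_X", "kap_R", "kap_G", "f_mf"}  # bounded in (0,1)


def _to_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return math.log(value / (1.0 - value))
    return math.log(value)


def _from_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-value))
    return math.exp(value)


def estimate(predict_fn: Callable[[DEBParams], dict],
             data: CalibrationDataset,
             initial_params: DEBParams,
             free: Sequence[str],
             max_iter: int = 500,
             xatol: float = 1e-4, fatol: float = 1e-9) -> FitResult:
    """Nelder-Mead minimisation of the symmetric bounded loss.

    ``free`` names the DEBParams fields to optimise; positivity (or, for
    fractions, the unit interval) is enforced by log / logit transforms.
    ``predict_fn`` maps a parameter set to a predictions dict matching
    ``data``.  Returns the best parameters found; ``converged=False`` flags
    hitting the iteration budget.
    """
    free = list(free)
    for name in free:
        if not hasattr(initial_params, name):
            raise ValueError(f"unknown parameter {name!r}")
    if not free:
        return FitResult(params=initial_params,
                         loss=symmetric_bounded_loss(data, predict_fn(initial_params)),
                         trace=[], converged=True, message="no free parameters")

    x0 = np.array([_to_internal(n, getattr(initial_params, n)) for n in free])
    trace: list = []
    best = {"loss": math.inf, "params": initial_params}

    def objective(x: np.ndarray) -> float:
        kwargs = {n: _from_internal(n, xi) for n, xi in zip(free, x)}
        try:
            p = initial_params.replace(**kwargs)
            loss = symmetric_bounded_loss(data, predict_fn(p))
        except (ValueError, RuntimeError):
            return 1e12
        if loss < best["loss"]:
            best["loss"] = loss
            best["params"] = p
            trace.append((len(trace), loss))
        return loss

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol})
    return FitResult(params=best["params"], loss=best["loss"], trace=trace,
                     converged=bool(res.success), message=res.message)
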