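"""Boundary-condition parameter calibration.

The boundary-parameter vector is optimized on a retrospective training set
by minimizing the mean squared error between computed CT-FFR and measured
FFR on the natural FFR scale, then frozen for prospective application.
Optimization is multi-start bounded Nelder-Mead (derivative-free; the
solver sits inside the objective) over Latin-hypercube starting points,
deterministic for a fixed seed.

``h`` (the hyperemia factor) is excluded from the default free subset:
only the ratio R_ref / h enters the model, so h is confounded with the
outlet resistance scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import CalibrationError, ValidationError
from .geometry import Lesion, VesselTree
from .hemodynamics import BloodModel, BoundaryParams, ct_ffr

DEFAULT_FREE = (
    "outlet_resistance_scale",
    "diameter_exponent",
    "turbulent_loss_coefficient",
)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "outlet_resistance_scale": (60.0, 900.0),
    "diameter_exponent": (0.0, 6.0),
    "turbulent_loss_coefficient": (0.0, 5.0),
    "hyperemia_factor": (1.0, 8.0),
    "aortic_pressure": (60.0, 130.0),
}


class IdentifiabilityWarning(UserWarning):
    """Training set unlikely to pin down the free parameters."""


@dataclass(frozen=True)
class TrainingCase:
    """One retrospective vessel: geometry, target lesion, invasive FFR."""

    tree: VesselTree
    lesion: Lesion
    measured_ffr: float

    def __post_init__(self):
        if not (0.0 < self.measured_ffr <= 1.0):
            raise ValidationError(
                f"measured_ffr must lie in (0, 1], got {self.measured_ffr}"
            )


@dataclass
class CalibrationResult:
    """Frozen-parameter artifact produced by the optimizer."""

    theta_hat: BoundaryParams
    mse: float
    n_cases: int
    converged: bool
    starts: int
    seed: int
    free: tuple[str, ...]
    start_results: list[dict] = field(default_factory=list)


def ffr_mse(
    theta: BoundaryParams,
    cases: Sequence[TrainingCase],
    blood: BloodModel | None = None,
    offset: float = 25.0,
) -> float:
    """Mean over cases of (computed CT-FFR - measured FFR)^2."""
    if len(cases) == 0:
        raise ValidationError("need at least one training case")
    errs = np.empty(len(cases))
    for i, case in enumerate(cases):
        try:
            computed = ct_ffr(case.tree, case.lesion, theta, blood, offset=offset)
        except Exception as exc:  # noqa: BLE001 - annotate case, re-raise
            raise CalibrationError(f"solver failed on case {i}: {exc}") from exc
        errs[i] = computed - case.measured_ffr
    return float(np.mean(errs**2))


class BoundaryParamEstimator(BaseEstimator):
    """Scikit-learn style estimator wrapping the calibration loop.

    ``fit(cases)`` optimizes the free parameters on TrainingCase objects;
    ``predict(cases)`` returns frozen-parameter CT-FFR values.

    Parameters
    ----------
    free : tuple of str
        Names of BoundaryParams fields to optimize.
    bounds : mapping or None
        Per-parameter (low, high); defaults from DEFAULT_BOUNDS.
    n_starts : int
        Latin-hypercube starting points for the simplex search.
    seed : int
        Seeds the start design; the search itself is deterministic.
    base_params : BoundaryParams or None
        Values for the non-free parameters.
    """

    def __init__(
        self,
        free: tuple[str, ...] = DEFAULT_FREE,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        n_starts: int = 8,
        seed: int = 0,
        base_params: BoundaryParams | None = None,
        blood: BloodModel | None = None,
        offset: float = 25.0,
        start_maxiter: int = 250,
        polish_maxiter: int = 800,
        start_xatol: float = 1e-3,
        polish_xatol: float = 1e-7,
    ):
        self.free = free
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.base_params = base_params
        self.blood = blood
        self.offset = offset
        self.start_maxiter = start_maxiter
        self.polish_maxiter = polish_maxiter
        self.start_xatol = start_xatol
        self.polish_xatol = polish_xatol

    # -- internals ------------------------------------------------------
    def _resolve_bounds(self) -> list[tuple[float, float]]:
        table = dict(DEFAULT_BOUNDS)
        if self.bounds:
            table.update(self.bounds)
        out = []
        for name in self.free:
            if name not in table:
                raise ValidationError(f"no bounds known for free parameter {name!r}")
            lo, hi = table[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValidationError(f"bounds for {name!r} must be finite with hi > lo")
            out.append((float(lo), float(hi)))
        return out

    def _theta(self, z: np.ndarray, lo: np.ndarray, span: np.ndarray) -> BoundaryParams:
        base = self.base_params or BoundaryParams()
        values = lo + np.clip(z, 0.0, 1.0) * span
        return base.with_values(**dict(zip(self.free, values)))

    # -- sklearn API ----------------------------------------------------
    def fit(self, cases: Sequence[TrainingCase], y=None) -> "BoundaryParamEstimator":
        cases = list(cases)
        if not cases:
            raise ValidationError("need at least one training case")
        if y is not None:
            y = np.asarray(y, dtype=float)
            if y.shape != (len(cases),):
                raise ValidationError("y must have one measured FFR per case")
            cases = [
                TrainingCase(c.tree, c.lesion, float(v)) for c, v in zip(cases, y)
            ]
        degrees = [
            les.degree for c in cases for les in c.tree.lesions
        ] or [c.lesion.degree for c in cases]
        if degrees and (max(degrees) - min(degrees) < 20.0):
            warnings.warn(
                "training lesions span < 20 percentage points of stenosis degree; "
                "the turbulent-loss coefficient may be poorly identified",
                IdentifiabilityWarning,
                stacklevel=2,
            )

        pairs = self._resolve_bounds()
        lo = np.array([p[0] for p in pairs])
        span = np.array([p[1] - p[0] for p in pairs])
        d = len(self.free)

        # theta-independent compilation of every case, reused across the
        # thousands of simplex evaluations
        from .hemodynamics import compile_network, compile_probe, fast_ct_ffr

        nets = [compile_network(c.tree, self.blood) for c in cases]
        probes = [
            compile_probe(net, c.lesion, self.offset) for net, c in zip(nets, cases)
        ]
        target = np.array([c.measured_ffr for c in cases])

        def objective(z: np.ndarray) -> float:
            theta = self._theta(z, lo, span)
            pred = np.array(
                [fast_ct_ffr(net, pr, theta) for net, pr in zip(nets, probes)]
            )
            return float(np.mean((pred - target) ** 2))

        sampler = qmc.LatinHypercube(d=d, seed=self.seed)
        starts = sampler.random(self.n_starts)
        unit_bounds = [(0.0, 1.0)] * d
        results, failures = [], []
        for i, z0 in enumerate(starts):
            try:
                res = minimize(
                    objective,
                    z0,
                    method="Nelder-Mead",
                    bounds=unit_bounds,
                    options={
                        "maxiter": self.start_maxiter,
                        "xatol": self.start_xatol,
                        "fatol": 1e-12,
                    },
                )
                results.append({"start": i, "x0": z0, "x": res.x, "mse": float(res.fun),
                                "success": bool(res.success)})
            except Exception as exc:  # noqa: BLE001 - collected as diagnostics
                failures.append({"start": i, "x0": z0, "error": str(exc)})
        if not results:
            raise CalibrationError("all optimizer starts failed", diagnostics=failures)

        best = min(results, key=lambda r: r["mse"])
        res = minimize(
            objective,
            best["x"],
            method="Nelder-Mead",
            bounds=unit_bounds,
            options={
                "maxiter": self.polish_maxiter,
                "xatol": self.polish_xatol,
                "fatol": 1e-16,
            },
        )
        z_hat = res.x if res.fun <= best["mse"] else best["x"]
        mse_hat = float(min(res.fun, best["mse"]))

        self.theta_ = self._theta(z_hat, lo, span)
        self.mse_ = mse_hat
        self.n_iter_ = int(res.nit)
        self.result_ = CalibrationResult(
            theta_hat=self.theta_,
            mse=self.mse_,
            n_cases=len(cases),
            converged=bool(res.success or best["success"]),
            starts=self.n_starts,
            seed=self.seed,
            free=tuple(self.free),
            start_results=results + failures,
        )
        return self

    def predict(self, cases: Iterable) -> np.ndarray:
        """CT-FFR under the frozen parameters for TrainingCase or
        (tree, lesion) items."""
        if not hasattr(self, "theta_"):
            raise NotFittedError("call fit before predict")
        out = []
        for item in cases:
            if isinstance(item, TrainingCase):
                tree, lesion = item.tree, item.lesion
            else:
                tree, lesion = item
            out.append(ct_ffr(tree, lesion, self.theta_, self.blood, offset=self.offset))
        return np.asarray(out)

    def score(self, cases: Sequence[TrainingCase], y=None) -> float:
        """Negative MSE (higher is better, sklearn convention)."""
        cases = list(cases)
        target = np.asarray(
            [c.measured_ffr for c in cases] if y is None else y, dtype=float
        )
        pred = self.predict(cases)
        return -float(np.mean((pred - target) ** 2))


def optimize_boundary_params(
    cases: Sequence[TrainingCase],
    free: tuple[str, ...] = DEFAULT_FREE,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    **kwargs,
) -> CalibrationResult:
    """Functional wrapper over :class:`BoundaryParamEstimator`."""
    est = BoundaryParamEstimator(
        free=free, bounds=bounds, n_starts=n_starts, seed=seed, **kwargs
    )
    est.fit(cases)
    return est.result_


def freeze_and_apply(
    result: CalibrationResult | BoundaryParams,
    cohort: Mapping[str, tuple[VesselTree, Lesion]],
    blood: BloodModel | None = None,
    offset: float = 25.0,
) -> pd.DataFrame:
    """Apply frozen parameters, unchanged, to every cohort vessel.

    Returns a DataFrame (vessel_id, ct_ffr, status, reason); per-vessel
    solver failures are recorded as missing with a reason, never fatal.
    """
    if isinstance(result, CalibrationResult):
        if not result.converged:
            raise CalibrationError("refusing to apply an unconverged calibration")
        theta = result.theta_hat
    else:
        theta = result
    rows = []
    for vessel_id, (tree, lesion) in cohort.items():
        try:
            value = ct_ffr(tree, lesion, theta, blood, offset=offset)
            rows.append({"vessel_id": vessel_id, "ct_ffr": value, "status": "ok",
                         "reason": ""})
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            rows.append({"vessel_id": vessel_id, "ct_ffr": np.nan, "status": "failed",
                         "reason": str(exc)})
    return pd.DataFrame(rows, columns=["vessel_id", "ct_ffr", "status", "reason"])
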