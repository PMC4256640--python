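"""The geoadditive Poisson model: predictor assembly, likelihood, priors.

Counts y_i in areal unit i are modelled as

    y_i ~ Poisson(mu_i),   mu_i = exp(eta_i + offset_i),
    eta_i = alpha + x_i' beta + sum_j f_j(x_ij) + f_spat(s_i),

with offset_i = log(population_i / 1000) so the fixed effects act on the
events-per-1000-population rate scale.  Priors: improper flat on the fixed
effects and intercept; P-spline (random-walk) priors on each smooth f_j;
an intrinsic MRF (graph Laplacian) prior on the spatial field f_spat; and
inverse-gamma(a, b) hyperpriors on every prior variance tau^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import gammaln

from .graph import MRFStructure, WardGraph, build_mrf_precision
from .io import WardDataset
from .smoothers import SplineBasis, bspline_basis

__all__ = [
    "ModelSpec",
    "FitReadyModel",
    "LinearPredictorState",
    "build_design",
    "linear_predictor",
    "poisson_loglik",
    "combined_air_quality_index",
    "make_offset",
]

# linear predictors are clipped here before exponentiation
ETA_CLIP = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the predictor and with what priors."""

    fixed_terms: tuple[str, ...] = ()
    smooth_terms: tuple[tuple[str, dict], ...] = ()  # (covariate, bspline settings)
    spatial: bool = False
    offset_mode: str = "per_1000_population"  # or "none"
    hyperprior_a: float = 0.001
    hyperprior_b: float = 0.001
    include_intercept: bool = True
    standardize: bool = False

    def __post_init__(self):
        if self.offset_mode not in ("per_1000_population", "none"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")
        if self.hyperprior_a <= 0 or self.hyperprior_b <= 0:
            raise ValueError("hyperprior parameters must be > 0")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(
            self, "smooth_terms", tuple((n, dict(s)) for n, s in self.smooth_terms)
        )


@dataclass
class SmoothTerm:
    name: str
    basis: SplineBasis


@dataclass
class FitReadyModel:
    """Everything the sampler needs, in one aligned bundle."""

    y: np.ndarray
    X: np.ndarray  # fixed design incl. intercept column if requested
    fixed_names: tuple[str, ...]
    smooths: list[SmoothTerm]
    mrf: MRFStructure | None
    offset: np.ndarray
    spec: ModelSpec
    graph: WardGraph | None
    ward_ids: tuple[str, ...]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.y)

    @property
    def has_intercept(self) -> bool:
        return self.spec.include_intercept


@dataclass
class LinearPredictorState:
    """Current values of every coefficient block and variance."""

    intercept: float
    beta: np.ndarray  # non-intercept fixed effects
    gammas: list[np.ndarray]  # spline coefficients, one per smooth
    f_spat: np.ndarray  # per-ward spatial effect (empty if no spatial term)
    tau2_smooth: list[float]
    tau2_spat: float


def make_offset(populations: np.ndarray, offset_mode: str) -> np.ndarray:
    populations = np.asarray(populations, dtype=float)
    if offset_mode == "per_1000_population":
        return np.log(populations / 1000.0)
    if offset_mode == "none":
        return np.zeros_like(populations)
    raise ValueError(f"unknown offset_mode {offset_mode!r}")


def build_design(
    dataset: WardDataset,
    spec: ModelSpec,
    graph: WardGraph | None = None,
) -> FitReadyModel:
    """Assemble design matrices, penalties, MRF structure and offset.

    The graph is re-indexed to the dataset's ward order so that row i of
    every design block refers to the same unit.
    """
    n = len(dataset)
    for name in spec.fixed_terms:
        if name not in dataset.covariate_names:
            raise KeyError(f"fixed term {name!r} not found among dataset covariates")
    for name, _ in spec.smooth_terms:
        if name not in dataset.covariate_names:
            raise KeyError(f"smooth term {name!r} not found among dataset covariates")

    cols = []
    names = []
    if spec.include_intercept:
        cols.append(np.ones(n))
        names.append("constant")
    for name in spec.fixed_terms:
        x = dataset.covariate(name)
        if spec.standardize:
            sd = x.std()
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant; cannot standardize")
            x = (x - x.mean()) / sd
        cols.append(x)
        names.append(name)
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    smooths = []
    for name, settings in spec.smooth_terms:
        basis = bspline_basis(dataset.covariate(name), **settings)
        smooths.append(SmoothTerm(name=name, basis=basis))

    mrf = None
    g = None
    if spec.spatial:
        if graph is None:
            raise ValueError("spec requests a spatial term but no graph was given")
        if set(graph.node_ids) != set(dataset.ward_ids):
            raise ValueError("graph node ids do not match dataset ward ids")
        g = graph.reindex(dataset.ward_ids)
        mrf = build_mrf_precision(g)

    offset = make_offset(dataset.populations, spec.offset_mode)
    return FitReadyModel(
        y=dataset.counts.astype(float),
        X=X,
        fixed_names=tuple(names),
        smooths=smooths,
        mrf=mrf,
        offset=offset,
        spec=spec,
        graph=g,
        ward_ids=dataset.ward_ids,
    )


def initial_state(model: FitReadyModel) -> LinearPredictorState:
    """Sensible starting point: intercept at the crude log rate, rest at 0."""
    ybar = max(float(np.mean(model.y)), 0.01)
    intercept = float(np.log(ybar) - np.mean(model.offset)) if model.has_intercept else 0.0
    p = model.X.shape[1] - (1 if model.has_intercept else 0)
    return LinearPredictorState(
        intercept=intercept,
        beta=np.zeros(p),
        gammas=[np.zeros(s.basis.n_basis) for s in model.smooths],
        f_spat=np.zeros(model.n_units) if model.mrf is not None else np.empty(0),
        tau2_smooth=[0.1 for _ in model.smooths],
        tau2_spat=0.1,
    )


def linear_predictor(state: LinearPredictorState, model: FitReadyModel) -> np.ndarray:
    """eta_i = intercept + x_i' beta + sum_j B_j(x_i) gamma_j + f_spat(s_i)."""
    coefs = []
    if model.has_intercept:
        coefs.append(state.intercept)
    coefs.extend(np.atleast_1d(state.beta))
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape[0] != model.X.shape[1]:
        raise ValueError(
            f"fixed coefficient length {coefs.shape[0]} != design columns {model.X.shape[1]}"
        )
    eta = model.X @ coefs if model.X.shape[1] else np.zeros(model.n_units)
    if len(state.gammas) != len(model.smooths):
        raise ValueError("number of smooth coefficient vectors does not match model")
    for term, gamma in zip(model.smooths, state.gammas):
        if len(gamma) != term.basis.n_basis:
            raise ValueError(f"smooth {term.name!r}: coefficient length mismatch")
        eta = eta + term.basis.B @ gamma
    if model.mrf is not None:
        if len(state.f_spat) != model.n_units:
            raise ValueError("spatial effect length does not match number of units")
        eta = eta + state.f_spat
    return eta


def poisson_loglik(y, eta, offset) -> float:
    """Poisson log likelihood sum_i [ y_i lp_i - exp(lp_i) - log(y_i!) ], lp = eta + offset."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if y.shape != eta.shape or y.shape != offset.shape:
        raise ValueError("y, eta, offset must have equal length")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    lp = eta + offset
    mu = np.exp(np.clip(lp, -ETA_CLIP, ETA_CLIP))
    return float(np.sum(y * lp - mu - gammaln(y + 1.0)))


def combined_air_quality_index(nox, so2, pm, ben):
    """Combined air-quality score: the four pollutant indicators summed.

    Each indicator is expressed relative to its national standard (1 = at
    the standard), so four pollutants all at standard give a score of 4.
    Accepts scalars or aligned arrays.
    """
    parts = [np.asarray(v, dtype=float) for v in (nox, so2, pm, ben)]
    for name, v in zip(("nox", "so2", "pm", "ben"), parts):
        if np.any(v < 0):
            raise ValueError(f"pollutant indicator {name!r} must be >= 0")
    total = parts[0] + parts[1] + parts[2] + parts[3]
    return float(total) if np.ndim(total) == 0 else total
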