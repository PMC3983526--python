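"""Local and global parameter-sensitivity ranking.

The elementary quantity is the relative local sensitivity of an
observable ``y_O(t)`` to a parameter ``p``,

    S_p^{eps,O}(t) = (dy_O(t)/dp) * p / max(|y_O(t)|, guard),

computed by central finite differences with a relative parameter step
(a forward-sensitivity ODE route is provided as an independent
cross-check). Sensitivities are evaluated on the same observation
design used for fitting — the fitted observables at the dataset time
points — since the ranking is about importance for what is actually
measured.

Ranking aggregates the squared relative sensitivities over experiments,
observables and times into a root-mean-square score per parameter
(``msqr``); the global variant additionally averages over Latin
Hypercube samples of the parameter space within bounds. The local rank
is exactly the one-sample special case of the global rank. The score is
reported with the square root applied (a rootless variant is available
by flag; the induced ranking order is identical either way).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from .model import (
    IntegrationError,
    N_STATES,
    ObservableMap,
    _as_param_array,
    _jac_arr,
    _rhs_arr,
    observe,
    quiescent_state,
    simulate,
)
from .parameters import CANONICAL_NAMES, ParameterSet, resolve_name
from .synth import Design

__all__ = [
    "SensitivityDesign",
    "SensitivityTensor",
    "RankTable",
    "relative_sensitivities",
    "forward_sensitivities",
    "local_rank",
    "global_rank",
    "lhs_sample",
    "compare_ranks",
]

logger = logging.getLogger(__name__)

#: floor on |y| in the relative normalization, to avoid division by a
#: near-zero observable value
EPSILON_GUARD = 1e-9


@dataclass(frozen=True)
class SensitivityDesign:
    """Where sensitivities are evaluated: observables, times, stimulus."""

    times: tuple[float, ...]
    observables: tuple[str, ...] = ObservableMap.FITTED
    S: float = 1.0

    @classmethod
    def default(cls) -> "SensitivityDesign":
        d = Design()
        return cls(times=tuple(d.times()), observables=d.observables, S=d.S)

    @classmethod
    def from_dataset(cls, dataset) -> "SensitivityDesign":
        times = tuple(np.unique(dataset.df["time"]))
        return cls(times=times, observables=tuple(dataset.observables()),
                   S=float(dataset.meta.get("S", 1.0)))


@dataclass
class SensitivityTensor:
    """Relative sensitivities indexed (sample, observable, time, parameter)."""

    values: np.ndarray                # (n_lhs, n_obs, n_times, n_params)
    observables: tuple[str, ...]
    times: np.ndarray
    parameters: tuple[str, ...]
    thetas: list[ParameterSet] = field(default_factory=list)

    def __post_init__(self):
        expect = (len(self.thetas) or self.values.shape[0],
                  len(self.observables), len(self.times), len(self.parameters))
        if self.values.shape != expect:
            raise ValueError(f"tensor shape {self.values.shape} != {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite sensitivities")

    def msqr(self, sqrt: bool = True) -> np.ndarray:
        """RMS (or mean-square, ``sqrt=False``) score per parameter."""
        ms = np.mean(self.values ** 2, axis=(0, 1, 2))
        return np.sqrt(ms) if sqrt else ms


#: simulations behind finite-difference derivatives run at tighter
#: tolerances than ordinary runs: with a relative parameter step h the
#: integrator error is amplified by 1/(2h)
_FD_RTOL, _FD_ATOL = 1e-10, 1e-12


def _observable_curves(theta, design: SensitivityDesign, obs_map: ObservableMap,
                       init: np.ndarray) -> np.ndarray:
    """(n_obs, n_times) noiseless observable values at the design times."""
    times = np.asarray(design.times, dtype=float)
    tgrid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = simulate(theta, init, design.S, tgrid, rtol=_FD_RTOL, atol=_FD_ATOL)
    frame = observe(traj, obs_map, names=list(design.observables))
    frame = frame[np.isin(frame["time"], times)]
    return frame[list(design.observables)].to_numpy().T


def relative_sensitivities(theta: ParameterSet,
                           design: SensitivityDesign | None = None,
                           parameters: Sequence[str] | None = None,
                           rel_step: float = 1e-5,
                           epsilon_guard: float = EPSILON_GUARD,
                           obs_map: ObservableMap | None = None,
                           init: np.ndarray | None = None) -> SensitivityTensor:
    """One slice of relative local sensitivities at a nominal theta.

    Derivatives are central finite differences with relative step
    ``rel_step`` on each parameter; normalization divides by
    ``max(|y_O(t)|, epsilon_guard)`` and multiplies by the nominal
    parameter value. Guarded points are logged.
    """
    design = design or SensitivityDesign.default()
    obs_map = obs_map or ObservableMap.default()
    names = tuple(resolve_name(n) for n in (parameters or CANONICAL_NAMES))
    if init is None:
        init = quiescent_state(theta)

    try:
        y0 = _observable_curves(theta, design, obs_map, init)
    except IntegrationError as err:
        raise IntegrationError(f"nominal simulation failed: {err}") from err
    guard_hits = int(np.sum(np.abs(y0) < epsilon_guard))
    if guard_hits:
        logger.info("epsilon guard active at %d observable points", guard_hits)
    denom = np.maximum(np.abs(y0), epsilon_guard)

    vals = np.empty((1, len(design.observables), len(design.times), len(names)))
    for j, pname in enumerate(names):
        p = theta[pname]
        h = rel_step * p
        try:
            y_hi = _observable_curves(theta.replace(**{pname: p + h}), design,
                                      obs_map, init)
            y_lo = _observable_curves(theta.replace(**{pname: p - h}), design,
                                      obs_map, init)
        except IntegrationError as err:
            raise IntegrationError(
                f"sensitivity simulation failed for parameter {pname}: {err}"
            ) from err
        dydp = (y_hi - y_lo) / (2 * h)
        vals[0, :, :, j] = dydp * p / denom
    return SensitivityTensor(values=vals, observables=tuple(design.observables),
                             times=np.asarray(design.times), parameters=names,
                             thetas=[theta])


def forward_sensitivities(theta: ParameterSet, design: SensitivityDesign,
                          parameters: Sequence[str],
                          obs_map: ObservableMap | None = None,
                          init: np.ndarray | None = None,
                          epsilon_guard: float = EPSILON_GUARD,
                          rtol: float = 1e-10, atol: float = 1e-12) -> SensitivityTensor:
    """Relative sensitivities via the forward variational ODEs.

    Integrates the state jointly with ``s_p = dx/dp`` using
    ``ds_p/dt = J(x) s_p + df/dp``, an independent route from the
    trajectory finite differences in :func:`relative_sensitivities`.
    """
    obs_map = obs_map or ObservableMap.default()
    names = tuple(resolve_name(n) for n in parameters)
    if init is None:
        init = quiescent_state(theta)
    p_full = theta.as_array()
    idx = [CANONICAL_NAMES.index(n) for n in names]
    n_p = len(idx)
    S = design.S

    def dfdp(x, k):
        h = 1e-6 * p_full[k]
        p_hi = p_full.copy(); p_hi[k] += h
        p_lo = p_full.copy(); p_lo[k] -= h
        return (_rhs_arr(x, p_hi, S) - _rhs_arr(x, p_lo, S)) / (2 * h)

    def aug_rhs(_t, z):
        x = z[:N_STATES]
        J = _jac_arr(x, p_full, S)
        out = np.empty_like(z)
        out[:N_STATES] = _rhs_arr(x, p_full, S)
        for a, k in enumerate(idx):
            s = z[N_STATES * (a + 1): N_STATES * (a + 2)]
            out[N_STATES * (a + 1): N_STATES * (a + 2)] = J @ s + dfdp(x, k)
        return out

    times = np.asarray(design.times, dtype=float)
    tgrid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    z0 = np.concatenate([init, np.zeros(N_STATES * n_p)])
    sol = solve_ivp(aug_rhs, (tgrid[0], tgrid[-1]), z0, method="LSODA",
                    t_eval=tgrid, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"forward sensitivity integration failed: {sol.message}")
    keep = np.isin(sol.t, times)
    M = obs_map.matrix(list(design.observables))
    x_t = sol.y[:N_STATES, keep].T
    y0 = (x_t @ M.T).T
    denom = np.maximum(np.abs(y0), epsilon_guard)
    vals = np.empty((1, len(design.observables), len(times), n_p))
    for a, (k, pname) in enumerate(zip(idx, names)):
        s_t = sol.y[N_STATES * (a + 1): N_STATES * (a + 2), keep].T
        dydp = (s_t @ M.T).T
        vals[0, :, :, a] = dydp * p_full[k] / denom
    return SensitivityTensor(values=vals, observables=tuple(design.observables),
                             times=times, parameters=names, thetas=[theta])


@dataclass
class RankTable:
    """Parameters sorted by decreasing sensitivity score.

    Ties are broken by canonical parameter order so rankings are
    deterministic.
    """

    scores: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("scores must be non-negative")
        order = sorted(self.scores,
                       key=lambda n: (-self.scores[n], CANONICAL_NAMES.index(n)))
        self.scores = {n: float(self.scores[n]) for n in order}

    def ranking(self) -> list[str]:
        return list(self.scores)

    def rank_of(self, name: str) -> int:
        """1-based rank of a parameter."""
        return self.ranking().index(resolve_name(name)) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": list(self.scores),
                             "score": list(self.scores.values()),
                             "rank": np.arange(1, len(self.scores) + 1)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def local_rank(theta: ParameterSet, design: SensitivityDesign | None = None,
               sqrt: bool = True, **kw) -> RankTable:
    """Rank all 24 parameters by RMS relative sensitivity at theta."""
    design = design or SensitivityDesign.default()
    tensor = relative_sensitivities(theta, design, **kw)
    scores = dict(zip(tensor.parameters, tensor.msqr(sqrt=sqrt)))
    return RankTable(scores, metadata={"kind": "local", "n_lhs": 1,
                                       "theta": dict(theta.values),
                                       "S": design.S, "sqrt": sqrt})


def lhs_sample(bounds: Mapping[str, tuple[float, float]], n_lhs: int,
               seed: int = 0) -> list[dict[str, float]]:
    """Latin Hypercube parameter samples, stratified in log space.

    Each parameter's ``n_lhs`` values occupy distinct equal-probability
    strata of its log-range, guaranteeing even marginal coverage with
    few samples.
    """
    if n_lhs < 1:
        raise ValueError("n_lhs must be >= 1")
    names = [resolve_name(n) for n in bounds]
    lo = np.array([bounds[n][0] for n in bounds], dtype=float)
    hi = np.array([bounds[n][1] for n in bounds], dtype=float)
    if np.any(lo <= 0) or np.any(hi < lo):
        raise ValueError("bounds must be positive with lo <= hi")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n=n_lhs)
    vals = 10.0 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))
    return [dict(zip(names, row)) for row in vals]


def global_rank(theta_nominal: ParameterSet,
                bounds: Mapping[str, tuple[float, float]] | None = None,
                n_lhs: int = 200, design: SensitivityDesign | None = None,
                seed: int = 0, sqrt: bool = True,
                bounds_scale: tuple[float, float] = (0.1, 10.0),
                max_fail_fraction: float = 0.2, **kw) -> RankTable:
    """Rank parameters by RMS relative sensitivity over LHS samples.

    Samples are drawn within ``bounds`` (default 0.1x-10x nominal, log
    space); a sensitivity slice is evaluated at every sample and the
    squared sensitivities are averaged over samples, observables and
    times before the root. With ``n_lhs=1`` the single sample is the
    nominal theta itself, reducing exactly to :func:`local_rank`.
    Samples whose simulations fail are dropped (logged); more than
    ``max_fail_fraction`` failures is an error.
    """
    design = design or SensitivityDesign.default()
    if bounds is None:
        bounds = {n: (bounds_scale[0] * theta_nominal[n],
                      bounds_scale[1] * theta_nominal[n])
                  for n in CANONICAL_NAMES}
    if n_lhs == 1:
        thetas = [theta_nominal]
    else:
        thetas = [theta_nominal.replace(**s)
                  for s in lhs_sample(bounds, n_lhs, seed=seed)]
    slices, n_failed = [], 0
    for th in thetas:
        try:
            slices.append(relative_sensitivities(th, design, **kw))
        except (IntegrationError, RuntimeError):
            n_failed += 1
    if n_failed:
        logger.warning("dropped %d/%d LHS samples with failed simulations",
                       n_failed, len(thetas))
    if n_failed > max_fail_fraction * len(thetas):
        raise RuntimeError(f"{n_failed}/{len(thetas)} LHS samples failed")
    values = np.concatenate([s.values for s in slices], axis=0)
    tensor = SensitivityTensor(values=values, observables=slices[0].observables,
                               times=slices[0].times,
                               parameters=slices[0].parameters,
                               thetas=[s.thetas[0] for s in slices])
    scores = dict(zip(tensor.parameters, tensor.msqr(sqrt=sqrt)))
    return RankTable(scores, metadata={
        "kind": "global", "n_lhs": n_lhs, "n_used": len(slices), "seed": seed,
        "bounds": {n: list(map(float, bounds[n])) for n in bounds},
        "S": design.S, "sqrt": sqrt})


def compare_ranks(table_a: RankTable, table_b: RankTable) -> pd.DataFrame:
    """Per-parameter score ratio (B/A) and signed rank displacement.

    A positive displacement means the parameter moved up (became more
    important) in B relative to A. Zero-score denominators yield an
    infinite ratio.
    """
    if set(table_a.scores) != set(table_b.scores):
        raise ValueError("rank tables cover different parameter sets")
    names = table_a.ranking()
    sa = np.array([table_a.scores[n] for n in names])
    sb = np.array([table_b.scores[n] for n in names])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sa > 0, sb / sa, np.where(sb > 0, np.inf, 1.0))
    rank_a = np.array([table_a.rank_of(n) for n in names])
    rank_b = np.array([table_b.rank_of(n) for n in names])
    return pd.DataFrame({"name": names, "score_a": sa, "score_b": sb,
                         "ratio": ratio, "rank_a": rank_a, "rank_b": rank_b,
                         "displacement": rank_a - rank_b})
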