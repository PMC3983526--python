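"""Generalized-least-squares calibration with multistart local search.

The objective is the weighted quadratic form

    J(theta) = sum_eps sum_O  r' Q r,     r = y_model - y_measured,

summed over experiments and observables, with a diagonal non-negative
weighting matrix Q per (experiment, observable) block. Weighting modes:
every datum equally (``equal``), per-datum exclusion (``exclude``), or
down-scaling each block by the square of its largest measured value
(``scale_reduce``) so observables of different magnitude contribute
comparably.

Minimization runs a bounded trust-region least-squares solver from many
random starting points drawn log-uniformly inside the parameter bounds
(multistart, mimicking Monte-Carlo sampling of initial guesses) and
keeps the best local optimum, with a full per-start audit trail.

Three named presets reproduce the free-parameter choices of the three
historical calibration rounds against cyclin D, cyclin E and total-Rb
time courses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import IntegrationError, ObservableMap, observe, quiescent_state, simulate
from .parameters import CANONICAL_NAMES, ParameterSet, resolve_name
from .synth import TimeCourseDataset

__all__ = [
    "WeightScheme",
    "FitProblem",
    "FitResult",
    "RoundPreset",
    "build_weights",
    "gls_objective",
    "sample_starts",
    "multistart_fit",
    "round_presets",
    "ROUND_FREE_PARAMETERS",
]

#: J assigned to a start whose simulation fails, instead of aborting it
PENALTY_J = 1e8

#: Free parameters of the three calibration rounds. Round 1 frees the 12
#: numerically estimated constants; round 2 drops the four least
#: sensitive of them (KCE, kkCD, kRE, KS) and adds the two Rb
#: phosphorylation rates (kP1, kP2); round 3 frees the 14 constants with
#: the lowest global sensitivity.
ROUND_FREE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "round1": ("kRE", "kkE", "kkM", "kCDS", "kR", "KS",
               "kkCE", "KE", "KCE", "dRP", "kkCD", "kb"),
    "round2": ("kkE", "kkM", "kCDS", "kR", "kkCE", "KE",
               "dRP", "kb", "kP1", "kP2"),
    "round3": ("dMC", "KM", "kkM", "dE", "kRE", "kR", "dR",
               "dRP", "dCE", "KCE", "kkCE", "kkCD", "kCDS", "KS"),
}


@dataclass(frozen=True)
class WeightScheme:
    """How the diagonal of each block's weighting matrix is filled.

    ``equal``
        every weight 1.
    ``exclude``
        weight 1 except for data matching ``excluded`` — an iterable of
        ``(experiment, observable, time)`` triples — which get weight 0
        and therefore no influence on J at all.
    ``scale_reduce``
        per-block constant ``1 / max(|ym|)^2``, the convention that
        equalizes the contribution of observables of different orders
        of magnitude. ``literal=True`` switches to the bare
        ``max(|ym|)^2`` (which amplifies, rather than suppresses, large
        observables; kept for comparison with sources that print it
        this way).
    """

    mode: str = "equal"
    excluded: tuple = ()
    literal: bool = False

    def __post_init__(self):
        if self.mode not in ("equal", "exclude", "scale_reduce"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")


def build_weights(dataset: TimeCourseDataset,
                  scheme: WeightScheme) -> dict[tuple, np.ndarray]:
    """Diagonal weights per (experiment, observable) block.

    The dataset's own per-datum weight column multiplies the scheme's
    weights, so stored exclusions survive any mode.
    """
    out: dict[tuple, np.ndarray] = {}
    for exp in dataset.experiments:
        for obs in dataset.observables(exp):
            block = dataset.block(exp, obs)
            base = block["weight"].to_numpy(dtype=float)
            if scheme.mode == "equal":
                w = np.ones(len(block))
            elif scheme.mode == "exclude":
                w = np.ones(len(block))
                times = block["time"].to_numpy()
                for (e, o, t) in scheme.excluded:
                    if e == exp and o == obs:
                        w[np.isclose(times, t)] = 0.0
            else:  # scale_reduce
                m2 = float(np.max(np.abs(block["value"]))) ** 2
                if m2 == 0:
                    w = np.ones(len(block))
                else:
                    w = np.full(len(block), m2 if scheme.literal else 1.0 / m2)
            out[(exp, obs)] = w * base
    return out


@dataclass
class FitProblem:
    """A calibration problem: data, free parameters, bounds, the rest.

    ``theta_nominal`` supplies the fixed parameters and the nominal
    values from which default bounds (0.1x to 10x) are derived.
    ``init`` is the initial state for every simulated experiment;
    by default the dataset's recorded initial state is used when
    present, otherwise the quiescent state of ``theta_nominal``.
    """

    dataset: TimeCourseDataset
    free_names: Sequence[str]
    theta_nominal: ParameterSet
    S: float | None = None
    bounds: Mapping[str, tuple[float, float]] | None = None
    init: np.ndarray | None = None
    weight_scheme: WeightScheme = field(default_factory=WeightScheme)
    obs_map: ObservableMap | None = None
    label: str = "custom"

    def __post_init__(self):
        names = [resolve_name(n) for n in self.free_names]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free parameter names")
        self.free_names = tuple(names)
        fixed = [n for n in CANONICAL_NAMES if n not in names]
        assert set(fixed) | set(names) == set(CANONICAL_NAMES)
        self.fixed_names = tuple(fixed)

        bounds = {} if self.bounds is None else {
            resolve_name(k): tuple(v) for k, v in self.bounds.items()}
        for n in names:
            lo, hi = bounds.get(n, (0.1 * self.theta_nominal[n],
                                    10.0 * self.theta_nominal[n]))
            if not (0 < lo <= hi):
                raise ValueError(f"invalid bounds for {n}: ({lo}, {hi})")
            bounds[n] = (lo, hi)
        self.bounds = {n: bounds[n] for n in names}

        if self.S is None:
            self.S = float(self.dataset.meta.get("S", 1.0))
        if self.init is None:
            if "init" in self.dataset.meta:
                self.init = np.asarray(self.dataset.meta["init"], dtype=float)
            else:
                self.init = quiescent_state(self.theta_nominal)
        self.obs_map = self.obs_map or ObservableMap.default()
        self._weights = build_weights(self.dataset, self.weight_scheme)

    def theta_from_free(self, free_values: Sequence[float]) -> ParameterSet:
        return self.theta_nominal.replace(
            **dict(zip(self.free_names, free_values)))

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        return lo, hi


def _residuals(theta: ParameterSet, problem: FitProblem) -> np.ndarray:
    """Stacked sqrt(weight)-scaled residuals over all data blocks."""
    parts = []
    for exp in problem.dataset.experiments:
        obs_names = problem.dataset.observables(exp)
        times = np.unique(np.concatenate(
            [problem.dataset.block(exp, o)["time"].to_numpy() for o in obs_names]))
        tgrid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
        traj = simulate(theta, problem.init, problem.S, tgrid)
        frame = observe(traj, problem.obs_map, names=obs_names)
        frame = frame.set_index("time")
        for o in obs_names:
            block = problem.dataset.block(exp, o)
            y = frame.loc[block["time"].to_numpy(), o].to_numpy()
            r = y - block["value"].to_numpy()
            parts.append(np.sqrt(problem._weights[(exp, o)]) * r)
    return np.concatenate(parts)


def gls_objective(theta, problem: FitProblem) -> float:
    """The GLS objective J at one parameter set.

    A failed integration yields the fixed penalty value instead of an
    exception so a multistart sweep can continue past bad regions.
    """
    if not isinstance(theta, ParameterSet):
        theta = problem.theta_from_free(theta)
    try:
        r = _residuals(theta, problem)
    except (IntegrationError, FloatingPointError):
        return PENALTY_J
    return float(np.dot(r, r))


def sample_starts(problem: FitProblem, n_starts: int, seed: int = 0) -> np.ndarray:
    """Log-uniform starting points inside the bounds, seeded.

    Returns an array of shape ``(n_starts, n_free)`` in the order of
    ``problem.free_names``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = problem.bounds_arrays()
    u = rng.uniform(size=(n_starts, len(lo)))
    return 10.0 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))


@dataclass
class FitResult:
    """Best-of-multistart outcome plus the per-start audit trail."""

    theta: ParameterSet
    J: float
    J_per_datum: float
    free_names: tuple[str, ...]
    starts: list[dict]
    label: str = "custom"

    def __post_init__(self):
        if self.J < 0:
            raise ValueError("objective cannot be negative")

    def to_json(self, path) -> None:
        payload = {
            "label": self.label,
            "J": self.J,
            "J_per_datum": self.J_per_datum,
            "free_names": list(self.free_names),
            "theta": dict(self.theta.values),
            "starts": self.starts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def multistart_fit(problem: FitProblem, n_starts: int = 20, seed: int = 0,
                   starts: np.ndarray | None = None, max_nfev: int = 2000,
                   tol: float = 1e-10) -> FitResult:
    """Run the bounded local solver from every start; keep the best.

    Each start is refined in log10 parameter space by a trust-region
    reflective least-squares minimizer constrained to the bounds, with
    at most ``max_nfev`` residual evaluations. Starts whose every
    evaluation fails keep the penalty objective; if all starts fail an
    error carrying the per-start log is raised.
    """
    if starts is None:
        starts = sample_starts(problem, n_starts, seed=seed)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    lo, hi = problem.bounds_arrays()
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    n_data = problem.dataset.n_data()
    penalty_res = np.full(n_data, np.sqrt(PENALTY_J / n_data))

    def res_log(z: np.ndarray) -> np.ndarray:
        theta = problem.theta_from_free(10.0 ** z)
        try:
            return _residuals(theta, problem)
        except (IntegrationError, FloatingPointError):
            return penalty_res

    records: list[dict] = []
    best = None
    for x0 in starts:
        z0 = np.clip(np.log10(x0), log_lo, log_hi)
        try:
            sol = least_squares(res_log, z0, bounds=(log_lo, log_hi),
                                method="trf", max_nfev=max_nfev,
                                ftol=tol, xtol=tol, gtol=tol)
            x_opt = 10.0 ** sol.x
            J = float(2 * sol.cost)
            rec = {"start": list(map(float, x0)),
                   "theta_free": list(map(float, x_opt)),
                   "J": J, "nfev": int(sol.nfev), "success": bool(sol.success)}
        except Exception as err:
            rec = {"start": list(map(float, x0)), "theta_free": None,
                   "J": PENALTY_J, "nfev": 0, "success": False,
                   "error": str(err)}
        records.append(rec)
        if rec["theta_free"] is not None and (best is None or rec["J"] < best["J"]):
            best = rec
    if best is None or best["J"] >= PENALTY_J:
        raise RuntimeError(f"all {len(starts)} starts failed; per-start log: {records}")
    theta_best = problem.theta_from_free(best["theta_free"])
    return FitResult(theta=theta_best, J=best["J"],
                     J_per_datum=best["J"] / max(n_data, 1),
                     free_names=problem.free_names, starts=records,
                     label=problem.label)


@dataclass(frozen=True)
class RoundPreset:
    """Named template for one historical calibration round."""

    label: str
    free_names: tuple[str, ...]

    def problem(self, dataset: TimeCourseDataset,
                theta_nominal: ParameterSet | None = None,
                **kwargs) -> FitProblem:
        from .parameters import load_fixture
        theta = theta_nominal or load_fixture("original")
        return FitProblem(dataset=dataset, free_names=self.free_names,
                          theta_nominal=theta, label=self.label, **kwargs)


def round_presets(name: str) -> RoundPreset:
    """The free-parameter template of round1, round2 or round3."""
    if name not in ROUND_FREE_PARAMETERS:
        raise KeyError(f"unknown round preset {name!r}; "
                       f"choose from {sorted(ROUND_FREE_PARAMETERS)}")
    return RoundPreset(label=name, free_names=ROUND_FREE_PARAMETERS[name])
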