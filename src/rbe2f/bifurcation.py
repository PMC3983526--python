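"""Equilibrium continuation and bistability analysis.

The switch's defining behaviour is a saddle-node (fold) pair in the
stimulus ``S``: over a window ``[S_lo, S_hi]`` a low-E2F and a high-E2F
stable equilibrium coexist, separated by an unstable one, and the width
of the window is the hysteresis of the restriction point.

The workhorse is a pseudo-arclength continuation on the augmented
unknown ``u = (x, S)``: a predictor step along the branch tangent
followed by a Newton corrector in the hyperplane orthogonal to the
tangent. Arclength parametrization lets the tracer round fold points
where natural-parameter stepping in ``S`` breaks down. Folds are
located by a sign change of the tangent's ``S``-component and refined
by bisection along the branch. A brute-force multi-start root-finding
sweep over a coarse ``S`` grid optionally backs the tracer so that
disconnected branches are not missed.

The continuation core is generic over ``f(x, s)`` callbacks; thin
wrappers bind it to the Rb-E2F model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import _as_param_array, _jac_arr, _rhs_arr, find_equilibria, quiescent_state
from .parameters import ParameterSet, resolve_name

__all__ = [
    "Branch",
    "FoldPoint",
    "BistabilityRegion",
    "trace_branch",
    "continue_branch",
    "detect_folds",
    "hysteresis_width",
    "equilibria_at",
    "two_param_region",
    "classify_parameter_set",
    "BISTABLE",
    "NOT_BISTABLE",
]

BISTABLE = "bistable_with_hysteresis"
NOT_BISTABLE = "monostable_or_transcritical"

#: stability is decided on the sign of the leading eigenvalue real part
#: at this tolerance
_EIG_TOL = 1e-8


@dataclass
class Branch:
    """One continuously traced equilibrium branch."""

    s: np.ndarray                 # parameter value at each point
    states: np.ndarray            # (n_points, n_states)
    stable: np.ndarray            # bool per point
    leading_eig: np.ndarray       # real part of leading eigenvalue
    ds_initial: float = 0.0
    stalled: bool = False

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class FoldPoint:
    """A saddle-node: the branch's S-coordinate reverses direction."""

    s: float
    state: np.ndarray
    branch_index: int = 0


@dataclass
class BistabilityRegion:
    """Fold count and bistable S-window along a secondary parameter."""

    param: str
    values: np.ndarray
    fold_counts: np.ndarray            # -1 marks a failed grid point
    windows: list                      # (S_lo, S_hi) or None per value

    def bistable_values(self) -> np.ndarray:
        return self.values[self.fold_counts == 2]


# ----------------------------------------------------------------------
# generic pseudo-arclength core
# ----------------------------------------------------------------------

def _f_s(f: Callable, x: np.ndarray, s: float) -> np.ndarray:
    h = 1e-6 * max(1.0, abs(s))
    return (f(x, s + h) - f(x, s - h)) / (2 * h)


def _tangent(f, jac, x, s, prev: np.ndarray | None) -> np.ndarray:
    """Unit tangent of the branch at (x, s), oriented along ``prev``."""
    n = len(x)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = jac(x, s)
    A[:n, n] = _f_s(f, x, s)
    if prev is None:
        prev = np.zeros(n + 1)
        prev[n] = 1.0
    A[n] = prev
    b = np.zeros(n + 1)
    b[n] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, b, rcond=None)[0]
    nrm = np.linalg.norm(t)
    if nrm == 0 or not np.all(np.isfinite(t)):
        raise RuntimeError("tangent computation failed")
    t /= nrm
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _correct(f, jac, u_pred: np.ndarray, normal: np.ndarray,
             anchor: np.ndarray, tol: float = 1e-10,
             max_iter: int = 15) -> np.ndarray | None:
    """Newton iteration for f(x,s)=0 on the plane normal·(u-anchor)=0."""
    n = len(u_pred) - 1
    u = u_pred.copy()
    for _ in range(max_iter):
        x, s = u[:n], u[n]
        fx = f(x, s)
        g = np.dot(normal, u - anchor)
        if not np.all(np.isfinite(fx)):
            return None
        if np.max(np.abs(fx)) < tol and abs(g) < tol:
            return u
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = jac(x, s)
        A[:n, n] = _f_s(f, x, s)
        A[n] = normal
        try:
            du = np.linalg.solve(A, -np.concatenate([fx, [g]]))
        except np.linalg.LinAlgError:
            return None
        u = u + du
        if not np.all(np.isfinite(u)) or np.linalg.norm(u) > 1e9:
            return None
    return None


def _leading_eig(jac, x, s) -> float:
    return float(np.max(np.linalg.eigvals(jac(x, s)).real))


def trace_branch(f: Callable, jac: Callable, x0: np.ndarray, s0: float,
                 s_range: tuple[float, float], direction: float = +1.0,
                 ds0: float = 1e-3, ds_max: float = 0.02, ds_min: float = 1e-9,
                 max_steps: int = 20000, eq_tol: float = 1e-8) -> Branch:
    """Trace one equilibrium branch of ``f(x, s) = 0`` by pseudo-arclength.

    ``x0`` must satisfy ``f(x0, s0) = 0`` within ``eq_tol``. The trace
    stops when ``s`` leaves ``s_range`` (with a small margin), when the
    state norm blows up, or when the step size underflows (the branch is
    then returned with ``stalled=True``).
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    s_lo, s_hi = s_range
    margin = 1e-6 + 5e-3 * (s_hi - s_lo)

    if np.max(np.abs(f(x0, s0))) > eq_tol:
        raise ValueError("seed state is not an equilibrium at the start of the range")

    pts_s, pts_x = [s0], [x0.copy()]
    u = np.concatenate([x0, [s0]])
    t = _tangent(f, jac, x0, s0, None)
    if t[n] * direction < 0:
        t = -t
    ds = ds0
    stalled = False
    for _ in range(max_steps):
        stepped = False
        while ds >= ds_min:
            u_pred = u + ds * t
            u_new = _correct(f, jac, u_pred, t, u_pred)
            if u_new is not None:
                stepped = True
                break
            ds /= 2
        if not stepped:
            stalled = True
            break
        try:
            t_new = _tangent(f, jac, u_new[:n], u_new[n], t)
        except RuntimeError:
            stalled = True
            break
        u, t = u_new, t_new
        pts_s.append(float(u[n]))
        pts_x.append(u[:n].copy())
        if u[n] > s_hi + margin or u[n] < s_lo - margin:
            break
        if np.linalg.norm(u[:n]) > 1e6:
            stalled = True
            break
        ds = min(ds * 1.3, ds_max)
    else:
        stalled = True

    s_arr = np.array(pts_s)
    x_arr = np.array(pts_x)
    eigs = np.array([_leading_eig(jac, x, s) for x, s in zip(x_arr, s_arr)])
    return Branch(s=s_arr, states=x_arr, stable=eigs < _EIG_TOL,
                  leading_eig=eigs, ds_initial=ds0, stalled=stalled)


def detect_folds(branches: Sequence[Branch], f: Callable = None,
                 jac: Callable = None, s_range: tuple[float, float] | None = None,
                 tol_s: float = 1e-5) -> list[FoldPoint]:
    """Locate saddle-nodes on traced branches.

    A fold is bracketed wherever the sign of ``dS`` between consecutive
    branch points reverses, then refined by bisection along the branch
    secant (Newton-corrected back onto the branch at every probe) until
    the bracket's S-extent is below ``tol_s``. Without ``f``/``jac``
    callbacks the bracket midpoint is returned unrefined.
    """
    folds: list[FoldPoint] = []
    for bi, br in enumerate(branches):
        if len(br) < 3:
            continue
        ds = np.diff(br.s)
        for i in range(len(ds) - 1):
            if ds[i] == 0 or ds[i + 1] == 0:
                continue
            if np.sign(ds[i]) != np.sign(ds[i + 1]):
                # fold between points i and i+2; refine on that arc
                u_a = np.concatenate([br.states[i], [br.s[i]]])
                u_b = np.concatenate([br.states[i + 2], [br.s[i + 2]]])
                if f is not None and jac is not None:
                    fold = _bisect_fold(f, jac, u_a, u_b, tol_s)
                else:
                    fold = np.concatenate([br.states[i + 1], [br.s[i + 1]]])
                s_f = float(fold[-1])
                if s_range is not None and not (s_range[0] <= s_f <= s_range[1]):
                    continue
                if any(abs(s_f - fp.s) < 10 * tol_s
                       and np.linalg.norm(fold[:-1] - fp.state)
                       < 1e-3 * (1 + np.linalg.norm(fp.state))
                       for fp in folds):
                    continue
                folds.append(FoldPoint(s=s_f, state=fold[:-1], branch_index=bi))
    folds.sort(key=lambda fp: fp.s)
    return folds


def _branch_point_at(f, jac, u_a, u_b, lam):
    """Newton-correct the convex combination of two branch points."""
    d = u_b - u_a
    nd = np.linalg.norm(d)
    if nd == 0:
        return u_a, d
    d = d / nd
    u_pred = u_a + lam * (u_b - u_a)
    u = _correct(f, jac, u_pred, d, u_pred)
    return u, d


def _bisect_fold(f, jac, u_a, u_b, tol_s) -> np.ndarray:
    """Bisect the tangent S-component sign change between two points."""
    n = len(u_a) - 1

    def tangent_s(lam):
        u, d = _branch_point_at(f, jac, u_a, u_b, lam)
        if u is None:
            return None, None
        t = _tangent(f, jac, u[:n], u[n], d)
        return t[n], u

    lo, hi = 0.0, 1.0
    sign_lo, u_lo = tangent_s(lo)
    sign_hi, u_hi = tangent_s(hi)
    if sign_lo is None or sign_hi is None or sign_lo * sign_hi > 0:
        # degenerate bracket; fall back to midpoint
        u_mid, _ = _branch_point_at(f, jac, u_a, u_b, 0.5)
        return u_mid if u_mid is not None else 0.5 * (u_a + u_b)
    best = u_lo if abs(sign_lo) < abs(sign_hi) else u_hi
    for _ in range(60):
        if abs(u_hi[n] - u_lo[n]) < tol_s and abs(hi - lo) < 1e-3:
            break
        mid = 0.5 * (lo + hi)
        sign_mid, u_mid = tangent_s(mid)
        if sign_mid is None:
            break
        best = u_mid
        if sign_mid * sign_lo <= 0:
            hi, u_hi, sign_hi = mid, u_mid, sign_mid
        else:
            lo, u_lo, sign_lo = mid, u_mid, sign_mid
    return best


def hysteresis_width(folds: Sequence[FoldPoint]) -> float:
    """Width of the bistable S-window: S-distance between the two folds.

    Returns 0 for fewer than two folds; with more than two (anomalous
    for this system) the outermost window is returned with a warning.
    """
    if len(folds) < 2:
        return 0.0
    if len(folds) > 2:
        warnings.warn(f"{len(folds)} folds found; reporting the outermost S-window")
    s_vals = [fp.s for fp in folds]
    return float(max(s_vals) - min(s_vals))


def equilibria_at(branches: Sequence[Branch], f: Callable, jac: Callable,
                  s: float, tol: float = 1e-10) -> list[np.ndarray]:
    """All branch crossings at a fixed parameter value ``s``.

    Brackets are found by scanning consecutive branch points, then the
    state is Newton-corrected at fixed ``s``. Nearby duplicates are
    merged.
    """
    out: list[np.ndarray] = []
    for br in branches:
        for i in range(len(br) - 1):
            s0, s1 = br.s[i], br.s[i + 1]
            if not (min(s0, s1) - 1e-12 <= s <= max(s0, s1) + 1e-12):
                continue
            w = 0.5 if s1 == s0 else (s - s0) / (s1 - s0)
            x = (1 - w) * br.states[i] + w * br.states[i + 1]
            for _ in range(30):
                fx = f(x, s)
                if np.max(np.abs(fx)) < tol:
                    break
                try:
                    x = x + np.linalg.solve(jac(x, s), -fx)
                except np.linalg.LinAlgError:
                    break
            else:
                continue
            if np.max(np.abs(f(x, s))) > 1e-8:
                continue
            if not any(np.max(np.abs(x - y) / (1 + np.abs(y))) < 1e-5 for y in out):
                out.append(x)
    return out


# ----------------------------------------------------------------------
# model-specific wrappers
# ----------------------------------------------------------------------

def _model_callbacks(theta):
    p = _as_param_array(theta)
    return (lambda x, s: _rhs_arr(x, p, s),
            lambda x, s: _jac_arr(x, p, s))


def continue_branch(theta, s_range: tuple[float, float] = (0.0, 2.5),
                    seed_state: np.ndarray | None = None,
                    brute_force: bool = True, sweep_points: int = 9,
                    sweep_starts: int = 40, seed: int = 0,
                    **trace_kw) -> list[Branch]:
    """Trace the model's equilibrium branches over a stimulus range.

    Starts from ``seed_state`` (default: the quiescent state at the low
    end of the range) and, when ``brute_force`` is set, backs the trace
    with a multi-start root-finding sweep on a coarse S grid so that
    equilibria disconnected from the seeded branch get their own trace.
    """
    f, jac = _model_callbacks(theta)
    s_lo, s_hi = s_range
    if seed_state is None:
        if s_lo == 0.0:
            seed_state = quiescent_state(theta, seed=seed)
        else:
            eqs = find_equilibria(theta, s_lo, seed=seed)
            stable = [e for e in eqs if e["stable"]]
            if not stable:
                raise RuntimeError(f"no stable equilibrium at S={s_lo}")
            seed_state = stable[0]["state"]

    branches = [trace_branch(f, jac, seed_state, s_lo, s_range, +1.0, **trace_kw)]

    if brute_force:
        prev = None
        for s in np.linspace(s_lo, s_hi, sweep_points):
            extra = [] if prev is None else [e["state"] for e in prev]
            eqs = find_equilibria(theta, s, n_starts=sweep_starts, seed=seed,
                                  extra_starts=extra)
            prev = eqs
            known = equilibria_at(branches, f, jac, s)
            for e in eqs:
                x = e["state"]
                if any(np.max(np.abs(x - y) / (1 + np.abs(y))) < 1e-5
                       for y in known):
                    continue
                for direction in (+1.0, -1.0):
                    br = trace_branch(f, jac, x, s, s_range, direction, **trace_kw)
                    if len(br) > 1:
                        branches.append(br)
    return branches


def model_folds(theta, s_range: tuple[float, float] = (0.0, 2.5),
                brute_force: bool = True, seed: int = 0,
                **kw) -> tuple[list[Branch], list[FoldPoint]]:
    """Branches plus refined fold points for one parameter set."""
    f, jac = _model_callbacks(theta)
    branches = continue_branch(theta, s_range, brute_force=brute_force,
                               seed=seed, **kw)
    folds = detect_folds(branches, f, jac, s_range=s_range)
    return branches, folds


def classify_parameter_set(theta, s_range: tuple[float, float] = (0.0, 2.5),
                           min_width: float = 1e-4, brute_force: bool = True,
                           seed: int = 0) -> str:
    """Bistable-with-hysteresis vs not, from the fold count in S.

    A set is called bistable when the continuation finds exactly two
    saddle-nodes in the scanned stimulus range separated by more than
    ``min_width``; everything else (monostable or transcritical
    behaviour) is lumped into the second class.
    """
    _, folds = model_folds(theta, s_range, brute_force=brute_force, seed=seed)
    if len(folds) == 2 and hysteresis_width(folds) > min_width:
        return BISTABLE
    return NOT_BISTABLE


def bistable_upper_limit(theta, param_name: str, lo: float, hi: float,
                         step: float = 1.0,
                         s_range: tuple[float, float] = (0.0, 2.5),
                         coarse: int = 64, seed: int = 0) -> tuple[float, int]:
    """Largest grid value of one parameter that still classifies bistable.

    Scans the grid ``lo, lo+step, ..., hi`` (all other parameters fixed
    at ``theta``): a coarse pass locates the last bistable-to-not
    transition, which is then refined to neighbouring grid points by
    bisection. Returns the largest bistable grid value and the number
    of continuation runs spent. Assumes a single transition inside the
    bracket, which the coarse pass verifies on its grid.
    """
    theta = theta if isinstance(theta, ParameterSet) else ParameterSet.from_array(theta)
    pname = resolve_name(param_name)
    grid = np.arange(lo, hi + 0.5 * step, step)
    n_eval = 0

    def is_bistable(value: float) -> bool:
        nonlocal n_eval
        n_eval += 1
        th = theta.replace(**{pname: float(value)})
        return classify_parameter_set(th, s_range, brute_force=False,
                                      seed=seed) == BISTABLE

    coarse_idx = list(range(0, len(grid), coarse))
    if coarse_idx[-1] != len(grid) - 1:
        coarse_idx.append(len(grid) - 1)
    flags = [is_bistable(grid[i]) for i in coarse_idx]
    if not any(flags):
        raise RuntimeError(f"no bistable {pname} value on the coarse grid")
    last_true = max(k for k, fl in enumerate(flags) if fl)
    if last_true == len(coarse_idx) - 1:
        warnings.warn(f"{pname} still bistable at the top of the scanned grid")
        return float(grid[coarse_idx[-1]]), n_eval
    i_lo, i_hi = coarse_idx[last_true], coarse_idx[last_true + 1]
    while i_hi - i_lo > 1:
        mid = (i_lo + i_hi) // 2
        if is_bistable(grid[mid]):
            i_lo = mid
        else:
            i_hi = mid
    return float(grid[i_lo]), n_eval


def two_param_region(theta, param_name: str,
                     scale_range: tuple[float, float] = (0.1, 10.0),
                     s_range: tuple[float, float] = (0.0, 2.5),
                     n_grid: int = 61, brute_force: bool = False,
                     values: np.ndarray | None = None,
                     seed: int = 0) -> BistabilityRegion:
    """Map the bistable region over one secondary parameter.

    The parameter is scanned on a log grid spanning ``scale_range``
    times its nominal value (or on explicit ``values``); at each grid
    point the S-continuation is re-run and the fold count and bistable
    S-window are recorded. Failed grid points are marked with count -1.
    """
    theta = theta if isinstance(theta, ParameterSet) else ParameterSet.from_array(theta)
    pname = resolve_name(param_name)
    if values is None:
        nominal = theta[pname]
        values = nominal * np.logspace(np.log10(scale_range[0]),
                                       np.log10(scale_range[1]), n_grid)
    values = np.asarray(values, dtype=float)
    counts = np.empty(len(values), dtype=int)
    windows: list = []
    for i, v in enumerate(values):
        try:
            th = theta.replace(**{pname: float(v)})
            _, folds = model_folds(th, s_range, brute_force=brute_force, seed=seed)
            counts[i] = len(folds)
            if len(folds) >= 2:
                s_vals = [fp.s for fp in folds]
                windows.append((float(min(s_vals)), float(max(s_vals))))
            else:
                windows.append(None)
        except Exception as err:  # failed grid point: mark and move on
            warnings.warn(f"{pname}={v:g}: continuation failed ({err})")
            counts[i] = -1
            windows.append(None)
    anomalies = np.sum((counts != 0) & (counts != 2) & (counts != -1))
    if anomalies:
        warnings.warn(f"{int(anomalies)} grid points with fold count outside {{0, 2}}")
    return BistabilityRegion(param=pname, values=values, fold_counts=counts,
                             windows=windows)
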