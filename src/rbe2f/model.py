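"""The seven-ODE Rb-E2F restriction-point switch.

State variables (concentrations, model-native units):

====  =======================================================
MC    c-Myc
E     free (active) E2F
CD    cyclin D / CDK4-6 activity
CE    cyclin E / CDK2 activity
R     hypo-phosphorylated (active) Rb
RP    hyper-phosphorylated (inactive) Rb
RE    Rb-E2F repressive complex
====  =======================================================

Growth-factor stimulation enters through a single non-negative scalar
``S`` held constant during a run. Myc and cyclin D synthesis respond to
S through Michaelis-Menten terms; Myc drives E2F and cyclin D; E2F
drives its own synthesis and cyclin E; cyclins D and E phosphorylate Rb
both free and in the Rb-E2F complex (releasing E2F); a phosphatase term
recycles phosphorylated Rb. The positive feedback through E2F
autoactivation plus the double-negative feedback through Rb sequestration
make the system bistable in S for suitable kinetic constants.

Time and concentration are treated as model-native dimensionless units
throughout: the published time-course figures label axes in minutes and
nM, but the rate constants are not consistent with those units and no
conversion is ever stated, so none is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import CANONICAL_NAMES, ParameterSet

__all__ = [
    "STATE_NAMES",
    "IntegrationError",
    "Trajectory",
    "ObservableMap",
    "rhs",
    "jacobian",
    "simulate",
    "quiescent_state",
    "find_equilibria",
    "observe",
]

STATE_NAMES: tuple[str, ...] = ("MC", "E", "CD", "CE", "R", "RP", "RE")
N_STATES = len(STATE_NAMES)

_P_IDX = {name: i for i, name in enumerate(CANONICAL_NAMES)}


class IntegrationError(RuntimeError):
    """ODE integration failed (stiff blow-up or solver breakdown)."""


def _as_param_array(theta) -> np.ndarray:
    if isinstance(theta, ParameterSet):
        return theta.as_array()
    arr = np.asarray(theta, dtype=float)
    if arr.shape != (len(CANONICAL_NAMES),):
        raise ValueError("theta must be a ParameterSet or a 24-vector in canonical order")
    return arr


def _check_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"state must have length {N_STATES}")
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state vector")
    return x


def rhs(state, theta, S: float) -> np.ndarray:
    """Time derivatives of the 7 species at one state.

    Parameters
    ----------
    state
        Length-7 vector in ``STATE_NAMES`` order.
    theta
        :class:`~rbe2f.parameters.ParameterSet` (or 24-vector in
        canonical order).
    S
        Constant growth-factor stimulus, ``S >= 0``.
    """
    x = _check_state(state)
    p = _as_param_array(theta)
    if not np.isfinite(S) or S < 0:
        raise ValueError(f"stimulus must be finite and non-negative, got {S}")
    return _rhs_arr(x, p, float(S))


def _rhs_arr(x: np.ndarray, p: np.ndarray, S: float) -> np.ndarray:
    """Unchecked fast core of :func:`rhs` on raw arrays."""
    MC, E, CD, CE, R, RP, RE = x
    (dMC, dE, dCD, dCE, dR, dRE, dRP,
     kP1, kP2, kDP,
     kRE, kkE, kkM, kkCD, kkCE, kCDS, kR, kb,
     KM, KCD, KRP, KS, KE, KCE) = p

    fS = S / (KS + S)
    fM = MC / (KM + MC)
    fE = E / (KE + E)
    # cyclin-dependent Rb phosphorylation, free Rb and Rb in complex
    phos_R = kP1 * CD * R / (KCD + R) + kP2 * CE * R / (KCE + R)
    phos_RE = kP1 * CD * RE / (KCD + RE) + kP2 * CE * RE / (KCE + RE)
    dephos = kDP * RP / (KRP + RP)

    return np.array([
        kkM * fS - dMC * MC,
        kkE * fM * fE + kb * fM + phos_RE - dE * E - kRE * R * E,
        kkCD * fM + kCDS * fS - dCD * CD,
        kkCE * fE - dCE * CE,
        kR + dephos - kRE * R * E - phos_R - dR * R,
        phos_R + phos_RE - dephos - dRP * RP,
        kRE * R * E - phos_RE - dRE * RE,
    ])


def jacobian(state, theta, S: float, method: str = "analytic",
             rel_step: float = 1e-7) -> np.ndarray:
    """7x7 Jacobian of :func:`rhs` with respect to the state.

    ``method='analytic'`` uses closed-form derivatives;
    ``method='fd'`` uses central finite differences (kept as an
    independent cross-check of the hand-derived expressions).
    """
    x = _check_state(state)
    p = _as_param_array(theta)
    S = float(S)
    if method == "analytic":
        return _jac_arr(x, p, S)
    if method == "fd":
        J = np.empty((N_STATES, N_STATES))
        for i in range(N_STATES):
            h = rel_step * max(1.0, abs(x[i]))
            e = np.zeros(N_STATES)
            e[i] = h
            J[:, i] = (_rhs_arr(x + e, p, S) - _rhs_arr(x - e, p, S)) / (2 * h)
        return J
    raise ValueError(f"unknown jacobian method {method!r}")


def _jac_arr(x: np.ndarray, p: np.ndarray, S: float) -> np.ndarray:
    MC, E, CD, CE, R, RP, RE = x
    (dMC, dE, dCD, dCE, dR, dRE, dRP,
     kP1, kP2, kDP,
     kRE, kkE, kkM, kkCD, kkCE, kCDS, kR, kb,
     KM, KCD, KRP, KS, KE, KCE) = p

    fM = MC / (KM + MC)
    fE = E / (KE + E)
    dfM = KM / (KM + MC) ** 2
    dfE = KE / (KE + E) ** 2

    # phosphorylation of free Rb: g(CD, CE, R)
    g_R = kP1 * CD * KCD / (KCD + R) ** 2 + kP2 * CE * KCE / (KCE + R) ** 2
    g_CD = kP1 * R / (KCD + R)
    g_CE = kP2 * R / (KCE + R)
    # phosphorylation of complexed Rb: h(CD, CE, RE)
    h_RE = kP1 * CD * KCD / (KCD + RE) ** 2 + kP2 * CE * KCE / (KCE + RE) ** 2
    h_CD = kP1 * RE / (KCD + RE)
    h_CE = kP2 * RE / (KCE + RE)
    dephos_RP = kDP * KRP / (KRP + RP) ** 2

    J = np.zeros((N_STATES, N_STATES))
    # MC
    J[0, 0] = -dMC
    # E
    J[1, 0] = (kkE * fE + kb) * dfM
    J[1, 1] = kkE * fM * dfE - dE - kRE * R
    J[1, 2] = h_CD
    J[1, 3] = h_CE
    J[1, 4] = -kRE * E
    J[1, 6] = h_RE
    # CD
    J[2, 0] = kkCD * dfM
    J[2, 2] = -dCD
    # CE
    J[3, 1] = kkCE * dfE
    J[3, 3] = -dCE
    # R
    J[4, 1] = -kRE * R
    J[4, 2] = -g_CD
    J[4, 3] = -g_CE
    J[4, 4] = -kRE * E - g_R - dR
    J[4, 5] = dephos_RP
    # RP
    J[5, 2] = g_CD + h_CD
    J[5, 3] = g_CE + h_CE
    J[5, 4] = g_R
    J[5, 5] = -dephos_RP - dRP
    J[5, 6] = h_RE
    # RE
    J[6, 1] = kRE * R
    J[6, 2] = -h_CD
    J[6, 3] = -h_CE
    J[6, 4] = kRE * E
    J[6, 6] = -h_RE - dRE
    return J


@dataclass
class Trajectory:
    """Simulated time course: a time grid and one state row per time."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 7)
    theta: ParameterSet | None = None
    S: float = 0.0
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0) and len(self.t) > 1:
            raise ValueError("time grid must be 1-D and strictly increasing")
        if self.y.shape != (len(self.t), N_STATES):
            raise ValueError("state matrix shape must be (n_times, 7)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time", self.t)
        return df

    def to_csv(self, path, observables: "ObservableMap | None" = None) -> None:
        df = self.to_frame()
        if observables is not None:
            obs = observe(self, observables)
            for col in obs.columns.drop("time"):
                df[col] = obs[col].to_numpy()
        df.to_csv(path, index=False)


def simulate(theta, init, S: float, tgrid, rtol: float = 1e-8,
             atol: float = 1e-10, method: str = "LSODA") -> Trajectory:
    """Integrate the switch from ``init`` under constant stimulus ``S``.

    The default integrator is stiff-capable (LSODA with the analytic
    Jacobian); tolerances follow the package defaults ``rtol=1e-8``,
    ``atol=1e-10``. Raises :class:`IntegrationError` on solver failure
    rather than returning silent NaNs.
    """
    x0 = _check_state(init)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    p = _as_param_array(theta)
    S = float(S)
    t = np.asarray(tgrid, dtype=float)
    if t.ndim != 1 or len(t) < 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("tgrid must be 1-D, non-empty and strictly increasing")
    theta_obj = theta if isinstance(theta, ParameterSet) else ParameterSet.from_array(p)
    if len(t) == 1:
        return Trajectory(t, x0[None, :], theta=theta_obj, S=S)

    sol = solve_ivp(
        lambda _t, x: _rhs_arr(x, p, S),
        (t[0], t[-1]), x0, method=method, t_eval=t,
        jac=lambda _t, x: _jac_arr(x, p, S),
        rtol=rtol, atol=atol,
    )
    if not sol.success or sol.y.shape[1] != len(t) or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"integration failed: {sol.message}")
    y = sol.y.T.copy()
    y[0] = x0  # the solver's interpolant need not return t0 bit-exactly
    return Trajectory(t, y, theta=theta_obj, S=S)


def find_equilibria(theta, S: float, n_starts: int = 50, seed: int = 0,
                    log_range: tuple[float, float] = (-4.0, 3.0),
                    tol: float = 1e-10, merge_tol: float = 1e-6,
                    extra_starts: Sequence[np.ndarray] = ()) -> list[dict]:
    """Multi-start root finding on the right-hand side.

    Starts are log-uniform over ``10**log_range`` per species (the
    model's attractors span several orders of magnitude), plus any
    caller-supplied states. Duplicate roots are merged on relative
    distance; each root is classified stable/unstable from the leading
    eigenvalue of the analytic Jacobian.

    Returns a list of dicts with keys ``state``, ``stable``,
    ``leading_eig`` sorted by the E2F coordinate.
    """
    p = _as_param_array(theta)
    S = float(S)
    rng = np.random.default_rng(seed)
    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    starts += list(10.0 ** rng.uniform(log_range[0], log_range[1],
                                       size=(n_starts, N_STATES)))
    roots: list[dict] = []
    for x0 in starts:
        with np.errstate(divide="ignore", invalid="ignore"):
            sol = root(lambda x: _rhs_arr(x, p, S), x0, method="hybr",
                       jac=lambda x: _jac_arr(x, p, S))
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1e-8) or np.max(np.abs(_rhs_arr(x, p, S))) > tol:
            continue
        x = np.clip(x, 0.0, None)
        if any(np.max(np.abs(x - r["state"]) / (1.0 + np.abs(r["state"]))) < merge_tol
               for r in roots):
            continue
        lead = np.max(np.linalg.eigvals(_jac_arr(x, p, S)).real)
        roots.append({"state": x, "stable": bool(lead < 0), "leading_eig": float(lead)})
    roots.sort(key=lambda r: r["state"][1])
    return roots


def quiescent_state(theta, n_starts: int = 50, seed: int = 0) -> np.ndarray:
    """The stable equilibrium with lowest E2F at zero stimulus.

    This is the serum-starved resting state and the package's default
    initial condition. Long-horizon relaxation from the empty state is
    tried first (robust, since the quiescent state is attracting from
    low concentrations), followed by a Newton polish; a multistart root
    search is the fallback.
    """
    p = _as_param_array(theta)
    candidates: list[np.ndarray] = []
    try:
        traj = simulate(theta, np.zeros(N_STATES), 0.0,
                        np.array([0.0, 2000.0]), rtol=1e-10, atol=1e-12)
        sol = root(lambda x: _rhs_arr(x, p, 0.0), traj.y[-1], method="hybr",
                   jac=lambda x: _jac_arr(x, p, 0.0))
        x = np.clip(sol.x, 0.0, None)
        if (sol.success and np.min(sol.x) > -1e-8
                and np.max(np.abs(_rhs_arr(x, p, 0.0))) < 1e-9
                and np.max(np.linalg.eigvals(_jac_arr(x, p, 0.0)).real) < 0):
            candidates.append(x)
    except IntegrationError:
        pass
    if not candidates:
        candidates = [r["state"] for r in
                      find_equilibria(theta, 0.0, n_starts=n_starts, seed=seed)
                      if r["stable"]]
    if not candidates:
        raise RuntimeError("no stable equilibrium found at S=0")
    return min(candidates, key=lambda x: x[1])


class ObservableMap:
    """Named non-negative linear combinations of the state variables.

    The default map exposes the three fitted observables — ``CycD``
    (cyclin D), ``CycE`` (cyclin E) and ``RbTotal`` (hypo- plus
    hyper-phosphorylated Rb) — together with the two Rb phospho-forms.
    ``include_complex_in_total=True`` adds the Rb sequestered in the
    Rb-E2F complex (itself hypo-phosphorylated) to ``RbTotal``.
    """

    #: the observables the calibration fits by default
    FITTED = ("CycD", "CycE", "RbTotal")

    def __init__(self, combos: Mapping[str, Mapping[str, float]]):
        self.combos: dict[str, dict[str, float]] = {}
        for obs, combo in combos.items():
            clean: dict[str, float] = {}
            for state, coef in combo.items():
                if state not in STATE_NAMES:
                    raise KeyError(f"observable {obs!r} references unknown state {state!r}")
                coef = float(coef)
                if coef < 0:
                    raise ValueError(f"observable {obs!r}: negative coefficient for {state}")
                clean[state] = coef
            self.combos[obs] = clean

    @classmethod
    def default(cls, include_complex_in_total: bool = False) -> "ObservableMap":
        total = {"R": 1.0, "RP": 1.0}
        if include_complex_in_total:
            total["RE"] = 1.0
        return cls({
            "CycD": {"CD": 1.0},
            "CycE": {"CE": 1.0},
            "RbTotal": total,
            "RbPhospho": {"RP": 1.0},
            "RbHypo": {"R": 1.0},
        })

    def names(self) -> list[str]:
        return list(self.combos)

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Coefficient matrix (n_observables x 7) for the given names."""
        names = list(self.combos) if names is None else list(names)
        M = np.zeros((len(names), N_STATES))
        for i, obs in enumerate(names):
            if obs not in self.combos:
                raise KeyError(f"unknown observable {obs!r}")
            for state, coef in self.combos[obs].items():
                M[i, STATE_NAMES.index(state)] = coef
        return M


def observe(traj: Trajectory, obs_map: ObservableMap,
            names: Sequence[str] | None = None) -> pd.DataFrame:
    """Apply an observable map to a trajectory, returning tidy columns."""
    names = obs_map.names() if names is None else list(names)
    M = obs_map.matrix(names)
    out = pd.DataFrame(traj.y @ M.T, columns=names)
    out.insert(0, "time", traj.t)
    return out
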