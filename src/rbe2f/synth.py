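"""Synthetic sparse time-course data for calibration studies.

The calibration assumes sparse measurements of a few observables with
additive homoscedastic Gaussian noise of known constant variance. This
module produces datasets with exactly that structure from a known
ground-truth parameter set, so that parameter recovery can be measured.
A generated dataset emulates densitometry-style protein time courses:
by default the three fitted observables (cyclin D, cyclin E, total Rb)
at 10 equispaced times, with per-observable noise SD equal to 5% of
that observable's trajectory maximum.

What it deliberately does not emulate: blot saturation, loading
normalization, replicate correlation, or heteroscedastic noise.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ObservableMap, observe, quiescent_state, simulate
from .parameters import ParameterSet

__all__ = ["NoiseModel", "Design", "TimeCourseDataset", "generate"]

_COLUMNS = ["experiment", "observable", "time", "value", "weight"]


@dataclass(frozen=True)
class NoiseModel:
    """Additive homoscedastic Gaussian noise with known constant SD.

    ``sigma`` is either one SD for every observable, a per-observable
    mapping, or ``None``, in which case the SD is ``sigma_rel`` times
    each observable's noiseless trajectory maximum (default 5%). Draws
    pushing a concentration below zero are clipped to zero (which
    slightly biases low-signal points).
    """

    sigma: float | Mapping[str, float] | None = None
    seed: int = 0
    kind: str = "homoscedastic"
    sigma_rel: float = 0.05

    def sigma_for(self, observable: str, signal_max: float) -> float:
        if self.sigma is None:
            s = self.sigma_rel * signal_max
        elif isinstance(self.sigma, Mapping):
            s = float(self.sigma[observable])
        else:
            s = float(self.sigma)
        if s < 0:
            raise ValueError("sigma must be non-negative")
        return s


@dataclass(frozen=True)
class Design:
    """Sampling design: which observables, when, under which stimulus."""

    n_times: int = 10
    #: the default stimulus sits above the switching threshold of the
    #: published parameter set (serum-stimulated cells committed to
    #: passing the restriction point) and the window covers the smooth
    #: early-G1 transient; the E2F/cyclin-E jump itself occurs much
    #: later (t ~ 200 at S=1.5) because passage through the switch is
    #: slow, so trajectories inside the window vary smoothly with the
    #: kinetic constants — the regime in which least-squares recovery
    #: is well posed
    horizon: float = 30.0
    observables: tuple[str, ...] = ObservableMap.FITTED
    S: float = 1.5
    t_start: float | None = None   # default: horizon / n_times

    def times(self) -> np.ndarray:
        if self.n_times < 2:
            raise ValueError("design needs at least 2 time points")
        t0 = self.horizon / self.n_times if self.t_start is None else self.t_start
        return np.linspace(t0, self.horizon, self.n_times)


class TimeCourseDataset:
    """Measured values and weights per experiment, observable and time.

    Stored as a tidy table with columns ``experiment, observable, time,
    value, weight`` plus a metadata dict (noise SDs, seed, stimulus,
    ground-truth parameters and initial state when synthetic).
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None,
                 known_observables: Sequence[str] | None = None):
        df = df.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        df = df[_COLUMNS].reset_index(drop=True)
        known = set(ObservableMap.default(include_complex_in_total=False).names()
                    if known_observables is None else known_observables)
        bad = set(df["observable"]) - known
        if bad:
            raise ValueError(f"unknown observable name(s): {sorted(bad)}")
        if not np.all(np.isfinite(df["value"])):
            raise ValueError("non-finite measured values")
        if np.any(df["weight"] < 0):
            raise ValueError("weights must be non-negative")
        for (exp, obs), g in df.groupby(["experiment", "observable"]):
            t = g["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing for "
                                 f"experiment {exp}, observable {obs}")
        self.df = df
        self.meta = dict(meta or {})

    # -- accessors -----------------------------------------------------

    @property
    def experiments(self) -> list:
        return sorted(self.df["experiment"].unique())

    def observables(self, experiment=None) -> list[str]:
        df = self.df if experiment is None else self.df[self.df["experiment"] == experiment]
        return sorted(df["observable"].unique())

    def block(self, experiment, observable) -> pd.DataFrame:
        m = (self.df["experiment"] == experiment) & (self.df["observable"] == observable)
        return self.df[m]

    def n_data(self) -> int:
        return len(self.df)

    def theta_true(self) -> ParameterSet | None:
        if "theta_true" in self.meta:
            return ParameterSet(self.meta["theta_true"],
                                provenance=self.meta.get("theta_provenance", "custom"))
        return None

    # -- round-trip ----------------------------------------------------

    def to_csv(self, path) -> None:
        meta = dict(self.meta)
        with open(path, "w") as fh:
            fh.write("# rbe2f time-course dataset\n")
            fh.write("# meta: " + json.dumps(meta, sort_keys=True) + "\n")
            self.df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, known_observables: Sequence[str] | None = None
                 ) -> "TimeCourseDataset":
        meta: dict = {}
        lines = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#"):
                    if line.startswith("# meta:"):
                        meta = json.loads(line[len("# meta:"):])
                    continue
                lines.append(line)
        try:
            df = pd.read_csv(io.StringIO("".join(lines)))
        except Exception as err:
            raise ValueError(f"malformed dataset CSV {path}: {err}") from err
        for col in ("experiment", "observable", "time", "value"):
            if col not in df.columns:
                raise ValueError(f"dataset CSV {path}: missing column {col!r}")
        bad = df.index[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
        if len(bad):
            raise ValueError(f"dataset CSV {path}: non-numeric value at data row "
                             f"{bad[0] + 1}, column 'value'")
        return cls(df, meta=meta, known_observables=known_observables)


def generate(theta_true: ParameterSet, S: float | None = None,
             design: Design | None = None, noise: NoiseModel | None = None,
             init: np.ndarray | None = None, experiment: int = 1,
             obs_map: ObservableMap | None = None) -> TimeCourseDataset:
    """Simulate, observe and corrupt: one synthetic experiment.

    The model is integrated from ``init`` (default: the quiescent state
    of ``theta_true``) under constant stimulus, the designed observables
    are read off at the designed times, and Gaussian noise is added and
    clipped at zero. With ``sigma=0`` the measured values equal the
    noiseless model output exactly.
    """
    design = design or Design()
    if S is not None:
        design = Design(n_times=design.n_times, horizon=design.horizon,
                        observables=design.observables, S=float(S),
                        t_start=design.t_start)
    noise = noise or NoiseModel()
    obs_map = obs_map or ObservableMap.default()
    unknown = set(design.observables) - set(obs_map.names())
    if unknown:
        raise ValueError(f"design names unknown observables: {sorted(unknown)}")

    if init is None:
        init = quiescent_state(theta_true)
    times = design.times()
    tgrid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = simulate(theta_true, init, design.S, tgrid)
    obs = observe(traj, obs_map, names=list(design.observables))
    obs = obs[np.isin(obs["time"], times)]

    rng = np.random.default_rng(noise.seed)
    rows = []
    sigmas = {}
    for name in design.observables:
        y = obs[name].to_numpy()
        s = noise.sigma_for(name, float(np.max(np.abs(y))))
        sigmas[name] = s
        ym = np.clip(y + rng.normal(0.0, s, size=len(y)) if s > 0 else y, 0.0, None)
        for t, v in zip(times, ym):
            rows.append((experiment, name, float(t), float(v), 1.0))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    meta = {
        "seed": noise.seed,
        "sigma": sigmas,
        "S": design.S,
        "theta_true": dict(theta_true.values),
        "theta_provenance": theta_true.provenance,
        "init": [float(v) for v in init],
    }
    return TimeCourseDataset(df, meta=meta)
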