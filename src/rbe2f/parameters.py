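"""Kinetic parameter sets of the Rb-E2F switch model.

The model has 24 strictly positive kinetic constants. Several of them
appear in the literature under more than one spelling (e.g. the Myc
degradation rate is written ``dM``, ``degM`` or ``dMC``); an alias map
resolves every known spelling to one canonical name so that parameter
files from any source merge cleanly.

Four named fixtures ship with the package: ``original`` (the published
values) and ``opt1``/``opt2``/``opt3`` (three successive re-calibration
rounds, each merged over the original values for the parameters that
round held fixed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NAMES",
    "ALIASES",
    "PROVENANCES",
    "ParameterSet",
    "load_fixture",
]

#: Canonical parameter names, in the fixed order used by array views.
CANONICAL_NAMES: tuple[str, ...] = (
    "dMC", "dE", "dCD", "dCE", "dR", "dRE", "dRP",
    "kP1", "kP2", "kDP",
    "kRE", "kkE", "kkM", "kkCD", "kkCE", "kCDS", "kR", "kb",
    "KM", "KCD", "KRP", "KS", "KE", "KCE",
)

#: Alternative spellings found in the literature, mapped to canonical names.
ALIASES: dict[str, str] = {
    "degM": "dMC",
    "dM": "dMC",
    "degE": "dE",
    "degR": "dR",
    "degCE": "dCE",
    "degRP": "dRP",
    "kM": "kkM",
    "kE": "kkE",
    "kCE": "kkCE",
    "kCD": "kkCD",
}

PROVENANCES = ("original", "opt1", "opt2", "opt3", "custom")

_INDEX = {name: i for i, name in enumerate(CANONICAL_NAMES)}


class ParameterError(ValueError):
    """Raised for incomplete, unknown, or non-positive parameters."""


def resolve_name(name: str) -> str:
    """Map any accepted spelling to its canonical parameter name."""
    name = name.strip()
    if name in _INDEX:
        return name
    if name in ALIASES:
        return ALIASES[name]
    raise ParameterError(f"unknown parameter name: {name!r}")


@dataclass(frozen=True)
class ParameterSet:
    """An immutable, complete set of the 24 kinetic constants.

    Parameters
    ----------
    values
        Mapping from parameter name (canonical or aliased) to a strictly
        positive value. Must cover all 24 parameters exactly.
    provenance
        One of ``original``, ``opt1``, ``opt2``, ``opt3``, ``custom``.
    """

    values: Mapping[str, float]
    provenance: str = "custom"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        resolved: dict[str, float] = {}
        for raw, v in self.values.items():
            key = resolve_name(raw)
            if key in resolved:
                raise ParameterError(f"duplicate parameter after alias resolution: {key}")
            v = float(v)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"parameter {key} must be strictly positive, got {v}")
            resolved[key] = v
        missing = set(CANONICAL_NAMES) - resolved.keys()
        if missing:
            raise ParameterError(f"missing parameters: {sorted(missing)}")
        if self.provenance not in PROVENANCES:
            raise ParameterError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "values", dict(sorted(resolved.items(), key=lambda kv: _INDEX[kv[0]])))

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_name(name)]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        """Values as a float array in canonical order."""
        return np.array([self.values[n] for n in CANONICAL_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float], provenance: str = "custom",
                   name: str = "") -> "ParameterSet":
        arr = np.asarray(list(arr), dtype=float)
        if arr.shape != (len(CANONICAL_NAMES),):
            raise ParameterError(f"expected {len(CANONICAL_NAMES)} values, got {arr.shape}")
        return cls(dict(zip(CANONICAL_NAMES, arr)), provenance=provenance, name=name)

    def replace(self, provenance: str = "custom", name: str = "",
                **updates: float) -> "ParameterSet":
        """A copy with some parameters replaced (aliases accepted)."""
        merged = dict(self.values)
        for raw, v in updates.items():
            merged[resolve_name(raw)] = float(v)
        return ParameterSet(merged, provenance=provenance, name=name)

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {"name": self.name, "provenance": self.provenance,
                   "parameters": self.values}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        if "parameters" in payload:
            return cls(payload["parameters"],
                       provenance=payload.get("provenance", "custom"),
                       name=payload.get("name", ""))
        return cls(payload)

    def to_csv(self, path) -> None:
        pd.DataFrame({"name": list(self.values), "value": list(self.values.values())}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "custom") -> "ParameterSet":
        df = pd.read_csv(path)
        if not {"name", "value"} <= set(df.columns):
            raise ParameterError("parameter CSV needs 'name' and 'value' columns")
        return cls(dict(zip(df["name"], df["value"])), provenance=provenance)


def load_fixture(name: str) -> ParameterSet:
    """Load a packaged parameter set: original, opt1, opt2 or opt3."""
    if name not in ("original", "opt1", "opt2", "opt3"):
        raise ParameterError(f"no packaged parameter set named {name!r}")
    ref = resources.files("rbe2f").joinpath("data", f"{name}.json")
    payload = json.loads(ref.read_text())
    return ParameterSet(payload["parameters"], provenance=payload["provenance"],
                        name=payload["name"])
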