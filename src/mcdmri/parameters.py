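"""Parameter registry shared by composite models.

Composite models (distributed models and multi-compartment models) aggregate
the parameters of their sub-models under prefixed names
``<ModelName>_<enumeration>_<parameter>`` (enumeration is 1-based per model
class, so two Sticks become C1Stick_1 / C1Stick_2). Each entry carries its
cardinality, SI unit, optimization bounds and a status: free, fixed(value),
or linked(rule). Supported link rules are the three used in practice:

* equal      — target copies another parameter;
* tortuous   — lambda_perp = (1 - f_intra) * lambda_par;
* scaled     — target = scale * source (invertible optimization rescale).

Link resolution is iterative, so chained equalities resolve transitively;
cycles are rejected at registration time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ParameterEntry", "ParameterRegistry"]


@dataclass
class ParameterEntry:
    cardinality: int
    unit: str
    bounds: Any
    status: str = "free"          # free | fixed | linked
    value: Any = None             # fixed value (scalar, pair, or voxel map)
    link: tuple | None = None     # ('equal', src) | ('tortuous', par, frac)
                                  # | ('scaled', src, factor)


class ParameterRegistry:
    def __init__(self):
        self.entries: dict[str, ParameterEntry] = {}
        self.sub_models: list[tuple[str, Any]] = []  # (prefix, model)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_models(cls, models) -> "ParameterRegistry":
        reg = cls()
        counts: dict[str, int] = {}
        for model in models:
            counts[model.name] = counts.get(model.name, 0) + 1
            prefix = f"{model.name}_{counts[model.name]}"
            reg.sub_models.append((prefix, model))
            for local, (card, unit, bounds) in model._parameters.items():
                reg.entries[f"{prefix}_{local}"] = ParameterEntry(
                    card, unit, bounds)
        return reg

    def add(self, name, cardinality, unit, bounds):
        if name in self.entries:
            raise ValueError(f"duplicate parameter name {name}")
        self.entries[name] = ParameterEntry(cardinality, unit, bounds)

    # -- status manipulation ----------------------------------------------
    def _require(self, name):
        if name not in self.entries:
            raise ValueError(
                f"unknown parameter {name!r}; known: {sorted(self.entries)}")
        return self.entries[name]

    def fix(self, name, value):
        e = self._require(name)
        e.status, e.value = "fixed", value

    def link_equal(self, target, source):
        self._require(source)
        e = self._require(target)
        e.status, e.link = "linked", ("equal", source)
        self._check_acyclic()

    def link_tortuous(self, target_perp, source_par, source_fraction):
        self._require(source_par)
        self._require(source_fraction)
        e = self._require(target_perp)
        e.status, e.link = "linked", ("tortuous", source_par, source_fraction)
        self._check_acyclic()

    def link_scaled(self, target, source, factor):
        self._require(source)
        e = self._require(target)
        e.status, e.link = "linked", ("scaled", source, factor)
        self._check_acyclic()

    def _check_acyclic(self):
        # follow 'equal'/'scaled' chains; tortuous sources must not loop back
        for start in self.entries:
            seen, name = set(), start
            while True:
                e = self.entries[name]
                if e.status != "linked":
                    break
                if name in seen:
                    raise ValueError(f"cyclic parameter link through {name}")
                seen.add(name)
                name = e.link[1]

    # -- queries -----------------------------------------------------------
    @property
    def free_names(self):
        return [n for n, e in self.entries.items() if e.status == "free"]

    @property
    def fixed_values(self):
        return {n: e.value for n, e in self.entries.items()
                if e.status == "fixed"}

    def cardinality(self, name):
        return self._require(name).cardinality

    def bounds(self, name):
        return self._require(name).bounds

    # -- evaluation --------------------------------------------------------
    def resolve(self, values: dict) -> dict:
        """Complete a dict of free-parameter values with fixed and linked
        entries; returns the full flat parameter dict."""
        full = dict(values)
        for n, e in self.entries.items():
            if e.status == "fixed" and n not in full:
                # caller-supplied values take precedence (per-voxel
                # overrides of voxel-wise fixed maps)
                full[n] = e.value
        linked = [(n, e) for n, e in self.entries.items()
                  if e.status == "linked"]
        for _ in range(len(linked) + 1):
            progress = False
            for n, e in linked:
                if n in full:
                    continue
                kind = e.link[0]
                if kind == "equal":
                    if e.link[1] in full:
                        full[n] = full[e.link[1]]
                        progress = True
                elif kind == "scaled":
                    if e.link[1] in full:
                        full[n] = e.link[2] * np.asarray(full[e.link[1]])
                        progress = True
                elif kind == "tortuous":
                    _, par, frac = e.link
                    if par in full and frac in full:
                        full[n] = (1.0 - float(full[frac])) * float(full[par])
                        progress = True
            if not progress:
                break
        missing = set(self.entries) - set(full)
        if missing:
            raise ValueError(f"unresolved parameters: {sorted(missing)}")
        return full

    def scatter(self, full: dict) -> list[dict]:
        """Split a full flat dict into per-sub-model keyword dicts. Names
        absent from ``full`` (e.g. orientations removed by the spherical-mean
        or spherical-harmonics flavor) are skipped."""
        out = []
        for prefix, model in self.sub_models:
            kw = {}
            for local in model._parameters:
                name = f"{prefix}_{local}"
                if name in full:
                    kw[local] = full[name]
            out.append(kw)
        return out

    def as_spec(self) -> dict:
        """Serializable view: names, cardinalities, status and links."""
        return {
            n: {
                "cardinality": e.cardinality, "unit": e.unit,
                "status": e.status,
                "value": None if e.value is None else np.asarray(e.value).tolist(),
                "link": None if e.link is None else list(e.link),
            } for n, e in self.entries.items()
        }
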