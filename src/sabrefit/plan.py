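"""Multiline model plans: bind one SABRE equation to each dataset and declare
every parameter fixed, or free and shared across a named group of datasets.

A plan ties together the six (or 2*m) concentration-effect datasets of a
Furchgott-type experiment.  The shipped preset reproduces the unified global
regression over three agonists times two pretreatment states: gain ``gamma``
and Hill coefficient ``n`` shared across all datasets, efficacy
``eps_<agonist>`` and affinity ``logKd_<agonist>`` shared within each
agonist's control/pretreated pair, and the operable-receptor fraction ``q``
shared across the pretreated datasets only.  In the final phase ``n`` and
the efficacies are constrained to 1, leaving gamma, q and one logKd per
agonist free (five parameters for the three-agonist design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PARAM_BOUNDS, SabreParams
from .data import ECDataset

__all__ = [
    "ParamSpec",
    "ModelPlan",
    "strategy5_plan",
    "build_plan",
    "group_code_map",
    "pack_parameters",
    "unpack_parameters",
    "plan_to_dict",
    "plan_from_dict",
]

#: Dataset-code assignment of the six-group design: letter -> (agonist, pretreated).
_GROUP_CODES = {
    "A": ("NECA", False),
    "D": ("NECA", True),
    "B": ("CPA", False),
    "E": ("CPA", True),
    "C": ("CHA", False),
    "F": ("CHA", True),
}

_FIELD_OF = {"gamma": "gamma", "n": "n", "q": "q"}  # plus eps_*/logKd_* prefixes


def group_code_map() -> dict[str, tuple[str, bool]]:
    """The fixed single-letter dataset codes of the six-group design."""
    return dict(_GROUP_CODES)


def lookup_group_code(code: str) -> tuple[str, bool]:
    try:
        return _GROUP_CODES[code]
    except KeyError:
        raise KeyError(f"unknown group code {code!r}; known: {sorted(_GROUP_CODES)}") from None


@dataclass(frozen=True)
class ParamSpec:
    """One named parameter of a plan.

    ``value`` is None for a free parameter and the fixed value otherwise.
    ``scope`` is the set of dataset labels whose equations reference it.
    """

    name: str
    scope: frozenset[str]
    value: float | None = None

    @property
    def free(self) -> bool:
        return self.value is None

    @property
    def sabre_field(self) -> str:
        """Which SabreParams field this spec supplies (eps/gamma/n/logKd/q)."""
        if self.name in _FIELD_OF:
            return _FIELD_OF[self.name]
        for prefix in ("eps", "logKd"):
            if self.name.startswith(prefix + "_"):
                return prefix
        raise ValueError(f"cannot infer model field from parameter name {self.name!r}")

    def bounds(self) -> tuple[float, float]:
        lo, hi = PARAM_BOUNDS[self.sabre_field]
        # open lower ends get a tiny positive floor so the optimizer's box is closed
        if self.sabre_field in ("eps", "gamma", "n"):
            lo = 1e-8
        return lo, hi


@dataclass
class ModelPlan:
    """The compiled multiline specification.

    ``bindings`` maps each dataset label to (agonist, pretreated); ``params``
    declares every symbol each bound equation needs exactly once.
    """

    bindings: dict[str, tuple[str, bool]]
    params: list[ParamSpec]
    phase: str = "final"

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter name(s): {dupes}")
        for p in self.params:
            if not p.scope:
                raise ValueError(f"parameter {p.name!r} has empty scope")
            if not p.free:
                lo, hi = PARAM_BOUNDS[p.sabre_field]
                if not (lo <= p.value <= hi) or not np.isfinite(p.value):
                    raise ValueError(
                        f"fixed value {p.value} of {p.name!r} outside bounds [{lo}, {hi}]"
                    )
            unknown = p.scope - set(self.bindings)
            if unknown:
                raise ValueError(
                    f"parameter {p.name!r} scoped to unbound dataset(s) {sorted(unknown)}"
                )
        for label, (_, pretreated) in self.bindings.items():
            needed = self._needed_fields(pretreated)
            for fld in needed:
                specs = [
                    p for p in self.params if p.sabre_field == fld and label in p.scope
                ]
                if len(specs) != 1:
                    raise ValueError(
                        f"dataset {label!r} needs exactly one {fld!r} parameter in "
                        f"scope, found {len(specs)}"
                    )
        for p in self.params:
            if p.sabre_field == "q":
                controls = [lb for lb in p.scope if not self.bindings[lb][1]]
                if controls:
                    raise ValueError(
                        f"q parameter {p.name!r} scoped to control dataset(s) "
                        f"{sorted(controls)}; q applies only to pretreated datasets"
                    )

    @staticmethod
    def _needed_fields(pretreated: bool) -> tuple[str, ...]:
        return ("eps", "gamma", "n", "logKd") + (("q",) if pretreated else ())

    @property
    def free_params(self) -> list[ParamSpec]:
        """Free specs in the plan's packing order (alphabetical by name)."""
        return sorted((p for p in self.params if p.free), key=lambda p: p.name)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free_params]

    @property
    def k_free(self) -> int:
        return len(self.free_names)

    def spec_for(self, label: str, fld: str) -> ParamSpec | None:
        for p in self.params:
            if p.sabre_field == fld and label in p.scope:
                return p
        return None


def build_plan(
    datasets: list[ECDataset],
    phase: str = "final",
    fix: dict[str, float] | None = None,
) -> ModelPlan:
    """Generic plan builder for any paired multi-agonist Furchgott design.

    Sharing rules: gamma and n across all datasets; eps/logKd within each
    agonist's datasets; q across all pretreated datasets.  ``fix`` maps
    parameter names to fixed values; the ``"final"`` phase fixes n and every
    eps at 1.0, the ``"preliminary"`` phase leaves them free.
    """
    if phase not in ("preliminary", "final"):
        raise ValueError(f"phase must be 'preliminary' or 'final', got {phase!r}")
    labels = [ds.label for ds in datasets]
    if len(set(labels)) != len(labels):
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise ValueError(f"duplicate dataset group(s): {dupes}")
    bindings = {ds.label: (ds.agonist, ds.pretreated) for ds in datasets}
    agonists = list(dict.fromkeys(ds.agonist for ds in datasets))
    for ag in agonists:
        states = {ds.pretreated for ds in datasets if ds.agonist == ag}
        if states != {False, True}:
            missing = "pretreated" if True not in states else "control"
            raise ValueError(f"agonist {ag!r} is missing its {missing} group")

    fix = dict(fix or {})
    if phase == "final":
        fix.setdefault("n", 1.0)
        for ag in agonists:
            fix.setdefault(f"eps_{ag}", 1.0)

    all_scope = frozenset(labels)
    pret_scope = frozenset(lb for lb in labels if bindings[lb][1])
    params = [
        ParamSpec("gamma", all_scope, fix.get("gamma")),
        ParamSpec("n", all_scope, fix.get("n")),
        ParamSpec("q", pret_scope, fix.get("q")),
    ]
    for ag in agonists:
        ag_scope = frozenset(lb for lb in labels if bindings[lb][0] == ag)
        params.append(ParamSpec(f"eps_{ag}", ag_scope, fix.get(f"eps_{ag}")))
        params.append(ParamSpec(f"logKd_{ag}", ag_scope, fix.get(f"logKd_{ag}")))
    return ModelPlan(bindings=bindings, params=params, phase=phase)


def strategy5_plan(datasets: list[ECDataset], phase: str = "final") -> ModelPlan:
    """The unified six-dataset preset: exactly 3 agonists x 2 pretreatment states.

    Final phase: n and the three efficacies fixed at 1; free set is
    {gamma, q, logKd per agonist} (5 parameters).  Preliminary phase: eps and
    n also free and shared (9 parameters).
    """
    plan = build_plan(datasets, phase=phase)  # raises naming any unpaired group
    agonists = {ds.agonist for ds in datasets}
    if len(datasets) != 6 or len(agonists) != 3:
        raise ValueError(
            "the preset requires exactly 6 groups from 3 agonists "
            f"(got {len(datasets)} groups, {len(agonists)} agonists)"
        )
    return plan


def pack_parameters(plan: ModelPlan, values: dict[str, float]) -> np.ndarray:
    """Flatten a name->value mapping of the free parameters into a vector."""
    try:
        return np.array([values[n] for n in plan.free_names], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing value for free parameter {exc.args[0]!r}") from None


def unpack_parameters(plan: ModelPlan, vector) -> dict[str, SabreParams]:
    """Resolve a free-parameter vector into complete per-dataset SabreParams.

    Control datasets get q = 1 exactly (the control form of the equation).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (plan.k_free,):
        raise ValueError(
            f"expected vector of length {plan.k_free}, got shape {vector.shape}"
        )
    values = {p.name: p.value for p in plan.params if not p.free}
    values.update(dict(zip(plan.free_names, vector)))
    out = {}
    for label, (_, pretreated) in plan.bindings.items():
        kwargs = {}
        for fld in plan._needed_fields(pretreated):
            spec = plan.spec_for(label, fld)
            kwargs[fld] = values[spec.name]
        if not pretreated:
            kwargs["q"] = 1.0
        out[label] = SabreParams(**kwargs)
    return out


def plan_to_dict(plan: ModelPlan) -> dict:
    """Serialize a plan to a plain key-value document (JSON-compatible)."""
    return {
        "phase": plan.phase,
        "bindings": {
            lb: {"agonist": ag, "pretreatment": "X" if pre else "N"}
            for lb, (ag, pre) in plan.bindings.items()
        },
        "params": [
            {
                "name": p.name,
                "scope": sorted(p.scope),
                "status": "free" if p.free else "fixed",
                **({} if p.free else {"value": p.value}),
            }
            for p in plan.params
        ],
    }


def plan_from_dict(doc: dict) -> ModelPlan:
    bindings = {
        lb: (b["agonist"], b["pretreatment"] == "X")
        for lb, b in doc["bindings"].items()
    }
    params = [
        ParamSpec(
            name=p["name"],
            scope=frozenset(p["scope"]),
            value=None if p["status"] == "free" else float(p["value"]),
        )
        for p in doc["params"]
    ]
    return ModelPlan(bindings=bindings, params=params, phase=doc.get("phase", "final"))
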