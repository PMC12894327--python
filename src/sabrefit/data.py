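"""Concentration-effect tables: in-memory containers and long-format CSV I/O.

The on-disk format is a tidy CSV with one row per measured point and columns
``agonist, pretreatment, log_conc, effect_pct[, replicate]``, where
``pretreatment`` is ``"N"`` (control) or ``"X"`` (irreversible-antagonist
pretreated), ``log_conc`` is log10 molar concentration and ``effect_pct`` is
the effect as percent of the system maximal effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ECPoint",
    "ECDataset",
    "read_ec_table",
    "write_ec_table",
    "normalize_effects",
]

REQUIRED_COLUMNS = ("agonist", "pretreatment", "log_conc", "effect_pct")

# hard validation bounds on effect_pct; noise may push points slightly
# outside [0, 100] and fitting must not clip them
_Y_BOUNDS = (-25.0, 125.0)


@dataclass(frozen=True)
class ECPoint:
    """One measured point: x = log10 molar concentration, y = % of E_max."""

    x: float
    y: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.x):
            raise ValueError(f"log_conc must be finite, got {self.x}")
        if not np.isfinite(self.y) or not (_Y_BOUNDS[0] <= self.y <= _Y_BOUNDS[1]):
            raise ValueError(
                f"effect_pct must be finite in [{_Y_BOUNDS[0]}, {_Y_BOUNDS[1]}], got {self.y}"
            )


@dataclass
class ECDataset:
    """One experimental group's concentration-effect points.

    ``pretreated`` is False for control curves ("N") and True for curves
    recorded after irreversible-antagonist pretreatment ("X").
    """

    agonist: str
    pretreated: bool
    points: list[ECPoint] = field(default_factory=list)
    group_code: str | None = None

    def __post_init__(self) -> None:
        if not self.agonist:
            raise ValueError("agonist label must be non-empty")
        if len({p.x for p in self.points}) < 2:
            raise ValueError(
                f"dataset {self.label!r} needs >= 2 distinct concentrations"
            )

    @property
    def label(self) -> str:
        return f"{self.agonist}:{'X' if self.pretreated else 'N'}"

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p.y for p in self.points], dtype=float)


def _fail(line: int, msg: str) -> ValueError:
    return ValueError(f"line {line}: {msg}")


def read_ec_table(path) -> list[ECDataset]:
    """Parse a long-format CSV into datasets grouped by (agonist, pretreatment).

    Row order is preserved within groups; groups appear in first-occurrence
    order.  Errors cite the 1-based file line (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    has_rep = "replicate" in df.columns

    groups: dict[tuple[str, bool], list[ECPoint]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header occupies line 1
        agonist = row["agonist"].strip()
        if not agonist:
            raise _fail(line, "empty agonist label")
        pre = row["pretreatment"].strip()
        if pre not in ("N", "X"):
            raise _fail(line, f"pretreatment must be 'N' or 'X', got {pre!r}")
        try:
            x = float(row["log_conc"])
            y = float(row["effect_pct"])
        except ValueError as exc:
            raise _fail(line, f"unparseable number ({exc})") from None
        rep = None
        if has_rep and row["replicate"].strip():
            try:
                rep = int(row["replicate"])
            except ValueError:
                raise _fail(line, f"unparseable replicate id {row['replicate']!r}") from None
        try:
            point = ECPoint(x=x, y=y, replicate=rep)
        except ValueError as exc:
            raise _fail(line, str(exc)) from None
        groups.setdefault((agonist, pre == "X"), []).append(point)

    return [
        ECDataset(agonist=agonist, pretreated=pretreated, points=pts)
        for (agonist, pretreated), pts in groups.items()
    ]


def write_ec_table(datasets: list[ECDataset], path) -> None:
    """Write datasets to the long CSV format that :func:`read_ec_table` reads."""
    rows = []
    for ds in datasets:
        for p in ds.points:
            rows.append(
                {
                    "agonist": ds.agonist,
                    "pretreatment": "X" if ds.pretreated else "N",
                    "log_conc": repr(p.x),
                    "effect_pct": repr(p.y),
                    "replicate": "" if p.replicate is None else p.replicate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def normalize_effects(raw_effects, emax: float):
    """Express raw effect values as percent of the maximal effect: 100*E/emax."""
    if not np.isfinite(emax) or emax <= 0:
        raise ValueError(f"emax must be positive, got {emax}")
    out = 100.0 * np.asarray(raw_effects, dtype=float) / emax
    return out
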