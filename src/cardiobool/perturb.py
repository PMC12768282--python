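"""Knockout/overexpression battery and scoring against literature expectations.

Presence of a cell type under a perturbation is a qualitative attractor
criterion: some steady state of the perturbed, clamped network must carry
the atrial (MYL7+, MYL2-) or ventricular (MYL2+, MYL7-) marker pattern,
with heart-field attribution taken from the WNT input condition and the
perturbed nodes themselves excluded from marker matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .attractors import find_attractors
from .logic import Perturbation, apply_perturbation
from .models import ModelDefinition

__all__ = [
    "PerturbationExperiment",
    "SuccessMatrix",
    "load_battery",
    "simulated_presence",
    "run_battery",
]

#: (axis levels, condition name) in the published row order.
CONDITION_ORDER: tuple[tuple[Mapping[str, int], str], ...] = (
    ({"WNT": 0, "RA": 1}, "WNT=0,RA=1"),
    ({"WNT": 0, "RA": 0}, "WNT=0,RA=0"),
    ({"WNT": 1, "RA": 1}, "WNT=1,RA=1"),
    ({"WNT": 1, "RA": 0}, "WNT=1,RA=0"),
)

_ATRIAL = {"MYL7": 1, "MYL2": 0}
_VENTRICULAR = {"MYL2": 1, "MYL7": 0}


@dataclass(frozen=True)
class PerturbationExperiment:
    """One battery row: perturbations plus expected presence per condition."""

    id: str
    perturbations: tuple[Perturbation, ...]
    expected: Mapping[str, bool]  # condition name -> cell type expected present
    label: str = ""


def load_battery(path: str | Path | None = None) -> tuple[PerturbationExperiment, ...]:
    """Load the built-in battery, or one from a JSON file of the same shape."""
    if path is None:
        text = (resources.files("cardiobool.models") / "data" / "perturbation_battery.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    out = []
    for exp in raw["experiments"]:
        perts = tuple(Perturbation(p["node"], p["mode"]) for p in exp["perturbations"])
        expected = {k: bool(v) for k, v in exp["expected"].items()}
        out.append(
            PerturbationExperiment(exp["id"], perts, expected, exp.get("label", ""))
        )
    return tuple(out)


def simulated_presence(
    model: ModelDefinition,
    perturbations: Sequence[Perturbation],
    levels: Mapping[str, int],
) -> dict[str, bool]:
    """Presence of the atrial and ventricular cell types under one condition.

    Returns ``{"aCM": bool, "vCM": bool}``: whether any steady attractor of
    the perturbed, clamped network carries the marker pattern (the branch,
    FHF vs SHF, is fixed by the WNT level and not re-checked on markers).
    Perturbed nodes are excluded from marker matching.
    """
    net = apply_perturbation(model.clamped_network(levels), perturbations)
    ignore = net.perturbed
    present = {"aCM": False, "vCM": False}
    for att in find_attractors(net):
        if not att.is_steady:
            continue
        state = att.states[0]
        for key, markers in (("aCM", _ATRIAL), ("vCM", _VENTRICULAR)):
            if all(state[n] == v for n, v in markers.items() if n not in ignore):
                present[key] = True
    return present


def _condition_cell_type(levels: Mapping[str, int]) -> str:
    return "aCM" if levels["RA"] else "vCM"


@dataclass
class SuccessMatrix:
    """Experiment x condition comparison of simulated vs expected presence."""

    cells: pd.DataFrame  # columns: experiment, condition, expected, simulated, match
    experiment_order: tuple[str, ...]

    @property
    def total_matches(self) -> int:
        return int(self.cells["match"].sum())

    @property
    def total_cells(self) -> int:
        return len(self.cells)

    def success_rates(self) -> dict[str, float]:
        """Per-experiment fraction of matching conditions."""
        by = self.cells.groupby("experiment", sort=False)["match"].mean()
        return {e: float(by[e]) for e in self.experiment_order}

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()

    def render_text(self) -> str:
        wide_sim = self.cells.pivot(index="condition", columns="experiment", values="simulated")
        wide_exp = self.cells.pivot(index="condition", columns="experiment", values="expected")
        cond_order = [c for _, c in CONDITION_ORDER]
        lines = [f"{'condition':<14}" + "".join(f"{e:>12}" for e in self.experiment_order)]
        lines.append(f"{'':<14}" + "".join(f"{'Exp/Sim':>12}" for _ in self.experiment_order))
        for cond in cond_order:
            cells = []
            for e in self.experiment_order:
                exp = "+" if wide_exp.loc[cond, e] else "-"
                sim = "+" if wide_sim.loc[cond, e] else "-"
                mark = "" if exp == sim else " x"
                cells.append(f"{exp}/{sim}{mark:>3}".rjust(12))
            lines.append(f"{cond:<14}" + "".join(cells))
        rates = self.success_rates()
        lines.append(
            f"{'success rate':<14}"
            + "".join(f"{rates[e] * 100:>11.0f}%" for e in self.experiment_order)
        )
        lines.append(f"total: {self.total_matches}/{self.total_cells} matches")
        return "\n".join(lines)


def run_battery(
    model: ModelDefinition,
    experiments: Sequence[PerturbationExperiment] | None = None,
) -> SuccessMatrix:
    """Run every experiment across the four signaling conditions and score it."""
    if experiments is None:
        experiments = load_battery()
    records = []
    for exp in experiments:
        for levels, cond_name in CONDITION_ORDER:
            presence = simulated_presence(model, exp.perturbations, levels)
            simulated = presence[_condition_cell_type(levels)]
            expected = exp.expected[cond_name]
            records.append(
                {
                    "experiment": exp.id,
                    "condition": cond_name,
                    "expected": expected,
                    "simulated": simulated,
                    "match": expected == simulated,
                }
            )
    cells = pd.DataFrame.from_records(records)
    return SuccessMatrix(cells, tuple(e.id for e in experiments))
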