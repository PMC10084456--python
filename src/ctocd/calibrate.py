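"""Two-point analytical calibration of the GRRO/GPRO parameters.

Because sigma_Av varies exactly linearly in alpha (GRRO) and beta (GPRO), the
parameter reproducing a reference shielding follows from two probe
integrations and an exact linear solve -- no iteration.  Calibration runs use
*uniform*-parameter integrations (one grid pass per probe, all nuclei read
out simultaneously), which avoids foreign-cell cross-talk during fitting; the
per-nucleus fits are independent by linearity.

Fitted parameters are aggregated into element-level or environment-level
tables (mean, sample standard deviation, count), and the expected shielding
error of using a pooled mean is |slope| * std.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .becke import MolecularGrid, molecular_grid
from .envtype import classify_atom
from .molecule import Molecule, perceive_bonds
from .shielding import integrate_shielding_all_nuclei

__all__ = [
    "DegenerateSlopeError",
    "CalibrationRecord",
    "ParameterTable",
    "two_point_fit",
    "calibrate_molecule",
    "aggregate",
    "propagate_error",
]

DEFAULT_PROBES = {"GRRO": (0.0, -0.01), "GPRO": (0.0, -0.05)}


class DegenerateSlopeError(ValueError):
    pass


def two_point_fit(p1: float, s1: float, p2: float, s2: float, s_target: float):
    """Exact linear solve: returns (parameter, slope, intercept).

    slope = (s2 - s1)/(p2 - p1); parameter = p1 + (s_target - s1)/slope.
    """
    if p1 == p2:
        raise ValueError("probe parameters must differ")
    if abs(s2 - s1) < 1e-12:
        raise DegenerateSlopeError(
            f"shielding insensitive to the parameter (|ds| = {abs(s2 - s1):.2e} ppm)"
        )
    slope = (s2 - s1) / (p2 - p1)
    intercept = s1 - slope * p1
    return p1 + (s_target - s1) / slope, slope, intercept


@dataclass
class CalibrationRecord:
    nucleus: int
    element: str
    environment: str
    scheme: str
    slope: float  # ppm per parameter unit
    intercept: float  # sigma_Av at parameter 0 (the DZ1 value), ppm
    parameter: float
    reference: float  # ppm
    residual: float  # ppm; 0 by construction unless flagged
    degenerate: bool = False


@dataclass
class ParameterTable:
    grouping: str  # "element" | "environment"
    entries: dict[str, tuple[float, float, int]]  # key -> (mean, std, n)
    provenance: dict = field(default_factory=dict)

    def lookup(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.entries.items()}

    def to_json(self, path=None) -> str:
        payload = {
            "grouping": self.grouping,
            "entries": {k: {"mean": v[0], "std": v[1], "n": v[2]} for k, v in self.entries.items()},
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ParameterTable":
        d = json.loads(text)
        entries = {k: (v["mean"], v["std"], v["n"]) for k, v in d["entries"].items()}
        return cls(d["grouping"], entries, d.get("provenance", {}))


def calibrate_molecule(
    state,
    references: dict[int, float],
    scheme: str = "GRRO",
    probes: tuple[float, float] | None = None,
    grid: MolecularGrid | None = None,
    grid_kwargs: dict | None = None,
) -> list[CalibrationRecord]:
    """One record per referenced nucleus; two uniform-probe grid passes total."""
    if probes is None:
        probes = DEFAULT_PROBES[scheme]
    p1, p2 = probes
    mol = state.molecule
    if grid is None:
        grid = molecular_grid(mol, **(grid_kwargs or {}))
    r1 = integrate_shielding_all_nuclei(state, p1, scheme, grid=grid)
    r2 = integrate_shielding_all_nuclei(state, p2, scheme, grid=grid)
    mol_b = mol if mol.bonds or mol.natoms == 1 else perceive_bonds(mol)
    out: list[CalibrationRecord] = []
    for n in range(mol.natoms):
        if n not in references:
            warnings.warn(f"no reference shielding for nucleus {n} ({mol.symbols[n]}); skipped")
            continue
        target = float(references[n])
        env = classify_atom(mol_b, n).tag
        try:
            p, slope, intercept = two_point_fit(
                p1, float(r1.sigma_av[n]), p2, float(r2.sigma_av[n]), target
            )
            resid = (intercept + slope * p) - target
            out.append(
                CalibrationRecord(n, mol.symbols[n], env, scheme, slope, intercept, p, target, resid)
            )
        except DegenerateSlopeError:
            out.append(
                CalibrationRecord(
                    n, mol.symbols[n], env, scheme, 0.0, float(r1.sigma_av[n]),
                    np.nan, target, np.nan, degenerate=True,
                )
            )
    return out


def aggregate(records: list[CalibrationRecord], grouping: str = "element",
              provenance: dict | None = None) -> ParameterTable:
    """Mean and sample (n-1) standard deviation of the fitted parameters per group."""
    if not records:
        raise ValueError("no calibration records to aggregate")
    if grouping not in ("element", "environment"):
        raise ValueError(f"grouping must be 'element' or 'environment', got {grouping!r}")
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.degenerate:
            continue
        key = r.element if grouping == "element" else r.environment
        groups.setdefault(key, []).append(r.parameter)
    entries = {}
    for key, vals in groups.items():
        v = np.asarray(vals)
        std = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        entries[key] = (float(v.mean()), std, len(v))
    return ParameterTable(grouping, entries, provenance or {})


def propagate_error(slope: float, std: float) -> float:
    """Predicted shielding error (ppm) of using a pooled mean parameter."""
    if not (np.isfinite(slope) and np.isfinite(std)):
        raise ValueError("slope and std must be finite")
    return abs(slope) * std
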