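"""Per-residue backbone geometry and B-factor statistics.

Backbone conformation is judged on the (phi, psi) torsion pair against a
category-specific probability grid (general / GLY / PRO / pre-PRO /
ILE-VAL), interpolated bilinearly on the periodic torsion torus.  The
continuous probability is mapped to the familiar three-way traffic-light
classification by two configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .model_io import Chain, Residue

__all__ = [
    "BFactorStats",
    "RamaTable",
    "ConformationClass",
    "DEFAULT_RAMA_THRESHOLDS",
    "bfactor_summary",
    "dihedral_angle",
    "backbone_torsions",
    "rama_probability",
    "rama_classify",
    "rama_category",
    "load_rama_table",
    "load_default_rama_tables",
]

#: Coot-style probability thresholds (favored_min, allowed_min).  The
#: exact values used by Coot are not published alongside the method;
#: these defaults are overridable everywhere they are consumed.
DEFAULT_RAMA_THRESHOLDS = (0.02, 0.002)

#: C(i-1)-N(i) distance beyond which the chain is treated as broken (Å).
CHAIN_BREAK_DISTANCE = 2.5


class ConformationClass(str, Enum):
    FAVORED = "favored"
    ALLOWED = "allowed"
    OUTLIER = "outlier"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class BFactorStats:
    """Min/max/mean/SD (population) of a residue's atomic B-factors, Å²."""

    minimum: float
    maximum: float
    mean: float
    sd: float


def bfactor_summary(
    residue: Residue, include_hydrogens: bool = False
) -> BFactorStats | None:
    """Summarize the B-factors of a residue's included atoms.

    Hydrogens are excluded by default.  Returns None (an absent result,
    to be flagged by the caller) when no atoms remain.
    """
    values = [
        a.b_factor
        for a in residue.atoms
        if include_hydrogens or not a.is_hydrogen
    ]
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return BFactorStats(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std()),  # population SD
    )


def dihedral_angle(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float | None:
    """IUPAC-signed torsion angle (degrees, [-180, 180)) of four points.

    Returns None for degenerate geometry (collinear triples).
    """
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / norm_b1))
    angle = math.degrees(math.atan2(y, x))
    if angle >= 180.0:
        angle -= 360.0
    return angle


def _positions(residue: Residue | None, *names: str) -> list[np.ndarray] | None:
    if residue is None:
        return None
    out = []
    for name in names:
        atom = residue.atom(name)
        if atom is None:
            return None
        out.append(atom.position)
    return out


def backbone_torsions(
    chain: Chain,
    index: int,
    break_distance: float = CHAIN_BREAK_DISTANCE,
) -> tuple[float | None, float | None]:
    """(phi, psi) in degrees for the residue at ``index`` in ``chain``.

    phi needs C of the preceding residue; psi needs N of the following
    one.  Either angle is absent (None) at chain termini, across a chain
    break (peptide C-N distance > ``break_distance``), or when a required
    atom is missing — never an exception.
    """
    residue = chain.residues[index]
    prev_res = chain.residues[index - 1] if index > 0 else None
    next_res = chain.residues[index + 1] if index + 1 < len(chain.residues) else None

    phi = psi = None
    this = _positions(residue, "N", "CA", "C")
    if this is not None:
        n_i, ca_i, c_i = this
        prev_c = _positions(prev_res, "C")
        if prev_c is not None:
            if np.linalg.norm(n_i - prev_c[0]) <= break_distance:
                phi = dihedral_angle(prev_c[0], n_i, ca_i, c_i)
        next_n = _positions(next_res, "N")
        if next_n is not None:
            if np.linalg.norm(next_n[0] - c_i) <= break_distance:
                psi = dihedral_angle(n_i, ca_i, c_i, next_n[0])
    return phi, psi


@dataclass
class RamaTable:
    """A periodic (phi, psi) probability grid for one residue category."""

    category: str
    grid: np.ndarray  # shape (n_phi, n_psi), probabilities in [0, 1]
    phi_origin: float
    psi_origin: float
    phi_step: float
    psi_step: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("RamaTable grid must be 2-D")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("RamaTable probabilities must lie in [0, 1]")


def rama_probability(phi: float, psi: float, table: RamaTable) -> float:
    """Bilinear interpolation of the probability grid on the torsion torus."""
    n_phi, n_psi = table.grid.shape
    u = (phi - table.phi_origin) / table.phi_step
    v = (psi - table.psi_origin) / table.psi_step
    i0 = math.floor(u)
    j0 = math.floor(v)
    fu = u - i0
    fv = v - j0
    g = table.grid
    i0 %= n_phi
    j0 %= n_psi
    i1 = (i0 + 1) % n_phi
    j1 = (j0 + 1) % n_psi
    value = (
        g[i0, j0] * (1 - fu) * (1 - fv)
        + g[i1, j0] * fu * (1 - fv)
        + g[i0, j1] * (1 - fu) * fv
        + g[i1, j1] * fu * fv
    )
    return float(value)


def rama_classify(
    p: float, thresholds: tuple[float, float] = DEFAULT_RAMA_THRESHOLDS
) -> ConformationClass:
    """Map a Ramachandran probability to favored/allowed/outlier.

    ``thresholds`` is (favored_min, allowed_min); boundaries inclusive on
    the better side, i.e. p == favored_min is favored.
    """
    favored_min, allowed_min = thresholds
    if not favored_min > allowed_min:
        raise ValueError("favored_min must exceed allowed_min")
    if p >= favored_min:
        return ConformationClass.FAVORED
    if p >= allowed_min:
        return ConformationClass.ALLOWED
    return ConformationClass.OUTLIER


def rama_category(residue: Residue, next_residue: Residue | None) -> str:
    """Assign the probability-table category for a residue."""
    if residue.name == "GLY":
        return "GLY"
    if residue.name == "PRO":
        return "PRO"
    if next_residue is not None and next_residue.name == "PRO":
        return "pre-PRO"
    if residue.name in ("ILE", "VAL"):
        return "ILE_VAL"
    return "general"


def load_rama_table(path: str | Path) -> RamaTable:
    """Load a probability grid from the documented CSV dialect.

    Header comment lines carry category, axis origins, steps and sizes;
    data rows are ``phi,psi,probability``.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if line.lower().startswith("phi"):
                continue
            a, b, c = line.split(",")
            rows.append((float(a), float(b), float(c)))
    n_phi = int(meta["phi_n"])
    n_psi = int(meta["psi_n"])
    grid = np.zeros((n_phi, n_psi))
    phi0 = float(meta["phi_origin"])
    psi0 = float(meta["psi_origin"])
    dphi = float(meta["phi_step"])
    dpsi = float(meta["psi_step"])
    for phi, psi, p in rows:
        i = round((phi - phi0) / dphi) % n_phi
        j = round((psi - psi0) / dpsi) % n_psi
        grid[i, j] = p
    return RamaTable(
        category=meta.get("category", "general"),
        grid=grid,
        phi_origin=phi0,
        psi_origin=psi0,
        phi_step=dphi,
        psi_step=dpsi,
    )


def load_default_rama_tables() -> dict[str, RamaTable]:
    """Load the synthetic probability grids shipped with the package."""
    data_dir = Path(__file__).parent / "data"
    tables = {}
    for path in sorted(data_dir.glob("rama_*_synthetic.csv")):
        table = load_rama_table(path)
        tables[table.category] = table
    return tables
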