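"""Synthetic test-data generators: models, maps and reference libraries.

Everything the package needs to exercise itself — coordinate files,
density maps / reflection sets, Ramachandran grids, rotamer central
values and contour grids — can be generated here from a seeded spec, so
no external downloads are ever required.  Generators are pure functions
of their spec: identical spec, identical bytes.

Models are built by internal-coordinate (NeRF) placement from ideal
bond lengths and angles, with only the torsions varying, so torsion
recovery is exact up to numerical round-off; chemical realism beyond
that (packing, clashes) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .density import DensityMap, ReflectionSet, reflections_from_map
from .geometry import RamaTable
from .model_io import StructureModel, read_model
from .rotamer import CentralValuesEntry, RawGrids

__all__ = [
    "FixtureSpec",
    "place_atom",
    "synthetic_model",
    "write_model_pdb",
    "synthetic_map",
    "synthetic_reflections",
    "synthetic_rama_table",
    "synthetic_rotamer_reference",
    "synthetic_percentile_records",
]

# Ideal backbone internal coordinates (lengths Å, angles degrees).
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.4}
_OMEGA = 180.0

# Minimal side-chain topology: (atom, parent triplet, bond, angle);
# the torsion is chi_k for gamma/delta/... atoms, fixed for CB.
_SIDE_CHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float]]] = {
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.7)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9)],
}

_ELEMENTS = {"N": "N", "C": "C", "O": "O", "S": "S"}

TORSION_REGIMES = {
    "helix": (-57.0, -47.0),
    "sheet": (-120.0, 135.0),
}


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic model (and optional map)."""

    seed: int = 0
    n_chains: int = 1
    n_residues: int = 8
    sequence: str | None = None  # one-letter; cycled if shorter
    torsion_regime: str = "helix"  # helix | sheet | random
    chi_angles: dict[int, list[float]] = field(default_factory=dict)
    b_base: float = 20.0
    b_gradient: float = 0.0
    b_hotspots: dict[int, float] = field(default_factory=dict)
    displace: dict[int, float] = field(default_factory=dict)  # residue -> Å
    resolution: float = 2.0
    map_noise_sd: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


_ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "V": "VAL", "L": "LEU",
    "C": "CYS", "T": "THR", "D": "ASP", "K": "LYS",
}


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: position D given chain A-B-C and D's internals."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion_series(spec: FixtureSpec, rng: np.random.Generator):
    if spec.torsion_regime in TORSION_REGIMES:
        phi, psi = TORSION_REGIMES[spec.torsion_regime]
        return [(phi, psi)] * spec.n_residues
    if spec.torsion_regime == "random":
        phis = rng.uniform(-180, 180, spec.n_residues)
        psis = rng.uniform(-180, 180, spec.n_residues)
        return list(zip(phis.tolist(), psis.tolist()))
    raise ValueError(f"unknown torsion regime {spec.torsion_regime!r}")


def _sequence(spec: FixtureSpec) -> list[str]:
    letters = spec.sequence or "A"
    seq = [letters[i % len(letters)] for i in range(spec.n_residues)]
    bad = [ch for ch in seq if ch not in _ONE_TO_THREE]
    if bad:
        raise ValueError(f"fixture builder does not know residue letters {bad}")
    return [_ONE_TO_THREE[ch] for ch in seq]


def _build_chain(spec: FixtureSpec, rng: np.random.Generator, offset: np.ndarray):
    """Returns a list of (res_name, {atom: position}) for one chain."""
    torsions = _torsion_series(spec, rng)
    names = _sequence(spec)
    residues: list[tuple[str, dict[str, np.ndarray]]] = []
    prev = None  # (N, CA, C) of previous residue
    prev_psi = None
    for i, (res_name, (phi, psi)) in enumerate(zip(names, torsions)):
        atoms: dict[str, np.ndarray] = {}
        if prev is None:
            n = np.array([0.0, 0.0, 0.0]) + offset
            ca = n + np.array([_BOND["N-CA"], 0.0, 0.0])
            angle = math.radians(_ANGLE["N-CA-C"])
            c = ca + _BOND["CA-C"] * np.array(
                [-math.cos(angle), math.sin(angle), 0.0]
            )
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, _BOND["C-N"], _ANGLE["CA-C-N"], prev_psi)
            ca = place_atom(pca, pc, n, _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
            c = place_atom(pc, n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        atoms["N"], atoms["CA"], atoms["C"] = n, ca, c
        prev_psi = psi
        # Carbonyl O: anti-periplanar to the next N, i.e. torsion psi+180
        # about N-CA-C.
        atoms["O"] = place_atom(n, ca, c, _BOND["C-O"], _ANGLE["CA-C-O"],
                                psi + 180.0)
        if res_name != "GLY":
            atoms["CB"] = place_atom(c, n, ca, _BOND["CA-CB"],
                                     _ANGLE["N-CA-CB"], -122.6)
        chi = list(spec.chi_angles.get(i, []))
        for k, (aname, parents, bond, angle_deg) in enumerate(
            _SIDE_CHAINS.get(res_name, [])
        ):
            torsion = chi[k] if k < len(chi) else 180.0
            p0, p1, p2 = (atoms[p] for p in parents)
            atoms[aname] = place_atom(p0, p1, p2, bond, angle_deg, torsion)
        residues.append((res_name, atoms))
        prev = (n, ca, c)
    # post-build perturbations
    for idx, dist in spec.displace.items():
        if 0 <= idx < len(residues):
            direction = rng.normal(size=3)
            direction = direction / np.linalg.norm(direction) * dist
            for aname in residues[idx][1]:
                residues[idx][1][aname] = residues[idx][1][aname] + direction
    return residues


_ATOM_ORDER = ["N", "CA", "C", "O", "CB", "OG", "OG1", "SG", "CG", "CG1",
               "OD1", "CD", "CD1", "CE", "NE", "NZ", "OE1", "CZ"]


def synthetic_model(spec: FixtureSpec) -> gemmi.Structure:
    """Build a synthetic polypeptide as a gemmi Structure."""
    rng = spec.rng()
    structure = gemmi.Structure()
    structure.name = "synthetic"
    structure.resolution = spec.resolution
    model = gemmi.Model("1")
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_chains)]
    for ci, cid in enumerate(chain_ids):
        offset = np.array([0.0, 0.0, ci * 20.0])
        chain = gemmi.Chain(cid)
        for i, (res_name, atoms) in enumerate(_build_chain(spec, rng, offset)):
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(i + 1, " ")
            b = spec.b_base + spec.b_gradient * i + spec.b_hotspots.get(i, 0.0)
            for aname in sorted(atoms, key=_ATOM_ORDER.index):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(_ELEMENTS[aname[0]])
                atom.pos = gemmi.Position(*atoms[aname])
                atom.b_iso = b
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    structure.add_model(model)
    # generous P1 cell around the model
    structure.cell = _bounding_cell(structure)
    structure.spacegroup_hm = "P 1"
    return structure


def _bounding_cell(structure: gemmi.Structure, margin: float = 8.0) -> gemmi.UnitCell:
    coords = np.array(
        [[a.pos.x, a.pos.y, a.pos.z]
         for model in structure for ch in model for r in ch for a in r]
    )
    span = coords.max(axis=0) - coords.min(axis=0) + 2 * margin
    return gemmi.UnitCell(*(float(s) for s in span), 90, 90, 90)


def write_model_pdb(structure: gemmi.Structure, path) -> StructureModel:
    """Write the structure to PDB (shifted into its cell) and re-read it."""
    coords = np.array(
        [[a.pos.x, a.pos.y, a.pos.z]
         for model in structure for ch in model for r in ch for a in r]
    )
    shift = coords.min(axis=0) - 8.0
    for model in structure:
        for ch in model:
            for r in ch:
                for a in r:
                    a.pos = gemmi.Position(
                        a.pos.x - shift[0], a.pos.y - shift[1], a.pos.z - shift[2]
                    )
    structure.write_pdb(str(path))
    return read_model(str(path))


def synthetic_map(
    model: StructureModel,
    spec: FixtureSpec,
    cell: gemmi.UnitCell | None = None,
) -> DensityMap:
    """Sum-of-Gaussians density for a model: amplitude ∝ Z, width ∝ d_min.

    Optional white noise (``spec.map_noise_sd``, in absolute density
    units) is seeded from the spec.
    """
    if cell is None:
        coords = np.array(
            [a.position for ch in model.chains for r in ch.residues for a in r.atoms]
        )
        span = coords.max(axis=0) + 8.0
        cell = gemmi.UnitCell(*(float(max(s, 10.0)) for s in span), 90, 90, 90)
    width = max(spec.resolution / 3.0, 0.4)  # Gaussian sigma, Å
    spacing = spec.resolution / 3.0
    dims = tuple(
        max(6, int(np.ceil(L / spacing)) + int(np.ceil(L / spacing)) % 2)
        for L in (cell.a, cell.b, cell.c)
    )
    grid = np.zeros(dims)
    axes = [np.arange(n) * (L / n) for n, L in zip(dims, (cell.a, cell.b, cell.c))]
    cutoff = 4.0 * width
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                _add_gaussian(grid, axes, (cell.a, cell.b, cell.c),
                              atom.position, atom.proton_number, width, cutoff)
    if spec.map_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        grid = grid + rng.normal(0.0, spec.map_noise_sd, size=dims)
    return DensityMap(grid=grid, cell=cell)


def _add_gaussian(grid, axes, lengths, center, amplitude, width, cutoff):
    slices = []
    deltas = []
    for axis, L, x0 in zip(axes, lengths, center):
        n = len(axis)
        d = (axis - x0 + L / 2) % L - L / 2  # minimum-image distance
        idx = np.nonzero(np.abs(d) <= cutoff)[0]
        slices.append(idx)
        deltas.append(d[idx])
    if any(len(s) == 0 for s in slices):
        return
    dx, dy, dz = np.meshgrid(*deltas, indexing="ij")
    patch = amplitude * np.exp(-(dx**2 + dy**2 + dz**2) / (2 * width**2))
    grid[np.ix_(*slices)] += patch


def synthetic_reflections(dmap: DensityMap) -> ReflectionSet:
    """Forward transform of a map into its full unique reflection set."""
    return reflections_from_map(dmap, d_min=None)


def synthetic_rama_table(
    category: str = "general",
    step: float = 15.0,
    basins: list[tuple[float, float, float, float]] | None = None,
    floor: float = 1e-4,
) -> RamaTable:
    """Analytic probability grid with Gaussian basins.

    ``basins`` rows are (phi0, psi0, height, width_deg); defaults place
    an alpha-helical basin at (-57, -47) and a beta basin at (-120, 135).
    """
    if basins is None:
        basins = [(-57.0, -47.0, 0.4, 25.0), (-120.0, 135.0, 0.3, 30.0),
                  (58.0, 45.0, 0.05, 20.0)]
    n = int(round(360.0 / step))
    phis = -180.0 + step * np.arange(n)
    psis = -180.0 + step * np.arange(n)
    grid = np.full((n, n), floor)
    pp, ss = np.meshgrid(phis, psis, indexing="ij")
    for phi0, psi0, height, width in basins:
        dphi = (pp - phi0 + 180.0) % 360.0 - 180.0
        dpsi = (ss - psi0 + 180.0) % 360.0 - 180.0
        grid = grid + height * np.exp(-(dphi**2 + dpsi**2) / (2 * width**2))
    grid = np.clip(grid, 0.0, 1.0)
    return RamaTable(category=category, grid=grid, phi_origin=-180.0,
                     psi_origin=-180.0, phi_step=step, psi_step=step)


def synthetic_rotamer_reference(
    seed: int = 0,
    residue_types: dict[str, int] | None = None,
    step: float = 10.0,
) -> tuple[dict[str, list[CentralValuesEntry]], RawGrids]:
    """Small rotamer reference: central values + matching raw grids.

    ``residue_types`` maps 3-letter codes to their chi dimensionality
    (default SER:1, LEU:2, LYS:3).  Rotamer centers are drawn seeded;
    rotamericity on the lattice is a Gaussian mixture over the centers
    scaled so basin cores classify favored and the far field outlier,
    with a sprinkling of unknown (absent) points.
    """
    if residue_types is None:
        residue_types = {"SER": 1, "LEU": 2, "LYS": 3}
    rng = np.random.default_rng(seed)
    central: dict[str, list[CentralValuesEntry]] = {}
    raw: RawGrids = {}
    for rtype, n_chi in residue_types.items():
        n_rot = int(rng.integers(2, 4))
        entries = []
        centers = []
        for r in range(n_rot):
            means = tuple(float(m) for m in rng.uniform(-180, 180, n_chi))
            sds = tuple(float(s) for s in rng.uniform(8, 15, n_chi))
            entries.append(
                CentralValuesEntry(rtype, f"rot{r+1}", means, sds)
            )
            centers.append((np.array(means), np.array(sds)))
        central[rtype] = entries
        size = int(round(360.0 / step))
        meta = {
            "origins": [-180.0] * n_chi,
            "spacings": [step] * n_chi,
            "sizes": [size] * n_chi,
        }
        sparse: dict[tuple[float, ...], float] = {}
        grids = np.meshgrid(
            *[-180.0 + step * np.arange(size) for _ in range(n_chi)],
            indexing="ij",
        )
        coords = np.stack([g.ravel() for g in grids], axis=-1)
        values = np.zeros(len(coords))
        for means, sds in centers:
            d = (coords - means + 180.0) % 360.0 - 180.0
            z2 = ((d / (2.0 * sds)) ** 2).sum(axis=1)
            values += 40.0 * np.exp(-z2 / 2.0)
        drop = rng.random(len(coords)) < 0.02  # a few unknown points
        for coord, value, skip in zip(coords, values, drop):
            if skip:
                continue
            sparse[tuple(float(c) for c in coord)] = float(value)
        raw[rtype] = (meta, sparse)
    return central, raw


def synthetic_percentile_records(
    seed: int = 0, n_per_metric: int = 2000
) -> list[tuple[str, float, float]]:
    """Plausible (metric, value, resolution) records for library building."""
    rng = np.random.default_rng(seed)
    records: list[tuple[str, float, float]] = []
    resolutions = rng.uniform(0.8, 4.5, n_per_metric)
    for res in resolutions:
        b_mean = float(rng.lognormal(math.log(10 + 15 * res), 0.4))
        records.append(("b_mean", b_mean, float(res)))
        records.append(("b_max", b_mean * float(rng.uniform(1.05, 1.6)), float(res)))
        fit = float(rng.gamma(2.0, 0.15 + 0.08 * res))
        records.append(("fit_all", fit, float(res)))
        records.append(("fit_side", fit * float(rng.uniform(0.8, 1.6)), float(res)))
        records.append(("rama_prob", float(rng.beta(2.0, 1.5)), float(res)))
        records.append(("rotamer_score", float(rng.gamma(1.5, 0.8)), float(res)))
    return records
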