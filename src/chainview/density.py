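"""Electron-density map handling and real-space fit scoring.

A map is synthesized from amplitude/phase structure factors by placing
each coefficient (plus its Friedel mate) on an FFT grid and inverse
transforming:  rho(x) = (1/V) * sum_h F_h exp(i phi_h) exp(-2 pi i h.x).

An atom's fit score is -ln Phi(z) where z is the deviation of the
(proton-number-normalized) density at the atom's position from the map
mean in units of the map SD: 0 for an atom sitting in arbitrarily strong
density, ln 2 at exactly mean density, and growing without bound as the
atom falls into negative density.  Residue scores are plain means of
atom scores over the whole residue, the backbone set {N, CA, C, O, OXT}
and the remaining (side-chain) atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.special import ndtr

from .model_io import Residue

__all__ = [
    "DensityMap",
    "ReflectionSet",
    "ResidueFitScores",
    "DegenerateMapError",
    "BACKBONE_ATOMS",
    "map_from_reflections",
    "reflections_from_map",
    "density_at",
    "atom_fit_score",
    "residue_fit_scores",
    "read_reflections_text",
    "write_reflections_text",
    "read_mtz_reflections",
    "read_ccp4_map",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_TINY = np.finfo(float).tiny


class DegenerateMapError(RuntimeError):
    """The map is constant (SD = 0) and cannot normalize anything."""


@dataclass
class DensityMap:
    """A real-space density grid over one unit cell (P1 sampling)."""

    grid: np.ndarray  # shape (n1, n2, n3), fractional axes a, b, c
    cell: gemmi.UnitCell
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("density grid must be 3-D")
        self.mean = float(self.grid.mean())
        self.sd = float(self.grid.std())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def is_degenerate(self) -> bool:
        # constant up to round-off: SD negligible against the map scale
        scale = max(float(np.abs(self.grid).max()), 1e-300)
        return self.sd <= 1e-12 * scale


@dataclass
class ReflectionSet:
    """Unique structure factors (amplitude + phase) for one data set."""

    hkl: np.ndarray  # (n, 3) int Miller indices
    amplitude: np.ndarray  # (n,) >= 0
    phase_deg: np.ndarray  # (n,)
    cell: gemmi.UnitCell
    d_min: float  # resolution limit, Å
    grid_shape: tuple[int, int, int] | None = None  # synthesis grid hint

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")
        keys = {tuple(r) for r in self.hkl}
        if len(keys) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")

    def __len__(self) -> int:
        return len(self.hkl)


@dataclass(frozen=True)
class ResidueFitScores:
    all_atoms: float | None
    backbone: float | None
    side_chain: float | None


def _grid_dims(cell: gemmi.UnitCell, spacing: float, hint=None) -> tuple[int, int, int]:
    if hint is not None:
        return tuple(hint)
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = max(4, int(np.ceil(length / spacing)))
        dims.append(n + (n % 2))  # even sizes keep FFT layout simple
    return tuple(dims)


def map_from_reflections(
    refl: ReflectionSet, sampling: float = 1.5
) -> DensityMap:
    """Inverse Fourier synthesis of an amplitude/phase reflection set.

    The grid spacing is at most d_min / (2 * sampling) per axis (the
    default oversampling of 1.5 gives the conventional d_min/3 sampling
    rate).  Friedel mates are filled in automatically so the synthesis
    is real.  A set carrying only the (0,0,0) term yields a constant —
    degenerate — map, flagged via :attr:`DensityMap.is_degenerate`.
    """
    if len(refl) == 0:
        raise ValueError("empty reflection set")
    spacing = refl.d_min / (2.0 * sampling)
    dims = _grid_dims(refl.cell, spacing, refl.grid_shape)
    coef = np.zeros(dims, dtype=complex)
    volume = refl.cell.volume
    phases = np.deg2rad(refl.phase_deg)
    values = refl.amplitude * np.exp(1j * phases)
    filled: dict[tuple[int, int, int], complex] = {}
    for (h, k, l), c in zip(refl.hkl, values):
        filled[(int(h), int(k), int(l))] = c
    for (h, k, l), c in list(filled.items()):
        mate = (-h, -k, -l)
        if mate not in filled:
            filled[mate] = np.conj(c)
    for (h, k, l), c in filled.items():
        idx = (-h) % dims[0], (-k) % dims[1], (-l) % dims[2]
        coef[idx] = c
    n_total = np.prod(dims)
    rho = np.fft.ifftn(coef) * (n_total / volume)
    return DensityMap(grid=rho.real, cell=refl.cell)


def reflections_from_map(
    dmap: DensityMap,
    d_min: float | None = None,
    include_dc: bool = True,
) -> ReflectionSet:
    """Forward transform: unique structure factors of a gridded map.

    With ``d_min=None`` every unique FFT grid frequency is returned
    (together with the grid-shape hint), so a subsequent synthesis on
    the same grid reproduces the map to numerical precision.
    """
    dims = dmap.shape
    volume = dmap.cell.volume
    n_total = np.prod(dims)
    coef = np.fft.fftn(dmap.grid) * (volume / n_total)
    hkl = []
    amps = []
    phases = []
    half = [n // 2 for n in dims]
    for h in range(-half[0] + 1, half[0] + 1):
        for k in range(-half[1] + 1, half[1] + 1):
            for l in range(-half[2] + 1, half[2] + 1):
                if (h, k, l) < (0, 0, 0):
                    continue  # keep one Friedel mate
                if (h, k, l) == (0, 0, 0) and not include_dc:
                    continue
                if d_min is not None and (h, k, l) != (0, 0, 0):
                    if dmap.cell.calculate_d([h, k, l]) < d_min:
                        continue
                c = coef[(-h) % dims[0], (-k) % dims[1], (-l) % dims[2]]
                hkl.append((h, k, l))
                amps.append(abs(c))
                phases.append(np.degrees(np.angle(c)))
    d_eff = d_min if d_min is not None else max(
        dmap.cell.a / dims[0], dmap.cell.b / dims[1], dmap.cell.c / dims[2]
    ) * 2.0
    return ReflectionSet(
        hkl=np.array(hkl),
        amplitude=np.array(amps),
        phase_deg=np.array(phases),
        cell=dmap.cell,
        d_min=d_eff,
        grid_shape=dmap.shape if d_min is None else None,
    )


def density_at(dmap: DensityMap, position: np.ndarray) -> float:
    """Trilinear interpolation of the map at a Cartesian position (Å)."""
    pos = np.asarray(position, dtype=float)
    frac = dmap.cell.fractionalize(gemmi.Position(*pos))
    fcoords = np.array([frac.x, frac.y, frac.z]) % 1.0
    dims = np.array(dmap.shape)
    u = fcoords * dims
    i0 = np.floor(u).astype(int)
    f = u - i0
    i0 %= dims
    i1 = (i0 + 1) % dims
    g = dmap.grid
    c00 = g[i0[0], i0[1], i0[2]] * (1 - f[0]) + g[i1[0], i0[1], i0[2]] * f[0]
    c10 = g[i0[0], i1[1], i0[2]] * (1 - f[0]) + g[i1[0], i1[1], i0[2]] * f[0]
    c01 = g[i0[0], i0[1], i1[2]] * (1 - f[0]) + g[i1[0], i0[1], i1[2]] * f[0]
    c11 = g[i0[0], i1[1], i1[2]] * (1 - f[0]) + g[i1[0], i1[1], i1[2]] * f[0]
    c0 = c00 * (1 - f[1]) + c10 * f[1]
    c1 = c01 * (1 - f[1]) + c11 * f[1]
    return float(c0 * (1 - f[2]) + c1 * f[2])


def atom_fit_score(
    rho: float, proton_number: int, map_mean: float, map_sd: float
) -> float:
    """-ln Phi(z) fit score for one atom (natural log).

    rho is first normalized by the proton number; z is its deviation
    from the map mean in map-SD units.  Larger scores mean poorer fit.
    """
    if map_sd <= 0:
        raise DegenerateMapError("map SD is zero; fit scores are undefined")
    if proton_number < 1:
        raise ValueError("proton_number must be >= 1")
    z = (rho / proton_number - map_mean) / map_sd
    p = max(float(ndtr(z)), _TINY)
    return -float(np.log(p))


def residue_fit_scores(
    residue: Residue,
    dmap: DensityMap,
    include_hydrogens: bool = False,
) -> ResidueFitScores:
    """Mean atom fit scores: all atoms, backbone subset, side chain."""
    all_scores: list[float] = []
    backbone: list[float] = []
    side_chain: list[float] = []
    for atom in residue.atoms:
        if atom.is_hydrogen and not include_hydrogens:
            continue
        rho = density_at(dmap, atom.position)
        score = atom_fit_score(rho, atom.proton_number, dmap.mean, dmap.sd)
        all_scores.append(score)
        (backbone if atom.name in BACKBONE_ATOMS else side_chain).append(score)

    def _mean(values: list[float]) -> float | None:
        return float(np.mean(values)) if values else None

    return ResidueFitScores(
        all_atoms=_mean(all_scores),
        backbone=_mean(backbone),
        side_chain=_mean(side_chain),
    )


# ---------------------------------------------------------------------------
# I/O: plain-text reflection dialect, MTZ, CCP4 maps


def write_reflections_text(refl: ReflectionSet, path) -> None:
    """Write the documented plain-text (h k l F phi) dialect."""
    with open(path, "w") as fh:
        fh.write(
            "# CELL %.4f %.4f %.4f %.3f %.3f %.3f\n"
            % (
                refl.cell.a,
                refl.cell.b,
                refl.cell.c,
                refl.cell.alpha,
                refl.cell.beta,
                refl.cell.gamma,
            )
        )
        fh.write(f"# RESOLUTION {refl.d_min:.4f}\n")
        if refl.grid_shape is not None:
            fh.write("# GRID %d %d %d\n" % tuple(refl.grid_shape))
        for (h, k, l), amp, phi in zip(refl.hkl, refl.amplitude, refl.phase_deg):
            fh.write(f"{h} {k} {l} {amp:.8g} {phi:.8g}\n")


def read_reflections_text(path) -> ReflectionSet:
    """Read the plain-text (h k l F phi) dialect."""
    cell = None
    d_min = None
    grid_shape = None
    hkl, amps, phases = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "CELL":
                    cell = gemmi.UnitCell(*(float(x) for x in parts[1:7]))
                elif parts and parts[0] == "RESOLUTION":
                    d_min = float(parts[1])
                elif parts and parts[0] == "GRID":
                    grid_shape = tuple(int(x) for x in parts[1:4])
                continue
            h, k, l, amp, phi = line.split()
            hkl.append((int(h), int(k), int(l)))
            amps.append(float(amp))
            phases.append(float(phi))
    if cell is None or d_min is None:
        raise ValueError(f"reflection file {path!r} lacks CELL/RESOLUTION headers")
    return ReflectionSet(
        hkl=np.array(hkl),
        amplitude=np.array(amps),
        phase_deg=np.array(phases),
        cell=cell,
        d_min=d_min,
        grid_shape=grid_shape,
    )


def read_mtz_reflections(
    path, amplitude_col: str = "FWT", phase_col: str = "PHWT"
) -> ReflectionSet:
    """Read amplitude/phase columns (map coefficients) from an MTZ file."""
    mtz = gemmi.read_mtz_file(str(path))
    data = np.array(mtz, copy=False)
    labels = [col.label for col in mtz.columns]
    try:
        fi = labels.index(amplitude_col)
        pi = labels.index(phase_col)
    except ValueError as exc:
        raise ValueError(
            f"MTZ lacks requested columns {amplitude_col!r}/{phase_col!r}; "
            f"available: {labels}"
        ) from exc
    hkl = data[:, 0:3].astype(int)
    amps = data[:, fi]
    phases = data[:, pi]
    ok = np.isfinite(amps) & np.isfinite(phases)
    return ReflectionSet(
        hkl=hkl[ok],
        amplitude=amps[ok],
        phase_deg=phases[ok],
        cell=mtz.cell,
        d_min=mtz.resolution_high(),
    )


def read_ccp4_map(path) -> DensityMap:
    """Read a precomputed CCP4 map as the density source."""
    ccp4 = gemmi.read_ccp4_map(str(path), setup=True)
    grid = ccp4.grid
    arr = np.array(grid, copy=True)
    return DensityMap(grid=arr, cell=grid.unit_cell)
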