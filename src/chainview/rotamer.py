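"""Side-chain (rotamer) conformation scoring and classification.

Two complementary routes are implemented:

* a **continuous score** from per-rotamer "central values" — each chi
  dimension of each recognized rotamer is modelled as a Gaussian; the
  score is the minimum over rotamers of the quadratic mean of the
  per-dimension z-scores.  0 means a chi set sitting exactly on some
  rotamer's means; 1 means, loosely, one standard deviation away.

* a **discrete classification** from contour grids over chi space.
  Rotamericity percentages are thresholded once (<= 0.3% outlier,
  >= 2.0% favored, else allowed; unobserved lattice points are a fourth
  "unknown" state), each grid is flattened row-major so a chi vector maps
  to a single calculable flat index, the four states are packed four to
  a byte (2 bits each) and the whole library is gzip-compressed.  Load
  is a single decompress + reshape, so lookups avoid any interpolation
  or tree search at run time.
"""

from __future__ import annotations

import gzip
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ConformationClass

__all__ = [
    "CentralValuesEntry",
    "ContourGrid",
    "CompressedLibrary",
    "ChiMismatchError",
    "LibraryBuildError",
    "LibraryLoadError",
    "DEFAULT_ROTAMER_THRESHOLDS",
    "CHI_PERIODS",
    "wrap_degrees",
    "rotamer_score",
    "grid_index",
    "classify_rotamer",
    "pack_states",
    "unpack_states",
    "compress_library",
    "decompress_library",
    "load_central_values",
    "load_contour_grid_text",
]

#: Rotamericity thresholds in percent: (outlier_max, favored_min).
#: Values at or below the first are outliers; at or above the second,
#: favored; in between, allowed.  Matched to the MolProbity convention.
DEFAULT_ROTAMER_THRESHOLDS = (0.3, 2.0)

#: Torsion period per chi angle, degrees.  The terminal chi of the
#: two-fold symmetric side chains repeats every 180 degrees.
CHI_PERIODS: dict[str, tuple[float, ...]] = {
    "ASP": (360.0, 180.0),
    "GLU": (360.0, 360.0, 180.0),
    "PHE": (360.0, 180.0),
    "TYR": (360.0, 180.0),
}

_STATE_TO_CLASS = {
    0: ConformationClass.UNKNOWN,
    1: ConformationClass.OUTLIER,
    2: ConformationClass.ALLOWED,
    3: ConformationClass.FAVORED,
}

_MAGIC = b"CVROTLIB1\n"


class ChiMismatchError(ValueError):
    """Chi angle count does not match the reference data's dimensions."""


class LibraryBuildError(RuntimeError):
    """Raised when raw contour-grid input cannot be compressed."""


class LibraryLoadError(RuntimeError):
    """Raised when a compressed library payload is corrupt."""


def wrap_degrees(delta, period: float = 360.0):
    """Wrap an angle difference into (-period/2, period/2]."""
    wrapped = np.asarray(delta, dtype=float) % period
    half = period / 2.0
    wrapped = np.where(wrapped > half, wrapped - period, wrapped)
    return float(wrapped) if np.ndim(delta) == 0 else wrapped


def nint(x: float) -> int:
    """Nearest integer, rounding halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CentralValuesEntry:
    """Mean and SD of every chi angle for one recognized rotamer."""

    residue_type: str
    rotamer_name: str
    chi_means: tuple[float, ...]
    chi_sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.chi_means) != len(self.chi_sds) or len(self.chi_means) < 1:
            raise ValueError("chi_means and chi_sds must have equal length >= 1")
        if any(sd <= 0 for sd in self.chi_sds):
            raise ValueError("all chi SDs must be positive")

    @property
    def n_chi(self) -> int:
        return len(self.chi_means)


def rotamer_score(
    chis: list[float] | tuple[float, ...],
    entries: list[CentralValuesEntry],
    periods: tuple[float, ...] | None = None,
) -> float:
    """Continuous rotamer score: min over rotamers of the RMS z-score.

    For each rotamer i the per-dimension z-score is the wrapped chi
    deviation over the rotamer's SD; the rotamer's score is
    sqrt(mean(z^2)) and the residue's score is the minimum over all
    recognized rotamers.  Angle differences wrap periodically (360° by
    default, or per-chi ``periods``).
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    n = entries[0].n_chi
    if len(chis) != n:
        raise ChiMismatchError(
            f"{len(chis)} chi angles given, reference has {n} dimensions"
        )
    chis_arr = np.asarray(chis, dtype=float)
    if periods is None:
        periods = (360.0,) * n
    best = math.inf
    for entry in entries:
        if entry.n_chi != n:
            raise ChiMismatchError("inconsistent chi dimensions across rotamers")
        z2 = 0.0
        for x, mu, sd, period in zip(chis_arr, entry.chi_means, entry.chi_sds, periods):
            z = wrap_degrees(x - mu, period) / sd
            z2 += z * z
        best = min(best, math.sqrt(z2 / n))
    return best


@dataclass
class ContourGrid:
    """A flattened chi-space classification lattice for one residue type.

    ``values`` holds one 2-bit state per lattice point (0 unknown,
    1 outlier, 2 allowed, 3 favored) in row-major order: the flat index
    of lattice coordinate (i_1 .. i_N) is sum_n i_n * prod(sizes[n+1:]).
    """

    residue_type: str
    axis_origins: tuple[float, ...]
    axis_spacings: tuple[float, ...]
    axis_sizes: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        n = len(self.axis_origins)
        if not (len(self.axis_spacings) == len(self.axis_sizes) == n):
            raise ValueError("axis metadata lengths disagree")
        total = int(np.prod(self.axis_sizes))
        if self.values.size != total:
            raise ValueError(
                f"values length {self.values.size} != lattice size {total}"
            )
        if self.values.size and self.values.max() > 3:
            raise ValueError("states must lie in [0, 3]")

    @property
    def n_dims(self) -> int:
        return len(self.axis_origins)

    @property
    def n_points(self) -> int:
        return int(self.values.size)


def grid_index(chis: list[float] | tuple[float, ...], grid: ContourGrid) -> int:
    """Flat index of the lattice node nearest to a chi vector.

    Per dimension the node is nint((chi - origin) / spacing), wrapped
    periodically into [0, size); indices combine row-major.
    """
    if len(chis) != grid.n_dims:
        raise ChiMismatchError(
            f"{len(chis)} chi angles given, grid is {grid.n_dims}-D"
        )
    index = 0
    stride = grid.n_points
    for chi, origin, spacing, size in zip(
        chis, grid.axis_origins, grid.axis_spacings, grid.axis_sizes
    ):
        stride //= size
        i = nint((chi - origin) / spacing) % size
        index += i * stride
    return index


def classify_rotamer(
    chis: list[float] | tuple[float, ...], grid: ContourGrid
) -> ConformationClass:
    """Discrete rotamer class of the lattice node nearest to ``chis``."""
    return _STATE_TO_CLASS[int(grid.values[grid_index(chis, grid)])]


def pack_states(states: np.ndarray) -> bytes:
    """Pack 2-bit states four to a byte.

    Point j occupies bits 2*(j mod 4) .. 2*(j mod 4)+1 of byte j // 4,
    little-end-first within the byte.  The payload is exactly
    ceil(len(states)/4) bytes.
    """
    states = np.asarray(states, dtype=np.uint8)
    if states.size and states.max() > 3:
        raise ValueError("states must lie in [0, 3]")
    n_bytes = (states.size + 3) // 4
    padded = np.zeros(n_bytes * 4, dtype=np.uint8)
    padded[: states.size] = states
    quads = padded.reshape(-1, 4)
    packed = (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    )
    return packed.astype(np.uint8).tobytes()


def unpack_states(payload: bytes, n_points: int) -> np.ndarray:
    """Inverse of :func:`pack_states` for a declared point count."""
    if len(payload) < (n_points + 3) // 4:
        raise LibraryLoadError(
            f"payload truncated: {len(payload)} bytes cannot hold {n_points} states"
        )
    raw = np.frombuffer(payload, dtype=np.uint8)
    states = np.empty(len(payload) * 4, dtype=np.uint8)
    states[0::4] = raw & 0b11
    states[1::4] = (raw >> 2) & 0b11
    states[2::4] = (raw >> 4) & 0b11
    states[3::4] = (raw >> 6) & 0b11
    return states[:n_points]


def threshold_rotamericity(
    value: float, thresholds: tuple[float, float] = DEFAULT_ROTAMER_THRESHOLDS
) -> int:
    """Map a rotamericity percentage to a 2-bit state (1/2/3)."""
    outlier_max, favored_min = thresholds
    if value <= outlier_max:
        return 1
    if value >= favored_min:
        return 3
    return 2


@dataclass
class CompressedLibrary:
    """Header metadata plus one gzip stream of packed 2-bit grids."""

    headers: dict[str, dict]  # residue_type -> axis metadata + offsets
    order: list[str]  # residue types in payload order
    payload: bytes  # gzip of the concatenated packed grids

    def to_bytes(self) -> bytes:
        header_json = json.dumps(
            {"order": self.order, "headers": self.headers},
            sort_keys=True,
            separators=(",", ":"),
        ).encode()
        return (
            _MAGIC
            + len(header_json).to_bytes(8, "little")
            + header_json
            + self.payload
        )

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CompressedLibrary":
        if not blob.startswith(_MAGIC):
            raise LibraryLoadError("bad magic bytes: not a rotamer library file")
        offset = len(_MAGIC)
        header_len = int.from_bytes(blob[offset : offset + 8], "little")
        offset += 8
        try:
            meta = json.loads(blob[offset : offset + header_len].decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise LibraryLoadError(f"corrupt library header: {exc}") from exc
        return cls(
            headers=meta["headers"],
            order=meta["order"],
            payload=blob[offset + header_len :],
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_bytes())

    @classmethod
    def read(cls, path: str | Path) -> "CompressedLibrary":
        return cls.from_bytes(Path(path).read_bytes())


RawGrids = dict[str, tuple[dict, dict[tuple[float, ...], float]]]


def compress_library(
    raw_grids: RawGrids,
    thresholds: tuple[float, float] = DEFAULT_ROTAMER_THRESHOLDS,
    lattice_tol: float = 1e-6,
) -> CompressedLibrary:
    """Threshold, flatten, bit-pack and gzip a raw contour-grid library.

    ``raw_grids`` maps residue type to (axis metadata, sparse mapping of
    chi coordinates to rotamericity percent).  Axis metadata must carry
    ``origins``, ``spacings`` and ``sizes``.  Lattice points absent from
    the sparse mapping become state 0 (unknown).  Coordinates that do
    not sit on the declared lattice are a fatal build error.
    """
    headers: dict[str, dict] = {}
    order = sorted(raw_grids)
    chunks: list[bytes] = []
    offset = 0
    for rtype in order:
        meta, sparse = raw_grids[rtype]
        origins = tuple(float(x) for x in meta["origins"])
        spacings = tuple(float(x) for x in meta["spacings"])
        sizes = tuple(int(x) for x in meta["sizes"])
        n_points = int(np.prod(sizes))
        states = np.zeros(n_points, dtype=np.uint8)
        grid = ContourGrid(rtype, origins, spacings, sizes, states)
        for coords, value in sparse.items():
            if len(coords) != len(sizes):
                raise LibraryBuildError(
                    f"{rtype}: coordinate {coords} has wrong dimensionality"
                )
            for c, o, sp in zip(coords, origins, spacings):
                steps = (c - o) / sp
                if abs(steps - nint(steps)) > lattice_tol:
                    raise LibraryBuildError(
                        f"{rtype}: coordinate {coords} is off-lattice"
                    )
            states[grid_index(coords, grid)] = threshold_rotamericity(
                float(value), thresholds
            )
        packed = pack_states(states)
        headers[rtype] = {
            "origins": list(origins),
            "spacings": list(spacings),
            "sizes": list(sizes),
            "offset": offset,
            "n_bytes": len(packed),
        }
        chunks.append(packed)
        offset += len(packed)
    payload = gzip.compress(b"".join(chunks), mtime=0)
    return CompressedLibrary(headers=headers, order=order, payload=payload)


def decompress_library(lib: CompressedLibrary) -> dict[str, ContourGrid]:
    """Exact inverse of :func:`compress_library`'s packing."""
    try:
        raw = gzip.decompress(lib.payload)
    except (OSError, EOFError, zlib.error) as exc:
        raise LibraryLoadError(f"corrupt gzip payload: {exc}") from exc
    grids: dict[str, ContourGrid] = {}
    for rtype in lib.order:
        meta = lib.headers[rtype]
        sizes = tuple(int(x) for x in meta["sizes"])
        n_points = int(np.prod(sizes))
        start = int(meta["offset"])
        end = start + int(meta["n_bytes"])
        if end > len(raw):
            raise LibraryLoadError(
                f"payload truncated while reading grid for {rtype}"
            )
        states = unpack_states(raw[start:end], n_points)
        grids[rtype] = ContourGrid(
            residue_type=rtype,
            axis_origins=tuple(float(x) for x in meta["origins"]),
            axis_spacings=tuple(float(x) for x in meta["spacings"]),
            axis_sizes=sizes,
            values=states,
        )
    return grids


def load_central_values(path: str | Path) -> dict[str, list[CentralValuesEntry]]:
    """Load central-values tables from the documented CSV dialect.

    Rows: ``residue,rotamer,mean1,sd1[,mean2,sd2,...]``; comment lines
    start with '#'.
    """
    entries: dict[str, list[CentralValuesEntry]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            rtype, rname = parts[0], parts[1]
            numbers = [float(p) for p in parts[2:] if p != ""]
            means = tuple(numbers[0::2])
            sds = tuple(numbers[1::2])
            entries.setdefault(rtype, []).append(
                CentralValuesEntry(rtype, rname, means, sds)
            )
    return entries


def load_contour_grid_text(path: str | Path) -> tuple[str, dict, dict]:
    """Load one raw contour grid from the documented text format.

    Header comments declare residue type and axis metadata; data rows
    are whitespace- or comma-separated chi coordinates followed by the
    rotamericity percentage.  Returns (residue_type, axis_meta, sparse).
    """
    meta_raw: dict[str, str] = {}
    sparse: dict[tuple[float, ...], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta_raw[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            *coords, value = (float(p) for p in parts)
            sparse[tuple(coords)] = value
    rtype = meta_raw["residue"]
    meta = {
        "origins": [float(x) for x in meta_raw["origins"].split()],
        "spacings": [float(x) for x in meta_raw["spacings"].split()],
        "sizes": [int(x) for x in meta_raw["sizes"].split()],
    }
    return rtype, meta, sparse
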