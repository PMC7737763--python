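"""The per-residue metrics cascade.

Walks a parsed model chain by chain, computes every metric for each
amino-acid residue (B-factor statistics, backbone torsions + the
Ramachandran probability and class, the continuous rotamer score and
discrete rotamer class, density-fit scores when a map is available) and
contextualizes the continuous values against the percentile library.
The result, one :class:`MetricsRecord` per residue, is the unit of
display for the report module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import density as density_mod
from . import geometry, percentiles, rotamer
from .model_io import Residue, StructureModel, is_amino_acid

__all__ = ["CHI_ATOMS", "MetricsRecord", "ReferenceSet", "measure_chis", "analyse_model"]

#: Atom quadruples defining each chi torsion, per residue type.
#: chi_k is the torsion over atoms (k-1 .. k+2) of the listed path
#: N, CA, CB, <gamma>, <delta>, ...
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


@dataclass
class MetricsRecord:
    """Everything computed for one residue — the report's display unit."""

    chain_id: str
    seq_num: int
    insertion_code: str
    name: str
    bfactor: geometry.BFactorStats | None = None
    phi: float | None = None
    psi: float | None = None
    rama_probability: float | None = None
    rama_class: geometry.ConformationClass = geometry.ConformationClass.UNKNOWN
    rotamer_score: float | None = None
    rotamer_class: geometry.ConformationClass | None = None  # None = no chis
    fit: density_mod.ResidueFitScores | None = None
    percentiles: dict[str, int] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    missing: bool = False

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.seq_num}{self.insertion_code}"

    def continuous_metrics(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.bfactor is not None:
            out["b_mean"] = self.bfactor.mean
            out["b_max"] = self.bfactor.maximum
        if self.rama_probability is not None:
            out["rama_prob"] = self.rama_probability
        if self.rotamer_score is not None:
            out["rotamer_score"] = self.rotamer_score
        if self.fit is not None:
            if self.fit.all_atoms is not None:
                out["fit_all"] = self.fit.all_atoms
            if self.fit.side_chain is not None:
                out["fit_side"] = self.fit.side_chain
        return out


@dataclass
class ReferenceSet:
    """Pluggable reference data consumed by the cascade."""

    rama_tables: dict[str, geometry.RamaTable] = field(default_factory=dict)
    rama_thresholds: tuple[float, float] = geometry.DEFAULT_RAMA_THRESHOLDS
    central_values: dict[str, list[rotamer.CentralValuesEntry]] = field(
        default_factory=dict
    )
    contour_grids: dict[str, rotamer.ContourGrid] = field(default_factory=dict)
    percentile_library: percentiles.PercentileLibrary | None = None
    allow_het: frozenset[str] = frozenset()
    include_hydrogens: bool = False

    @classmethod
    def default(cls) -> "ReferenceSet":
        """Reference set from the synthetic data shipped with the package."""
        from pathlib import Path

        data_dir = Path(__file__).parent / "data"
        central = {}
        cv_path = data_dir / "central_values_synthetic.csv"
        if cv_path.exists():
            central = rotamer.load_central_values(cv_path)
        grids = {}
        raw: rotamer.RawGrids = {}
        for path in sorted(data_dir.glob("contour_*_synthetic.txt")):
            rtype, meta, sparse = rotamer.load_contour_grid_text(path)
            raw[rtype] = (meta, sparse)
        if raw:
            grids = rotamer.decompress_library(rotamer.compress_library(raw))
        try:
            plib = percentiles.load_default_percentile_library()
        except FileNotFoundError:
            plib = None
        return cls(
            rama_tables=geometry.load_default_rama_tables(),
            central_values=central,
            contour_grids=grids,
            percentile_library=plib,
        )


def measure_chis(residue: Residue) -> tuple[list[float] | None, bool]:
    """Measure the chi torsions of a residue from its atoms.

    Returns (chis, complete).  ``chis`` is None for residue types with
    no chi angles (GLY, ALA, non-standard); ``complete`` is False when
    any defining atom is missing, in which case the measured prefix is
    returned but should be flagged "incomplete" by the caller.
    """
    quads = CHI_ATOMS.get(residue.name)
    if not quads:
        return None, True
    chis: list[float] = []
    for quad in quads:
        atoms = [residue.atom(name) for name in quad]
        if any(a is None for a in atoms):
            return (chis if chis else None), False
        angle = geometry.dihedral_angle(*(a.position for a in atoms))
        if angle is None:
            return (chis if chis else None), False
        chis.append(angle)
    return chis, True


def _analyse_residue(
    chain, index: int, refs: ReferenceSet, dmap
) -> MetricsRecord:
    residue = chain.residues[index]
    record = MetricsRecord(
        chain_id=chain.chain_id,
        seq_num=residue.seq_num,
        insertion_code=residue.insertion_code,
        name=residue.name,
    )
    record.bfactor = geometry.bfactor_summary(
        residue, include_hydrogens=refs.include_hydrogens
    )
    if record.bfactor is None:
        record.flags.add("no-atoms")

    record.phi, record.psi = geometry.backbone_torsions(chain, index)
    if record.phi is not None and record.psi is not None and refs.rama_tables:
        next_res = (
            chain.residues[index + 1] if index + 1 < len(chain.residues) else None
        )
        category = geometry.rama_category(residue, next_res)
        table = refs.rama_tables.get(category) or refs.rama_tables.get("general")
        if table is not None:
            record.rama_probability = geometry.rama_probability(
                record.phi, record.psi, table
            )
            record.rama_class = geometry.rama_classify(
                record.rama_probability, refs.rama_thresholds
            )

    chis, complete = measure_chis(residue)
    if residue.name in CHI_ATOMS:
        if not complete:
            record.flags.add("incomplete-side-chain")
            record.rotamer_class = geometry.ConformationClass.UNKNOWN
        elif chis is not None:
            periods = rotamer.CHI_PERIODS.get(residue.name)
            entries = refs.central_values.get(residue.name)
            if entries:
                try:
                    record.rotamer_score = rotamer.rotamer_score(
                        chis, entries, periods
                    )
                except rotamer.ChiMismatchError:
                    record.flags.add("chi-mismatch")
            grid = refs.contour_grids.get(residue.name)
            if grid is not None and grid.n_dims == len(chis):
                record.rotamer_class = rotamer.classify_rotamer(chis, grid)
            else:
                record.rotamer_class = geometry.ConformationClass.UNKNOWN

    if dmap is not None and not dmap.is_degenerate:
        record.fit = density_mod.residue_fit_scores(
            residue, dmap, include_hydrogens=refs.include_hydrogens
        )
    return record


def analyse_model(
    model: StructureModel,
    dmap: density_mod.DensityMap | None = None,
    refs: ReferenceSet | None = None,
) -> dict[str, list[MetricsRecord]]:
    """Run the full cascade: one MetricsRecord per amino-acid residue.

    Percentiles (when a percentile library is configured) are looked up
    at the model's resolution, or against the all-data entry when the
    resolution is unknown, and stored on the higher-is-better display
    convention.
    """
    if refs is None:
        refs = ReferenceSet()
    results: dict[str, list[MetricsRecord]] = {}
    for chain in model.chains:
        records = []
        for index, residue in enumerate(chain.residues):
            if not is_amino_acid(residue, refs.allow_het):
                continue
            record = _analyse_residue(chain, index, refs, dmap)
            if refs.percentile_library is not None:
                for metric, value in record.continuous_metrics().items():
                    try:
                        record.percentiles[metric] = percentiles.display_percentile(
                            refs.percentile_library, metric, value, model.resolution
                        )
                    except percentiles.UnknownMetricError:
                        pass
            records.append(record)
        if records:
            results[chain.chain_id] = records
    return results
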