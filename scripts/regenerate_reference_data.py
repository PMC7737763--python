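"""Regenerate the synthetic reference data shipped with the package.

The shipped Ramachandran grids, rotamer central values / contour grids
and percentile library are synthetic stand-ins with realistic shapes,
produced deterministically by the fixtures module.  Rerun this script
after changing the generators:

    python scripts/regenerate_reference_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chainview import fixtures, percentiles  # noqa: E402

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "chainview" / "data"

RAMA_BASINS = {
    # (phi0, psi0, height, width_deg) rows per category
    "general": [(-57.0, -47.0, 0.5, 25.0), (-120.0, 135.0, 0.4, 30.0),
                (58.0, 45.0, 0.05, 18.0)],
    "GLY": [(-57.0, -47.0, 0.35, 30.0), (-120.0, 135.0, 0.3, 35.0),
            (57.0, 47.0, 0.35, 30.0), (120.0, -135.0, 0.3, 35.0)],
    "PRO": [(-60.0, -35.0, 0.5, 15.0), (-60.0, 150.0, 0.4, 15.0)],
    "pre-PRO": [(-57.0, -47.0, 0.35, 22.0), (-120.0, 135.0, 0.45, 28.0)],
    "ILE_VAL": [(-62.0, -45.0, 0.45, 20.0), (-115.0, 130.0, 0.45, 25.0)],
}


def write_rama_tables() -> None:
    for category, basins in RAMA_BASINS.items():
        table = fixtures.synthetic_rama_table(category, step=15.0, basins=basins)
        path = DATA_DIR / f"rama_{category}_synthetic.csv"
        with open(path, "w") as fh:
            fh.write("# synthetic ramachandran probability grid\n")
            fh.write(f"# category: {category}\n")
            fh.write("# phi_origin: -180.0\n# psi_origin: -180.0\n")
            fh.write("# phi_step: 15.0\n# psi_step: 15.0\n")
            fh.write("# phi_n: 24\n# psi_n: 24\n")
            fh.write("phi,psi,probability\n")
            n = table.grid.shape[0]
            for i in range(n):
                for j in range(n):
                    phi = -180.0 + 15.0 * i
                    psi = -180.0 + 15.0 * j
                    fh.write(f"{phi:.1f},{psi:.1f},{table.grid[i, j]:.5f}\n")
        print("wrote", path)


def write_rotamer_reference() -> None:
    central, raw = fixtures.synthetic_rotamer_reference(
        seed=7, residue_types={"SER": 1, "LEU": 2}, step=10.0
    )
    cv_path = DATA_DIR / "central_values_synthetic.csv"
    with open(cv_path, "w") as fh:
        fh.write("# synthetic rotamer central values\n")
        fh.write("# residue,rotamer,mean1,sd1[,mean2,sd2,...]\n")
        for rtype in sorted(central):
            for e in central[rtype]:
                nums = ",".join(
                    f"{m:.2f},{s:.2f}" for m, s in zip(e.chi_means, e.chi_sds)
                )
                fh.write(f"{rtype},{e.rotamer_name},{nums}\n")
    print("wrote", cv_path)
    for rtype, (meta, sparse) in raw.items():
        path = DATA_DIR / f"contour_{rtype}_synthetic.txt"
        with open(path, "w") as fh:
            fh.write("# synthetic rotamericity contour grid\n")
            fh.write(f"# residue: {rtype}\n")
            fh.write("# origins: " + " ".join(str(x) for x in meta["origins"]) + "\n")
            fh.write("# spacings: " + " ".join(str(x) for x in meta["spacings"]) + "\n")
            fh.write("# sizes: " + " ".join(str(x) for x in meta["sizes"]) + "\n")
            for coords in sorted(sparse):
                row = " ".join(f"{c:.1f}" for c in coords)
                fh.write(f"{row} {sparse[coords]:.4f}\n")
        print("wrote", path)


def write_percentile_library() -> None:
    records = fixtures.synthetic_percentile_records(seed=11, n_per_metric=4000)
    lib = percentiles.build_percentile_library(
        records, provenance="synthetic stand-in (seeded generator)"
    )
    # shipped defaults only need coarse precision; keeps the file small
    for table in [*lib.bins, lib.all_data]:
        for metric in table:
            table[metric] = np.round(table[metric], 4)
    path = DATA_DIR / "percentiles_synthetic.json"
    lib.write(path)
    print("wrote", path)


if __name__ == "__main__":
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_rama_tables()
    write_rotamer_reference()
    write_percentile_library()
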