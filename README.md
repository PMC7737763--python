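# chainview

Per-residue validation metrics for protein models, presented as a
compact, interactive radial **chain-view** report.

During iterative model building and refinement, crystallographers need
to see — at a glance, for every residue of every chain — where a model
is geometrically implausible or fits its electron density poorly.
`chainview` computes the common per-residue validation metrics itself,
places them on a shared percentile scale, and renders them as one
radial SVG diagram per chain: one angular segment per residue, one
concentric ring per metric, with a toggle that animates between two
model iterations so the effect of a refinement round is immediately
visible.

## Metrics

For each amino-acid residue the cascade computes:

* **B-factor statistics** — minimum, maximum, mean and population SD of
  the atomic B-factors (Å²).
* **Backbone conformation** — (φ, ψ) torsions, a probability from a
  category-specific Ramachandran grid (general / Gly / Pro / pre-Pro /
  Ile-Val), and a favored / allowed / outlier class from configurable
  thresholds (defaults 0.02 / 0.002).
* **Side-chain conformation** — a continuous rotamer score from
  per-rotamer "central values":

      score = min_i sqrt( (1/N) Σ_n ((χ_n − μ_in) / σ_in)² )

  i.e. the minimum over recognized rotamers *i* of the quadratic mean of
  per-chi z-scores, with angle differences wrapped periodically; plus a
  discrete class looked up in a compressed chi-space contour grid.
  Rotamericity percentages are thresholded once (≤ 0.3 % outlier,
  ≥ 2.0 % favored, unobserved points "unknown"), flattened row-major so
  a chi vector maps to a single computable index

      index = Σ_n nint((χ_n − Χ_n0) / Δ_n) · Π_{m>n} dim(Χ_m),

  packed four 2-bit states per byte and gzip-compressed — loading is a
  single decompress, lookup is an array access.
* **Density fit** — a map is synthesized from amplitude/phase structure
  factors by FFT (or read from a CCP4 map); each atom scores
  `−ln Φ((ρ/Z − μ_map)/σ_map)` where Φ is the standard normal CDF, ρ the
  interpolated density at the atom and Z its proton number. Residue
  scores are means over all atoms, the backbone set {N, CA, C, O, OXT}
  and the side chain.

Continuous metrics are contextualized by a **percentile library**:
empirical thresholds at every integer percentile, in ten non-uniform
resolution bins plus an unbinned entry for models of unknown
resolution.

Two model iterations are collated by global pairwise sequence
alignment (Needleman–Wunsch, deterministic tie-breaks), so both fit in
one graphic even when chains were renamed or residues added; alignment
gaps appear as black "missing residue" spots at the rim.

## Worked example

Generate a small synthetic model plus matching reflection data, then
build a report:

```
$ chainview fixtures --seed 7 --residues 10 --sequence ASVLG --with-reflections -o inputs
inputs/model.pdb
inputs/reflections.txt
$ chainview report -l inputs/model.pdb --reflections inputs/reflections.txt -o report_out
report_out/report.html
```

or equivalently from Python:

```python
from chainview import generate_report

summary = generate_report(
    latest_model_path="inputs/model.pdb",
    latest_reflections_path="inputs/reflections.txt",
    output_dir="report_out",
    mode="full",
)
```

`report_out/report.html` is a single self-contained file; opening it
shows the radial chain-view and the residue-view panel.  The run
summary reports one chain of 10 residues at 2.0 Å with density fit
enabled.  Inspecting one residue's record directly:

```python
from chainview.model_io import read_model
from chainview.metrics import ReferenceSet, analyse_model
from chainview.density import read_reflections_text, map_from_reflections

model = read_model("inputs/model.pdb")
dmap = map_from_reflections(read_reflections_text("inputs/reflections.txt"))
record = analyse_model(model, dmap, ReferenceSet.default())["A"][3]
print(record.label, record.name)      # A/4 LEU
print(record.phi, record.psi)         # -57.0 -47.0   (helical fixture)
print(record.rama_class)              # favored
print(record.fit.all_atoms)           # 0.0545  (low score = good fit)
print(record.percentiles)             # e.g. {'b_mean': 95, 'fit_all': 99, ...}
```

Percentiles are reported on a higher-is-better convention: this
residue's B-factors and density fit rank in the high 90s against the
reference distributions, while its backbone sits squarely in the
favored alpha-helical basin.  Note that the reference tables shipped
with the package (Ramachandran grids, rotamer library, percentile
library) are *synthetic stand-ins* with realistic shapes — useful for
testing and demonstration; drop in real reference files for production
use (`ReferenceSet` accepts any tables in the documented formats, and
`chainview build-rotamer-lib` / `build-percentiles` rebuild the
compressed libraries from raw data).

## Layout

* `src/chainview/model_io.py` — PDB parsing into a typed hierarchy
* `src/chainview/geometry.py` — B-factors, torsions, Ramachandran
* `src/chainview/rotamer.py` — rotamer score + compressed contour grids
* `src/chainview/density.py` — map synthesis and fit scoring
* `src/chainview/percentiles.py` — resolution-binned percentile library
* `src/chainview/compare.py` — chain pairing and sequence alignment
* `src/chainview/metrics.py` — the per-residue cascade
* `src/chainview/report.py` — SVG chain-view / residue-view, HTML report
* `src/chainview/fixtures.py` — synthetic models, maps, reference data
* `src/chainview/cli.py` — the `chainview` command

See `docs/methods.md` for the models, conventions and numerical choices.
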