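# Methods

This note records the models implemented in `chainview`, the
conventions and defaults chosen where the design was genuinely open,
and what the synthetic test data do and do not establish.

## Model parsing

Coordinates are parsed with gemmi and flattened into a typed
chain → residue → atom hierarchy. Decisions:

* **Altlocs.** Per-residue metrics must be single-valued, so one
  conformer is kept per atom name: highest occupancy, ties broken by
  file order.
* **Amino-acid gate.** A residue is analyzable iff its name is one of
  the 20 canonical codes and N, CA, C are all present. HETATM residues
  (e.g. MSE) are excluded unless allow-listed
  (`ReferenceSet.allow_het`), because the reference libraries cover
  only the canonical types.
* **Hydrogens** are parsed but excluded from B-factor and density-fit
  aggregation by default (`include_hydrogens=True` to change): the
  scores should reflect experiment-resolved atoms.
* Only the first MODEL block of a multi-model file is read; the report
  is per-iteration, not per-NMR-model.
* Residue identity is (chain id, author seq number, insertion code).

## Backbone geometry

φ(i) uses C(i−1)–N(i)–CA(i)–C(i); ψ(i) uses N(i)–CA(i)–C(i)–N(i+1);
IUPAC sign convention, range [−180, 180). A peptide C–N distance above
**2.5 Å** is treated as a chain break and suppresses the torsions that
span it — a standard sanity bound on a bonded peptide. Degenerate
(collinear) quadruples yield an absent angle, never an exception.

Ramachandran probabilities come from per-category grids (general, GLY,
PRO, pre-PRO, ILE/VAL; pre-PRO wins over the name-based categories
except GLY/PRO themselves) interpolated bilinearly on the periodic
torsion torus. Classification thresholds default to
**favored ≥ 0.02, allowed ≥ 0.002** — the exact values used by other
packages are not published, so they are configurable everywhere
(`ReferenceSet.rama_thresholds`).

## Rotamer analysis

The continuous score models each chi dimension of each recognized
rotamer as a Gaussian: per-dimension z-scores of the wrapped deviation
from the rotamer's mean over its SD, combined by quadratic mean, then
minimized over all recognized rotamers. Units are "standard deviations
from the nearest rotamer": 0 = dead center, 1 ≈ one SD out. All
recognized rotamers are evaluated (no pruning). Chi angles are
periodic over 360°, except the terminal chi of the two-fold symmetric
side chains (ASP, GLU, PHE, TYR), periodic over 180°.

The discrete classification uses contour grids of empirical
rotamericity over chi space, thresholded once at build time:
**≤ 0.3 % → outlier, ≥ 2.0 % → favored**, in between → allowed, and a
fourth **unknown** state for lattice points absent from the raw data.
Grids are flattened row-major; the flat index of a chi vector is

    index = Σ_n nint((χ_n − origin_n) / spacing_n) · Π_{m>n} size_m

with `nint` rounding halves **away from zero** (the raw data never
place values at exact half-grid offsets, so the choice only matters
for robustness) and out-of-range nodes wrapped modulo the axis size —
valid because each axis spans a full period.

States are packed four per byte: point *j* occupies bits
2·(j mod 4)..2·(j mod 4)+1 of byte ⌊j/4⌋, little end first; the
concatenated payload is gzip-compressed behind a small JSON header
(axis origins/spacings/sizes and byte offsets per residue type, after
versioned magic bytes). Decompression restores every state exactly;
the pre-gzip footprint is exactly ⌈points/4⌉ bytes. Loading is one
gzip decompress plus array reshapes.

Residues whose chi set cannot be fully measured (missing side-chain
atoms) get an absent score and an `incomplete-side-chain` flag;
residue types with no chi angles (GLY, ALA) get no rotamer fields at
all rather than a misleading "unknown".

## Density fit

Maps are synthesized from amplitude/phase coefficients (2mFo−DFc-style
coefficients are expected to be combined upstream; no sigma-A weighting
happens here) by placing each coefficient and its Friedel mate on an
FFT grid: ρ(x) = (1/V) Σ F e^{iφ} e^{−2πi h·x}. The grid spacing is
d_min/(2·sampling) with sampling = 1.5 by default, i.e. the
conventional d_min/3 rate. If both a CCP4 map and reflections are
given, the map file wins — resynthesis differences should never be
silent.

The atom score is −ln Φ(z) with z = (ρ/Z − μ_map)/σ_map: the density
at the atom (trilinear, periodic) normalized by proton number, then
standardized against the **raw** map's mean and SD (the literal reading
of the formula; normalizing the whole map first would only rescale
μ, σ). Natural log; Φ is clamped at machine-tiny before the log so the
score stays finite in pathological density. ln 2 ≈ 0.693 therefore
means "sitting at exactly mean density"; smaller is better. Residue
scores are plain means over all non-hydrogen atoms, the backbone set
{N, CA, C, O, OXT}, and the rest (side chain); empty subsets are
absent, not zero. A constant (DC-only) map is flagged degenerate and
produces no fit scores.

## Percentile library

Per metric and per resolution bin, thresholds at integer percentiles
1–99 are empirical quantiles with linear interpolation between order
statistics (numpy's default, the type-7 rule) — chosen so regeneration
is reproducible. Default bin edges (Å): 1.0, 1.3, 1.5, 1.8, 2.0, 2.3,
2.5, 3.0, 4.0 → ten bins; the count is fixed by design, the edges ship
as data and are configurable. An unbinned all-data entry serves models
of unknown resolution, and bins left empty for a metric fall back to
it at query time. A query returns the largest percentile whose
threshold the value reaches (0 below the first).

Raw percentiles are rank positions of the metric's own distribution;
the report displays them on a single **higher-is-better** convention,
flipping metrics whose polarity is higher-is-worse (B-factors, fit
scores, rotamer score). The flip happens in exactly one place
(`percentiles.display_percentile`).

## Two-iteration collation

Chains pair by identical id first; leftovers pair greedily by best
global alignment score (ties broken by chain id), so pairing is
independent of chain order. Alignment is Needleman–Wunsch on
one-letter sequences (non-standard residues map to 'X', scoring 0
against anything) with match +1, mismatch −1, gap −2, configurable;
dynamic-program ties prefer diagonal, then up, making the traceback —
and therefore the whole report — deterministic. One alignment column
becomes one angular position; the gap side carries a missing marker.
No coordinate-based superposition or renumbering heuristics are
applied: alignment is the mechanism, author numbering is display
metadata.

## Report rendering

Ring order (inner → outer) defaults to: Ramachandran class, rotamer
class, mean B, max B, all-atom fit, side-chain fit — discrete rings as
traffic-light wedges, continuous rings as radial line graphs. The
first residue sits at 12 o'clock, angles grow clockwise, and a small
fixed gap (14°) stays free for the selector arm's rest position.

Continuous values are min–max scaled within the chain (optionally the
whole model), flipped where higher is worse so poor values always
point inward, and skewed by r^γ with **γ = 2** by default so the poor
end of the axis is visually exaggerated. An all-constant ring renders
at full radius: nothing to emphasize. Positions whose value is absent
take the ring's median radius and are additionally marked; missing
residues get black spots at the rim.

The "unknown" rotamer state is colored like an outlier (flagging
conservatively) but keeps its own class token, so counts remain
separable. Inapplicable (no-chi) residues get a neutral color instead.

Both versions' ring geometries are embedded in the SVG; the toggle
animates a linear interpolation between them (500 ms, 20 steps), with
an instant swap under `prefers-reduced-motion`. The document exposes
`selectResidue(chainIndex, positionIndex)` and `toggleVersion()` as
plain script hooks, and every segment carries a stable element id, so
host GUIs can drive the panel or link residues to a 3D viewer.

Reports are emitted as one self-contained HTML file. The full mode
appends per-chain summary tables (residue counts, outlier counts,
metric means); the minimized mode contains only the graphical panel
for iframe or direct insertion. CSS is namespaced under `.cv-root` in
both modes. Legacy compatibility mode mechanically rewrites the
interaction script (const/let → var, arrows → function expressions);
the template deliberately avoids any other modern syntax so the
rewrite is total. Rendering contains no timestamps and no randomness:
identical inputs give byte-identical output.

## Synthetic data

The fixtures module builds polypeptides by internal-coordinate (NeRF)
placement from a small table of ideal bond lengths and angles — only
torsions vary, so stated (φ, ψ, χ) are recovered to numerical
precision (~1e-12°; PDB files round to 1e-3 Å, which costs ~0.05°).
Side-chain coverage is the small set needed for chi measurement tests
(SER, VAL, CYS, THR, LEU, ASP, LYS plus ALA/GLY). Maps are sums of
per-atom Gaussians (amplitude ∝ Z, σ = d_min/3) with optional seeded
white noise; their forward FFT yields an exactly consistent reflection
set. Synthetic rotamer references plant Gaussian basins at seeded
centers so ground-truth classifications are known for every lattice
point; synthetic Ramachandran tables place analytic basins (alpha at
(−57, −47), beta at (−120, 135)).

These generators emulate the *shapes* of real data, not its content:
passing tests demonstrate that the metric formulas, the compression
pipeline, the percentile machinery and the rendering contracts behave
correctly, but say nothing about agreement with real Top8000 or
PDB-REDO-derived references, which must be supplied by the user for
production use. The shipped default reference files are generated by
`scripts/regenerate_reference_data.py` and are labelled `synthetic` in
their filenames.

Problem sizes in the test suite are deliberately modest — models of
6–12 residues, maps of ~10⁴–10⁵ grid points, libraries of a few
thousand records, plus a 1,200-residue render to exercise the
chain-view's high-count regime — chosen to probe every contract while
keeping the suite quick to run.

## Known limitations

* No bond-length/angle/planarity/chirality outlier detection, no
  clash analysis of our own (external per-residue flags can be
  ingested and displayed).
* Density synthesis supports amplitude+phase coefficients only; no
  sigma-A weighting, no EDSTATS-style RSR/RSCC, no cryo-EM box maps.
* The fit score is intentionally simple (one density sample per atom);
  it discriminates misplaced residues but is not a substitute for full
  real-space correlation.
* Percentile quality is only as good as the record stream the library
  was built from; the shipped library is synthetic.
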