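"""End-to-end report generation: the package's one-call entry point.

``generate_report`` runs the full cascade — coordinate parsing, metric
calculation (geometry, rotamer, density fit when experimental data are
supplied), percentile normalization, two-iteration collation by
sequence alignment — and writes the HTML report plus a machine-readable
run summary into the output directory.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import yaml

from . import compare, density, report
from .metrics import MetricsRecord, ReferenceSet, analyse_model
from .model_io import StructureModel, read_model

__all__ = ["generate_report", "load_config"]


def load_config(path) -> report.ChainViewConfig:
    """Build a ChainViewConfig from a YAML file of overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "ring_order" in raw:
        kwargs["ring_order"] = tuple(
            (str(m), str(k)) for m, k in raw["ring_order"]
        )
    for key in ("gamma", "scale_scope", "selector_position", "animation_ms",
                "gap_degrees", "inner_radius", "outer_radius"):
        if key in raw:
            kwargs[key] = raw[key]
    config = report.ChainViewConfig(**kwargs)
    if "colors" in raw:
        config.colors.update(raw["colors"])
    if "polarity" in raw:
        config.polarity.update(raw["polarity"])
    return config


def _load_density(
    map_path, reflections_path, amplitude_col, phase_col, warnings: list[str]
):
    """Map-file input wins over reflections; failures warn, never abort."""
    if map_path:
        try:
            return density.read_ccp4_map(map_path)
        except Exception as exc:  # noqa: BLE001 - surfaced as a warning
            warnings.append(f"unreadable map file {map_path!r}: {exc}")
            return None
    if reflections_path:
        path = str(reflections_path)
        try:
            if path.lower().endswith(".mtz"):
                refl = density.read_mtz_reflections(path, amplitude_col, phase_col)
            else:
                refl = density.read_reflections_text(path)
            return density.map_from_reflections(refl)
        except Exception as exc:  # noqa: BLE001
            warnings.append(f"unreadable reflections {path!r}: {exc}")
            return None
    return None


def generate_report(
    latest_model_path,
    previous_model_path=None,
    latest_reflections_path=None,
    previous_reflections_path=None,
    latest_map_path=None,
    previous_map_path=None,
    output_dir="chainview_out",
    mode: str = "full",
    compat: str = "modern",
    config=None,
    amplitude_col: str = "FWT",
    phase_col: str = "PHWT",
    refs: ReferenceSet | None = None,
    verbose: bool = False,
) -> dict:
    """Generate a validation report bundle on disk.

    Returns the run summary dict (also written as run_summary.json
    beside the report).  Reflections/maps are optional: without them
    the density-fit rings are simply omitted.  With a previous-model
    path the report gains the two-iteration toggle.
    """
    timings: dict[str, float] = {}
    warnings: list[str] = []
    t0 = time.perf_counter()

    latest = read_model(latest_model_path)
    previous = read_model(previous_model_path) if previous_model_path else None
    timings["parse"] = time.perf_counter() - t0

    if refs is None:
        refs = ReferenceSet.default()

    t1 = time.perf_counter()
    map_latest = _load_density(
        latest_map_path, latest_reflections_path, amplitude_col, phase_col, warnings
    )
    map_previous = _load_density(
        previous_map_path, previous_reflections_path, amplitude_col, phase_col,
        warnings,
    ) if previous is not None else None
    timings["density"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    metrics_latest = analyse_model(latest, map_latest, refs)
    metrics_previous = (
        analyse_model(previous, map_previous, refs) if previous is not None else None
    )
    timings["metrics"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    collated: dict[str, list[tuple[MetricsRecord | None, MetricsRecord | None]]] = {}
    two_versions = metrics_previous is not None
    if metrics_previous is None:
        for chain_id, records in metrics_latest.items():
            collated[chain_id] = [(rec, None) for rec in records]
    else:
        pairs, unpaired_latest, unpaired_previous = compare.pair_chains(
            latest, previous
        )
        for pair in pairs:
            collated[pair.chain_id_latest] = compare.collate_positions(
                pair,
                metrics_latest[pair.chain_id_latest],
                metrics_previous[pair.chain_id_previous],
            )
        for chain_id in unpaired_latest:
            collated[chain_id] = [
                (rec, None) for rec in metrics_latest[chain_id]
            ]
        if unpaired_previous:
            warnings.append(
                "chains only in the previous model were not displayed: "
                + ", ".join(unpaired_previous)
            )
    timings["collate"] = time.perf_counter() - t3

    chain_config = (
        load_config(config) if isinstance(config, (str, Path))
        else (config or report.ChainViewConfig())
    )
    t4 = time.perf_counter()
    html = report.build_report(
        collated,
        config=chain_config,
        mode=mode,
        compat=compat,
        two_versions=two_versions,
    )
    timings["render"] = time.perf_counter() - t4

    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.html"
    report_path.write_text(html)

    summary = {
        "report": str(report_path),
        "mode": mode,
        "compat": compat,
        "two_versions": two_versions,
        "chains": {cid: len(pos) for cid, pos in collated.items()},
        "n_residues_latest": sum(
            len(records) for records in metrics_latest.values()
        ),
        "resolution": latest.resolution,
        "density_fit": map_latest is not None,
        "warnings": warnings,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    if verbose:  # pragma: no cover - logging cosmetics
        for stage, seconds in timings.items():
            print(f"[chainview] {stage}: {seconds:.3f} s")
        for warning in warnings:
            print(f"[chainview] warning: {warning}")
    return summary
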