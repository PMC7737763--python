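"""Resolution-binned integer-percentile normalization of metrics.

Raw metric values (B-factors in Å², fit scores in -ln-probability units,
Ramachandran probabilities ...) are incommensurable; displaying them on
one graphic requires a common scale.  The library stores, for each
metric and each of ten non-uniform resolution bins (plus an unbinned
"all data" entry for models of unknown resolution), the empirical
threshold at every integer percentile 1..99.  Querying a value returns
the largest percentile whose threshold it reaches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PercentileLibrary",
    "UnknownMetricError",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_POLARITY",
    "build_percentile_library",
    "percentile_of",
    "display_percentile",
    "load_default_percentile_library",
]

#: Default resolution bin edges in Å: nine ascending edges → ten bins.
DEFAULT_BIN_EDGES = (1.0, 1.3, 1.5, 1.8, 2.0, 2.3, 2.5, 3.0, 4.0)

#: higher-is-worse flag per built-in metric.
DEFAULT_POLARITY = {
    "b_mean": True,
    "b_max": True,
    "fit_all": True,
    "fit_side": True,
    "rama_prob": False,
    "rotamer_score": True,
}

PERCENTILE_LEVELS = np.arange(1, 100)


class UnknownMetricError(KeyError):
    """Queried metric is not present in the percentile library."""


@dataclass
class PercentileLibrary:
    """Integer-percentile thresholds per metric per resolution bin."""

    bin_edges: tuple[float, ...]
    bins: list[dict[str, np.ndarray]]  # len == len(bin_edges) + 1
    all_data: dict[str, np.ndarray]
    polarity: dict[str, bool] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.bin_edges) + 1:
            raise ValueError("bin count must be len(bin_edges) + 1")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def metrics(self) -> list[str]:
        return sorted(self.all_data)

    def bin_index(self, resolution: float) -> int:
        """Route a resolution to its bin (last bin is open-ended)."""
        return int(np.searchsorted(self.bin_edges, resolution, side="right"))

    def thresholds_for(self, metric: str, resolution: float | None) -> np.ndarray:
        if metric not in self.all_data:
            raise UnknownMetricError(metric)
        if resolution is not None:
            bin_thresholds = self.bins[self.bin_index(resolution)]
            if metric in bin_thresholds:  # empty bins fall back to all-data
                return bin_thresholds[metric]
        return self.all_data[metric]

    # --- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "version": 1,
            "bin_edges": list(self.bin_edges),
            "bins": [
                {m: [float(v) for v in t] for m, t in b.items()} for b in self.bins
            ],
            "all_data": {m: [float(v) for v in t] for m, t in self.all_data.items()},
            "polarity": self.polarity,
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PercentileLibrary":
        payload = json.loads(text)
        return cls(
            bin_edges=tuple(payload["bin_edges"]),
            bins=[
                {m: np.asarray(t, float) for m, t in b.items()}
                for b in payload["bins"]
            ],
            all_data={
                m: np.asarray(t, float) for m, t in payload["all_data"].items()
            },
            polarity=payload.get("polarity", {}),
            provenance=payload.get("provenance", ""),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "PercentileLibrary":
        return cls.from_json(Path(path).read_text())


def build_percentile_library(
    records,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    polarity: dict[str, bool] | None = None,
    provenance: str = "",
) -> PercentileLibrary:
    """Build a library from a stream of (metric, value, resolution) records.

    Records are routed to resolution bins; per bin and metric, empirical
    quantiles at percentiles 1..99 are taken with linear interpolation
    between order statistics (the type-7 rule).  Bins left empty for a
    metric are simply absent, and queries for them fall back to the
    all-data entry.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly ascending")
    n_bins = len(edges) + 1
    per_bin: list[dict[str, list[float]]] = [dict() for _ in range(n_bins)]
    pooled: dict[str, list[float]] = {}
    for metric, value, resolution in records:
        value = float(value)
        pooled.setdefault(metric, []).append(value)
        if resolution is not None and np.isfinite(resolution):
            idx = int(np.searchsorted(edges, float(resolution), side="right"))
            per_bin[idx].setdefault(metric, []).append(value)

    def quantiles(values: list[float]) -> np.ndarray:
        return np.quantile(
            np.asarray(values, float), PERCENTILE_LEVELS / 100.0, method="linear"
        )

    bins = [
        {metric: quantiles(vals) for metric, vals in bin_data.items() if vals}
        for bin_data in per_bin
    ]
    all_data = {metric: quantiles(vals) for metric, vals in pooled.items() if vals}
    return PercentileLibrary(
        bin_edges=edges,
        bins=bins,
        all_data=all_data,
        polarity=dict(DEFAULT_POLARITY if polarity is None else polarity),
        provenance=provenance,
    )


def percentile_of(
    lib: PercentileLibrary,
    metric: str,
    value: float,
    resolution: float | None = None,
) -> int:
    """Largest percentile whose threshold the value reaches (0..99).

    A value below the 1st-percentile threshold maps to 0.  An absent or
    unusable resolution bin falls back to the all-data entry.
    """
    thresholds = lib.thresholds_for(metric, resolution)
    return int(np.searchsorted(thresholds, value, side="right"))


def display_percentile(
    lib: PercentileLibrary,
    metric: str,
    value: float,
    resolution: float | None = None,
) -> int:
    """Percentile on the report's higher-is-better convention.

    Where the metric's polarity is higher-is-worse (B-factors, fit
    scores) the raw rank is flipped, so 99 always means "among the
    best".  This is the single place the flip happens.
    """
    p = percentile_of(lib, metric, value, resolution)
    if lib.polarity.get(metric, False):
        return 100 - p
    return p


def load_default_percentile_library() -> PercentileLibrary:
    """Load the synthetic percentile library shipped with the package."""
    path = Path(__file__).parent / "data" / "percentiles_synthetic.json"
    return PercentileLibrary.read(path)
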