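"""SVG chain-view / residue-view rendering and HTML report assembly.

The chain-view is a radial diagram: one angular segment per residue
(per alignment position when two model iterations are shown), one
concentric ring per metric.  Discrete rings (Ramachandran and rotamer
class) use traffic-light wedge coloring; continuous rings (B-factors,
density fit) are radial line graphs whose polarity always points poorer
values inward, exaggerated by a skew exponent so trouble spots dip
visibly toward the center.  Missing residues (gaps of the alignment)
are marked with black spots at the rim.

Rendering is deterministic: identical inputs and configuration produce
byte-identical output — no timestamps, no randomness.
"""

from __future__ import annotations

import json
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .geometry import ConformationClass
from .metrics import MetricsRecord

__all__ = [
    "ChainViewConfig",
    "axis_transform",
    "chain_view_svg",
    "residue_view_svg",
    "build_report",
    "to_legacy_js",
    "MODERN_JS_TOKENS",
]

#: Default ring order, innermost first: two discrete conformation rings,
#: then the four continuous rings.
DEFAULT_RING_ORDER: tuple[tuple[str, str], ...] = (
    ("rama", "discrete"),
    ("rotamer", "discrete"),
    ("b_mean", "continuous"),
    ("b_max", "continuous"),
    ("fit_all", "continuous"),
    ("fit_side", "continuous"),
)

DEFAULT_COLORS = {
    "favored": "#2e9e5b",
    "allowed": "#e8a33d",
    "outlier": "#d64045",
    "unknown": "#d64045",  # unknown is flagged as loudly as an outlier
    "na": "#cfd8dc",
    "missing": "#111111",
    "continuous": "#3a6ea5",
    "continuous_prev": "#9bb8d3",
    "selector": "#37474f",
    "flag": "#8e24aa",
}

METRIC_TITLES = {
    "rama": "Ramachandran",
    "rotamer": "Rotamer",
    "b_mean": "Mean B-factor",
    "b_max": "Max B-factor",
    "fit_all": "Density fit (all atoms)",
    "fit_side": "Density fit (side chain)",
}


@dataclass
class ChainViewConfig:
    ring_order: tuple[tuple[str, str], ...] = DEFAULT_RING_ORDER
    inner_radius: float = 130.0
    outer_radius: float = 420.0
    polarity: dict[str, bool] = field(
        default_factory=lambda: {
            "b_mean": True, "b_max": True, "fit_all": True, "fit_side": True,
            "rama_prob": False, "rotamer_score": True,
        }
    )
    gamma: float = 2.0
    scale_scope: str = "chain"  # chain | model
    colors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    selector_position: int = 0
    animation_ms: int = 500
    gap_degrees: float = 14.0

    def __post_init__(self) -> None:
        if not self.ring_order:
            raise ValueError("ring order must be non-empty")
        if not self.outer_radius > self.inner_radius:
            raise ValueError("radii must be strictly increasing")
        if self.gamma <= 0:
            raise ValueError("skew exponent gamma must be positive")


def axis_transform(
    values,
    higher_is_worse: bool,
    gamma: float = 2.0,
    minmax: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map raw metric values to radial fractions in [0, 1].

    Values are min-max scaled (within the chain unless an explicit
    ``minmax`` from a wider scope is given), flipped when higher is
    worse so poorer values always point inward, then skewed by
    ``r ** gamma`` (gamma > 1 exaggerates the poor end).  Non-finite
    entries stay NaN for the caller to flag.  All-constant input maps
    to 1.0 everywhere: no trough to show.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        return np.full(arr.shape, np.nan)
    if minmax is not None:
        vmin, vmax = minmax
    else:
        vmin = float(arr[finite].min())
        vmax = float(arr[finite].max())
    out = np.full(arr.shape, np.nan)
    if vmax == vmin:
        out[finite] = 1.0
        return out
    scaled = (arr[finite] - vmin) / (vmax - vmin)
    if higher_is_worse:
        scaled = 1.0 - scaled
    out[finite] = np.clip(scaled, 0.0, 1.0) ** gamma
    return out


# ---------------------------------------------------------------------------
# chain-view


def _unit(theta_deg: float) -> tuple[float, float]:
    # theta 0 at 12 o'clock, increasing clockwise (SVG y points down)
    rad = math.radians(theta_deg - 90.0)
    return math.cos(rad), math.sin(rad)


def _point(cx: float, cy: float, r: float, theta: float) -> tuple[float, float]:
    ux, uy = _unit(theta)
    return round(cx + r * ux, 2), round(cy + r * uy, 2)


def _wedge_path(cx, cy, r_lo, r_hi, t0, t1) -> str:
    large = 1 if (t1 - t0) > 180.0 else 0
    x0, y0 = _point(cx, cy, r_hi, t0)
    x1, y1 = _point(cx, cy, r_hi, t1)
    x2, y2 = _point(cx, cy, r_lo, t1)
    x3, y3 = _point(cx, cy, r_lo, t0)
    return (
        f"M {x0} {y0} A {r_hi} {r_hi} 0 {large} 1 {x1} {y1} "
        f"L {x2} {y2} A {r_lo} {r_lo} 0 {large} 0 {x3} {y3} Z"
    )


def _class_token(cls: ConformationClass | None) -> str:
    return "na" if cls is None else cls.value


def _ring_values(records, metric: str) -> np.ndarray:
    values = []
    for rec in records:
        if rec is None:
            values.append(np.nan)
        else:
            values.append(rec.continuous_metrics().get(metric, np.nan))
    return np.asarray(values, dtype=float)


def _radii_for(records, metric, config, band, model_minmax=None) -> np.ndarray:
    r_lo, r_hi = band
    values = _ring_values(records, metric)
    fracs = axis_transform(
        values,
        config.polarity.get(metric, True),
        config.gamma,
        minmax=model_minmax,
    )
    if np.isnan(fracs).all():
        return np.full(len(records), np.nan)
    median = float(np.nanmedian(fracs))
    fracs = np.where(np.isnan(fracs), median, fracs)
    return r_lo + fracs * (r_hi - r_lo)


def chain_view_svg(
    positions: list[tuple[MetricsRecord | None, MetricsRecord | None]],
    config: ChainViewConfig | None = None,
    chain_id: str = "",
    chain_index: int = 0,
    two_versions: bool = False,
    model_minmax: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Render the radial chain-view as a standalone SVG document.

    ``positions`` carries one (latest, previous) record pair per
    alignment position; None marks a residue missing from that version.
    Both versions' ring geometries are embedded so the toggle animation
    can interpolate between them client-side.
    """
    if not positions:
        raise ValueError("need at least one position")
    config = config or ChainViewConfig()
    n = len(positions)
    cx = cy = 500.0
    colors = config.colors
    gap = config.gap_degrees
    sweep = (360.0 - gap) / n
    t_start = gap / 2.0  # gap centered at 12 o'clock

    def theta(i: float) -> float:
        return t_start + i * sweep

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "viewBox": "0 0 1000 1000",
            "class": "cv-chain-view",
            "data-chain-id": chain_id,
            "data-n-positions": str(n),
        },
    )
    rings = config.ring_order
    band_width = (config.outer_radius - config.inner_radius) / len(rings)

    latest = [a for a, _ in positions]
    previous = [b for _, b in positions]

    for ri, (metric, kind) in enumerate(rings):
        r_lo = config.inner_radius + ri * band_width
        r_hi = r_lo + band_width * 0.92  # thin spacer between rings
        group = ET.SubElement(
            svg, "g", {"class": f"cv-ring cv-ring-{kind}", "data-metric": metric}
        )
        if kind == "discrete":
            for i, (rec_a, rec_b) in enumerate(positions):
                cls_a = _class_token(
                    None if rec_a is None else (
                        rec_a.rama_class if metric == "rama" else rec_a.rotamer_class
                    )
                )
                cls_b = _class_token(
                    None if rec_b is None else (
                        rec_b.rama_class if metric == "rama" else rec_b.rotamer_class
                    )
                )
                attrs = {
                    "d": _wedge_path(cx, cy, r_lo, r_hi, theta(i), theta(i + 1)),
                    "class": f"seg {metric} {cls_a}",
                    "fill": colors.get(cls_a, colors["na"]),
                    "data-class-a": cls_a,
                    "data-fill-a": colors.get(cls_a, colors["na"]),
                }
                if two_versions:
                    attrs["data-class-b"] = cls_b
                    attrs["data-fill-b"] = colors.get(cls_b, colors["na"])
                ET.SubElement(group, "path", attrs)
        else:
            minmax = (model_minmax or {}).get(metric)
            radii_a = _radii_for(latest, metric, config, (r_lo, r_hi), minmax)
            if np.isnan(radii_a).all():
                continue  # metric absent for the whole chain (e.g. no map)
            pts_a = " ".join(
                "%s,%s" % _point(cx, cy, r, theta(i + 0.5))
                for i, r in enumerate(radii_a)
            )
            attrs = {
                "points": pts_a,
                "class": f"cv-line {metric}",
                "fill": "none",
                "stroke": colors["continuous"],
                "stroke-width": "2",
                "data-pa": pts_a,
            }
            if two_versions:
                radii_b = _radii_for(previous, metric, config, (r_lo, r_hi), minmax)
                if not np.isnan(radii_b).all():
                    attrs["data-pb"] = " ".join(
                        "%s,%s" % _point(cx, cy, r, theta(i + 0.5))
                        for i, r in enumerate(radii_b)
                    )
            ET.SubElement(group, "polyline", attrs)

    # rim: missing-residue spots and external flags
    rim = config.outer_radius + 14.0
    marker_group = ET.SubElement(svg, "g", {"class": "cv-rim"})
    for i, (rec_a, rec_b) in enumerate(positions):
        x, y = _point(cx, cy, rim, theta(i + 0.5))
        if rec_a is None or (two_versions and rec_b is None):
            side = "a" if rec_a is None else "b"
            ET.SubElement(
                marker_group,
                "circle",
                {
                    "cx": str(x), "cy": str(y), "r": "4",
                    "class": f"missing-marker v-{side}",
                    "fill": colors["missing"],
                },
            )
        rec = rec_a or rec_b
        if rec is not None and rec.flags & {"clash", "flip"}:
            ET.SubElement(
                marker_group,
                "circle",
                {
                    "cx": str(x), "cy": str(y), "r": "5",
                    "class": "flag-marker " + " ".join(
                        sorted(f"flag-{f}" for f in rec.flags & {"clash", "flip"})
                    ),
                    "fill": "none",
                    "stroke": colors["flag"],
                    "stroke-width": "2",
                },
            )

    # residue selector arm + per-position hit wedges (anchors for hosts)
    sel = min(max(config.selector_position, 0), n - 1)
    ax, ay = _point(cx, cy, config.outer_radius + 8, theta(sel + 0.5))
    ET.SubElement(
        svg,
        "line",
        {
            "x1": str(cx), "y1": str(cy), "x2": str(ax), "y2": str(ay),
            "class": "cv-selector-arm",
            "id": f"cv-arm-{chain_index}",
            "stroke": colors["selector"],
            "stroke-width": "2.5",
            "data-angle-step": f"{sweep:.6f}",
            "data-angle-start": f"{t_start + 0.5 * sweep:.6f}",
        },
    )
    hits = ET.SubElement(svg, "g", {"class": "cv-hits"})
    for i, (rec_a, rec_b) in enumerate(positions):
        rec = rec_a or rec_b
        label = rec.label if rec is not None else f"{chain_id}/gap{i}"
        ET.SubElement(
            hits,
            "path",
            {
                "d": _wedge_path(
                    cx, cy, config.inner_radius, config.outer_radius + 10,
                    theta(i), theta(i + 1),
                ),
                "class": "cv-hit",
                "id": f"cv-res-{chain_index}-{i}",
                "data-label": label,
                "fill": "transparent",
                "onclick": f"selectResidue({chain_index},{i})",
            },
        )
    return ET.tostring(svg, encoding="unicode")


# ---------------------------------------------------------------------------
# residue-view


def _traffic_box(parent, x, y, metric, cls_token, colors):
    ET.SubElement(
        parent,
        "rect",
        {
            "x": str(x), "y": str(y), "width": "26", "height": "26", "rx": "5",
            "class": f"rv-box {metric} {cls_token}",
            "fill": colors.get(cls_token, colors["na"]),
        },
    )
    ET.SubElement(
        parent,
        "text",
        {"x": str(x + 36), "y": str(y + 18), "class": "rv-box-label"},
    ).text = METRIC_TITLES.get(metric, metric)


def residue_view_svg(
    record: MetricsRecord,
    chain_distributions: dict[str, tuple[float, float, float, float]],
    layout: str = "default",
    config: ChainViewConfig | None = None,
) -> str:
    """Render the residue-view for one record.

    ``chain_distributions`` maps each continuous metric to the
    (min, max, mean, sd) of its percentile values within the chain.
    The default layout shows traffic-light boxes for the discrete
    classes and one percentile bar per continuous metric (bar extent =
    chain min..max, dashed lines at mean and mean±SD, marker at the
    residue's percentile).  The radar layout places every metric on the
    percentile scale as a polygon vertex with a hover bubble.
    """
    config = config or ChainViewConfig()
    colors = config.colors
    if layout == "radar":
        return _radar_svg(record, colors)
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "viewBox": "0 0 420 560",
            "class": "cv-residue-view",
        },
    )
    title = ET.SubElement(svg, "text", {"x": "20", "y": "34", "class": "rv-title",
                                        "id": "rv-title"})
    title.text = f"{record.label} {record.name}"
    _traffic_box(svg, 20, 60, "rama", _class_token(record.rama_class), colors)
    _traffic_box(svg, 20, 100, "rotamer", _class_token(record.rotamer_class), colors)

    bar_metrics = [m for m, kind in config.ring_order if kind == "continuous"]
    bar_top, bar_bottom = 180.0, 520.0
    bar_h = bar_bottom - bar_top
    x = 40.0
    step = 90.0

    def y_of(p: float) -> float:
        return round(bar_bottom - (p / 100.0) * bar_h, 2)

    for metric in bar_metrics:
        group = ET.SubElement(svg, "g", {"class": "rv-bar", "data-metric": metric})
        ET.SubElement(group, "text", {
            "x": str(x - 6), "y": str(bar_bottom + 24), "class": "rv-bar-label",
        }).text = METRIC_TITLES.get(metric, metric)
        dist = chain_distributions.get(metric)
        if dist is not None:
            dmin, dmax, dmean, dsd = dist
            ET.SubElement(group, "rect", {
                "x": str(x), "y": str(y_of(dmax)), "width": "30",
                "height": str(max(round(y_of(dmin) - y_of(dmax), 2), 0.5)),
                "class": "rv-spectrum", "fill": "#e3ecf3",
            })
            for tag, p in (("mean", dmean), ("sd-lo", dmean - dsd),
                           ("sd-hi", dmean + dsd)):
                p = min(max(p, 0.0), 100.0)
                ET.SubElement(group, "line", {
                    "x1": str(x - 4), "x2": str(x + 34),
                    "y1": str(y_of(p)), "y2": str(y_of(p)),
                    "class": f"rv-dash rv-dash-{tag}",
                    "stroke": "#546e7a", "stroke-dasharray": "4 3",
                })
        p_res = record.percentiles.get(metric)
        if p_res is not None:
            ET.SubElement(group, "rect", {
                "x": str(x - 2), "y": str(y_of(p_res) - 2.5),
                "width": "34", "height": "5",
                "class": "rv-marker", "id": f"rv-marker-{metric}",
                "fill": colors["continuous"],
            })
            ET.SubElement(group, "text", {
                "x": str(x), "y": str(bar_top - 10),
                "class": "rv-percentile", "id": f"rv-pct-{metric}",
            }).text = str(p_res)
        x += step
    return ET.tostring(svg, encoding="unicode")


def _radar_svg(record: MetricsRecord, colors) -> str:
    metrics = sorted(record.percentiles)
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "viewBox": "0 0 420 420",
            "class": "cv-residue-view cv-radar",
            "data-n-metrics": str(len(metrics)),
        },
    )
    cx = cy = 210.0
    radius = 150.0
    k = max(len(metrics), 1)

    def vertex(i: int, r: float) -> tuple[float, float]:
        ang = math.radians(360.0 * i / k - 90.0)
        return round(cx + r * math.cos(ang), 2), round(cy + r * math.sin(ang), 2)

    for level in (20, 40, 60, 80, 100):
        pts = " ".join("%s,%s" % vertex(i, radius * level / 100.0) for i in range(k))
        ET.SubElement(svg, "polygon", {
            "points": pts, "class": "radar-grid", "fill": "none",
            "stroke": "#b0bec5",
        })
    if metrics:
        pts = " ".join(
            "%s,%s" % vertex(i, radius * record.percentiles[m] / 100.0)
            for i, m in enumerate(metrics)
        )
        ET.SubElement(svg, "polygon", {
            "points": pts, "class": "radar-data",
            "fill": colors["continuous"], "fill-opacity": "0.35",
            "stroke": colors["continuous"],
        })
        raw = record.continuous_metrics()
        for i, m in enumerate(metrics):
            vx, vy = vertex(i, radius * record.percentiles[m] / 100.0)
            dot = ET.SubElement(svg, "circle", {
                "cx": str(vx), "cy": str(vy), "r": "6",
                "class": f"radar-dot {m}", "fill": colors["continuous"],
            })
            bubble = ET.SubElement(dot, "title")
            value = raw.get(m)
            value_txt = "n/a" if value is None else f"{value:.3f}"
            bubble.text = (
                f"{METRIC_TITLES.get(m, m)}: {value_txt} "
                f"(percentile {record.percentiles[m]})"
            )
            lx, ly = vertex(i, radius + 24)
            ET.SubElement(svg, "text", {
                "x": str(lx), "y": str(ly), "class": "radar-label",
                "text-anchor": "middle",
            }).text = METRIC_TITLES.get(m, m)
    return ET.tostring(svg, encoding="unicode")


# ---------------------------------------------------------------------------
# JS / CSS / HTML assembly

#: Modern-syntax tokens that must never appear in legacy-compat output.
MODERN_JS_TOKENS = ("const ", "let ", "=>", "class ", "async ", "await ", "`")

_JS_TEMPLATE = """
const cvState = {chain: 0, version: 'a', position: 0, animating: false};
const cvData = __CV_DATA__;

function cvById(id) { return document.getElementById(id); }

function selectChain(ci) {
  cvState.chain = ci;
  const views = document.querySelectorAll('.cv-chain-wrap');
  for (let i = 0; i < views.length; i++) {
    views[i].style.display = (i === ci) ? 'block' : 'none';
  }
  selectResidue(ci, 0);
}

function selectResidue(ci, pos) {
  cvState.position = pos;
  const arm = cvById('cv-arm-' + ci);
  if (arm) {
    const start = parseFloat(arm.getAttribute('data-angle-start'));
    const step = parseFloat(arm.getAttribute('data-angle-step'));
    arm.setAttribute('transform',
      'rotate(' + (step * pos) + ' 500 500)');
    void start;
  }
  const info = cvData.chains[ci].positions[pos];
  if (!info) { return; }
  const title = cvById('rv-title');
  if (title && info.label) {
    title.textContent = info.label + ' ' + (info.name || '');
  }
  const pcts = info.percentiles || {};
  for (const metric in pcts) {
    const marker = cvById('rv-marker-' + metric);
    const text = cvById('rv-pct-' + metric);
    if (marker) {
      const y = 520 - (pcts[metric] / 100) * 340;
      marker.setAttribute('y', (y - 2.5).toFixed(2));
    }
    if (text) { text.textContent = '' + pcts[metric]; }
  }
}

function cvLerpPoints(pa, pb, t) {
  const a = pa.split(' ');
  const b = pb.split(' ');
  const out = [];
  for (let i = 0; i < a.length; i++) {
    const pa2 = a[i].split(',');
    const pb2 = (b[i] || a[i]).split(',');
    const x = parseFloat(pa2[0]) * (1 - t) + parseFloat(pb2[0]) * t;
    const y = parseFloat(pa2[1]) * (1 - t) + parseFloat(pb2[1]) * t;
    out.push(x.toFixed(2) + ',' + y.toFixed(2));
  }
  return out.join(' ');
}

function cvApplyVersion(t) {
  const lines = document.querySelectorAll('.cv-line');
  for (let i = 0; i < lines.length; i++) {
    const pa = lines[i].getAttribute('data-pa');
    const pb = lines[i].getAttribute('data-pb');
    if (pa && pb) {
      lines[i].setAttribute('points', cvLerpPoints(pa, pb, t));
    }
  }
  const segs = document.querySelectorAll('.cv-ring-discrete path');
  for (let i = 0; i < segs.length; i++) {
    const fb = segs[i].getAttribute('data-fill-b');
    if (fb) {
      segs[i].setAttribute('fill',
        t >= 0.5 ? fb : segs[i].getAttribute('data-fill-a') ||
          segs[i].getAttribute('fill'));
    }
  }
}

function toggleVersion() {
  if (cvState.animating) { return; }
  const target = cvState.version === 'a' ? 1 : 0;
  const origin = 1 - target;
  cvState.version = target === 1 ? 'b' : 'a';
  const reduced = window.matchMedia &&
    window.matchMedia('(prefers-reduced-motion: reduce)').matches;
  if (reduced) { cvApplyVersion(target); return; }
  const duration = cvData.animationMs || 500;
  const steps = 20;
  let step = 0;
  cvState.animating = true;
  const timer = setInterval(function () {
    step += 1;
    const t = origin + (target - origin) * (step / steps);
    cvApplyVersion(t);
    if (step >= steps) {
      clearInterval(timer);
      cvState.animating = false;
    }
  }, duration / steps);
}

(function () {
  const toggle = cvById('cv-version-toggle');
  if (toggle) {
    toggle.addEventListener('change', toggleVersion);
  }
  const select = cvById('cv-chain-select');
  if (select) {
    select.addEventListener('change', function () {
      selectChain(parseInt(select.value, 10));
    });
  }
  selectResidue(0, cvData.selector || 0);
})();
"""

_CSS = """
.cv-root { font-family: Helvetica, Arial, sans-serif; color: #263238; }
.cv-root .cv-panel { display: flex; flex-wrap: wrap; gap: 16px; }
.cv-root .cv-chain-wrap { flex: 2 1 480px; }
.cv-root .cv-residue-wrap { flex: 1 1 280px; }
.cv-root svg text { font-size: 14px; }
.cv-root .rv-title { font-size: 20px; font-weight: bold; }
.cv-root .cv-hit { cursor: pointer; }
.cv-root .cv-hit:hover { fill: rgba(55, 71, 79, 0.12); }
.cv-root table.cv-summary { border-collapse: collapse; margin-top: 18px; }
.cv-root table.cv-summary td, .cv-root table.cv-summary th {
  border: 1px solid #b0bec5; padding: 4px 10px; }
.cv-root .cv-toggle-row { margin: 8px 0; }
.cv-root .cv-empty { font-size: 18px; padding: 40px; }
"""


def to_legacy_js(js: str) -> str:
    """Rewrite the controlled JS template into archaic-keyword form.

    Only constructs the template actually uses are rewritten: const/let
    declarations become var, single-expression arrow functions become
    function expressions, for-in const loops lose their const.
    """
    out = js.replace("const ", "var ").replace("let ", "var ")
    out = re.sub(r"\(([^()]*)\)\s*=>\s*\{", r"function(\1) {", out)
    return out


def _report_data(collated, config) -> dict:
    chains = []
    for chain_id in sorted(collated):
        positions = []
        for rec_a, rec_b in collated[chain_id]:
            rec = rec_a or rec_b
            if rec is None:
                positions.append(None)
            else:
                positions.append(
                    {
                        "label": rec.label,
                        "name": rec.name,
                        "percentiles": rec.percentiles,
                        "rama": _class_token(rec.rama_class),
                        "rotamer": _class_token(rec.rotamer_class),
                    }
                )
        chains.append({"id": chain_id, "positions": positions})
    return {
        "chains": chains,
        "animationMs": config.animation_ms,
        "selector": config.selector_position,
    }


def _chain_distributions(records) -> dict[str, tuple[float, float, float, float]]:
    per_metric: dict[str, list[float]] = {}
    for rec in records:
        if rec is None:
            continue
        for metric, value in rec.percentiles.items():
            per_metric.setdefault(metric, []).append(float(value))
    out = {}
    for metric, values in per_metric.items():
        arr = np.asarray(values)
        out[metric] = (
            float(arr.min()), float(arr.max()),
            float(arr.mean()), float(arr.std()),
        )
    return out


def _summary_section(collated) -> str:
    rows = []
    for chain_id in sorted(collated):
        records = [a for a, _ in collated[chain_id] if a is not None]
        n = len(records)
        rama_out = sum(
            1 for r in records
            if r.rama_class in (ConformationClass.OUTLIER, ConformationClass.UNKNOWN)
        )
        rot_out = sum(
            1 for r in records
            if r.rotamer_class in (ConformationClass.OUTLIER,
                                   ConformationClass.UNKNOWN)
        )
        b_values = [r.bfactor.mean for r in records if r.bfactor is not None]
        fits = [
            r.fit.all_atoms for r in records
            if r.fit is not None and r.fit.all_atoms is not None
        ]
        rows.append(
            "<tr><td>{}</td><td>{}</td><td>{}</td><td>{}</td>"
            "<td>{}</td><td>{}</td></tr>".format(
                chain_id, n, rama_out, rot_out,
                f"{np.mean(b_values):.2f}" if b_values else "–",
                f"{np.mean(fits):.3f}" if fits else "–",
            )
        )
    return (
        '<section class="cv-summary-section"><h2>Chain summaries</h2>'
        '<table class="cv-summary"><tr><th>Chain</th><th>Residues</th>'
        "<th>Ramachandran non-favored/unknown</th><th>Rotamer outliers/unknown</th>"
        "<th>Mean B (Å²)</th><th>Mean fit score</th></tr>"
        + "".join(rows)
        + "</table></section>"
    )


def build_report(
    collated: dict[str, list[tuple[MetricsRecord | None, MetricsRecord | None]]],
    config: ChainViewConfig | None = None,
    mode: str = "full",
    compat: str = "modern",
    two_versions: bool = False,
    title: str = "Model validation report",
) -> str:
    """Assemble the single-file HTML report.

    ``mode`` is "full" (graphical panel + summary sections) or
    "minimized" (panel only, for embedding).  ``compat`` "legacy"
    rewrites the interaction script with archaic keywords only and is
    safe for direct insertion into host pages (the CSS is namespaced in
    both modes).
    """
    if mode not in ("full", "minimized"):
        raise ValueError(f"unknown mode {mode!r}")
    if compat not in ("modern", "legacy"):
        raise ValueError(f"unknown compat {compat!r}")
    config = config or ChainViewConfig()

    if not collated or all(not pos for pos in collated.values()):
        body = '<div class="cv-root"><p class="cv-empty">' \
               "No analyzable protein chains were found in the input model(s)." \
               "</p></div>"
        return (
            "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
            f"<title>{title}</title><style>{_CSS}</style></head>"
            f"<body>{body}</body></html>"
        )

    chain_ids = sorted(collated)
    model_minmax = None
    if config.scale_scope == "model":
        model_minmax = {}
        for metric, kind in config.ring_order:
            if kind != "continuous":
                continue
            values = np.concatenate(
                [_ring_values([a for a, _ in collated[cid]], metric)
                 for cid in chain_ids]
            )
            finite = values[np.isfinite(values)]
            if finite.size:
                model_minmax[metric] = (float(finite.min()), float(finite.max()))

    chain_views = []
    for ci, chain_id in enumerate(chain_ids):
        svg = chain_view_svg(
            collated[chain_id], config, chain_id, ci,
            two_versions=two_versions, model_minmax=model_minmax,
        )
        display = "block" if ci == 0 else "none"
        chain_views.append(
            f'<div class="cv-chain-wrap" style="display:{display}">{svg}</div>'
        )

    first_records = [a for a, _ in collated[chain_ids[0]] if a is not None]
    first_record = first_records[0] if first_records else None
    if first_record is None:
        residue_view = ""
    else:
        residue_view = residue_view_svg(
            first_record, _chain_distributions(first_records), config=config
        )

    selector_html = ""
    if len(chain_ids) > 1:
        options = "".join(
            f'<option value="{i}">Chain {cid}</option>'
            for i, cid in enumerate(chain_ids)
        )
        selector_html = (
            '<label>Chain: <select id="cv-chain-select">'
            f"{options}</select></label>"
        )
    toggle_html = ""
    if two_versions:
        toggle_html = (
            '<label class="cv-toggle-row">Previous iteration '
            '<input type="checkbox" id="cv-version-toggle"/></label>'
        )

    data_json = json.dumps(_report_data(collated, config), sort_keys=True,
                           separators=(",", ":"))
    js = _JS_TEMPLATE.replace("__CV_DATA__", data_json)
    if compat == "legacy":
        js = to_legacy_js(js)

    sections = "" if mode == "minimized" else _summary_section(collated)
    panel = (
        '<div class="cv-root">'
        f'<div class="cv-controls">{selector_html}{toggle_html}</div>'
        '<div class="cv-panel">'
        + "".join(chain_views)
        + f'<div class="cv-residue-wrap">{residue_view}</div>'
        "</div>"
        f"{sections}"
        "</div>"
    )
    header = "" if mode == "minimized" else f"<h1>{title}</h1>"
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
        f"<title>{title}</title><style>{_CSS}</style></head>"
        f"<body>{header}{panel}<script>{js}</script></body></html>"
    )
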