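"""Chain-view / residue-view SVG contracts and HTML report assembly."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest
from lxml import etree, html as lxml_html

from chainview.geometry import BFactorStats, ConformationClass
from chainview.metrics import MetricsRecord
from chainview.report import (
    ChainViewConfig,
    MODERN_JS_TOKENS,
    axis_transform,
    build_report,
    chain_view_svg,
    residue_view_svg,
    to_legacy_js,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


def record(i, chain="A", rama=ConformationClass.FAVORED,
           rot=ConformationClass.FAVORED, b_mean=20.0, pct=None):
    rec = MetricsRecord(
        chain_id=chain, seq_num=i + 1, insertion_code="", name="ALA",
        bfactor=BFactorStats(b_mean - 2, b_mean + 2, b_mean, 1.0),
        rama_probability=0.3, rama_class=rama,
        rotamer_score=0.5, rotamer_class=rot,
    )
    rec.percentiles = pct or {"b_mean": 40 + (i % 30), "b_max": 50,
                              "rama_prob": 60, "rotamer_score": 70}
    return rec


def positions(n, chain="A", **kw):
    return [(record(i, chain, **kw), None) for i in range(n)]


class TestAxisTransform:
    def test_polarity_flip_orders_worst_inward(self):
        out = axis_transform([10.0, 20.0, 30.0], higher_is_worse=True, gamma=2.0)
        assert out[0] == pytest.approx(1.0)
        assert out[2] == pytest.approx(0.0)
        assert out[0] > out[1] > out[2]

    def test_gamma_one_is_plain_scaling(self):
        out = axis_transform([0.0, 5.0, 10.0], higher_is_worse=False, gamma=1.0)
        assert out == pytest.approx([0.0, 0.5, 1.0])

    def test_power_rule(self):
        out = axis_transform([0.0, 5.0, 10.0], higher_is_worse=True, gamma=2.0)
        assert out[1] == pytest.approx(0.25)

    def test_constant_input_maps_to_one(self):
        out = axis_transform([7.0, 7.0, 7.0], higher_is_worse=True)
        assert out == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_preserved_and_range(self):
        out = axis_transform([1.0, np.nan, 3.0], higher_is_worse=False)
        assert np.isnan(out[1])
        assert np.nanmin(out) >= 0.0 and np.nanmax(out) <= 1.0

    def test_monotone_for_fixed_polarity(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 100, 50)
        out = axis_transform(values, higher_is_worse=False, gamma=2.0)
        order_in = np.argsort(values)
        assert np.all(np.diff(out[order_in]) >= 0)


class TestChainViewSvg:
    @pytest.mark.parametrize("n", [3, 100, 1200])
    def test_parses_with_correct_segment_count(self, n):
        svg = chain_view_svg(positions(n))
        root = etree.fromstring(svg.encode())
        hits = root.findall(f".//{SVG_NS}g[@class='cv-hits']/{SVG_NS}path")
        assert len(hits) == n
        # each discrete ring also carries one wedge per position
        for ring in root.findall(f".//{SVG_NS}g[@data-metric='rama']"):
            assert len(ring.findall(f"{SVG_NS}path")) == n

    def test_ring_count_matches_config(self):
        svg = chain_view_svg(positions(10))
        root = etree.fromstring(svg.encode())
        rings = root.findall(f".//{SVG_NS}g[@class='cv-ring cv-ring-discrete']")
        lines = root.findall(f".//{SVG_NS}g[@class='cv-ring cv-ring-continuous']")
        # fit rings are dropped (no map data) but b rings + 2 discrete remain
        assert len(rings) == 2
        assert len(lines) == 4  # groups exist even when the polyline is omitted

    def test_outlier_class_token_counts(self):
        pos = positions(10)
        outlier_rec = record(3, rot=ConformationClass.OUTLIER)
        pos[3] = (outlier_rec, None)
        svg = chain_view_svg(pos)
        root = etree.fromstring(svg.encode())
        wedges = root.findall(f".//{SVG_NS}g[@data-metric='rotamer']/{SVG_NS}path")
        tokens = [w.get("class").split()[-1] for w in wedges]
        assert tokens.count("outlier") == 1
        assert tokens.count("favored") == 9

    def test_unknown_rendered_with_outlier_color(self):
        pos = [(record(0, rot=ConformationClass.UNKNOWN), None)]
        svg = chain_view_svg(pos)
        root = etree.fromstring(svg.encode())
        wedge = root.find(f".//{SVG_NS}g[@data-metric='rotamer']/{SVG_NS}path")
        config = ChainViewConfig()
        assert wedge.get("fill") == config.colors["outlier"]
        assert "unknown" in wedge.get("class")

    def test_missing_markers_for_gap_positions(self):
        pos = positions(8)
        pos[5] = (pos[5][0], None)
        pos = [(a, (record(i) if i < 5 else None)) for i, (a, _) in enumerate(pos)]
        svg = chain_view_svg(pos, two_versions=True)
        root = etree.fromstring(svg.encode())
        markers = root.findall(f".//{SVG_NS}circle[@class='missing-marker v-b']")
        assert len(markers) == 3

    def test_deterministic_output(self):
        a = chain_view_svg(positions(40))
        b = chain_view_svg(positions(40))
        assert a == b

    def test_two_version_geometry_embedded(self):
        pos = [(record(i), record(i, b_mean=30.0 + i)) for i in range(6)]
        svg = chain_view_svg(pos, two_versions=True)
        root = etree.fromstring(svg.encode())
        line = root.find(f".//{SVG_NS}polyline[@class='cv-line b_mean']")
        assert line.get("data-pa") and line.get("data-pb")
        assert line.get("data-pa") != line.get("data-pb")


class TestResidueViewSvg:
    DISTS = {"b_mean": (20.0, 90.0, 55.0, 10.0), "b_max": (10.0, 80.0, 45.0, 8.0)}

    def test_marker_at_mean_coincides_with_middle_dash(self):
        rec = record(0, pct={"b_mean": 55})
        svg = residue_view_svg(rec, self.DISTS)
        root = etree.fromstring(svg.encode())
        bar = root.find(f".//{SVG_NS}g[@data-metric='b_mean']")
        dash = bar.find(f"{SVG_NS}line[@class='rv-dash rv-dash-mean']")
        marker = bar.find(f"{SVG_NS}rect[@class='rv-marker']")
        dash_y = float(dash.get("y1"))
        marker_center = float(marker.get("y")) + 2.5
        assert marker_center == pytest.approx(dash_y, abs=0.01)

    def test_constant_chain_degenerate_bar(self):
        rec = record(0, pct={"b_mean": 40})
        dists = {"b_mean": (40.0, 40.0, 40.0, 0.0)}
        svg = residue_view_svg(rec, dists)
        root = etree.fromstring(svg.encode())
        bar = root.find(f".//{SVG_NS}g[@data-metric='b_mean']")
        spectrum = bar.find(f"{SVG_NS}rect[@class='rv-spectrum']")
        assert float(spectrum.get("height")) <= 0.5
        dashes = bar.findall(f"{SVG_NS}line")
        ys = {d.get("y1") for d in dashes}
        assert len(ys) == 1  # sd lines coincide with the mean line

    @pytest.mark.parametrize("n_metrics", [5, 6])
    def test_radar_polygon_vertex_count(self, n_metrics):
        pct = {f"m{i}": 50 + i for i in range(n_metrics)}
        rec = record(0, pct=pct)
        svg = residue_view_svg(rec, {}, layout="radar")
        root = etree.fromstring(svg.encode())
        grids = root.findall(f".//{SVG_NS}polygon[@class='radar-grid']")
        for g in grids:
            assert len(g.get("points").split()) == n_metrics
        data = root.find(f".//{SVG_NS}polygon[@class='radar-data']")
        assert len(data.get("points").split()) == n_metrics
        bubbles = root.findall(f".//{SVG_NS}title")
        assert len(bubbles) == n_metrics
        assert "percentile" in bubbles[0].text


class TestBuildReport:
    def collated(self, n=6, chains=("A",), two=False):
        out = {}
        for cid in chains:
            if two:
                out[cid] = [(record(i, cid), record(i, cid)) for i in range(n)]
            else:
                out[cid] = positions(n, cid)
        return out

    def test_html_parses_and_embeds_svg(self):
        doc = build_report(self.collated())
        parsed = lxml_html.fromstring(doc)
        assert parsed.findall(".//svg") or doc.count("<svg") >= 2

    def test_minimized_mode_has_no_summary_sections(self):
        full = build_report(self.collated(), mode="full")
        mini = build_report(self.collated(), mode="minimized")
        assert "cv-summary-section" in full
        assert "cv-summary-section" not in mini
        assert "<svg" in mini

    def test_single_version_has_no_toggle(self):
        doc = build_report(self.collated(), two_versions=False)
        assert 'id="cv-version-toggle"' not in doc
        two = build_report(self.collated(two=True), two_versions=True)
        assert 'id="cv-version-toggle"' in two

    def test_chain_selector_only_with_multiple_chains(self):
        one = build_report(self.collated(chains=("A",)))
        two = build_report(self.collated(chains=("A", "B")))
        assert 'id="cv-chain-select"' not in one
        assert 'id="cv-chain-select"' in two

    def test_legacy_mode_has_no_modern_tokens(self):
        doc = build_report(self.collated(), compat="legacy")
        script = doc.split("<script>")[1].split("</script>")[0]
        for token in MODERN_JS_TOKENS:
            assert token not in script, f"modern token {token!r} in legacy JS"

    def test_modern_mode_does_use_modern_syntax(self):
        doc = build_report(self.collated(), compat="modern")
        script = doc.split("<script>")[1].split("</script>")[0]
        assert "const " in script

    def test_interaction_hooks_exposed(self):
        doc = build_report(self.collated())
        assert "function selectResidue(" in doc
        assert "function toggleVersion(" in doc

    def test_empty_input_gives_empty_state_message(self):
        doc = build_report({})
        assert "No analyzable protein chains" in doc

    def test_deterministic_bytes(self):
        a = build_report(self.collated(two=True), two_versions=True)
        b = build_report(self.collated(two=True), two_versions=True)
        assert a == b

    def test_css_is_namespaced(self):
        doc = build_report(self.collated())
        css = doc.split("<style>")[1].split("</style>")[0]
        selectors = [
            line.strip() for line in css.splitlines()
            if line.strip() and "{" in line
        ]
        assert selectors
        assert all(s.startswith(".cv-root") for s in selectors)


class TestLegacyTransform:
    def test_transform_removes_declarations(self):
        js = "const a = 1;\nlet b = () => { return a; };\n"
        out = to_legacy_js(js)
        assert "const " not in out and "let " not in out
        assert "=>" not in out
        assert "function()" in out.replace(" ", "")
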