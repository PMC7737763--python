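"""Rotamer scoring (central values), flat-index lookup and the
compressed 2-bit contour-grid library."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chainview.geometry import ConformationClass
from chainview.rotamer import (
    CentralValuesEntry,
    ChiMismatchError,
    CompressedLibrary,
    ContourGrid,
    LibraryBuildError,
    LibraryLoadError,
    classify_rotamer,
    compress_library,
    decompress_library,
    grid_index,
    pack_states,
    rotamer_score,
    threshold_rotamericity,
    unpack_states,
    wrap_degrees,
)


def entry(rtype, name, means, sds):
    return CentralValuesEntry(rtype, name, tuple(means), tuple(sds))


class TestRotamerScore:
    def test_zero_at_rotamer_means(self):
        e = entry("SER", "m", [63.0], [8.0])
        assert rotamer_score([63.0], [e]) == 0.0

    def test_one_sigma_single_chi_gives_one(self):
        e = entry("SER", "m", [63.0], [8.0])
        assert rotamer_score([71.0], [e]) == pytest.approx(1.0)

    def test_min_over_rotamers(self):
        # per-rotamer quadratic means computed by hand: 2.3 and 0.7
        e1 = entry("SER", "a", [0.0], [10.0])  # chi=23 -> z=2.3
        e2 = entry("SER", "b", [30.0], [10.0])  # chi=23 -> z=0.7
        assert rotamer_score([23.0], [e1, e2]) == pytest.approx(0.7)

    def test_wrap_rule_across_180(self):
        e = entry("SER", "m", [175.0], [10.0])
        assert rotamer_score([-175.0], [e]) == pytest.approx(1.0)

    def test_quadratic_mean_two_dims(self):
        e = entry("LEU", "m", [60.0, 180.0], [10.0, 20.0])
        # z = (1, 2) -> sqrt((1+4)/2)
        score = rotamer_score([70.0, 220.0], [e])
        assert score == pytest.approx(math.sqrt(2.5))

    def test_exhaustive_min_against_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(1, 4))
            entries = [
                entry("XXX", f"r{k}", rng.uniform(-180, 180, n),
                      rng.uniform(5, 20, n))
                for k in range(rng.integers(1, 5))
            ]
            chis = rng.uniform(-180, 180, n).tolist()
            brute = min(
                math.sqrt(
                    sum(
                        (wrap_degrees(c - m) / s) ** 2
                        for c, m, s in zip(chis, e.chi_means, e.chi_sds)
                    )
                    / n
                )
                for e in entries
            )
            assert rotamer_score(chis, entries) == pytest.approx(brute)

    def test_permutation_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(9)
        entries = [
            entry("XXX", f"r{k}", rng.uniform(-180, 180, 2), rng.uniform(5, 20, 2))
            for k in range(4)
        ]
        chis = [12.0, -140.0]
        s1 = rotamer_score(chis, entries)
        s2 = rotamer_score(chis, entries[::-1])
        assert s1 == s2 >= 0.0

    def test_chi_count_mismatch_raises_flaggable_error(self):
        e = entry("LEU", "m", [60.0, 180.0], [10.0, 10.0])
        with pytest.raises(ChiMismatchError):
            rotamer_score([60.0], [e])

    def test_symmetric_terminal_chi_period(self):
        e = entry("ASP", "m", [10.0, 0.0], [10.0, 10.0])
        # chi2 = 180 is identical to 0 under the 2-fold symmetry
        score = rotamer_score([10.0, 180.0], [e], periods=(360.0, 180.0))
        assert score == pytest.approx(0.0)


def make_grid(sizes, values=None, origins=None):
    n = len(sizes)
    origins = origins or tuple(-180.0 for _ in range(n))
    spacings = tuple(360.0 / s for s in sizes)
    total = int(np.prod(sizes))
    if values is None:
        values = np.zeros(total, dtype=np.uint8)
    return ContourGrid("XXX", tuple(origins), spacings, tuple(sizes), values)


class TestGridIndex:
    def test_origin_maps_to_zero(self):
        grid = make_grid([4, 5])
        assert grid_index([-180.0, -180.0], grid) == 0

    def test_2d_known_node(self):
        grid = make_grid([4, 5])
        # node (2, 3): brute-force enumeration order gives 2*5 + 3
        chis = [-180 + 2 * 90.0, -180 + 3 * 72.0]
        assert grid_index(chis, grid) == 13

    def test_full_period_wrap(self):
        grid = make_grid([6])
        assert grid_index([-180.0 + 360.0], grid) == grid_index([-180.0], grid)

    def test_bijection_against_enumeration_random_grids(self):
        rng = np.random.default_rng(17)
        from conftest import random_grid_spec

        for _ in range(200):
            meta = random_grid_spec(rng)
            grid = make_grid(
                meta["sizes"],
                origins=tuple(meta["origins"]),
            )
            seen = []
            for coord_idx in itertools.product(
                *(range(s) for s in meta["sizes"])
            ):
                chis = [
                    o + i * sp
                    for o, sp, i in zip(
                        meta["origins"], grid.axis_spacings, coord_idx
                    )
                ]
                # expected row-major flat index by explicit enumeration
                expected = 0
                for i, s in zip(coord_idx, meta["sizes"]):
                    expected = expected * s + i
                idx = grid_index(chis, grid)
                assert idx == expected
                seen.append(idx)
            assert sorted(seen) == list(range(grid.n_points))

    def test_nint_rounds_half_away_from_zero(self):
        grid = make_grid([8])  # spacing 45, origin -180
        # chi exactly halfway between nodes 2 and 3 -> 112.5 steps? use +0.5
        chi = -180.0 + 2.5 * 45.0
        assert grid_index([chi], grid) == 3


class TestPacking:
    def test_four_states_per_byte(self):
        rng = np.random.default_rng(5)
        for n in (4, 8, 40, 400):
            states = rng.integers(0, 4, n).astype(np.uint8)
            payload = pack_states(states)
            assert len(payload) == n // 4
            assert np.array_equal(unpack_states(payload, n), states)

    def test_partial_byte_padding(self):
        states = np.array([1, 2, 3], dtype=np.uint8)
        payload = pack_states(states)
        assert len(payload) == 1
        assert np.array_equal(unpack_states(payload, 3), states)

    def test_all_favored_byte_is_0xff(self):
        assert pack_states(np.array([3, 3, 3, 3], dtype=np.uint8)) == b"\xff"

    def test_declared_bit_order_little_end_first(self):
        # byte 0b00011011: bits 0-1 = 3, 2-3 = 2, 4-5 = 1, 6-7 = 0
        states = unpack_states(bytes([0b00011011]), 4)
        assert states.tolist() == [3, 2, 1, 0]

    def test_truncated_payload_raises(self):
        with pytest.raises(LibraryLoadError):
            unpack_states(b"\x00", 5)


class TestThresholds:
    @pytest.mark.parametrize(
        "value,state",
        [(0.0, 1), (0.3, 1), (0.30001, 2), (1.0, 2), (1.99, 2), (2.0, 3), (50.0, 3)],
    )
    def test_boundaries(self, value, state):
        assert threshold_rotamericity(value) == state

    def test_ladder_classification_boundaries(self):
        # nodes carrying rotamericity 0.05..3.00 in 0.05 steps
        values = [round(0.05 * k, 2) for k in range(1, 61)]
        sizes = [len(values)]
        meta = {"origins": [0.0], "spacings": [360.0 / len(values)],
                "sizes": sizes}
        sparse = {
            (meta["spacings"][0] * i,): v for i, v in enumerate(values)
        }
        lib = compress_library({"XXX": (meta, sparse)})
        grid = decompress_library(lib)["XXX"]
        outliers = [
            v for (c,), v in sparse.items()
            if classify_rotamer([c], grid) is ConformationClass.OUTLIER
        ]
        favored = [
            v for (c,), v in sparse.items()
            if classify_rotamer([c], grid) is ConformationClass.FAVORED
        ]
        assert max(outliers) == 0.3
        assert min(favored) == 2.0


class TestCompressedLibrary:
    def test_fully_favored_2x2_payload_byte(self):
        meta = {"origins": [0.0, 0.0], "spacings": [180.0, 180.0],
                "sizes": [2, 2]}
        sparse = {
            (x, y): 5.0 for x in (0.0, 180.0) for y in (0.0, 180.0)
        }
        lib = compress_library({"XXX": (meta, sparse)})
        import gzip

        assert gzip.decompress(lib.payload) == b"\xff"

    def test_missing_point_decodes_unknown(self):
        meta = {"origins": [0.0], "spacings": [90.0], "sizes": [4]}
        sparse = {(0.0,): 5.0, (90.0,): 5.0, (270.0,): 5.0}  # 180 missing
        grid = decompress_library(compress_library({"XXX": (meta, sparse)}))["XXX"]
        assert classify_rotamer([180.0], grid) is ConformationClass.UNKNOWN

    def test_off_lattice_coordinate_is_fatal(self):
        meta = {"origins": [0.0], "spacings": [90.0], "sizes": [4]}
        with pytest.raises(LibraryBuildError):
            compress_library({"XXX": (meta, {(45.1,): 5.0})})

    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_identity_randomized(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_grid_spec

        raw = {}
        expected = {}
        for t in range(rng.integers(1, 4)):
            rtype = f"T{t}"
            meta = random_grid_spec(rng, max_dims=3)
            total = int(np.prod(meta["sizes"]))
            values = rng.uniform(0, 4, total)
            present = rng.random(total) > 0.2
            sparse = {}
            states = np.zeros(total, dtype=np.uint8)
            for flat in range(total):
                if not present[flat]:
                    continue
                coord_idx = np.unravel_index(flat, meta["sizes"])
                coords = tuple(
                    o + i * sp
                    for o, sp, i in zip(
                        meta["origins"],
                        meta["spacings"],
                        coord_idx,
                    )
                )
                sparse[coords] = float(values[flat])
                states[flat] = threshold_rotamericity(values[flat])
            raw[rtype] = (meta, sparse)
            expected[rtype] = states
        grids = decompress_library(compress_library(raw))
        assert set(grids) == set(raw)
        for rtype, grid in grids.items():
            assert np.array_equal(grid.values, expected[rtype])

    def test_serialization_round_trip(self, rotamer_reference):
        _, raw = rotamer_reference
        lib = compress_library(raw)
        blob = lib.to_bytes()
        lib2 = CompressedLibrary.from_bytes(blob)
        g1 = decompress_library(lib)
        g2 = decompress_library(lib2)
        for rtype in g1:
            assert np.array_equal(g1[rtype].values, g2[rtype].values)

    def test_corrupt_payload_raises(self, rotamer_reference):
        _, raw = rotamer_reference
        lib = compress_library(raw)
        lib.payload = lib.payload[: len(lib.payload) // 2]
        with pytest.raises(LibraryLoadError):
            decompress_library(lib)

    def test_packed_footprint_exact(self):
        rng = np.random.default_rng(23)
        import gzip

        for _ in range(10):
            size = int(rng.integers(3, 40))
            meta = {"origins": [0.0], "spacings": [360.0 / size], "sizes": [size]}
            sparse = {
                (360.0 / size * i,): float(rng.uniform(0, 4))
                for i in range(size)
            }
            lib = compress_library({"XXX": (meta, sparse)})
            assert len(gzip.decompress(lib.payload)) == (size + 3) // 4

    def test_classification_matches_direct_thresholding(self, rotamer_reference):
        _, raw = rotamer_reference
        grids = decompress_library(compress_library(raw))
        class_of = {1: ConformationClass.OUTLIER, 2: ConformationClass.ALLOWED,
                    3: ConformationClass.FAVORED}
        for rtype, (meta, sparse) in raw.items():
            grid = grids[rtype]
            for coords, value in itertools.islice(sparse.items(), 200):
                assert classify_rotamer(list(coords), grid) is class_of[
                    threshold_rotamericity(value)
                ]
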