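import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofractal.portrait_fractals import (
    bioconsolidation_index,
    detect_arithmetic_sets,
    detect_collinear_sets,
    run_model2,
)
from myofractal.transforms import PortraitPoint, build_portrait


def points_from_ys(ys):
    return [
        PortraitPoint(gene=f"G{i+1}", lg=y, y=y, x=y - math.floor(y))
        for i, y in enumerate(ys)
    ]


def triple_oracle_union(points, tol):
    """Exhaustive oracle: a triple is near-collinear when any of its pair
    lines carries the third point within tol; union over all triples."""
    members = set()
    for trio in itertools.combinations(points, 3):
        hit = False
        for a, b, c in itertools.permutations(trio, 3):
            dx, dy = b.x - a.x, b.y - a.y
            length = math.hypot(dx, dy)
            if length == 0:
                continue
            dist = abs(dx * (c.y - a.y) - dy * (c.x - a.x)) / length
            if dist <= tol:
                hit = True
        if hit:
            members |= {p.gene for p in trio}
    return members


class TestArithmeticSets:
    def test_reference_worked_progression(self):
        # the published shifted-LG progression 0.20, 1.36, 2.49
        sets = detect_arithmetic_sets(
            [("MSTN", 0.20), ("MYOD1", 1.36), ("TBP", 2.49)], tol=0.05)
        assert len(sets) == 1
        assert sets[0].genes == {"MSTN", "MYOD1", "TBP"}

    def test_exact_progression_reported_once_maximally(self):
        sets = detect_arithmetic_sets(
            [("A", 0.0), ("B", 1.0), ("C", 2.0), ("D", 3.0)], tol=1e-9)
        assert len(sets) == 1
        assert sets[0].genes == {"A", "B", "C", "D"}

    def test_fewer_than_three_values_is_empty(self):
        assert detect_arithmetic_sets([("A", 0.0), ("B", 1.0)], tol=0.1) == []

    def test_matches_exhaustive_subset_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ys = rng.uniform(0, 10, size=rng.integers(3, 9))
            values = [(f"G{i}", float(y)) for i, y in enumerate(ys)]
            tol = float(rng.uniform(0.05, 0.5))
            got = {s.genes for s in detect_arithmetic_sets(values, tol)}
            qualifying = set()
            by_gene = dict(values)
            for r in range(3, len(values) + 1):
                for sub in itertools.combinations(by_gene, r):
                    sorted_ys = np.sort([by_gene[g] for g in sub])
                    diffs = np.diff(sorted_ys)
                    if diffs.max() - diffs.min() <= tol:
                        qualifying.add(frozenset(sub))
            expected = {s for s in qualifying
                        if not any(s < t for t in qualifying)}
            assert got == expected


class TestCollinearSets:
    def test_three_collinear_plus_far_point(self):
        pts = [
            PortraitPoint("A", 0, 1.0, 0.0),
            PortraitPoint("B", 0, 2.0, 0.1),
            PortraitPoint("C", 0, 3.0, 0.2),
            PortraitPoint("D", 0, 2.0, 0.9),
        ]
        sets = detect_collinear_sets(pts, tol=0.01)
        assert len(sets) == 1
        assert sets[0].genes == {"A", "B", "C"}
        assert sets[0].max_residual <= 1e-12

    def test_fewer_than_three_points_is_empty(self):
        pts = points_from_ys([1.2, 3.4])
        assert detect_collinear_sets(pts, tol=0.1) == []

    def test_matches_exhaustive_triple_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            ys = rng.uniform(0, 12, size=n)
            pts = points_from_ys(ys)
            tol = float(rng.uniform(0.005, 0.08))
            sets = detect_collinear_sets(pts, tol=tol,
                                         exclude_trivial_diagonal=False)
            union = set().union(*[s.genes for s in sets]) if sets else set()
            assert union == triple_oracle_union(pts, tol)

    def test_subsets_are_deduplicated(self):
        pts = points_from_ys([0.0, 1.1, 2.2, 3.3])  # one exact progression
        sets = detect_collinear_sets(pts, tol=0.01,
                                     exclude_trivial_diagonal=False)
        genes_sets = [s.genes for s in sets]
        for a, b in itertools.combinations(genes_sets, 2):
            assert not (a < b or b < a)

    def test_tolerance_monotonicity(self, expression):
        points = build_portrait(expression, "YC", "breast")
        previous = set()
        for tol in (0.005, 0.01, 0.02, 0.05, 0.1):
            sets = detect_collinear_sets(points, tol=tol)
            union = set().union(*[s.genes for s in sets]) if sets else set()
            assert previous <= union
            previous = union

    def test_trivial_diagonal_suppressed(self):
        # y < 1 for all three points: x = y, exactly collinear by construction
        pts = points_from_ys([0.1, 0.5, 0.9, 5.3])
        assert detect_collinear_sets(pts, tol=1e-6) == []
        kept = detect_collinear_sets(pts, tol=1e-6,
                                     exclude_trivial_diagonal=False)
        assert kept and kept[0].genes == {"G1", "G2", "G3"}


class TestBioconsolidationIndex:
    def test_reference_counts(self):
        assert bioconsolidation_index(6, 6, 8) == 0.75

    @pytest.mark.parametrize("k", [0, 3, 8])
    def test_zero_breast_members_zeroes_index(self, k):
        assert bioconsolidation_index(0, k, 8) == 0

    def test_full_panel_reaches_unity(self):
        assert bioconsolidation_index(8, 8, 8) == 1

    def test_counts_exceeding_panel_rejected(self):
        with pytest.raises(ValueError):
            bioconsolidation_index(9, 2, 8)

    @given(st.integers(0, 8), st.integers(0, 8))
    @settings(derandomize=True)
    def test_bounds_symmetry_monotonicity(self, nb, nt):
        ind = bioconsolidation_index(nb, nt, 8)
        assert 0 <= ind <= 1
        assert ind == bioconsolidation_index(nt, nb, 8)
        if nb < 8:
            assert bioconsolidation_index(nb + 1, nt, 8) >= ind


class TestRunModel2:
    def test_reference_cornish_counts_and_index(self, expression):
        res = run_model2(expression, "WC")
        assert (res.n_breast, res.n_thigh) == (6, 6)
        assert res.n_genes == 8
        assert res.ind == 0.75

    def test_all_reference_breeds_in_bounds(self, expression):
        for breed in expression.breeds:
            res = run_model2(expression, breed)
            assert 0 <= res.ind <= 1
            assert res.n_genes == 8

    def test_missing_tissue_rejected(self):
        from myofractal.data_model import FCRecord, FCTable

        table = FCTable([FCRecord("A", "breast", f"G{i}", 2.0 + i)
                         for i in range(4)])
        with pytest.raises(KeyError):
            run_model2(table, "A")

    def test_planted_progressions_are_mutually_consistent(self):
        """Planted APs in shifted-LG space are found by the collinear
        detector: the two fractal definitions agree on synthetic panels."""
        from myofractal.synthetic import SynthSpec, generate_portrait_panel

        spec = SynthSpec(n_breeds=1, n_genes=8, model="portrait_ap",
                         params={"n_members": 5, "common_difference": 1.12},
                         seed=31)
        table = generate_portrait_panel(spec)
        res = run_model2(table, "S1")
        assert res.n_breast == 5 and res.n_thigh == 5
        ap_sets = detect_arithmetic_sets(
            [(p.gene, p.y) for p in build_portrait(table, "S1", "breast")],
            tol=0.01)
        ap_union = set().union(*[s.genes for s in ap_sets])
        assert ap_union == set(res.members_breast)
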