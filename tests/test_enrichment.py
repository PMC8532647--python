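import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from oxiswitch.enrichment import (
    PathwayLibrary,
    annotate_mz,
    enrich,
    packaged_pathway_library,
    pathway_ease_p,
    permutation_gamma_adjust,
    read_pathway_library,
    select_top_fraction,
)
from oxiswitch.errors import ValidationError
from oxiswitch.peaktable import PipelineConfig

# independent element-mass oracle for glucose C6H12O6
GLUCOSE = 6 * 12.0 + 12 * 1.00782503207 + 6 * 15.9949146196
PROTON_ORACLE = 1.00782503207 - 0.00054857990907


def ease_oracle(k, K, n, N):
    """Exhaustive hypergeometric enumeration of P(X >= k-1)."""
    if k == 0:
        return 1.0
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k - 1, min(K, n) + 1)) / comb(N, n)


class TestAnnotate:
    def _library(self):
        return PathwayLibrary(
            [("pw1", "Test", ("GLC",))], {"GLC": 180.063388}
        )

    def test_glucose_within_10ppm(self):
        ion = GLUCOSE + PROTON_ORACLE
        delta_ppm = abs(181.0720 - ion) / ion * 1e6
        assert delta_ppm == pytest.approx(7.4, abs=0.2)
        ann = annotate_mz([(181.0720, "positive")], self._library(), ppm=10.0)
        assert ann == {0: {"GLC"}}

    def test_glucose_outside_5ppm(self):
        ann = annotate_mz([(181.0720, "positive")], self._library(), ppm=5.0)
        assert ann == {}

    def test_empty_library(self):
        lib = PathwayLibrary([], {})
        assert annotate_mz([(181.0720, "positive")], lib, ppm=10.0) == {}

    def test_negative_mode_adducts(self):
        ion = GLUCOSE - PROTON_ORACLE
        ann = annotate_mz([(ion, "negative")], self._library(), ppm=10.0)
        assert ann == {0: {"GLC"}}

    def test_many_to_many(self):
        lib = PathwayLibrary(
            [("pw1", "Test", ("A", "B"))], {"A": 180.063388, "B": 180.063500}
        )
        ann = annotate_mz([(GLUCOSE + PROTON_ORACLE, "positive")], lib, ppm=10.0)
        assert ann[0] == {"A", "B"}

    def test_invalid_ppm(self):
        with pytest.raises(ValidationError):
            annotate_mz([], self._library(), ppm=0.0)


class TestTopFraction:
    def test_two_smallest_of_twenty(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        idx = select_top_fraction(p, 0.10)
        assert len(idx) == 2
        assert set(idx) == set(np.argsort(p)[:2])

    def test_fraction_one_selects_all(self):
        assert len(select_top_fraction(np.ones(7), 1.0)) == 7

    def test_boundary_ties_included(self):
        p = np.array([0.001, 0.05, 0.05, 0.05, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9])
        idx = select_top_fraction(p, 0.2)  # ceil(2) -> cutoff p = 0.05, ties join
        assert set(idx) == {0, 1, 2, 3}

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            select_top_fraction(np.ones(3), 0.0)


class TestEaseP:
    def test_zero_overlap(self):
        assert pathway_ease_p(0, 5, 6, 20) == 1.0

    def test_worked_case(self):
        # N=20, K=5, n=6, k=5 -> P(X >= 4) = 540/38760
        assert pathway_ease_p(5, 5, 6, 20) == pytest.approx(540 / 38760, abs=1e-15)
        assert ease_oracle(5, 5, 6, 20) == 540 / 38760

    @pytest.mark.parametrize("N", [5, 10, 17])
    def test_small_sweep(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert pathway_ease_p(k, K, n, N) == pytest.approx(
                        ease_oracle(k, K, n, N), abs=1e-12
                    )

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            pathway_ease_p(6, 5, 6, 20)
        with pytest.raises(ValidationError):
            pathway_ease_p(1, 25, 6, 20)


def _toy_setup(seed=0, n_features=60, n_annotated=30):
    """Annotations mapping the first features to one compound each."""
    rng = np.random.default_rng(seed)
    codes = [f"C{i:03d}" for i in range(n_annotated)]
    masses = {c: float(rng.uniform(100, 500)) for c in codes}
    annotations = {i: {codes[i]} for i in range(n_annotated)}
    pw = [("pwA", "A", tuple(codes[:10])), ("pwB", "B", tuple(codes[10:20]))]
    library = PathwayLibrary(pw, masses)
    return annotations, library, n_features


class TestPermutationGamma:
    def test_deterministic(self):
        annotations, library, n = _toy_setup()
        raw = {"pwA": 0.01, "pwB": 0.5}
        a1, d1 = permutation_gamma_adjust(raw, annotations, n, library, 6, 200, seed=42)
        a2, d2 = permutation_gamma_adjust(raw, annotations, n, library, 6, 200, seed=42)
        assert a1 == a2 and d1 == d2

    def test_null_median_maps_near_half(self):
        # fully annotated features and large pathways give a null p
        # distribution smooth enough for the calibration-midpoint check
        n = 60
        codes = [f"C{i:03d}" for i in range(n)]
        masses = {c: 200.0 + i for i, c in enumerate(codes)}
        annotations = {i: {codes[i]} for i in range(n)}
        library = PathwayLibrary(
            [("pwA", "A", tuple(codes[:30])), ("pwB", "B", tuple(codes[30:]))], masses
        )
        # independent replay of the null process to find its median raw p
        rng = np.random.default_rng(7)
        null_ps = []
        for _ in range(600):
            subset = rng.choice(n, size=20, replace=False)
            k = sum(1 for i in subset if int(i) < 30)
            null_ps.append(pathway_ease_p(k, 30, 20, 60))
        med = float(np.median(null_ps))
        adj, _ = permutation_gamma_adjust(
            {"pwA": med, "pwB": med}, annotations, n, library, 20, 600, seed=7
        )
        assert 0.4 <= adj["pwA"] <= 0.6

    def test_min_permutations(self):
        annotations, library, n = _toy_setup()
        with pytest.raises(ValidationError):
            permutation_gamma_adjust({"pwA": 0.5}, annotations, n, library, 6, 50, 0)


class TestEnrich:
    def _corr_table(self, mzs, ps, mode="positive"):
        return pd.DataFrame(
            {
                "feature_id": [f"F{i}" for i in range(len(mzs))],
                "mz": mzs,
                "rt": np.linspace(30, 300, len(mzs)),
                "mode": mode,
                "p": ps,
            }
        )

    def test_planted_pathway_recovered(self, small_study):
        from oxiswitch.oximetry import ftoe_lookup
        from oxiswitch.screen import pearson_with_ftoe

        table = small_study.tables["positive"]
        corr = pearson_with_ftoe(table, ftoe_lookup(small_study.cohort))
        cfg = PipelineConfig(rng_seed=7, permutations=300)
        results = enrich(corr, small_study.library, cfg)
        assert results[0].pathway_id == "map_planted"
        assert results[0].adj_p < 0.05

    def test_no_significant_hits_all_raw_one(self):
        lib = PathwayLibrary([("pw1", "T", ("GLC",))], {"GLC": 180.063388})
        # the smallest p-values sit on unannotatable m/z values
        mzs = [500.0, 600.0, 700.0, 800.0, GLUCOSE + PROTON_ORACLE]
        ps = [0.001, 0.002, 0.8, 0.9, 0.95]
        results = enrich(self._corr_table(mzs, ps), lib, PipelineConfig(permutations=100))
        assert all(r.raw_p == 1.0 for r in results)

    def test_row_order_invariance(self):
        annotations, library, _ = _toy_setup()
        rng = np.random.default_rng(3)
        mzs = [library.masses[f"C{i:03d}"] + 1.007276 for i in range(30)] + list(
            rng.uniform(700, 900, 30)
        )
        ps = list(rng.uniform(size=60))
        t1 = self._corr_table(mzs, ps)
        cfg = PipelineConfig(rng_seed=5, permutations=100)
        r1 = enrich(t1, library, cfg)
        perm = rng.permutation(60)
        t2 = t1.iloc[perm].reset_index(drop=True)
        r2 = enrich(t2, library, cfg)
        assert [(r.pathway_id, r.n_hits, r.n_sig_hits, r.raw_p) for r in r1] == [
            (r.pathway_id, r.n_hits, r.n_sig_hits, r.raw_p) for r in r2
        ]

    def test_sig_hits_monotone_in_fraction(self):
        annotations, library, _ = _toy_setup()
        rng = np.random.default_rng(4)
        mzs = [library.masses[f"C{i:03d}"] + 1.007276 for i in range(30)]
        ps = list(rng.uniform(size=30))
        prev = 0
        for frac in (0.1, 0.3, 0.6, 1.0):
            cfg = PipelineConfig(sig_top_fraction=frac, permutations=100, rng_seed=1)
            res = {r.pathway_id: r for r in enrich(self._corr_table(mzs, ps), library, cfg)}
            assert res["pwA"].n_sig_hits >= prev
            prev = res["pwA"].n_sig_hits

    def test_nan_p_dropped_with_warning(self):
        lib = PathwayLibrary([("pw1", "T", ("GLC",))], {"GLC": 180.063388})
        t = self._corr_table([GLUCOSE + PROTON_ORACLE, 500.0], [0.01, np.nan])
        with pytest.warns(UserWarning, match="undefined p"):
            enrich(t, lib, PipelineConfig(permutations=100))


class TestLibraryIO:
    def test_packaged_library_valid(self):
        lib = packaged_pathway_library()
        assert [pid for pid, _, _ in lib.pathways] == [
            "map00030",
            "map00040",
            "map00053",
            "map00562",
        ]
        # Table-3 pathway sizes after de-duplication of repeated codes
        sizes = {pid: len(codes) for pid, _, codes in lib.pathways}
        assert sizes == {"map00030": 5, "map00040": 13, "map00053": 5, "map00562": 3}

    def test_round_trip(self, tmp_path):
        lib = packaged_pathway_library()
        path = tmp_path / "lib.tsv"
        with open(path, "w") as fh:
            fh.write("pathway_id\tname\tcompound_code\tneutral_mass\n")
            for pid, name, codes in lib.pathways:
                for c in codes:
                    fh.write(f"{pid}\t{name}\t{c}\t{lib.masses[c]!r}\n")
        back = read_pathway_library(path)
        assert back.pathways == lib.pathways
        assert back.masses == lib.masses

    def test_missing_mass_rejected(self):
        with pytest.raises(ValidationError, match="no mass entry"):
            PathwayLibrary([("pw", "X", ("A",))], {})
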