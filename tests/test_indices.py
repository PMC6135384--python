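import math

import numpy as np
import pandas as pd
import pytest

import foramstats as fs
from foramstats.io import TaxonAnnotation, ValidationError

SYM = [TaxonAnnotation("a", "symbiont_bearing", "porcellaneous"),
       TaxonAnnotation("b", "symbiont_bearing", "hyaline")]
HET = [TaxonAnnotation("a", "heterotrophic", "hyaline"),
       TaxonAnnotation("b", "heterotrophic", "agglutinated")]
MIX = [TaxonAnnotation("s", "symbiont_bearing", "porcellaneous"),
       TaxonAnnotation("o", "opportunistic", "hyaline"),
       TaxonAnnotation("h", "heterotrophic", "hyaline")]


class TestForamIndex:
    def test_pure_symbiont_is_ten(self):
        r = fs.foram_index({"a": 30.0, "b": 20.0}, SYM, sample_id="x")
        assert r.fi == pytest.approx(10.0, abs=1e-12)
        assert r.category == "reef_development"
        assert r.Ps == 1.0

    def test_pure_heterotrophic_is_two(self):
        r = fs.foram_index({"a": 5.0, "b": 7.0}, HET, sample_id="x")
        assert r.fi == pytest.approx(2.0, abs=1e-12)
        assert r.category == "marginal"  # boundary value 2 is marginal

    def test_hand_computed_mixture(self):
        # Ps=0.5, Po=0.3, Ph=0.2 -> 10*0.5 + 0.3 + 2*0.2 = 5.7
        r = fs.foram_index({"s": 50, "o": 30, "h": 20}, MIX)
        assert r.fi == pytest.approx(5.7, abs=1e-12)
        assert (r.Ps, r.Po, r.Ph) == pytest.approx((0.5, 0.3, 0.2))

    def test_scale_invariance(self, rng):
        row = {"s": 12.3, "o": 4.5, "h": 83.2}
        r1 = fs.foram_index(row, MIX)
        r2 = fs.foram_index({k: v * 37.5 for k, v in row.items()}, MIX)
        assert r1.fi == pytest.approx(r2.fi, abs=1e-12)

    def test_unknown_group_excluded_from_total(self):
        anns = MIX + [TaxonAnnotation("u", "unknown", "unknown")]
        with_u = fs.foram_index({"s": 10, "o": 10, "h": 10, "u": 500}, anns)
        without = fs.foram_index({"s": 10, "o": 10, "h": 10}, MIX)
        assert with_u.fi == pytest.approx(without.fi, abs=1e-12)

    def test_no_classifiable_specimens(self):
        anns = [TaxonAnnotation("u", "unknown", "unknown")]
        with pytest.raises(ValidationError, match="no classifiable"):
            fs.foram_index({"u": 100.0}, anns, sample_id="x")

    def test_fi_bounds_random_compositions(self, rng):
        for _ in range(200):
            row = dict(zip("soh", rng.random(3) + 1e-9))
            fi = fs.foram_index(row, MIX).fi
            assert 1.0 - 1e-12 <= fi <= 10.0 + 1e-12

    @pytest.mark.parametrize("fi,cat", [
        (4.001, "reef_development"), (4.0, "marginal"), (2.0, "marginal"),
        (1.999, "stressed"), (10.0, "reef_development"), (1.0, "stressed"),
    ])
    def test_category_boundaries(self, fi, cat):
        assert fs.classify_fi(fi) == cat


class TestSiteForamIndex:
    def _res(self, sid, fi):
        # build a ForamIndexResult via foram_index on a crafted composition
        ps = (fi - 2.0) / 8.0  # Po=0 composition with FI=10ps+2(1-ps)
        return fs.foram_index({"s": ps, "o": 0.0, "h": 1 - ps}, MIX, sample_id=sid)

    def test_mean_of_sample_fi(self):
        res = [self._res("a", 4.0), self._res("b", 4.32)]
        table = fs.site_foram_index(res, {"a": "X", "b": "X"})
        assert table.loc["X", "fi"] == pytest.approx(4.16, abs=1e-9)

    def test_singleton_site_identity(self):
        r = self._res("a", 3.3)
        table = fs.site_foram_index([r], {"a": "X"})
        assert table.loc["X", "fi"] == pytest.approx(r.fi, abs=1e-12)

    def test_pooled_counts_weighting(self):
        # pooled method weights by classified totals, not sample count
        r1 = fs.foram_index({"s": 90, "o": 0, "h": 10}, MIX, sample_id="a")
        r2 = fs.foram_index({"s": 0, "o": 0, "h": 300}, MIX, sample_id="b")
        pooled = fs.site_foram_index([r1, r2], {"a": "X", "b": "X"},
                                     method="pooled_counts")
        s, h = 90.0, 310.0
        expected = (10 * s + 2 * h) / (s + h)
        assert pooled.loc["X", "fi"] == pytest.approx(expected, abs=1e-12)

    def test_unmapped_sample_errors(self):
        with pytest.raises(ValidationError, match="missing"):
            fs.site_foram_index([self._res("a", 3.0)], {"b": "X"})

    def test_galapagos_site_ordering(self, galapagos):
        """Darwin's symbiont-rich reef tops site FI; a southern site is lowest."""
        a, taxa, _ = galapagos
        site = fs.site_foram_index(fs.foram_index_table(a, taxa))
        assert site["fi"].idxmax() == "DAR"
        assert site["fi"].idxmin() in ("FL", "SC")


class TestFisherAlpha:
    def _bisect_oracle(self, S, N):
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = (lo + hi) / 2
            if mid * math.log1p(N / mid) - S < 0:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    def test_single_species_many_specimens(self):
        # root of alpha*ln(1 + 1000/alpha) = 1, by independent bisection
        assert fs.fisher_alpha(1, 1000) == pytest.approx(
            self._bisect_oracle(1, 1000), abs=1e-6)
        assert fs.fisher_alpha(1, 1000) == pytest.approx(0.109672, abs=1e-5)

    def test_against_bisection_oracle(self, rng):
        for _ in range(100):
            N = int(rng.integers(10, 5000))
            S = int(rng.integers(1, N))
            assert fs.fisher_alpha(S, N) == pytest.approx(
                self._bisect_oracle(S, N), abs=1e-6)

    def test_defining_equation_residual(self, rng):
        for S, N in [(12, 292), (53, 315), (6, 293), (47, 475)]:
            a = fs.fisher_alpha(S, N)
            assert abs(a * math.log1p(N / a) - S) < 1e-6

    def test_monotonicity_grid(self):
        Ns = [100, 200, 400, 800, 1600]
        Ss = [5, 10, 20, 40, 80]
        for N in Ns:
            alphas = [fs.fisher_alpha(S, N) for S in Ss]
            assert all(a < b for a, b in zip(alphas, alphas[1:]))
        for S in Ss:
            alphas = [fs.fisher_alpha(S, N) for N in Ns]
            assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_errors(self):
        with pytest.raises(ValidationError, match="log-series undefined"):
            fs.fisher_alpha(10, 10)
        with pytest.raises(ValidationError):
            fs.fisher_alpha(0, 100)


class TestTernary:
    def test_porcellaneous_only(self):
        anns = [TaxonAnnotation("q", "heterotrophic", "porcellaneous")]
        t = fs.ternary_composition({"q": 55.0}, anns)
        assert (t.hyaline_pct, t.porcellaneous_pct, t.agglutinated_pct) == (0, 100, 0)

    def test_hand_computed_shares(self):
        anns = [TaxonAnnotation("h", "heterotrophic", "hyaline"),
                TaxonAnnotation("p", "heterotrophic", "porcellaneous"),
                TaxonAnnotation("g", "heterotrophic", "agglutinated")]
        t = fs.ternary_composition({"h": 30, "p": 10, "g": 10}, anns)
        assert (t.hyaline_pct, t.porcellaneous_pct, t.agglutinated_pct) == \
            pytest.approx((60, 20, 20))

    def test_shares_sum_to_100(self, galapagos):
        a, taxa, _ = galapagos
        table = fs.ternary_table(a, taxa)
        total = table.sum(axis=1)
        assert np.allclose(total, 100.0, atol=1e-9)

    def test_unknown_wall_error(self):
        anns = [TaxonAnnotation("u", "heterotrophic", "unknown")]
        with pytest.raises(ValidationError, match="wall"):
            fs.ternary_composition({"u": 10.0}, anns)

    def test_galapagos_wall_geography(self, galapagos):
        """Agglutinated share peaks in Isabela; SC and FL are hyaline-dominated."""
        a, taxa, _ = galapagos
        table = fs.ternary_table(a, taxa, by_island=True)
        assert table["agglutinated_pct"].idxmax() == "IS"
        for island in ("SC", "FL"):
            row = table.loc[island]
            assert row["hyaline_pct"] > row["porcellaneous_pct"]
            assert row["hyaline_pct"] > row["agglutinated_pct"]


def test_indices_table_columns(galapagos):
    a, taxa, _ = galapagos
    ref = fs.load_galapagos_reference()
    table = fs.indices_table(
        a, taxa,
        specimen_counts=ref["N"].to_dict(), richness=ref["S"].to_dict(),
    )
    assert list(table.columns) == [
        "S", "N", "fisher_alpha", "T", "Ps", "Po", "Ph", "FI", "category"]
    assert np.allclose(table[["Ps", "Po", "Ph"]].sum(axis=1), 1.0, atol=1e-9)
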