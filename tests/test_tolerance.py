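import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calciphile import (
    chi_square_2x2,
    lime_contingency,
    predict_tolerance,
    taxon_quartiles,
    taxonomy_summary,
)

from conftest import make_linked


def quantile_oracle(values, q):
    """Order-statistic interpolation, written from the definition:
    order statistic k (1-based) of n sits at probability (k-1)/(n-1)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = q * (n - 1)
    k = int(np.floor(h))
    if k >= n - 1:
        return xs[-1]
    return xs[k] + (h - k) * (xs[k + 1] - xs[k])


def linked_for_taxon(name, ph_values, caco3=0.0, **extra):
    return make_linked(
        [
            dict({"latin_name": name, "t_ph_h2o": v, "t_caco3": caco3}, **extra)
            for v in ph_values
        ]
    )


class TestTaxonQuartiles:
    def test_constant_sample(self):
        linked = linked_for_taxon("A", [7.8] * 12)
        out = taxon_quartiles(linked)
        row = out.iloc[0]
        assert row["ph_lq"] == row["ph_median"] == row["ph_uq"] == 7.8
        assert row["n"] == 12

    def test_one_to_nine(self):
        linked = linked_for_taxon("A", list(range(1, 10)) + [np.nan] * 0)
        out = taxon_quartiles(linked, min_n=9)
        row = out.iloc[0]
        assert row["ph_lq"] == 3.0
        assert row["ph_median"] == 5.0
        assert row["ph_uq"] == 7.0

    def test_min_n_cutoff(self):
        linked = pd.concat(
            [linked_for_taxon("Few", [6.0] * 9), linked_for_taxon("Many", [6.0] * 10)],
            ignore_index=True,
        )
        out = taxon_quartiles(linked, min_n=10)
        assert list(out["latin_name"]) == ["Many"]

    def test_ranks_are_separate_taxa(self):
        linked = pd.concat(
            [
                linked_for_taxon("R. alpha", [5.0] * 10, rank="species"),
                linked_for_taxon("R. alpha var. beta", [8.0] * 10, rank="variety"),
            ],
            ignore_index=True,
        )
        out = taxon_quartiles(linked)
        assert len(out) == 2

    def test_per_class_percentages(self):
        linked = linked_for_taxon("A", [5.0] * 5 + [8.0] * 5)
        out = taxon_quartiles(linked)
        row = out.iloc[0]
        assert row["pct_ph_4.5-5.5"] == 50.0
        assert row["pct_ph_7.2-8.5"] == 50.0
        assert row["pct_caco3_<2"] == 100.0

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(29)
        frames = []
        expected = {}
        for i in range(300):
            name = f"T{i:03d}"
            n = int(rng.integers(10, 60))
            vals = np.round(rng.uniform(3.5, 9.5, n), 1)
            frames.append(linked_for_taxon(name, vals))
            expected[name] = [quantile_oracle(vals, q) for q in (0.25, 0.5, 0.75)]
        out = taxon_quartiles(pd.concat(frames, ignore_index=True))
        for row in out.itertuples():
            lq, med, uq = expected[row.latin_name]
            assert row.ph_lq == pytest.approx(lq, abs=1e-12)
            assert row.ph_median == pytest.approx(med, abs=1e-12)
            assert row.ph_uq == pytest.approx(uq, abs=1e-12)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(31)
        vals = rng.uniform(3.5, 9.5, 25)
        out = taxon_quartiles(linked_for_taxon("A", vals))
        row = out.iloc[0]
        assert row["ph_lq"] <= row["ph_median"] <= row["ph_uq"]


class TestPredictTolerance:
    @staticmethod
    def summary_row(ph_uq, caco3_uq):
        return pd.DataFrame(
            [
                {
                    "latin_name": "A",
                    "rank": "species",
                    "subgenus": "X",
                    "n": 20,
                    "ph_uq": ph_uq,
                    "caco3_uq": caco3_uq,
                }
            ]
        )

    def test_both_above_thresholds(self):
        out = predict_tolerance(self.summary_row(8.0, 7.0))
        assert bool(out.iloc[0]["tolerant"])

    def test_ph_exactly_at_threshold_not_tolerant(self):
        out = predict_tolerance(self.summary_row(7.2, 5.0))
        assert not bool(out.iloc[0]["tolerant"])

    def test_caco3_exactly_at_threshold_not_tolerant(self):
        out = predict_tolerance(self.summary_row(8.0, 2.0))
        assert not bool(out.iloc[0]["tolerant"])

    def test_monotone_in_ph(self):
        # raising any specimen's pH cannot flip a taxon tolerant -> non-tolerant
        rng = np.random.default_rng(37)
        vals = np.round(rng.uniform(6.5, 8.5, 15), 1)
        base = taxon_quartiles(linked_for_taxon("A", vals, caco3=5.0))
        before = bool(predict_tolerance(base).iloc[0]["tolerant"])
        for i in range(len(vals)):
            bumped = vals.copy()
            bumped[i] += 1.0
            after = bool(
                predict_tolerance(
                    taxon_quartiles(linked_for_taxon("A", bumped, caco3=5.0))
                ).iloc[0]["tolerant"]
            )
            if before:
                assert after


class TestLimeContingency:
    @staticmethod
    def predictions(**tolerant_by_name):
        return pd.DataFrame(
            [
                {"latin_name": name, "tolerant": tol}
                for name, tol in tolerant_by_name.items()
            ]
        )

    def test_lime_classification(self):
        linked = make_linked(
            [{"latin_name": "A", "t_ph_h2o": 7.5, "t_caco3": 5.0}] * 10
        )
        counts, n_mixed = lime_contingency(linked, self.predictions(A=True))
        assert counts[0, 0] == 10 and n_mixed == 0

    def test_mixed_excluded(self):
        linked = make_linked(
            [{"latin_name": "A", "t_ph_h2o": 7.5, "t_caco3": 1.0}] * 10
        )
        counts, n_mixed = lime_contingency(linked, self.predictions(A=True))
        assert counts.sum() == 0 and n_mixed == 10

    def test_unpredicted_small_taxon_goes_non_tolerant(self):
        linked = make_linked(
            [{"latin_name": "Small", "t_ph_h2o": 7.5, "t_caco3": 5.0}] * 5
        )
        counts, _ = lime_contingency(linked, self.predictions(Other=True))
        assert counts[1, 0] == 5

    def test_unpredicted_small_taxon_excluded_policy(self):
        linked = make_linked(
            [{"latin_name": "Small", "t_ph_h2o": 7.5, "t_caco3": 5.0}] * 5
        )
        counts, _ = lime_contingency(
            linked, self.predictions(Other=True), unpredicted_taxa="exclude"
        )
        assert counts.sum() == 0

    def test_missing_prediction_for_large_taxon_raises(self):
        linked = make_linked(
            [{"latin_name": "Big", "t_ph_h2o": 7.5, "t_caco3": 5.0}] * 15
        )
        with pytest.raises(ValueError, match="prediction missing"):
            lime_contingency(linked, self.predictions(Other=True))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(41)
        records = []
        tolerant_map = {"A": True, "B": False, "C": True, "D": False}
        for _ in range(400):
            records.append(
                {
                    "latin_name": rng.choice(list(tolerant_map)),
                    "t_ph_h2o": round(rng.uniform(4.0, 9.0), 1),
                    "t_caco3": round(rng.choice([0.0, 1.0, 3.0, 8.0]), 1),
                }
            )
        linked = make_linked(records)
        predictions = self.predictions(**tolerant_map)
        counts, n_mixed = lime_contingency(linked, predictions)
        brute = np.zeros((2, 2), dtype=int)
        brute_mixed = 0
        for rec in linked.itertuples():
            lime = rec.t_ph_h2o > 7.2 and rec.t_caco3 > 2.0
            non_lime = rec.t_ph_h2o <= 7.2 and rec.t_caco3 <= 2.0
            if not lime and not non_lime:
                brute_mixed += 1
                continue
            i = 0 if tolerant_map[rec.latin_name] else 1
            j = 0 if lime else 1
            brute[i, j] += 1
        np.testing.assert_array_equal(counts, brute)
        assert n_mixed == brute_mixed
        assert counts.sum() + n_mixed == len(linked)


class TestChiSquare:
    def test_paper_style_table(self):
        result = chi_square_2x2(np.array([[2995, 5443], [3475, 19111]]))
        assert result.statistic == pytest.approx(1503.7, abs=0.1)
        assert result.df == 1
        assert result.p < 2.2e-16
        assert result.p_text() == "< 2.2e-16"

    def test_proportional_rows_give_zero(self):
        result = chi_square_2x2(np.array([[10, 20], [30, 60]]), correction=False)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_yates_closed_form_example(self):
        # N(|ad-bc| - N/2)^2 / (r1 r2 c1 c2) for (10,20;20,10) = 5.4
        result = chi_square_2x2(np.array([[10, 20], [20, 10]]), correction=True)
        assert result.statistic == pytest.approx(5.4, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 5], [0, 5]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[-1, 5], [5, 5]]))

    @given(
        a=st.integers(1, 500),
        b=st.integers(1, 500),
        c=st.integers(1, 500),
        d=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_uncorrected_matches_closed_form(self, a, b, c, d):
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        result = chi_square_2x2(np.array([[a, b], [c, d]]), correction=False)
        assert result.statistic == pytest.approx(closed, rel=1e-9)

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(43)
        for _ in range(50):
            table = rng.integers(1, 1000, size=(2, 2))
            ours = chi_square_2x2(table, correction=True)
            ref_stat, ref_p, ref_df, _ = chi2_contingency(table, correction=True)
            assert ours.statistic == pytest.approx(ref_stat, rel=1e-12)
            assert ours.p == pytest.approx(ref_p, rel=1e-9)
            assert ours.df == ref_df


def expand_taxa(spec_counts):
    """specimen table from {(name, rank, subgenus): n_specimens}."""
    frames = []
    for (name, rank, subgenus), n in spec_counts.items():
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": [f"{name}_{i}" for i in range(n)],
                    "latin_name": name,
                    "rank": rank,
                    "subgenus": subgenus,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestTaxonomySummary:
    def test_counts_and_coverage(self):
        described = pd.DataFrame(
            [
                {"kind": "subgenus", "name": "SgA", "described": 10},
                {"kind": "subgenus", "name": "SgB", "described": 5},
                {"kind": "rank", "name": "species", "described": 10},
                {"kind": "rank", "name": "variety", "described": 4},
                {"kind": "rank", "name": "subspecies", "described": 2},
            ]
        )
        specimens = expand_taxa(
            {
                ("S1", "species", "SgA"): 30,
                ("S2", "species", "SgA"): 20,
                ("S3", "species", "SgB"): 10,
                ("V1", "variety", "SgA"): 5,
                ("U1", "subspecies", "SgB"): 5,
            }
        )
        summary = taxonomy_summary(specimens, described, top_n=2)
        assert summary.n_species == 3
        assert summary.n_varieties == 1
        assert summary.n_subspecies == 1
        assert summary.n_taxa == 5
        assert summary.species_by_subgenus["SgA"] == 2
        assert summary.species_by_subgenus.sum() == summary.n_species
        assert summary.coverage_pct["species"] == 30.0
        assert summary.coverage_pct["variety"] == 25.0
        assert summary.coverage_pct["subspecies"] == 50.0
        # top-2 = 50 of 70 specimens
        assert summary.top_share_pct == pytest.approx(71.4)

    def test_unknown_subgenus_rejected(self):
        described = pd.DataFrame(
            [{"kind": "subgenus", "name": "SgA", "described": 10}]
        )
        specimens = expand_taxa({("S1", "species", "Mystery"): 3})
        with pytest.raises(KeyError):
            taxonomy_summary(specimens, described)

    def test_empty_dataset(self):
        summary = taxonomy_summary(
            pd.DataFrame(columns=["specimen_id", "latin_name", "rank", "subgenus"]),
            None,
        )
        assert summary.n_taxa == 0
        assert summary.n_specimens == 0
        assert summary.top_share_pct == 0.0
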