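import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from protomix import tmt
from protomix.synthetic import CohortConfig, generate_cohort, generate_expression, generate_psm_table
from protomix.tmt import (
    RatioMatrix,
    SchemaError,
    filter_psms,
    iqr_trim,
    mad_normalize,
    psm_ratios,
    reference_intensity,
    summarize_level,
    to_abundance,
)


def make_design(n_channels=4, n_plex=1):
    rows = []
    for p in range(1, n_plex + 1):
        for c in range(1, n_channels):
            rows.append((f"plex{p:02d}", f"ch{c:02d}", f"S{p}_{c}", False))
        rows.append((f"plex{p:02d}", f"ch{n_channels:02d}", f"REF{p}", True))
    return pd.DataFrame(rows, columns=["plex", "channel", "sample", "is_reference"])


def make_psm(rows, n_channels=4):
    """rows: list of dicts with intensities as tuple under 'i'."""
    recs = []
    for k, r in enumerate(rows):
        rec = {
            "plex": r.get("plex", "plex01"),
            "spectrum": r.get("spectrum", f"sp{k:04d}"),
            "peptide": r.get("peptide", f"PEP{k}"),
            "charge": r.get("charge", 2),
            "gene": r.get("gene", "G1"),
            "protein": r.get("protein", "P1"),
            "labeled": r.get("labeled", True),
            "contaminant": r.get("contaminant", False),
            "precursor_purity": r.get("purity", 0.9),
            "ms1_intensity": r.get("ms1", 100.0),
        }
        for ci, v in enumerate(r["i"], start=1):
            rec[f"intensity_ch{ci:02d}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilterPSMs:
    def test_purity_boundary(self):
        design = make_design()
        psm = make_psm([
            {"i": (10, 10, 10, 10), "purity": 0.49},
            {"i": (10, 10, 10, 10), "purity": 0.50},
        ])
        out = filter_psms(psm, design)
        assert list(out["precursor_purity"]) == [0.50]

    def test_redundancy_keeps_highest_summed(self):
        design = make_design()
        psm = make_psm([
            {"i": (2, 2, 2, 4), "peptide": "A", "spectrum": "a"},
            {"i": (4, 4, 4, 8), "peptide": "A", "spectrum": "b"},
        ])
        out = filter_psms(psm, design)
        assert list(out["spectrum"]) == ["b"]

    def test_redundancy_tie_first_spectrum(self):
        design = make_design()
        psm = make_psm([
            {"i": (4, 4, 4, 8), "peptide": "A", "spectrum": "b"},
            {"i": (4, 4, 4, 8), "peptide": "A", "spectrum": "a"},
        ])
        out = filter_psms(psm, design)
        assert list(out["spectrum"]) == ["a"]

    def test_unlabeled_and_contaminant_removed(self):
        design = make_design()
        psm = make_psm([
            {"i": (10, 10, 10, 10), "labeled": False, "peptide": "A"},
            {"i": (10, 10, 10, 10), "contaminant": True, "peptide": "B"},
            {"i": (10, 10, 10, 10), "peptide": "C"},
        ])
        out = filter_psms(psm, design)
        assert list(out["peptide"]) == ["C"]

    def test_missing_reference_removed(self):
        design = make_design()
        psm = make_psm([
            {"i": (10, 10, 10, 0), "peptide": "A"},
            {"i": (10, 10, 10, 5), "peptide": "B"},
        ])
        out = filter_psms(psm, design)
        assert list(out["peptide"]) == ["B"]

    def test_no_reference_channel_errors(self):
        design = make_design()
        design["is_reference"] = False
        with pytest.raises(SchemaError):
            filter_psms(make_psm([{"i": (1, 1, 1, 1)}]), design)

    def test_idempotent(self, rng):
        design = make_design()
        psm = make_psm([
            {"i": tuple(rng.uniform(1, 100, 4)), "peptide": f"P{k}"}
            for k in range(50)
        ])
        once = filter_psms(psm, design)
        twice = filter_psms(once, design)
        pd.testing.assert_frame_equal(once, twice)

    def test_brute_force_oracle(self, rng):
        """Survivors equal sequential application of each rule independently."""
        design = make_design()
        rows = []
        for k in range(200):
            rows.append({
                "i": tuple(rng.uniform(1, 100, 4)),
                "peptide": f"P{k % 120}",  # some redundancy
                "purity": float(rng.uniform(0.3, 1.0)),
                "labeled": bool(rng.random() > 0.05),
                "contaminant": bool(rng.random() < 0.05),
                "spectrum": f"sp{k:04d}",
            })
        # plant missing reference
        for k in rng.choice(200, 10, replace=False):
            lst = list(rows[k]["i"])
            lst[3] = 0.0
            rows[k]["i"] = tuple(lst)
        psm = make_psm(rows)
        out = filter_psms(psm, design)

        # oracle: one rule at a time, in the stated order
        t = psm.copy()
        t = t[t.labeled]
        t = t[t["intensity_ch04"] > 0]
        t = t[t.precursor_purity >= 0.5]
        icols = [c for c in t.columns if c.startswith("intensity_")]
        summed = t[icols].sum(axis=1)
        floor = np.percentile(summed, 5.0)
        t = t[summed >= floor]
        t = t[~t.contaminant]
        summed = t[icols].sum(axis=1)
        t = t.assign(_s=summed).sort_values(
            ["peptide", "_s", "spectrum"], ascending=[True, False, True]
        ).drop_duplicates(["peptide"], keep="first").drop(columns="_s")
        assert sorted(out["spectrum"]) == sorted(t["spectrum"])


class TestRatios:
    def test_reference_equal_gives_zero(self):
        design = make_design()
        psm = make_psm([{"i": (5, 10, 20, 10)}])
        long = psm_ratios(psm, design)
        by_sample = long.set_index("sample")["ratio"]
        assert by_sample["S1_2"] == pytest.approx(0.0)
        assert by_sample["S1_3"] == pytest.approx(1.0)
        assert by_sample["S1_1"] == pytest.approx(-1.0)

    def test_zero_channel_is_missing_not_neginf(self):
        design = make_design()
        psm = make_psm([{"i": (0, 10, 10, 10)}])
        long = psm_ratios(psm, design)
        val = long.set_index("sample").loc["S1_1", "ratio"]
        assert np.isnan(val)

    def test_random_matches_log2_quotient(self, rng):
        design = make_design()
        psm = make_psm([{"i": tuple(rng.uniform(1, 100, 4)), "peptide": f"P{k}"}
                        for k in range(30)])
        long = psm_ratios(psm, design)
        for _, row in long.iterrows():
            src = psm[psm.peptide == row.peptide].iloc[0]
            ch = make_design().set_index("sample").loc[row["sample"], "channel"]
            expected = np.log2(src[f"intensity_{ch}"]) - np.log2(src["intensity_ch04"])
            assert row.ratio == pytest.approx(expected)


class TestIQRTrim:
    def test_example_from_fences(self):
        # Q1=2, Q3=4 by linear interpolation, upper fence 7 -> 100 removed
        out = iqr_trim([1, 2, 3, 4, 100])
        assert list(out) == [1, 2, 3, 4]

    def test_constant_unchanged(self):
        out = iqr_trim([5.0] * 10)
        assert list(out) == [5.0] * 10

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            iqr_trim([np.nan])

    def test_brute_force_1000(self, rng):
        v = rng.normal(0, 1, 1000)
        q1, q3 = np.percentile(v, [25, 75])
        fence_lo, fence_hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expected = [x for x in v if fence_lo <= x <= fence_hi]
        np.testing.assert_allclose(np.sort(iqr_trim(v)), np.sort(expected))

    @given(hst.lists(hst.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_property_subset_and_fences(self, vals):
        out = iqr_trim(vals)
        v = np.asarray(vals, float)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        assert np.all(out >= q1 - 1.5 * iqr - 1e-9)
        assert np.all(out <= q3 + 1.5 * iqr + 1e-9)


class TestSummarize:
    def test_single_psm_passthrough(self):
        design = make_design()
        psm = make_psm([{"i": (5, 10, 20, 10), "gene": "G1"}])
        mat = summarize_level(psm_ratios(psm, design), "gene").values
        assert mat.loc["G1", "S1_3"] == pytest.approx(1.0)

    def test_outlier_trimmed_before_median(self):
        design = make_design()
        # three PSMs of one gene in one sample with ratios 0, 0, 10
        psm = make_psm([
            {"i": (10, 10, 10, 10), "gene": "G1", "peptide": "A"},
            {"i": (10, 10, 10, 10), "gene": "G1", "peptide": "B"},
            {"i": (10, 10, 10240, 10), "gene": "G1", "peptide": "C"},
        ])
        mat = summarize_level(psm_ratios(psm, design), "gene").values
        assert mat.loc["G1", "S1_3"] == pytest.approx(0.0)

    def test_groupby_trim_median_oracle(self, rng):
        design = make_design()
        psm = make_psm([
            {"i": tuple(rng.uniform(1, 100, 4)), "gene": f"G{k % 5}", "peptide": f"P{k}"}
            for k in range(40)
        ])
        long = psm_ratios(psm, design)
        mat = summarize_level(long, "gene").values
        for g in [f"G{i}" for i in range(5)]:
            for s in ["S1_1", "S1_2", "S1_3"]:
                vals = long[(long.gene == g) & (long["sample"] == s)]["ratio"].dropna()
                expected = np.median(iqr_trim(vals.to_numpy()))
                assert mat.loc[g, s] == pytest.approx(expected)

    def test_unknown_level_errors(self):
        design = make_design()
        long = psm_ratios(make_psm([{"i": (1, 1, 1, 1)}]), design)
        with pytest.raises(ValueError):
            summarize_level(long, "nope")


class TestMADNormalize:
    def test_single_sample_identity(self, rng):
        df = pd.DataFrame({"S1": rng.normal(0, 1, 30)})
        out = mad_normalize(RatioMatrix("gene", df))
        pd.testing.assert_frame_equal(out.values, df)

    def test_affine_disturbance_removed(self, rng):
        base = rng.normal(0, 1, 50)
        df = pd.DataFrame({"A": base, "B": 2.0 * base - 3.0})
        out = mad_normalize(RatioMatrix("gene", df)).values
        assert out["A"].median() == pytest.approx(out["B"].median())
        mad = lambda c: (c - c.median()).abs().median()  # noqa: E731
        assert mad(out["A"]) == pytest.approx(mad(out["B"]))

    def test_columns_hit_global_median_and_mad(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (50, 8)),
                          columns=[f"S{i}" for i in range(8)])
        out = mad_normalize(RatioMatrix("gene", df))
        for c in out.values.columns:
            col = out.values[c]
            assert col.median() == pytest.approx(out.global_median, abs=1e-9)
            mad = (col - col.median()).abs().median()
            assert mad == pytest.approx(out.global_mad, abs=1e-9)

    def test_missing_passthrough(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("ABC"))
        df.iloc[0, 0] = np.nan
        out = mad_normalize(RatioMatrix("gene", df)).values
        assert np.isnan(out.iloc[0, 0])

    def test_zero_mad_names_sample(self):
        df = pd.DataFrame({"GOOD": [1.0, 2.0, 3.0], "BAD": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="BAD"):
            mad_normalize(RatioMatrix("gene", df))


class TestReferenceIntensity:
    def test_single_ion(self):
        design = make_design()
        psm = make_psm([{"i": (30, 30, 30, 10), "ms1": 100.0}])
        ref = reference_intensity(psm, design, "gene")
        assert ref["G1"] == pytest.approx(100.0 * 10 / 100)

    def test_top3_only(self):
        design = make_design()
        rows = [{"i": (10, 10, 10, 10), "ms1": ms1, "peptide": f"P{k}", "gene": "G1"}
                for k, ms1 in enumerate([1, 2, 100, 200, 300])]
        ref = reference_intensity(make_psm(rows), design, "gene")
        # weight = 10/40 = 0.25 for all; top3 ms1 = 100+200+300
        assert ref["G1"] == pytest.approx(600 * 0.25)

    def test_brute_force_random(self, rng):
        design = make_design(n_channels=4, n_plex=2)
        rows = []
        for k in range(30):
            rows.append({
                "i": tuple(rng.uniform(1, 50, 4)),
                "ms1": float(rng.uniform(10, 1000)),
                "peptide": f"P{k}",
                "gene": f"G{k % 3}",
                "plex": f"plex{(k % 2) + 1:02d}",
            })
        psm = make_psm(rows)
        ref = reference_intensity(psm, design, "gene")
        for g in [f"G{i}" for i in range(3)]:
            per_plex = []
            for p in ["plex01", "plex02"]:
                sub = psm[(psm.gene == g) & (psm.plex == p)]
                if sub.empty:
                    continue
                top = sub.nlargest(3, "ms1_intensity")
                icols = [c for c in psm.columns if c.startswith("intensity_")]
                w = top["intensity_ch04"] / top[icols].sum(axis=1)
                per_plex.append(float((top["ms1_intensity"] * w).sum()))
            assert ref[g] == pytest.approx(np.mean(per_plex))

    def test_imputation_with_global_min(self):
        design = make_design()
        psm = make_psm([{"i": (30, 30, 30, 10), "ms1": 100.0, "gene": "G1"}])
        ref = reference_intensity(psm, design, "gene", impute_entries=["G1", "G2"])
        assert ref["G2"] == ref["G1"]


class TestToAbundance:
    def test_ref_one_identity(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (5, 3)), index=list("abcde"))
        m = RatioMatrix("gene", df)
        ref = pd.Series(1.0, index=df.index)
        pd.testing.assert_frame_equal(to_abundance(m, ref), df)

    def test_ref_eight_shifts_three(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (5, 3)), index=list("abcde"))
        ref = pd.Series(8.0, index=df.index)
        out = to_abundance(RatioMatrix("gene", df), ref)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy() + 3.0)

    def test_nonpositive_ref_errors(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (2, 2)), index=list("ab"))
        ref = pd.Series([1.0, 0.0], index=list("ab"))
        with pytest.raises(ValueError):
            to_abundance(RatioMatrix("gene", df), ref)


class TestEndToEnd:
    def test_zero_noise_recovers_planted_ratios(self, noiseless_config):
        cohort = generate_cohort(noiseless_config)
        res = tmt.quantify(cohort.psm, cohort.design, level="gene")
        expr = cohort.matrices["protein"]
        expected = expr.sub(np.log2(np.power(2.0, expr).mean(axis=1)), axis=0)
        got = res["ratios"].values.loc[expected.index, expected.columns]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(), atol=1e-9)

    def test_monotone_in_psm_ratio(self):
        design = make_design()
        base = [
            {"i": (10, 10, 10, 10), "gene": "G1", "peptide": "A"},
            {"i": (12, 10, 10, 10), "gene": "G1", "peptide": "B"},
            {"i": (14, 10, 10, 10), "gene": "G1", "peptide": "C"},
        ]
        m1 = summarize_level(psm_ratios(make_psm(base), design), "gene").values
        base[1]["i"] = (13, 10, 10, 10)  # raise one surviving ratio
        m2 = summarize_level(psm_ratios(make_psm(base), design), "gene").values
        assert m2.loc["G1", "S1_1"] >= m1.loc["G1", "S1_1"]
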