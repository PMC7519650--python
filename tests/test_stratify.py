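import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemomics import stratify


class TestResponseLabel:
    def test_nac_complete_downstaging(self):
        assert stratify.response_label({"treatment_context": "NAC", "post_cx_stage": "pT0N0"})

    def test_nac_noninvasive_downstaging(self):
        assert stratify.response_label({"treatment_context": "NAC", "post_cx_stage": "pTaN0"})
        assert stratify.response_label({"treatment_context": "NAC", "post_cx_stage": "CISN0"})

    def test_nac_residual_invasive_disease(self):
        assert not stratify.response_label(
            {"treatment_context": "NAC", "post_cx_stage": "pT2N0"}
        )
        assert not stratify.response_label(
            {"treatment_context": "NAC", "post_cx_stage": "pT0N1"}
        )

    def test_first_line_recist(self):
        rec = {"treatment_context": "first_line", "recist": "PR"}
        assert stratify.response_label(rec)
        assert not stratify.response_label({**rec, "recist": "SD"})
        assert not stratify.response_label({**rec, "recist": "PD"})

    def test_definitive_cr_downgrade(self):
        rec = {
            "treatment_context": "first_line",
            "recist": "CR",
            "bladder_intact": True,
            "post_cr_path_stage": "pT2",
        }
        assert not stratify.response_label(rec)
        assert stratify.response_label({**rec, "post_cr_path_stage": "pT0"})
        assert stratify.response_label({**rec, "post_cr_path_stage": "pTa"})

    def test_cr_without_bladder_or_pathology_stands(self):
        assert stratify.response_label(
            {"treatment_context": "first_line", "recist": "CR", "bladder_intact": False}
        )
        assert stratify.response_label(
            {"treatment_context": "first_line", "recist": "CR", "bladder_intact": True}
        )

    def test_missing_fields_unevaluable(self):
        assert stratify.response_label({"treatment_context": "NAC"}) is None
        assert stratify.response_label({"treatment_context": "first_line", "recist": "NA"}) is None
        # NAC stage without a nodal component is unevaluable, not non-responder
        assert (
            stratify.response_label({"treatment_context": "NAC", "post_cx_stage": "pT0"}) is None
        )

    def test_both_contexts_use_first_line(self):
        rec = {
            "treatment_context": "both",
            "post_cx_stage": "pT0N0",  # NAC says responder
            "recist": "PD",  # first-line says non-responder, and wins
        }
        assert not stratify.response_label(rec)


class TestGenomicInstabilityGroup:
    def features(self, **over):
        base = pd.DataFrame(
            {
                "sbs5_count": [100.0, 200.0, 300.0, 400.0],
                "indel_count": [10.0, 20.0, 30.0, 40.0],
                "percent_ai": [5.0, 10.0, 20.0, 40.0],
                "brca2_mutated": [False, False, False, False],
            },
            index=list("abcd"),
        )
        for k, v in over.items():
            base[k] = v
        return base

    def test_all_below_median_is_lgi(self):
        labels = stratify.genomic_instability_group(self.features())
        assert labels["a"] == "LGI" and labels["d"] == "HGI"

    def test_brca2_alone_is_hgi(self):
        f = self.features(brca2_mutated=[True, False, False, False])
        assert stratify.genomic_instability_group(f)["a"] == "HGI"

    def test_exact_median_is_lgi(self):
        """Strictly-above-median rule: sitting exactly at all medians -> LGI."""
        f = pd.DataFrame(
            {
                "sbs5_count": [100.0, 100.0, 100.0],
                "indel_count": [10.0, 10.0, 10.0],
                "percent_ai": [5.0, 5.0, 5.0],
                "brca2_mutated": [False] * 3,
            }
        )
        assert (stratify.genomic_instability_group(f) == "LGI").all()

    def test_any_single_feature_above_median_is_hgi(self):
        f = self.features(indel_count=[100.0, 20.0, 30.0, 40.0])
        assert stratify.genomic_instability_group(f)["a"] == "HGI"


class TestFisherMachinery:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals the sum of hypergeometric probabilities
        of tables at most as probable, for all margins <= 12."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            n, r1, c1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            probs = {
                x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)
            }
            p_enum = sum(p for x, p in probs.items() if p <= probs[a] * (1 + 1e-9))
            assert p_scipy == pytest.approx(p_enum, abs=1e-9)

    def test_or_invariances(self):
        a, b, c, d = 8, 3, 5, 9
        or1 = stratify._fisher_or(a, b, c, d)[0]
        # swapping both rows and both columns leaves the OR unchanged
        or2 = stratify._fisher_or(d, c, b, a)[0]
        assert or1 == pytest.approx(or2)
        # swapping one pair inverts it
        or3 = stratify._fisher_or(b, a, d, c)[0]
        assert or3 == pytest.approx(1.0 / or1)

    def test_no_association_table(self):
        or_, lo, hi, p, zero = stratify._fisher_or(1, 1, 1, 1)
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert not zero


class TestStratifyResponse:
    def test_planted_rates_recovered(self, rng):
        n = 100
        rows = []
        rates = {
            ("HGI", False): 0.8,
            ("HGI", True): 0.6,
            ("LGI", False): 0.5,
            ("LGI", True): 0.25,
        }
        for (inst, basq), rate in rates.items():
            for _ in range(n):
                rows.append((inst, basq, rng.random() < rate))
        df = pd.DataFrame(rows, columns=["inst", "basq", "resp"])
        res = stratify.stratify_response(df["inst"], df["basq"], df["resp"])
        for (inst, basq), rate in rates.items():
            name = f"{inst}/{'Ba-Sq' if basq else 'non-Ba-Sq'}"
            got = res["strata"][name]["rate"]
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(got - rate) < 4 * se
        assert res["chi2_p"] < 1e-3
        assert res["extreme_contrast"]["hgi_non_basq_rate"] > res["extreme_contrast"]["lgi_basq_rate"]

    def test_single_stratum_contrast_unavailable(self):
        df = pd.DataFrame(
            {"inst": ["HGI"] * 6, "basq": [False] * 6, "resp": [True, False] * 3}
        )
        res = stratify.stratify_response(df["inst"], df["basq"], df["resp"])
        assert res["extreme_contrast"] is None


class TestAssociationTable:
    def test_tcga_brca2_anchor(self):
        """6/0 responders among mutants vs 34/22 among wild-type."""
        feat = pd.DataFrame({"BRCA2_mut": [True] * 6 + [False] * 56})
        resp = pd.Series([True] * 6 + [True] * 34 + [False] * 22)
        row = stratify.association_table(feat, resp).iloc[0]
        assert round(row["fisher_p"], 2) == 0.08
        assert row["zero_cell"]

    def test_continuous_feature_dichotomized_with_logistic_p(self, rng):
        n = 80
        x = rng.normal(0, 1, n)
        resp = pd.Series(rng.random(n) < 1 / (1 + np.exp(-2 * x)))
        feat = pd.DataFrame({"score": x})
        row = stratify.association_table(feat, resp).iloc[0]
        assert row["logistic_p"] < 0.01
        assert row["odds_ratio"] > 1

    def test_constant_feature_rejected(self):
        feat = pd.DataFrame({"x": [1.0] * 10})
        resp = pd.Series([True, False] * 5)
        with pytest.raises(ValueError, match="constant"):
            stratify.association_table(feat, resp)

    def test_subgroup_rows_emitted(self, rng):
        n = 40
        feat = pd.DataFrame({"f": rng.random(n) < 0.5})
        resp = pd.Series(rng.random(n) < 0.5)
        sub = pd.Series(["NAC"] * 20 + ["first_line"] * 20)
        table = stratify.association_table(feat, resp, subgroups=sub)
        assert set(table["subgroup"]) == {"all", "NAC", "first_line"}
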