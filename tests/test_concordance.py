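import numpy as np
import pandas as pd
import pytest

from antagmap.concordance import (
    CaseControlEffect,
    classify_triplet,
    find_opposed_idps,
    hemisphere_merge,
    lookup_case_control,
    read_case_control,
    triangulate,
)
from antagmap.errors import InputError
from antagmap.fdr_scan import significant_table
from antagmap.sumstats_io import TargetSnp
from antagmap.synthetic_data import gen_case_control_table, paper_case_control_fixture


def _cc(disorder="SCZ", region="superior temporal", measure="SA",
        hemisphere="both", d=-0.196, p=1e-8):
    return CaseControlEffect(disorder, region, measure, hemisphere, d, p)


class TestHemisphereMerge:
    def test_published_superior_temporal_example(self):
        left = _cc(hemisphere="left", d=-0.196, p=9.2e-9)
        right = _cc(hemisphere="right", d=-0.195, p=9.3e-7)
        merged = hemisphere_merge(left, right)
        assert merged.d == pytest.approx(-0.1955)
        assert merged.p_adjusted < 0.05
        assert merged.hemisphere == "both"

    def test_sign_disagreement_flagged_nonsignificant(self):
        left = _cc(hemisphere="left", d=-0.2, p=1e-4)
        right = _cc(hemisphere="right", d=+0.2, p=1e-4)
        merged = hemisphere_merge(left, right, policy="both-required")
        assert merged.p_adjusted == 1.0

    def test_one_hemisphere_nonsignificant_fails_both_required(self):
        left = _cc(hemisphere="left", d=-0.2, p=1e-4)
        right = _cc(hemisphere="right", d=-0.1, p=0.4)
        assert hemisphere_merge(left, right).p_adjusted >= 0.05

    def test_either_policy_passes_single_hemisphere_through(self):
        left = _cc(hemisphere="left", d=-0.2, p=1e-4)
        merged = hemisphere_merge(left, None, policy="either")
        assert merged.d == pytest.approx(-0.2)
        assert merged.p_adjusted == pytest.approx(1e-4)

    def test_mismatched_regions_rejected(self):
        with pytest.raises(InputError):
            hemisphere_merge(_cc(hemisphere="left"), _cc(hemisphere="right", region="insula"))


@pytest.fixture
def scz_asd_target(rs9329221_target):
    return rs9329221_target


class TestClassifyTriplet:
    def test_published_mediation_example(self, scz_asd_target):
        # T allele: raises SCZ risk, lowers superior-temporal SA; SCZ patients
        # show significantly lower SA -> direction chain is consistent
        cc = {"SCZ": _cc(d=-0.196, p=1e-8), "ASD": _cc(disorder="ASD", d=0.02, p=0.8)}
        trip = classify_triplet(-12.496, scz_asd_target, cc, idp_id="SA_superior_temporal")
        assert trip.call == "consistent_mediation"
        assert trip.sign_snp_idp == "-"
        assert trip.sign_case_control["SCZ"] == "-"
        assert trip.sign_case_control["ASD"] == "ns"

    def test_sign_conflict_is_inconsistent(self, scz_asd_target):
        cc = {"SCZ": _cc(d=-0.196, p=1e-8), "ASD": None}
        trip = classify_triplet(+5.0, scz_asd_target, cc)
        assert trip.call == "inconsistent"

    def test_opposed_significant_signs(self, scz_asd_target):
        cc = {"SCZ": _cc(d=-0.2, p=1e-4),
              "ASD": _cc(disorder="ASD", d=+0.2, p=1e-4)}
        assert classify_triplet(-1.0, scz_asd_target, cc).call == "opposed_idp"

    def test_both_nonsignificant_indeterminate(self, scz_asd_target):
        cc = {"SCZ": _cc(p=0.9), "ASD": _cc(disorder="ASD", p=0.9)}
        trip = classify_triplet(-1.0, scz_asd_target, cc)
        assert trip.call == "indeterminate"
        assert trip.reason == "non-significant"

    def test_missing_case_control_data_flagged(self):
        target = TargetSnp("rs6748341", "2", 225377574, "C", "G", "SCZ", "ANO")
        trip = classify_triplet(5.788, target, {"SCZ": None, "ANO": None})
        assert trip.call == "indeterminate"
        assert trip.reason == "no-case-control-data"

    def test_invariant_to_reharmonization(self, scz_asd_target):
        # flipping to the other allele negates the IDP effect and swaps the
        # risk/protective annotation; the call must not change
        flipped = TargetSnp("rs9329221", "8", 10240202, "G", "T", "ASD", "SCZ")
        rng = np.random.default_rng(4)
        for _ in range(100):
            effect = rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 10)
            cc = {}
            for disorder in ("SCZ", "ASD"):
                if rng.random() < 0.2:
                    cc[disorder] = None
                else:
                    cc[disorder] = _cc(
                        disorder=disorder,
                        d=float(rng.choice([-1, 1]) * rng.uniform(0.01, 0.3)),
                        p=float(rng.choice([1e-4, 0.5])),
                    )
            a = classify_triplet(effect, scz_asd_target, cc)
            b = classify_triplet(-effect, flipped, cc)
            assert a.call == b.call


class TestFindOpposedIdps:
    def _significant(self):
        return pd.DataFrame(
            {
                "target_snp": ["rs9329221"],
                "used_snp": ["rs9329221"],
                "idp_id": ["SA_superior_temporal"],
                "region": ["superior temporal"],
                "measure": ["SA"],
                "effect": [-12.496],
                "p": [7.93e-12],
            }
        )

    def test_paper_mirroring_fixture_yields_empty_set(self, table1):
        sig = significant_table(table1.grid)
        cc = paper_case_control_fixture()
        pairs = [(t.disorder_risk, t.disorder_protective) for t in table1.targets]
        assert find_opposed_idps(sig, cc, pairs) == []

    def test_planted_opposition_is_found(self):
        cc = gen_case_control_table(
            [
                {"disorder": "SCZ", "region": "superior temporal", "measure": "SA",
                 "d": -0.2, "p_adjusted": 1e-4},
                {"disorder": "ASD", "region": "superior temporal", "measure": "SA",
                 "d": +0.2, "p_adjusted": 1e-4},
            ]
        )
        out = find_opposed_idps(self._significant(), cc, [("SCZ", "ASD")])
        assert out == [("SA_superior_temporal", ("ASD", "SCZ"))]

    def test_symmetric_in_disorder_pair(self):
        cc = gen_case_control_table(
            [
                {"disorder": "SCZ", "region": "superior temporal", "measure": "SA",
                 "d": -0.2, "p_adjusted": 1e-4},
                {"disorder": "ASD", "region": "superior temporal", "measure": "SA",
                 "d": +0.2, "p_adjusted": 1e-4},
            ]
        )
        a = find_opposed_idps(self._significant(), cc, [("SCZ", "ASD")])
        b = find_opposed_idps(self._significant(), cc, [("ASD", "SCZ")])
        assert a == b

    def test_all_nonsignificant_gives_empty(self):
        cc = gen_case_control_table(
            [
                {"disorder": "SCZ", "region": "superior temporal", "measure": "SA",
                 "d": -0.2, "p_adjusted": 1.0},
                {"disorder": "ASD", "region": "superior temporal", "measure": "SA",
                 "d": +0.2, "p_adjusted": 1.0},
            ]
        )
        assert find_opposed_idps(self._significant(), cc, [("SCZ", "ASD")]) == []


class TestIngestion:
    def test_subphenotype_rows_excluded(self, tmp_path):
        df = gen_case_control_table(
            [{"disorder": "MDD", "region": "insula", "measure": "CT",
              "d": -0.1, "p_adjusted": 0.01}]
        )
        df["subphenotype"] = ["", "recurrent episodes"]
        path = tmp_path / "cc.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = read_case_control(path)
        assert len(out) == 1

    def test_lookup_merges_hemispheres(self):
        cc = paper_case_control_fixture()
        merged = lookup_case_control(cc, "SCZ", "superior temporal", "SA")
        assert merged.d == pytest.approx(-0.1955)
        assert merged.p_adjusted < 0.05

    def test_lookup_missing_region_returns_none(self):
        cc = paper_case_control_fixture()
        assert lookup_case_control(cc, "SCZ", "cerebellum", "SA") is None


def test_triangulate_published_fixture_has_mediation_call(table1):
    """At least the superior-temporal SA association must triangulate cleanly."""
    sig = significant_table(table1.grid)
    trips = triangulate(sig, table1.targets, paper_case_control_fixture())
    assert len(trips) == 27
    mediated = {t.snp_id for t in trips if t.call == "consistent_mediation"}
    assert "rs9329221" in mediated
    assert not any(t.call == "opposed_idp" for t in trips)
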