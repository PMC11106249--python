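import itertools
import json

import numpy as np
import pandas as pd
import pytest

from appendhom.homology import (
    build_report,
    call_homology,
    decide_homology,
    shared_proportions,
    tau_homology,
    within_species_distinct,
)


def _de(gene_dirs, analysis_id):
    """Tiny DE table from {gene: direction}."""
    rows = []
    for g, d in gene_dirs.items():
        lfc = {"up": 2.0, "down": -2.0}.get(d, 0.0)
        fdr = 0.01 if d in ("up", "down") else 0.8
        rows.append(
            {"gene_id": g, "analysis_id": analysis_id, "log2fc": lfc,
             "pvalue": fdr / 2, "fdr": fdr, "direction": d}
        )
    return pd.DataFrame(rows)


class TestWithinSpeciesDistinct:
    def test_signal_with_quiet_control_is_retained(self):
        prof = within_species_distinct(
            {"horn_2mo": _de({"A": "up"}, "horn_2mo")},
            {"skin": _de({"A": "ns"}, "skin")},
        )
        assert prof.directions.at["A", "horn_2mo"] == "up"
        assert "A" not in prof.excluded

    def test_same_direction_control_excludes(self):
        prof = within_species_distinct(
            {"horn_2mo": _de({"A": "up"}, "horn_2mo")},
            {"skin": _de({"A": "up"}, "skin")},
        )
        assert prof.directions.at["A", "horn_2mo"] == "ns"
        assert "A" in prof.excluded

    def test_opposite_direction_control_retains_with_flag(self):
        # the bone-signalling pattern: down in pedicle, up in control bone
        prof = within_species_distinct(
            {"pedicle": _de({"MYOC": "down"}, "pedicle")},
            {"bone": _de({"MYOC": "up"}, "bone")},
        )
        assert prof.directions.at["MYOC", "pedicle"] == "down"
        assert prof.control_flags["MYOC"] == ["opposite_in_bone"]

    def test_missing_required_control_is_an_error(self):
        with pytest.raises(ValueError, match="bone"):
            within_species_distinct(
                {"pedicle": _de({"A": "up"}, "pedicle")},
                {"skin": _de({"A": "ns"}, "skin")},
                required_controls=("skin", "bone"),
            )


class TestDecideHomology:
    def test_shared_up_quiet_outgroup_is_homologous(self):
        status, d, sa, sb = decide_homology(
            {"horn_4mo": "up"}, {"pre_cartilage": "up"},
            {"skin": "ns", "bone": "ns", "cartilage_control": "ns"},
        )
        assert status == "homologous" and d == "up"
        assert sa == ("horn_4mo",) and sb == ("pre_cartilage",)

    def test_same_direction_outgroup_excludes(self):
        status, *_ = decide_homology(
            {"horn": "up"}, {"antler_tip": "up"}, {"skin": "up"}
        )
        assert status == "excluded_outgroup"

    def test_opposite_outgroup_direction_does_not_exclude(self):
        status, d, *_ = decide_homology(
            {"horn_2mo": "down"}, {"transition_zone": "down"},
            {"skin": "ns", "bone": "up"},
        )
        assert status == "homologous" and d == "down"

    def test_single_ingroup_signal_is_not_shared(self):
        status, *_ = decide_homology({"horn": "up"}, {"antler": "ns"}, {"skin": "ns"})
        assert status == "not_shared"

    def test_no_outgroup_makes_candidates_untestable(self):
        status, *_ = decide_homology({"horn": "up"}, {"antler": "up"}, None)
        assert status == "untestable_missing_outgroup"

    def test_matches_exhaustive_truth_table_oracle(self):
        """Brute-force enumeration over all direction combinations of one
        analysis per ingroup and one outgroup tissue, against a from-scratch
        restatement of the rule."""
        dirs = ["up", "down", "ns", "absent"]
        opp = {"up": "down", "down": "up"}
        for da, db, do in itertools.product(dirs, repeat=3):
            status, d, sa, sb = decide_homology({"a": da}, {"b": db}, {"o": do})
            sig = {"up", "down"}
            if da in sig and db == da:
                if do in ("ns", "absent") or do == opp[da]:
                    expect = "homologous"
                else:
                    expect = "excluded_outgroup"
            else:
                expect = "not_shared"
            assert status == expect, (da, db, do, status)

    def test_removing_outgroup_never_creates_homologous(self):
        dirs = ["up", "down", "ns", "absent"]
        for da, db, do in itertools.product(dirs, repeat=3):
            with_og, *_ = decide_homology({"a": da}, {"b": db}, {"o": do})
            without, *_ = decide_homology({"a": da}, {"b": db}, None)
            assert without != "homologous"
            if with_og == "homologous":
                assert without == "untestable_missing_outgroup"

    def test_adding_ingroup_tissue_only_grows_support(self):
        base_status, _, sa0, _ = decide_homology(
            {"a1": "up"}, {"b1": "up"}, {"o": "ns"}
        )
        grown_status, _, sa1, _ = decide_homology(
            {"a1": "up", "a2": "up"}, {"b1": "up"}, {"o": "ns"}
        )
        assert base_status == grown_status == "homologous"
        assert set(sa0) <= set(sa1)


class TestCallHomology:
    def _profiles(self):
        prof_a = within_species_distinct(
            {"horn_2mo": _de({"A": "up", "B": "up", "C": "down"}, "horn_2mo")},
            {"skin": _de({"A": "ns", "B": "ns", "C": "ns"}, "skin")},
        )
        prof_b = within_species_distinct(
            {"antler": _de({"A": "up", "B": "up", "C": "ns"}, "antler")},
            {"skin": _de({"A": "ns", "B": "ns", "C": "ns"}, "skin")},
        )
        return prof_a, prof_b

    def test_statuses_and_outgroup_conditioning(self):
        prof_a, prof_b = self._profiles()
        outgroup = {"skin": _de({"A": "ns", "B": "up", "C": "ns"}, "skin")}
        calls = call_homology(prof_a, prof_b, outgroup).set_index("gene_id")
        assert calls.at["A", "status"] == "homologous"
        assert calls.at["B", "status"] == "excluded_outgroup"
        assert calls.at["C", "status"] == "not_shared"

    def test_gene_absent_from_outgroup_counts_as_quiet(self):
        prof_a, prof_b = self._profiles()
        outgroup = {"skin": _de({"B": "ns"}, "skin")}  # A filtered out of pig
        calls = call_homology(prof_a, prof_b, outgroup).set_index("gene_id")
        assert calls.at["A", "status"] == "homologous"

    def test_within_species_exclusion_reported(self):
        prof_a = within_species_distinct(
            {"horn_2mo": _de({"A": "up"}, "horn_2mo")},
            {"skin": _de({"A": "up"}, "skin")},
        )
        prof_b = within_species_distinct(
            {"antler": _de({"A": "up"}, "antler")},
            {"skin": _de({"A": "ns"}, "skin")},
        )
        calls = call_homology(prof_a, prof_b, {"skin": _de({"A": "ns"}, "skin")})
        assert calls.set_index("gene_id").at["A", "status"] == (
            "excluded_within_species_control"
        )


def _tau_table(taxon, recs):
    rows = []
    for gene, strict, relaxed, ctrl in recs:
        rows.append(
            {
                "gene_id": gene,
                "taxon": taxon,
                "tau": 0.95,
                "strict_tissue": strict,
                "relaxed_tissues": relaxed,
                "control_specific": ctrl,
                "excluded": None,
            }
        )
    return pd.DataFrame(rows)


class TestTauHomology:
    APP_A = {"horn_bud_2mo", "horn_bud_4mo"}
    APP_B = {"reserve_mesenchyme", "pedicle", "antler_tip"}

    def test_shared_specificity_without_outgroup_hit_is_homologous(self):
        # the horn-development-gene pattern: specific to the young horn bud
        # and to antler reserve mesenchyme, nowhere in the outgroup
        a = _tau_table("cattle", [("RXFP2", "horn_bud_2mo", ("horn_bud_2mo",), False)])
        b = _tau_table("deer", [("RXFP2", "reserve_mesenchyme", ("reserve_mesenchyme",), False)])
        out = _tau_table("pig", [])
        calls = tau_homology(a, b, out, "strict", appendage_a=self.APP_A,
                             appendage_b=self.APP_B)
        row = calls.set_index("gene_id").loc["RXFP2"]
        assert row["status"] == "homologous"
        assert row["horn_support"] == ("horn_bud_2mo",)
        assert row["antler_support"] == ("reserve_mesenchyme",)

    def test_one_sided_specificity_not_shared(self):
        a = _tau_table("cattle", [("A", "horn_bud_2mo", ("horn_bud_2mo",), False)])
        b = _tau_table("deer", [])
        calls = tau_homology(a, b, _tau_table("pig", []), "strict",
                             appendage_a=self.APP_A, appendage_b=self.APP_B)
        assert calls.set_index("gene_id").at["A", "status"] == "not_shared"

    def test_control_specific_gene_excluded(self):
        a = _tau_table("cattle", [("A", None, ("horn_bud_2mo",), False)])
        b = _tau_table("deer", [("A", None, ("pedicle", "skin"), True)])
        calls = tau_homology(a, b, _tau_table("pig", []), "relaxed",
                             appendage_a=self.APP_A, appendage_b=self.APP_B)
        assert calls.set_index("gene_id").at["A", "status"] == (
            "excluded_within_species_control"
        )

    def test_outgroup_specific_gene_excluded(self):
        a = _tau_table("cattle", [("A", "horn_bud_2mo", ("horn_bud_2mo",), False)])
        b = _tau_table("deer", [("A", "pedicle", ("pedicle",), False)])
        out = _tau_table("pig", [("A", "skin", ("skin",), False)])
        calls = tau_homology(a, b, out, "strict", appendage_a=self.APP_A,
                             appendage_b=self.APP_B)
        assert calls.set_index("gene_id").at["A", "status"] == "excluded_outgroup"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            tau_homology(_tau_table("a", []), _tau_table("b", []), None, "loose",
                         appendage_a=set(), appendage_b=set())


class TestSharedProportions:
    def _calls(self):
        rows = []
        for g, horn, antler in [
            ("A", ("h2",), ("ant",)),
            ("B", ("h2", "h4"), ("ant", "tz")),
            ("C", ("h4",), ("tz",)),
        ]:
            rows.append(
                {"gene_id": g, "evidence_mode": "de", "horn_support": horn,
                 "antler_support": antler, "shared_direction": "up",
                 "status": "homologous", "control_flags": ""}
            )
        return pd.DataFrame(rows)

    def test_counts_and_proportions(self):
        out = shared_proportions(self._calls(), ["h2", "h4"], ["ant", "tz"])
        q = out.set_index(["horn_analysis", "antler_tissue"])
        assert q.at[("h2", "ant"), "shared_count"] == 2
        assert q.at[("h2", "ant"), "total"] == 2
        assert np.isclose(q.at[("h4", "tz"), "proportion"], 1.0)
        assert np.isclose(q.at[("h2", "tz"), "proportion"], 0.5)

    def test_empty_calls_yield_missing_proportions(self):
        empty = self._calls().iloc[:0]
        out = shared_proportions(empty, ["h2"], ["ant"])
        assert out["proportion"].isna().all()
        assert (out["shared_count"] == 0).all()


class TestBuildReport:
    def test_deterministic_and_valid_json(self):
        calls = TestSharedProportions()._calls()
        props = shared_proportions(calls, ["h2"], ["ant", "tz"])
        r1 = build_report(calls=calls, proportions=props, n_genes=3)
        r2 = build_report(calls=calls.copy(), proportions=props.copy(), n_genes=3)
        assert r1 == r2
        doc = json.loads(r1)
        assert {"calls", "proportions", "n_genes"} == set(doc)
        assert doc["calls"][0]["horn_support"] == ["h2"]

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            build_report()
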