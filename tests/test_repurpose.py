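"""Drug-repurposing stage: interaction scoring against a brute-force oracle,
trial aggregation, and the candidate table."""

import numpy as np
import pandas as pd
import pytest

from stemrx.repurpose import (
    DrugGeneInteraction,
    Phase,
    RedoEvidence,
    TrialRecord,
    aggregate_trials,
    build_candidate_table,
    candidate_frame,
    classify_cancer_drug,
    expand_polypharmacology,
    interaction_score,
    parse_phase,
    read_trial_registry,
    score_interaction_table,
    support_score,
)
from stemrx.repurpose import TargetDiseaseAssociation
from stemrx.targets import TargetGene


def brute_force_scores(table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Direct evaluation of the score formula, one python loop per edge."""
    edges = [(r.drug.lower().strip(), r.gene.upper().strip(),
              r.publication_count, r.source_count) for r in table.itertuples()]
    drugs = sorted({d for d, *_ in edges})
    genes = sorted({g for _, g, *_ in edges})
    gpd = {d: len({g for dd, g, *_ in edges if dd == d}) for d in drugs}
    dpg = {g: len({d for d, gg, *_ in edges if gg == g}) for g in genes}
    mean_gpd = sum(gpd.values()) / len(drugs)
    mean_dpg = sum(dpg.values()) / len(genes)
    return {
        (d, g): (pub + src) * (mean_gpd / gpd[d]) * (mean_dpg / dpg[g])
        for d, g, pub, src in edges
    }


def random_table(rng, max_drugs=20, max_genes=20) -> pd.DataFrame:
    nd = int(rng.integers(1, max_drugs + 1))
    ng = int(rng.integers(1, max_genes + 1))
    rows = []
    for i in range(nd):
        hit = rng.random(ng) < 0.3
        if not hit.any():
            hit[rng.integers(ng)] = True
        for j in np.flatnonzero(hit):
            rows.append(
                {
                    "drug": f"d{i}",
                    "gene": f"G{j}",
                    "publication_count": int(rng.integers(0, 50)),
                    "source_count": int(rng.integers(0, 10)),
                }
            )
    return pd.DataFrame(rows)


class TestInteractionScore:
    def test_single_edge_identity(self):
        table = pd.DataFrame(
            [{"drug": "d", "gene": "G", "publication_count": 3, "source_count": 2}]
        )
        edge = DrugGeneInteraction("d", "G", 3, 2)
        assert interaction_score(edge, table) == pytest.approx(5.0)

    def test_toy_table_matches_brute_force(self):
        table = pd.DataFrame(
            [
                ("d1", "G1", 4, 1),
                ("d1", "G2", 2, 2),
                ("d2", "G2", 7, 3),
                ("d2", "G3", 1, 1),
                ("d3", "G3", 9, 5),
            ],
            columns=["drug", "gene", "publication_count", "source_count"],
        )
        expected = brute_force_scores(table)
        scored = score_interaction_table(table)
        for r in scored.itertuples():
            assert r.interaction_score == pytest.approx(expected[(r.drug, r.gene)], rel=1e-12)

    def test_unrelated_edge_shifts_only_the_averages(self):
        base = pd.DataFrame(
            [
                ("d1", "G1", 5, 1),
                ("d1", "G2", 5, 1),
                ("d2", "G2", 5, 1),
            ],
            columns=["drug", "gene", "publication_count", "source_count"],
        )
        extra = pd.concat(
            [base, pd.DataFrame([("d3", "G3", 1, 1)], columns=base.columns)],
            ignore_index=True,
        )
        # hand-recomputed averages: base gpd mean = (2+1)/2, dpg mean = (1+2)/2
        # extra gpd mean = (2+1+1)/3, dpg mean = (1+2+1)/3
        s_base = score_interaction_table(base).set_index(["drug", "gene"])
        s_extra = score_interaction_table(extra).set_index(["drug", "gene"])
        ratio = ((4 / 3) / (3 / 2)) * ((4 / 3) / (3 / 2))
        assert s_extra.loc[("d1", "g1".upper()), "interaction_score"] == pytest.approx(
            s_base.loc[("d1", "G1"), "interaction_score"] * ratio
        )

    def test_random_tables_match_oracle(self, rng):
        for _ in range(30):
            table = random_table(rng)
            expected = brute_force_scores(table)
            scored = score_interaction_table(table)
            for r in scored.itertuples():
                got = r.interaction_score
                want = expected[(r.drug, r.gene)]
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_removing_a_drug_never_raises_other_partner_counts(self, rng):
        table = random_table(rng, max_drugs=10, max_genes=10)
        drugs = table["drug"].unique()
        if len(drugs) < 2:
            pytest.skip("degenerate draw")
        reduced = table[table["drug"] != drugs[0]]
        full_dpg = table.groupby("gene")["drug"].nunique()
        red_dpg = reduced.groupby("gene")["drug"].nunique()
        for g in red_dpg.index:
            assert red_dpg[g] <= full_dpg[g]

    def test_duplicate_edge_rejected(self):
        table = pd.DataFrame(
            [("d", "G", 1, 1), ("D", "g", 2, 2)],
            columns=["drug", "gene", "publication_count", "source_count"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            score_interaction_table(table)

    def test_absent_edge_rejected(self):
        table = pd.DataFrame(
            [("d", "G", 1, 1)], columns=["drug", "gene", "publication_count", "source_count"]
        )
        with pytest.raises(ValueError):
            interaction_score(DrugGeneInteraction("other", "G", 1, 1), table)


class TestPolypharmacology:
    TABLE = pd.DataFrame(
        [("dx", "G1", 1, 1), ("dx", "G2", 1, 1), ("dx", "G3", 1, 1)],
        columns=["drug", "gene", "publication_count", "source_count"],
    )

    def test_disease_associated_targets_sorted_by_score(self):
        assoc = [
            TargetDiseaseAssociation("G1", "cancer", 0.4),
            TargetDiseaseAssociation("G2", "cancer", 0.9),
            TargetDiseaseAssociation("G3", "other", 0.99),
        ]
        assert expand_polypharmacology("dx", self.TABLE, assoc, "cancer") == ["G2", "G1"]

    def test_absent_drug_gives_empty(self):
        assert expand_polypharmacology("nope", self.TABLE, [], "cancer") == []

    def test_score_ties_break_alphabetically(self):
        assoc = [
            TargetDiseaseAssociation("G2", "cancer", 0.5),
            TargetDiseaseAssociation("G1", "cancer", 0.5),
        ]
        assert expand_polypharmacology("dx", self.TABLE, assoc, "cancer") == ["G1", "G2"]


class TestTrials:
    def test_published_style_histogram_temozolomide_shape(self):
        registry = [
            TrialRecord(f"t{i}", "temozolomide", ph, "Recruiting", "Ewing's")
            for i, ph in enumerate(
                [Phase.P1] * 10 + [Phase.P1_2] * 4 + [Phase.P2] * 8 + [Phase.P3]
            )
        ]
        agg = aggregate_trials("Temozolomide", registry)
        assert agg["trial_count"] == 23
        assert agg["max_phase"] is Phase.P3
        assert agg["phase_hist"]["Phase 1"] == 10

    def test_other_never_beats_numbered_phase(self):
        registry = [
            TrialRecord(f"t{i}", "propofol", ph, "Recruiting", "GI")
            for i, ph in enumerate(
                [Phase.OTHER] * 19 + [Phase.P2] + [Phase.P3] * 2 + [Phase.P4] * 7
            )
        ]
        agg = aggregate_trials("propofol", registry)
        assert agg["trial_count"] == 29
        assert agg["max_phase"] is Phase.P4

    def test_empty_registry(self):
        agg = aggregate_trials("anything", [])
        assert agg["trial_count"] == 0 and agg["max_phase"] is None

    def test_histograms_all_sum_to_trial_count(self, rng):
        phases = list(Phase)
        registry = [
            TrialRecord(
                f"t{i}",
                "d",
                phases[int(rng.integers(len(phases)))],
                f"s{int(rng.integers(3))}",
                ["", "GI", "CNS"][int(rng.integers(3))],
            )
            for i in range(50)
        ]
        agg = aggregate_trials("d", registry)
        for axis in ("phase_hist", "status_hist", "cancer_type_hist"):
            assert sum(agg[axis].values()) == agg["trial_count"] == 50

    def test_malformed_phase_named_in_error(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text(
            "trial_id\tdrug\tphase\tstatus\tcancer_type\nNCT1\tdx\tPhase 9\tRecruiting\tGI\n"
        )
        with pytest.raises(ValueError, match="NCT1"):
            read_trial_registry(p)

    def test_phase_literals_parse(self):
        assert parse_phase("Phase 1/2") is Phase.P1_2
        assert parse_phase("other") is Phase.OTHER
        assert max(Phase.OTHER, Phase.P1) is Phase.P1


class TestCancerDrugAndSupport:
    def test_licence_membership_case_insensitive(self):
        licence = {"imatinib", "temozolomide"}
        assert classify_cancer_drug("Imatinib", licence)
        assert classify_cancer_drug("imatinib", licence)
        assert not classify_cancer_drug("Allopurinol", licence)

    @pytest.mark.parametrize(
        "flags, expected",
        [((True,) * 5, 5), ((False,) * 5, 0), ((True, True, False, False, False), 2)],
    )
    def test_support_score_counts_categories(self, flags, expected):
        ev = RedoEvidence("d", *flags)
        assert support_score(ev) == expected


class TestCandidateTable:
    def _inputs(self):
        table = pd.DataFrame(
            [
                ("verapamil", "ABCB1", 10, 3),
                ("imatinib", "ABCB1", 40, 5),
                ("imatinib", "KIT", 50, 5),
            ],
            columns=["drug", "gene", "publication_count", "source_count"],
        )
        targets = [TargetGene("ABCB1", {1}), TargetGene("XYZ1", {1})]
        return targets, table

    def test_two_drugs_one_licensed(self):
        targets, table = self._inputs()
        rows, summary = build_candidate_table(targets, table, {"imatinib"}, [], [])
        assert summary["n_drugs"] == 2
        assert summary["n_cancer_drugs"] == 1 and summary["n_non_cancer_drugs"] == 1
        assert summary["n_targets_with_drug"] == 1
        by_drug = {r.drug: r for r in rows}
        assert by_drug["imatinib"].targets == ["ABCB1"]  # restricted to target set

    def test_has_drug_flags_marked(self):
        targets, table = self._inputs()
        build_candidate_table(targets, table, set(), [], [])
        flags = {t.symbol: t.has_drug for t in targets}
        assert flags == {"ABCB1": True, "XYZ1": False}

    def test_no_hits_gives_empty_table(self):
        targets = [TargetGene("NOPE", {1})]
        _, table = self._inputs()
        rows, summary = build_candidate_table(targets, table, set(), [], [])
        assert rows == [] and summary["n_drugs"] == 0
        assert not targets[0].has_drug

    def test_min_targets_filter(self):
        targets = [TargetGene("ABCB1", {1}), TargetGene("KIT", {1})]
        _, table = self._inputs()
        rows, _ = build_candidate_table(targets, table, set(), [], [], min_targets=2)
        assert [r.drug for r in rows] == ["imatinib"]

    def test_summary_percentage_recomputes(self):
        targets, table = self._inputs()
        _, summary = build_candidate_table(targets, table, set(), [], [])
        assert summary["pct_targets_with_drug"] == round(
            100 * summary["n_targets_with_drug"] / summary["n_targets"]
        )

    def test_candidate_frame_shape(self):
        targets, table = self._inputs()
        rows, _ = build_candidate_table(targets, table, {"imatinib"}, [], [])
        df = candidate_frame(rows)
        assert {"drug", "targets", "cancer_drug", "trial_count", "max_phase"} <= set(df.columns)
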