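"""Co-elution grouping, adduct/isotope roles, library matching, MSI levels."""

import numpy as np
import pandas as pd
import pytest

from berrymet import annotate as ann
from berrymet.chem import expected_a1_ratio
from berrymet.io import sample_columns


def _peaks(rows, n_samples=8, seed=0):
    """rows: (feature_id, rt_min, mz, base_vector or None)."""
    rng = np.random.default_rng(seed)
    shared = rng.lognormal(0, 0.5, n_samples)
    data = []
    for fid, rt, mz, vec in rows:
        v = shared * 1e5 if vec is None else np.asarray(vec, float)
        data.append({"feature_id": fid, "rt_min": rt, "mz": mz,
                     **{f"S{i}": v[i] for i in range(n_samples)}})
    return pd.DataFrame(data)


def _library(entries):
    rows = []
    for name, formula, mass, rt_ref, ms2 in entries:
        rows.append({"name": name, "formula": formula, "neutral_mass": mass,
                     "compound_class": "flavonol", "charge": 0,
                     "rt_ref": rt_ref, "ms2_ref": ms2, "ms3_ref": ""})
    return pd.DataFrame(rows)


class TestGrouping:
    def test_identical_vectors_within_window_form_one_group(self):
        peaks = _peaks([("A", 10.00, 300.1, None), ("B", 10.033, 421.2, None)])
        groups = ann.group_features(peaks)
        assert groups["A"] == groups["B"]

    def test_perfect_correlation_outside_rt_window_stays_separate(self):
        peaks = _peaks([("A", 10.0, 300.1, None), ("B", 10.5, 421.2, None)])
        groups = ann.group_features(peaks)  # 30 s apart
        assert groups["A"] != groups["B"]

    def test_constant_feature_is_never_linked(self):
        peaks = _peaks(
            [("A", 10.0, 300.1, None), ("C", 10.01, 350.0, np.full(8, 7.0))]
        )
        groups = ann.group_features(peaks)
        assert groups["A"] != groups["C"]

    def test_partition_is_invariant_to_row_order(self, small_sim):
        peaks = small_sim.peaks["positive"]
        meta = small_sim.metadata
        nonblank = list(
            meta[(meta["polarity"] == "positive") & (meta["type"] != "blank")]["sample_id"]
        )
        g1 = ann.group_features(peaks, sample_ids=nonblank)
        shuffled = peaks.sample(frac=1, random_state=3).reset_index(drop=True)
        g2 = ann.group_features(shuffled, sample_ids=nonblank)
        part1 = {}
        part2 = {}
        for fid in g1.index:
            part1.setdefault(g1[fid], set()).add(fid)
            part2.setdefault(g2[fid], set()).add(fid)
        assert set(map(frozenset, part1.values())) == set(map(frozenset, part2.values()))

    def test_group_membership_recovers_truth_families(self, small_sim):
        # Rand index of recovered partition vs planted ion families >= 0.95
        pol = "negative"
        peaks = small_sim.peaks[pol]
        meta = small_sim.metadata
        nonblank = list(
            meta[(meta["polarity"] == pol) & (meta["type"] != "blank")]["sample_id"]
        )
        groups = ann.group_features(peaks, sample_ids=nonblank)
        truth = small_sim.truth.ions
        family = truth[truth["polarity"] == pol].set_index("feature_id")["name"]
        fids = [f for f in groups.index if f in family.index]
        same_truth = same_found = agree = 0
        n_pairs = 0
        for i in range(len(fids)):
            for j in range(i + 1, len(fids)):
                t = family[fids[i]] == family[fids[j]]
                g = groups[fids[i]] == groups[fids[j]]
                n_pairs += 1
                agree += t == g
        assert agree / n_pairs >= 0.95


class TestRoles:
    def test_proton_sodium_pair_infers_morin_neutral_mass(self):
        peaks = _peaks([("A", 14.0, 303.0499, None), ("B", 14.01, 325.0319, None)])
        peaks["group_id"] = 0
        res = ann.annotate_roles(peaks, "positive")
        assert res.base_feature == "A"
        assert res.roles["B"] == "adduct:[M+Na]+"
        assert res.neutral_mass == pytest.approx(302.0427, abs=5e-4)

    def test_c13_isotopologue_flagged_below_parent_intensity(self):
        base = np.full(8, 1e6)
        iso = base * expected_a1_ratio("C27H31O16")
        peaks = _peaks(
            [("A", 12.0, 611.1607, base), ("B", 12.0, 612.1641, iso)]
        )
        peaks["group_id"] = 0
        res = ann.annotate_roles(peaks, "positive")
        assert res.roles == {"A": "base", "B": "isotope"}

    def test_singleton_gets_default_adduct_neutral(self):
        peaks = _peaks([("A", 5.0, 200.0, None)])
        peaks["group_id"] = 0
        res = ann.annotate_roles(peaks, "negative")
        assert res.roles["A"] == "base"
        assert res.neutral_mass == pytest.approx(200.0 + 1.007276, abs=1e-6)

    def test_two_coeluting_parents_each_annotated(self):
        # two independent compounds merged in one correlation group: the
        # second parent and its isotope are peeled off in a second pass
        b1 = np.linspace(1, 2, 8) * 1e6
        peaks = _peaks(
            [
                ("A", 9.0, 400.0, b1),
                ("Aiso", 9.0, 401.00336, b1 * 0.2),
                ("B", 9.01, 522.5, b1 * 0.8),
                ("Biso", 9.01, 523.50336, b1 * 0.1),
            ]
        )
        peaks["group_id"] = 0
        res = ann.annotate_roles(peaks, "negative")
        roles = res.roles
        assert roles["Aiso"] == "isotope" and roles["Biso"] == "isotope"
        assert {roles["A"], roles["B"]} == {"base"}
        assert len(res.subgroups) == 2


class TestLibraryMatch:
    LIB = _library(
        [
            ("morin", "C15H10O7", 302.0427, 14.0, ""),
            ("isomerA", "C21H20O12", 464.0955, 8.0, ""),
            ("isomerB", "C21H20O12", 464.0955, 9.5, ""),
        ]
    )

    def test_five_ppm_window_accepts_and_rejects(self):
        hits = ann.match_library(302.0442, self.LIB)
        assert list(hits["name"]) == ["morin"]
        assert hits["ppm_error"].iloc[0] == pytest.approx(4.97, abs=0.05)
        assert len(ann.match_library(302.08, self.LIB)) == 0

    def test_isomeric_masses_return_multiple_hits(self):
        hits = ann.match_library(464.0955, self.LIB)
        assert len(hits) == 2

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            ann.match_library(-5.0, self.LIB)


class TestMsiLevels:
    @pytest.mark.parametrize(
        "evidence, level",
        [
            (dict(mass_match=True, rt_match=True, rt_available=True, ms2_match=True), "1"),
            (dict(mass_match=True, ms2_match=True, rt_available=False), "2plus"),
            (dict(mass_match=True, unique_hit=True), "2"),
            (dict(mass_match=True, unique_hit=False), "3"),
            (dict(), "4"),
            # an available MS3 reference must also match for level 1; the
            # ambiguous mass match then degrades to level 3
            (
                dict(mass_match=True, rt_match=True, rt_available=True, ms2_match=True,
                     ms3_available=True, ms3_match=False),
                "3",
            ),
        ],
    )
    def test_confidence_rules(self, evidence, level):
        assert ann.assign_msi_level(evidence) == level


class TestCollapseAndMerge:
    def test_collapse_ledger_accounts_for_every_removal(self):
        table = pd.DataFrame(
            {
                "feature_id": list("ABCDE"),
                "role": ["base", "isotope", "isotope", "adduct:[M+Na]+", "in_source_fragment"],
            }
        )
        retained, reasons = ann.collapse_redundancy(table)
        assert list(retained["feature_id"]) == ["A"]
        assert reasons == {"isotope": 2, "adduct": 1, "in_source_fragment": 1}

    def test_merge_rejects_asymmetric_sample_sets(self):
        pos = _peaks([("P1", 5.0, 300.0, None)])
        neg = _peaks([("N1", 5.0, 298.0, None)]).rename(columns={"S7": "S99"})
        empty = pd.DataFrame({"feature_id": [], "neutral_mass": []})
        with pytest.raises(ValueError, match="S99|S7"):
            ann.merge_polarities(pos, neg, empty, empty)

    def test_cross_polarity_corroboration_flag(self):
        pos = _peaks([("P1", 5.0, 303.0499, None)])
        neg = _peaks([("N1", 5.0, 301.0354, None), ("N2", 9.0, 500.0, None)])
        pos_ann = pd.DataFrame({"feature_id": ["P1"], "polarity": ["positive"],
                                "neutral_mass": [302.0427]})
        neg_ann = pd.DataFrame({"feature_id": ["N1", "N2"],
                                "polarity": ["negative", "negative"],
                                "neutral_mass": [302.0428, 501.0073]})
        combined, annotation = ann.merge_polarities(pos, neg, pos_ann, neg_ann)
        flags = annotation.set_index("feature_id")["corroborated"]
        assert flags["P1"] and flags["N1"] and not flags["N2"]
        assert len(combined) == 3  # both polarity rows retained, never fused


class TestEndToEnd:
    def test_collapse_retains_one_row_per_planted_compound(self, small_sim):
        pol = "negative"
        meta = small_sim.metadata
        nonblank = list(
            meta[(meta["polarity"] == pol) & (meta["type"] != "blank")]["sample_id"]
        )
        endo = small_sim.peaks[pol]
        contaminants = set(small_sim.truth.contaminants["feature_id"])
        endo = endo[~endo["feature_id"].isin(contaminants)].reset_index(drop=True)
        res = ann.annotate_features(endo, small_sim.library, pol, sample_ids=nonblank)
        retained, reasons = ann.collapse_redundancy(res.table)
        n_compounds = (
            small_sim.truth.ions.query("polarity == @pol")["name"].nunique()
        )  # includes morin
        assert len(retained) == pytest.approx(n_compounds, abs=2)
        assert len(res.table) == len(retained) + sum(reasons.values())

    def test_adduct_round_trip_within_tolerance(self, small_sim):
        # for every annotated adduct member: m/z - (adduct arithmetic on the
        # inferred neutral mass) agrees within 0.005 Da
        from berrymet.chem import DEFAULT_ADDUCTS

        by_label = {a.label: a for a in DEFAULT_ADDUCTS}
        pol = "positive"
        meta = small_sim.metadata
        nonblank = list(
            meta[(meta["polarity"] == pol) & (meta["type"] != "blank")]["sample_id"]
        )
        res = ann.annotate_features(
            small_sim.peaks[pol], small_sim.library, pol, sample_ids=nonblank
        )
        adducts = res.table[res.table["role"].str.startswith("adduct:")]
        assert len(adducts) > 0
        for _, row in adducts.iterrows():
            label = row["role"].split(":", 1)[1]
            predicted = by_label[label].mz(row["neutral_mass"])
            assert abs(row["mz"] - predicted) <= 0.005
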