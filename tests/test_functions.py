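"""Module-definition parsing, completeness scoring, Fisher occurrence
contrasts against a hypergeometric enumeration oracle, capability rules,
and gene-to-function abundance summation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from metasig.catalog import ValidationError
from metasig.functions import (
    ModuleParseError,
    capability_profile,
    completeness_contrast,
    default_capability_rules,
    fisher_exact_two_sided,
    functional_abundance,
    module_completeness,
    occurrence_contrast,
    parse_module_definition,
)


class TestParser:
    def test_top_level_spaces_are_steps(self):
        d = parse_module_definition("K00001 (K00002,K00003)")
        assert len(d.steps) == 2

    def test_plus_is_complex_and(self):
        d = parse_module_definition("K00010+K00011")
        assert len(d.steps) == 1
        assert not d.steps[0].evaluate({"K00010"})
        assert d.steps[0].evaluate({"K00010", "K00011"})

    def test_comma_is_or(self):
        d = parse_module_definition("K00002,K00003")
        assert d.steps[0].evaluate({"K00003"})

    def test_optional_components_dropped(self):
        d = parse_module_definition("K00001-K00099")
        assert d.steps[0].evaluate({"K00001"})
        d2 = parse_module_definition("K00001 -K00099")
        assert len(d2.steps) == 1 and d2.steps[0].evaluate({"K00001"})

    def test_nested_parentheses(self):
        d = parse_module_definition("((K1,K2) K3),K4")
        assert len(d.steps) == 1
        assert d.steps[0].evaluate({"K4"})
        assert d.steps[0].evaluate({"K1", "K3"})
        assert not d.steps[0].evaluate({"K1"})

    @pytest.mark.parametrize("bad", ["K00001 (K00002", "", "  ", "K1 ()",
                                     "K1 K2)"])
    def test_malformed_definitions_raise_with_position(self, bad):
        with pytest.raises(ModuleParseError):
            parse_module_definition(bad)

    @pytest.mark.parametrize(
        "text",
        [
            "K00001 (K00002,K00003)",
            "K00010+K00011",
            "K1,K2+K3",
            "(K1,K2)+K3 K4",
            "K1 K2 K3",
        ],
    )
    def test_round_trip(self, text):
        d = parse_module_definition(text)
        assert parse_module_definition(d.serialize()) == d


class TestCompleteness:
    def test_step_fraction(self):
        d = parse_module_definition("A (B,C) D")
        frac, complete = module_completeness(d, {"A", "C"})
        assert frac == pytest.approx(2 / 3) and not complete

    def test_saturation_and_empty(self):
        d = parse_module_definition("A (B,C) D")
        assert module_completeness(d, {"A", "B", "C", "D"}) == (1.0, True)
        assert module_completeness(d, set()) == (0.0, False)

    def test_monotone_in_ko_set(self, rng):
        d = parse_module_definition("A+B (C,D) (E F),G H")
        kos = list("ABCDEFGH")
        for _ in range(50):
            base = set(rng.choice(kos, size=int(rng.integers(0, 8)),
                                  replace=False))
            extra = base | set(rng.choice(kos, size=2))
            f1, _ = module_completeness(d, base)
            f2, _ = module_completeness(d, extra)
            assert f2 >= f1


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)
                / comb(n, row1, exact=True))

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherContrast:
    def test_known_table(self):
        assert fisher_exact_two_sided([[8, 2], [1, 9]]) == pytest.approx(
            0.00548, abs=5e-5
        )

    def test_matches_enumeration_oracle_small_margins(self, rng):
        for _ in range(60):
            a, b, c, d = (int(rng.integers(0, 16)) for _ in range(4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            got = fisher_exact_two_sided([[a, b], [c, d]])
            want = fisher_enumeration_oracle(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def _presence(self, case_present, case_absent, ctrl_present, ctrl_absent):
        species = [f"s{i}" for i in range(case_present + case_absent
                                          + ctrl_present + ctrl_absent)]
        labels = pd.Series(
            ["case_enriched"] * (case_present + case_absent)
            + ["control_enriched"] * (ctrl_present + ctrl_absent),
            index=species,
        )
        pres = pd.DataFrame(
            {"fn": [True] * case_present + [False] * case_absent
             + [True] * ctrl_present + [False] * ctrl_absent},
            index=species,
        )
        return pres, labels

    def test_uninformative_function_gets_p_one(self):
        pres, labels = self._presence(5, 0, 5, 0)
        out = occurrence_contrast(pres, labels)
        assert out.loc["fn", "p"] == 1.0

    def test_label_swap_flips_direction_keeps_p(self):
        pres, labels = self._presence(8, 2, 1, 9)
        out = occurrence_contrast(pres, labels)
        swapped = labels.map({"case_enriched": "control_enriched",
                              "control_enriched": "case_enriched"})
        out2 = occurrence_contrast(pres, swapped)
        assert out.loc["fn", "p"] == pytest.approx(out2.loc["fn", "p"])
        assert {out.loc["fn", "direction"], out2.loc["fn", "direction"]} == {
            "case_enriched", "control_enriched"
        }

    def test_unlabeled_species_rejected(self):
        pres, labels = self._presence(2, 2, 2, 2)
        with pytest.raises(ValidationError):
            occurrence_contrast(pres, labels.iloc[:-1])

    def test_type_one_error_controlled_under_random_labels(self, rng):
        fracs = []
        for _ in range(20):
            pres = pd.DataFrame(
                rng.random((40, 50)) < 0.5,
                index=[f"s{i}" for i in range(40)],
                columns=[f"K{j}" for j in range(50)],
            )
            labels = pd.Series(
                rng.permutation(["case_enriched"] * 20
                                + ["control_enriched"] * 20),
                index=pres.index,
            )
            out = occurrence_contrast(pres, labels)
            fracs.append((out["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05


class TestCompletenessContrast:
    def test_perfect_separation_minimal_p(self):
        # module complete in all 10 case-enriched and none of 10 control
        defs = {"M1": parse_module_definition("A B")}
        ko_sets = {f"c{i}": {"A", "B"} for i in range(10)}
        ko_sets.update({f"h{i}": {"A"} for i in range(10)})
        labels = pd.Series(
            ["case_enriched"] * 10 + ["control_enriched"] * 10,
            index=list(ko_sets),
        )
        out = completeness_contrast(defs, ko_sets, labels)
        # both extreme tables carry the minimal point mass 1/C(20,10)
        assert out.loc["M1", "p"] == pytest.approx(2 / comb(20, 10, exact=True),
                                                   rel=1e-6)

    def test_module_complete_nowhere_is_null(self):
        defs = {"M1": parse_module_definition("A B")}
        ko_sets = {f"s{i}": {"A"} for i in range(10)}
        labels = pd.Series(["case_enriched"] * 5 + ["control_enriched"] * 5,
                           index=list(ko_sets))
        out = completeness_contrast(defs, ko_sets, labels)
        assert out.loc["M1", "p"] == 1.0 and out.loc["M1", "q"] == 1.0

    def test_single_module_q_equals_p(self):
        defs = {"M1": parse_module_definition("A")}
        ko_sets = {"a": {"A"}, "b": set(), "c": {"A"}, "d": set()}
        labels = pd.Series(["case_enriched"] * 2 + ["control_enriched"] * 2,
                           index=list(ko_sets))
        out = completeness_contrast(defs, ko_sets, labels)
        assert out.loc["M1", "q"] == pytest.approx(out.loc["M1", "p"])


class TestCapabilities:
    def test_tryptophanase_marks_is_precursor(self):
        prof = capability_profile({"K01667"})
        assert prof["is_precursor"]
        assert not prof["tmao_precursor"]

    def test_empty_annotations_all_false(self):
        prof = capability_profile(set())
        assert not any(prof.values())

    def test_tma_lyase_rule_isolation(self):
        prof = capability_profile({"choline trimethylamine-lyase"})
        assert prof["tmao_precursor"]
        assert sum(prof.values()) == 1

    def test_rule_table_covers_all_capability_classes(self):
        rules = default_capability_rules()
        caps = set(rules["capability"])
        assert {"acetate_synthesis", "propionate_synthesis_I",
                "propionate_synthesis_II", "butyrate_synthesis_I",
                "butyrate_synthesis_II", "bile_salt_hydrolase",
                "dehydroxylation_7ab", "hydroxysteroid_dehydrogenase",
                "is_precursor", "pcs_precursor", "pag_precursor",
                "tmao_precursor"} <= caps

    def test_missing_markers_rejected(self):
        bad = pd.DataFrame({"capability": ["x"], "markers": [""]})
        with pytest.raises(ValidationError):
            capability_profile({"K1"}, bad)


class TestFunctionalAbundance:
    def test_summation_rule(self):
        genes = pd.DataFrame([[0.2, 0.3, 0.1]], index=["s"],
                             columns=["g1", "g2", "g3"])
        gmap = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                             "function_id": ["KO1", "KO1", "KO2"]})
        out = functional_abundance(genes, gmap)
        assert out.loc["s", "KO1"] == pytest.approx(0.5)
        assert out.loc["s", "KO2"] == pytest.approx(0.1)

    def test_empty_map_and_conservation_bound(self, rng):
        genes = pd.DataFrame(rng.random((4, 10)),
                             index=list("abcd"),
                             columns=[f"g{i}" for i in range(10)])
        assert functional_abundance(genes, pd.DataFrame(
            columns=["gene_id", "function_id"])).empty
        gmap = pd.DataFrame({"gene_id": [f"g{i}" for i in range(6)],
                             "function_id": ["K1", "K1", "K2", "K2", "K3", "K3"]})
        out = functional_abundance(genes, gmap)
        assert (out.sum(axis=1) <= genes.sum(axis=1) + 1e-12).all()

    def test_duplicate_gene_ids_rejected(self):
        genes = pd.DataFrame([[0.1, 0.2]], index=["s"], columns=["g1", "g2"])
        gmap = pd.DataFrame({"gene_id": ["g1", "g1"],
                             "function_id": ["K1", "K2"]})
        with pytest.raises(ValidationError):
            functional_abundance(genes, gmap)


class TestPlantedFunctionRecovery:
    def test_planted_direction_pairs_recovered(self):
        from metasig.simulate import (SimulationConfig, generate_ko_presence,
                                      generate_species_catalog,
                                      make_ground_truth)

        # ~50 labeled species give the 2x2 contrasts realistic power
        cfg = SimulationConfig(n_species=100, frac_differential=0.5, seed=21)
        catalog = generate_species_catalog(cfg)
        truth = make_ground_truth(catalog, cfg)
        presence = generate_ko_presence(catalog, truth, cfg)
        labels = pd.Series(
            {s: "case_enriched" if d > 0 else "control_enriched"
             for s, d in truth.differential_species.items()}
        )
        pres = presence.loc[labels.index]
        out = occurrence_contrast(pres, labels)
        hits = 0
        planted = truth.planted_module_assignments
        for fn, d in planted.items():
            want = "case_enriched" if d > 0 else "control_enriched"
            if out.loc[fn, "q"] < 0.05 and out.loc[fn, "direction"] == want:
                hits += 1
        assert hits / len(planted) >= 0.9
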