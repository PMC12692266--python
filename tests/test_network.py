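"""Enzyme rules, network closure, stoichiometry and peak membership."""

from collections import Counter

import pytest

from glycoforge.model import default_model
from glycoforge.network import (DEFAULT_PEAKS, DEFAULT_WHITELIST, PEAK_IDS,
                                PeakTable, build_stoichiometry,
                                generate_network)
from glycoforge.rules import DEFAULT_RULES, FACTOR_GROUPS, apply_rule
from glycoforge.structures import M5, parse_glycan_name


@pytest.fixture(scope="module")
def network():
    return generate_network()


def _rule(rule_id):
    return next(r for r in DEFAULT_RULES if r.rule_id == rule_id)


class TestApplyRule:
    def test_gnt1_on_m5_adds_13_antenna(self):
        p = apply_rule(_rule("gnt1"), M5)
        assert p is not None and p.glcnac_13 == 1 and p.mannose_count == 5

    def test_gnt1_blocked_on_occupied_site(self):
        assert apply_rule(_rule("gnt1"), parse_glycan_name("FA2")) is None

    def test_man2_requires_gnt1_product(self):
        assert apply_rule(_rule("man2"), M5) is None
        p = apply_rule(_rule("man2"), parse_glycan_name("M5A1"))
        assert p is not None and p.mannose_count == 3  # both mannoses in one event

    def test_fuct_blocked_by_bisecting_glcnac(self):
        assert apply_rule(_rule("fuct"), parse_glycan_name("A2B")) is None

    def test_man2_blocked_by_bisecting_glcnac(self):
        bisected_hybrid = parse_glycan_name("M5A1").with_features(bisecting=1)
        assert apply_rule(_rule("man2"), bisected_hybrid) is None

    def test_sialylation_linkages_cannot_mix(self):
        s1 = parse_glycan_name("A26G2S1")
        assert apply_rule(_rule("siat23_13"), s1) is None
        s2 = apply_rule(_rule("siat26_13"), s1)
        assert s2 is not None and s2.sia_count == 2

    def test_products_are_valid_structures(self):
        # closure over the whole whitelist exercises every rule/substrate pair
        for name in DEFAULT_WHITELIST:
            s = parse_glycan_name(name)
            for rule in DEFAULT_RULES:
                p = apply_rule(rule, s)
                if p is not None:
                    assert p.residue_count in (s.residue_count - 2 + 0,
                                               s.residue_count + 1,
                                               s.residue_count - 2)


class TestGenerateNetwork:
    def test_default_build_matches_printed_counts(self, network):
        assert network.n_species == 45
        assert network.n_reactions == 61

    def test_factor_groups_cover_all_reactions(self, network):
        groups = Counter(r.factor_group for r in network.reactions)
        assert set(groups) == set(FACTOR_GROUPS)
        assert len(groups) == 22
        assert sum(groups.values()) == 61

    def test_fixed_point_whitelist(self):
        net = generate_network(whitelist=["M5"])
        assert net.n_species == 1 and net.n_reactions == 0

    def test_two_species_whitelist_single_reaction(self):
        net = generate_network(whitelist=["M5", "M5A1"])
        assert net.n_species == 2 and net.n_reactions == 1
        (r,) = net.reactions
        assert r.enzyme_id == "GnTI"

    def test_unreachable_whitelist_species_reported(self):
        # FA2B requires FA2, which requires A2 or FA1 ... none whitelisted
        with pytest.raises(ValueError, match="FA2B"):
            generate_network(whitelist=["M5", "FA2B"])

    def test_deterministic_ordering(self, network):
        again = generate_network()
        assert again == network
        keys = [(s.residue_count, s.name) for s in network.species]
        assert keys == sorted(keys)


class TestStoichiometry:
    def test_columns_are_unit_conversions(self, network):
        N = build_stoichiometry(network)
        assert N.shape == (45, 61)
        assert ((N == -1).sum(axis=0) == 1).all()
        assert ((N == 1).sum(axis=0) == 1).all()
        assert (N.sum(axis=0) == 0).all()

    def test_row_degree_equals_incident_reactions(self, network):
        N = build_stoichiometry(network)
        incident = Counter()
        for r in network.reactions:
            incident[r.substrate] += 1
            incident[r.product] += 1
        degrees = (N != 0).sum(axis=1)
        assert [incident[i] for i in range(network.n_species)] == list(degrees)

    def test_single_reaction_toy_column(self):
        net = generate_network(whitelist=["M5", "M5A1"])
        N = build_stoichiometry(net)
        assert N[:, 0].tolist() in ([-1, 1], [1, -1])
        assert N[net.index["M5"], 0] == -1


class TestPeakTable:
    def test_membership_facts_from_the_study(self, network):
        pt = PeakTable(DEFAULT_PEAKS, network)
        assert pt.members["GP4"] == ("FA2",)
        assert pt.members["GP14"] == ("FA2G2",)
        assert set(pt.members["GP18"]) == {"A23BG2S1", "A26BG2S1",
                                           "FA23G2S1", "FA26G2S1"}
        assert "M5" in pt.members["GP5"]

    def test_22_peaks_disjoint_members(self, network):
        pt = PeakTable(DEFAULT_PEAKS, network)
        assert pt.n_peaks == 22
        all_members = [g for mem in pt.members.values() for g in mem]
        assert len(all_members) == len(set(all_members))

    def test_rejects_shared_species(self, network):
        peaks = {p: tuple(g) for p, g in DEFAULT_PEAKS.items()}
        peaks["GP2"] = ("A2", "FA2")  # FA2 already belongs to GP4
        with pytest.raises(ValueError, match="FA2"):
            PeakTable(peaks, network)

    def test_rejects_unknown_species(self, network):
        peaks = {p: tuple(g) for p, g in DEFAULT_PEAKS.items()}
        peaks["GP2"] = ("A2", "A4G4")
        with pytest.raises(ValueError, match="A4G4"):
            PeakTable(peaks, network)

    def test_excluded_peaks_absent(self):
        assert "GP3" not in PEAK_IDS and "GP20" not in PEAK_IDS
        assert len(PEAK_IDS) == 22


def test_rule_generated_and_file_loaded_networks_agree(tmp_path):
    """The shipped model file and the rule closure define identical networks."""
    from glycoforge.model import read_model, write_model

    m = default_model()
    path = tmp_path / "model.json"
    write_model(m, path)
    loaded = read_model(path)
    assert loaded.network == m.network
    assert loaded.peaks == m.peaks
    assert loaded == m
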