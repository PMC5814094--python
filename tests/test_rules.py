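"""Rule dialect parsing and hash-table lookup semantics."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from holosim.models import model1_rule_text, full_network_rule_text
from holosim.rules import (RuleParseError, build_table, combined_rate,
                           parse_rule, parse_rules, select_branch,
                           serialize_rule, MoleculeType, SiteType)


@pytest.fixture(scope="module")
def table1(molecules, rates):
    rules = parse_rules(model1_rule_text(rates), molecules)
    return build_table(rules, molecules)


def _cam_state(molecules, n, c, k=0, kp=0):
    cam = molecules["cam"]
    v = cam.default_state_vector()
    v[cam.site_index("N1")] = 1 if n >= 1 else 0
    v[cam.site_index("N2")] = 1 if n >= 2 else 0
    v[cam.site_index("C1")] = 1 if c >= 1 else 0
    v[cam.site_index("C2")] = 1 if c >= 2 else 0
    v[cam.site_index("k")] = k
    v[cam.site_index("kp")] = kp
    return v


class TestParser:
    def test_first_order_flag_rule(self):
        cal = MoleculeType("CaL", (SiteType("gate", "flag"),))
        rule = parse_rule("CaL{gate==0} <-> CaL{gate=1} kf=ro kb=rc",
                          {"CaL": cal}, rates={"ro": 3.5, "rc": 1.25})
        assert rule.order == 1
        assert rule.k_f == 3.5 and rule.k_b == 1.25
        assert rule.assignments[0].site == "gate"
        assert rule.assignments[0].value == 1

    def test_zero_rate_rule_is_valid(self, molecules):
        rule = parse_rule(
            "cam{C1==0, C2==0} + ca{b==0} <-> cam~ca{cam.C1=1, ca.b=1} "
            "kf=0 kb=0", molecules)
        assert rule.k_f == 0.0 and rule.k_b == 0.0

    def test_roundtrip_is_identity(self, molecules, rates):
        for line in model1_rule_text(rates).splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            rule = parse_rule(line, molecules)
            again = parse_rule(serialize_rule(rule), molecules)
            assert serialize_rule(again) == serialize_rule(rule)
            assert again == rule

    @pytest.mark.parametrize("bad,fragment", [
        ("cam{C1=1} + ca{} <-> cam~ca{cam.C1=1, ca.b=1} kf=1 kb=1", "'='"),
        ("cam{C1==0} + ca{} <-> cam~ca{cam.C1==1, ca.b=1} kf=1 kb=1", "'=='"),
        ("cam{C1==0} + ca{} -> cam~ca{cam.C1=1} kf=1 kb=1", "<->"),
        ("cam{C1==0} + ca{} <-> cam~ca{cam.C1=1, ca.b=1} kf=1", "kf"),
        ("wrong{x==0} <-> wrong{x=1} kf=1 kb=1", "unknown molecule"),
        ("cam{bogus==0} <-> cam{kp=1} kf=1 kb=1", "no site"),
    ])
    def test_errors_are_reported(self, molecules, bad, fragment):
        with pytest.raises((RuleParseError, KeyError)) as err:
            parse_rule(bad, molecules)
        assert fragment.lower() in str(err.value).lower()

    def test_model1_has_exactly_four_reversible_rules(self, molecules, rates):
        rules = parse_rules(model1_rule_text(rates), molecules)
        assert len(rules) == 4

    def test_model1_reachability_is_the_nine_state_network(self, table1, molecules):
        """Sequential lobe rules make exactly the 9 NxCy states reachable."""
        cam = molecules["cam"]
        ca = molecules["ca"]
        ca_free = ca.default_state_vector()
        reachable = set()
        frontier = [(0, 0)]
        while frontier:
            n, c = frontier.pop()
            if (n, c) in reachable:
                continue
            reachable.add((n, c))
            assert n <= 2 and c <= 2, "escaped the 9-state lattice"
            state = _cam_state(molecules, n, c)
            for rule in table1.lookup("cam", state, "ca", ca_free)[0]:
                site = next(a.site for a in rule.assignments
                            if a.target == "cam")
                if site.startswith("N"):
                    frontier.append((n + 1, c))
                else:
                    frontier.append((n, c + 1))
        assert reachable == {(n, c) for n in range(3) for c in range(3)}
        # cooperative ordering: N2 without N1 (and C2 without C1) unreachable
        bad = _cam_state(molecules, 0, 0)
        bad[cam.site_index("N2")] = 1
        cands, _ = table1.lookup("cam", bad, "ca", ca_free)
        assert all(r.assignments[0].site != "N2" for r in cands)


class TestTable:
    def test_apocam_lookup_branches(self, table1, molecules):
        ca_free = molecules["ca"].default_state_vector()
        apo = _cam_state(molecules, 0, 0)
        cands, _ = table1.lookup("cam", apo, "ca", ca_free)
        assert sorted(r.label for r in cands) == ["C1~ca", "N1~ca"]

    def test_fully_loaded_lookup_empty(self, table1, molecules):
        ca_free = molecules["ca"].default_state_vector()
        full = _cam_state(molecules, 2, 2)
        cands, ksum = table1.lookup("cam", full, "ca", ca_free)
        assert cands == [] and ksum == 0.0

    def test_lookup_equals_scan_exhaustively(self, molecules, rates):
        """Hash lookup returns exactly the brute-force scan result for every
        concrete state pair of the full two-layer network."""
        rules = parse_rules(full_network_rule_text(rates), molecules)
        table = build_table(rules, molecules)
        ca_states = [np.array([b], dtype=np.uint8) for b in (0, 1)]
        for n, c, k, kp in itertools.product(range(3), range(3), (0, 1), (0, 1)):
            cam_state = _cam_state(molecules, n, c, k, kp)
            for ca_state in ca_states:
                ca_pad = np.zeros(1, dtype=np.uint8)
                ca_pad[0] = ca_state[0]
                via_lookup = table.lookup("cam", cam_state, "ca", ca_pad)[0]
                via_scan = table.scan("cam", cam_state, "ca", ca_pad)
                assert via_lookup == via_scan
        # symmetric under reactant order
        apo = _cam_state(molecules, 0, 0)
        ca0 = np.zeros(1, dtype=np.uint8)
        assert (table.lookup("ca", ca0, "cam", apo)[0]
                == table.lookup("cam", apo, "ca", ca0)[0])

    def test_duplicate_labels_rejected(self, molecules):
        line = ("cam{C1==0, C2==0} + ca{b==0} <-> cam~ca{cam.C1=1, ca.b=1} "
                "kf=1 kb=1 label=X")
        line2 = ("cam{C1==1, C2==0} + ca{b==0} <-> cam~ca{cam.C2=1, ca.b=1} "
                 "kf=1 kb=1 label=X")
        rules = [parse_rule(line, molecules), parse_rule(line2, molecules)]
        with pytest.raises(ValueError, match="duplicate"):
            build_table(rules, molecules)


class TestBranching:
    def test_combined_rate_sums(self, molecules):
        r1 = parse_rule("cam{C1==0, C2==0} + ca{b==0} <-> "
                        "cam~ca{cam.C1=1, ca.b=1} kf=5 kb=1 label=a", molecules)
        r2 = parse_rule("cam{N1==0, N2==0} + ca{b==0} <-> "
                        "cam~ca{cam.N1=1, ca.b=1} kf=15 kb=1 label=b", molecules)
        assert combined_rate([r1, r2]) == 20.0
        assert combined_rate([r1]) == 5.0
        assert combined_rate([]) == 0.0

    def test_select_branch_partition(self, molecules):
        r1 = parse_rule("cam{C1==0, C2==0} + ca{b==0} <-> "
                        "cam~ca{cam.C1=1, ca.b=1} kf=1 kb=1 label=a", molecules)
        r2 = parse_rule("cam{N1==0, N2==0} + ca{b==0} <-> "
                        "cam~ca{cam.N1=1, ca.b=1} kf=1 kb=1 label=b", molecules)
        assert select_branch([r1, r2], 0.4) is r1
        assert select_branch([r1, r2], 0.6) is r2
        assert select_branch([r1], 0.999) is r1
        with pytest.raises(ValueError):
            select_branch([], 0.5)

    def test_branch_frequencies_match_rate_proportions(self, molecules, rng):
        """10^5 uniform draws split 1:3 follow the rate partition
        (chi-square, fixed seed)."""
        r1 = parse_rule("cam{C1==0, C2==0} + ca{b==0} <-> "
                        "cam~ca{cam.C1=1, ca.b=1} kf=1 kb=1 label=a", molecules)
        r2 = parse_rule("cam{N1==0, N2==0} + ca{b==0} <-> "
                        "cam~ca{cam.N1=1, ca.b=1} kf=3 kb=1 label=b", molecules)
        draws = 1.0 - rng.random(100_000)
        picks = np.array([select_branch([r1, r2], u) is r2 for u in draws])
        stat, p = chisquare([np.sum(~picks), np.sum(picks)],
                            [25_000, 75_000])
        assert p > 0.01
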