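"""Risk-network assembly, removal calculus, and combination/recovery tables."""

import itertools
import json

import numpy as np
import pytest

import seabed_era as se
from seabed_era.config_io import (
    config_from_dict,
    config_to_dict,
    dumps_config,
    merge_patch,
)
from seabed_era.elicitation import DEFAULT_BINS
from seabed_era.model import (
    DEPTH_EXTRACTION,
    GROUPS_BY_KEY,
    MINING_INTENSITY,
    NODULE_REMOVAL,
    PROCESSING_RETURN,
    SEDIMENT_DEPOSITION,
    combined_immediate_cpt,
    recovery_cpt_table,
)


class TestStructure:
    def test_published_structure_counts(self, default_model):
        _, net = default_model
        summary = se.structure_summary(net)
        assert summary["n_nodes"] == 73
        assert summary["n_edges"] == 154
        assert summary["n_roots"] == 7

    def test_sixty_biota_nodes(self, default_model):
        _, net = default_model
        assert se.structure_summary(net)["tiers"]["biota"] == 60

    def test_empty_network_summary(self):
        net = se.Network(variables={}, cpts={})
        summary = se.structure_summary(net)
        assert (summary["n_nodes"], summary["n_edges"], summary["n_roots"]) == (0, 0, 0)

    def test_deleted_edge_fails_expected_counts(self):
        config = se.default_config()
        spec = config.cpts["sediment_changes"]
        spec["parents"] = [SEDIMENT_DEPOSITION]  # drop the nodule-removal edge
        del spec["coeffs"][NODULE_REMOVAL]
        with pytest.raises(ValueError, match="counts"):
            se.assemble_network(config)

    def test_all_cpts_normalized(self, default_model):
        _, net = default_model
        for cpt in net.cpts.values():
            np.testing.assert_allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9)


class TestDirectRemoval:
    def test_sessile_full_removal_inside(self):
        g = GROUPS_BY_KEY["sessile_erect_suspension"]
        assert se.direct_removal_fraction(g, "100%", ">30 cm", "inside") == 1.0

    def test_zero_outside_mined_block(self):
        for key in GROUPS_BY_KEY:
            g = GROUPS_BY_KEY[key]
            assert se.direct_removal_fraction(g, "100%", ">30 cm", "near-field") == 0.0
            assert se.direct_removal_fraction(g, "100%", ">30 cm", "far-field") == 0.0

    def test_mobile_escape(self):
        g = GROUPS_BY_KEY["mobile_grazing_epibenthos"]
        assert se.direct_removal_fraction(g, "50%", "<10 cm", "inside") == pytest.approx(0.4)

    def test_monotone_in_intensity_and_depth(self):
        for key in ("deep_meiofauna", "scavenging_hyperbenthos"):
            g = GROUPS_BY_KEY[key]
            fr = [
                se.direct_removal_fraction(g, i, d, "inside")
                for i in ("50%", "75%", "100%")
                for d in ("<10 cm", "10-30 cm", ">30 cm")
            ]
            by_depth = np.array(fr).reshape(3, 3)
            assert np.all(np.diff(by_depth, axis=0) >= 0)  # intensity
            assert np.all(np.diff(by_depth, axis=1) >= 0)  # depth (flat if not infauna)

    def test_direct_cpt_point_masses_and_tie_rule(self):
        g = GROUPS_BY_KEY["deep_meiofauna"]
        cpt = se.direct_cpt(g)
        assert set(np.unique(cpt.table)) == {0.0, 1.0}
        # 50% intensity, <10 cm depth -> fraction 0.4, on the 0.4 edge -> bin 21-40
        row = cpt.table[0 * 9 + 0 * 3 + 0]
        np.testing.assert_array_equal(row, [0, 1, 0, 0, 0])
        # full removal -> last bin
        row = cpt.table[2 * 9 + 2 * 3 + 0]
        np.testing.assert_array_equal(row, [0, 0, 0, 0, 1])
        # outside the block -> first bin
        row = cpt.table[2 * 9 + 2 * 3 + 1]
        np.testing.assert_array_equal(row, [1, 0, 0, 0, 0])


class TestCombinedImmediate:
    def test_low_low_column_matches_closed_form(self):
        table = combined_immediate_cpt(DEFAULT_BINS, grid_m=200)
        # P((1-D1)(1-D2) >= 0.8) for D1, D2 ~ U(0, 0.2) = 25(0.2 + 0.8 ln 0.8)
        p0 = 25 * (0.2 + 0.8 * np.log(0.8))
        np.testing.assert_allclose(table[0], [p0, 1 - p0, 0, 0, 0], atol=0.005)

    def test_matches_monte_carlo(self):
        table = combined_immediate_cpt(DEFAULT_BINS, grid_m=200)
        rng = np.random.default_rng(2024)
        edges = np.asarray(DEFAULT_BINS.edges)
        pairs = [(i, j) for i in range(5) for j in range(5)]
        for i, j in [pairs[k] for k in rng.choice(len(pairs), 10, replace=False)]:
            d1 = rng.uniform(edges[i], edges[i + 1], 200_000)
            d2 = rng.uniform(edges[j], edges[j + 1], 200_000)
            t = 1 - (1 - d1) * (1 - d2)
            mc = np.bincount(np.searchsorted(edges[1:-1], t, side="left"), minlength=5) / t.size
            np.testing.assert_allclose(table[i * 5 + j], mc, atol=0.005)

    def test_symmetric_in_inputs(self):
        table = combined_immediate_cpt(DEFAULT_BINS, grid_m=120)
        for i, j in itertools.combinations(range(5), 2):
            np.testing.assert_allclose(table[i * 5 + j], table[j * 5 + i], atol=1e-12)

    def test_total_dominates_both_inputs(self):
        # T >= max(D1, D2): no mass below the higher input bin
        table = combined_immediate_cpt(DEFAULT_BINS, grid_m=100)
        for i, j in itertools.product(range(5), repeat=2):
            lo = max(i, j)
            assert table[i * 5 + j][:lo].sum() == 0.0

    def test_top_bin_absorbs(self):
        table = combined_immediate_cpt(DEFAULT_BINS, grid_m=100)
        np.testing.assert_allclose(table[4 * 5 + 4], [0, 0, 0, 0, 1], atol=1e-12)

    def test_grid_guard(self):
        with pytest.raises(ValueError):
            combined_immediate_cpt(DEFAULT_BINS, grid_m=10)


class TestRecovery:
    def test_full_recovery_concentrates_at_zero(self):
        table = recovery_cpt_table((1.0,), DEFAULT_BINS)
        np.testing.assert_array_equal(table[:, 0], 1.0)

    def test_no_recovery_keeps_bin(self):
        table = recovery_cpt_table((0.0,), DEFAULT_BINS)
        np.testing.assert_allclose(table, np.eye(5), atol=1e-12)

    def test_scaled_uniform_split(self):
        # immediate bin (0.8, 1.0], r = 0.5 -> U(0.4, 0.5): all mass in 41-60
        table = recovery_cpt_table((0.5,), DEFAULT_BINS)
        np.testing.assert_allclose(table[4], [0, 0, 1, 0, 0], atol=1e-12)
        # immediate bin (0.6, 0.8], r = 0.5 -> U(0.3, 0.4): all in 21-40
        np.testing.assert_allclose(table[3], [0, 1, 0, 0, 0], atol=1e-12)

    def test_stronger_recovery_never_raises_expected_decrease(self):
        mids = DEFAULT_BINS.midpoints
        for r_lo, r_hi in ((0.1, 0.4), (0.2, 0.9)):
            lo = recovery_cpt_table((r_lo,), DEFAULT_BINS) @ mids
            hi = recovery_cpt_table((r_hi,), DEFAULT_BINS) @ mids
            assert np.all(hi <= lo + 1e-12)


class TestDefaultConfig:
    def test_high_scenario_states(self, default_model):
        config, _ = default_model
        high = config.scenario("high").assignments
        assert high[MINING_INTENSITY] == "100%"
        assert high[DEPTH_EXTRACTION] == ">30 cm"
        assert high[PROCESSING_RETURN] == "at seafloor"

    def test_intermediate_scenario_states(self, default_model):
        config, _ = default_model
        inter = config.scenario("intermediate").assignments
        assert inter[MINING_INTENSITY] == "50%"
        assert inter[DEPTH_EXTRACTION] == "<10 cm"

    def test_elicitation_specs_worst_mean_geq_best_mean(self, default_model):
        config, _ = default_model
        n_checked = 0
        for spec in config.cpts.values():
            if spec.get("type") != "beta_elicitation":
                continue
            best, worst = se.BetaSpec(*spec["best"]), se.BetaSpec(*spec["worst"])
            assert worst.mean >= best.mean
            n_checked += 1
        assert n_checked == 15

    def test_contaminant_weight_lowest_for_every_group(self, default_model):
        config, _ = default_model
        for spec in config.cpts.values():
            if spec.get("type") != "beta_elicitation":
                continue
            weights = {d["parent"]: d["weight"] for d in spec["influences"]}
            release = weights.pop("contaminant_release")
            assert release < min(weights.values())

    def test_nodule_removal_never_lowers_significant_changes(self, default_model):
        _, net = default_model
        cpt = net.cpts["sediment_changes"]
        p_sig = cpt.table[:, 1].reshape(3, 2)  # (deposition, nodule{yes,no})
        assert np.all(p_sig[:, 0] >= p_sig[:, 1])

    def test_fifteen_groups_with_expected_traits(self, default_model):
        config, _ = default_model
        groups = config.functional_groups()
        assert len(groups) == 15
        infauna = [g for g in groups if g.habit == "infauna"]
        assert len(infauna) == 6 and all(g.depth_sensitive for g in infauna)
        assert {g.escape_fraction for g in groups if g.habit == "epifauna-mobile"} == {0.2}
        assert {g.escape_fraction for g in groups if g.habit == "hyperbenthos"} == {0.3}


class TestConfigRoundTrip:
    def test_export_load_export_identical(self, tmp_path):
        config = se.default_config()
        path = tmp_path / "model.json"
        se.save_config(config, path)
        reloaded = se.load_config(path)
        assert dumps_config(reloaded) == dumps_config(config)
        net = se.assemble_network(reloaded)
        assert se.structure_summary(net)["n_nodes"] == 73

    def test_missing_variables_section_rejected(self):
        with pytest.raises(se.ConfigError, match="variables"):
            config_from_dict({"cpts": {}})

    def test_unknown_key_rejected_with_path(self):
        doc = config_to_dict(se.default_config())
        doc["cpts"]["sediment_changes"]["typo"] = 1
        with pytest.raises(se.ConfigError, match="cpts.sediment_changes"):
            config_from_dict(doc)

    def test_patch_changes_only_targeted_keys(self):
        base = config_to_dict(se.default_config())
        patch = {"cpts": {"particle_size": {"type": "table", "parents": [],
                                            "table": [[0.5, 0.3, 0.2]]}}}
        merged = merge_patch(base, patch)
        assert merged["cpts"]["particle_size"]["table"] == [[0.5, 0.3, 0.2]]
        before = json.dumps({k: v for k, v in base["cpts"].items() if k != "particle_size"},
                            sort_keys=True)
        after = json.dumps({k: v for k, v in merged["cpts"].items() if k != "particle_size"},
                           sort_keys=True)
        assert before == after
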