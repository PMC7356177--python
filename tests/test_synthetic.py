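import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from lncnet.data import CODING
from lncnet.errors import ConfigError
from lncnet.network import k_core
from lncnet.synthetic import (
    GeneratorConfig,
    generate_all,
    generate_cohort,
    generate_network,
    write_fixture,
)

from oracles import k_core_exhaustive


class TestGenerateCohort:
    def test_zero_noise_fold_changes_are_exact(self):
        config = GeneratorConfig(n_coding=200, n_lnc=40, noise_sd=0.0,
                                 frac_de=0.3, module_count=2,
                                 module_size=6, seed=3)
        matrix, truth = generate_cohort(config)
        case = matrix.values[matrix.samples_in_group("case")]
        control = matrix.values[matrix.samples_in_group("control")]
        diff = case.mean(axis=1) - control.mean(axis=1)
        for feature, fc in truth.planted_fc.items():
            expected = np.sign(fc) * np.log2(abs(fc))
            assert diff[feature] == pytest.approx(expected, abs=1e-9)

    def test_same_seed_same_matrix(self):
        config = GeneratorConfig(n_coding=300, n_lnc=50, frac_de=0.2,
                                 module_count=3, module_size=6, seed=11)
        m1, _ = generate_cohort(config)
        m2, _ = generate_cohort(config)
        pd.testing.assert_frame_equal(m1.values, m2.values, check_exact=True)

    def test_empirical_fc_close_to_planted_at_defaults(self, default_bundle):
        # the measured log2 FC is planted log2 FC + noise with standard
        # error noise_sd * sqrt(1/n_case + 1/n_control); check that the
        # empirical values track the planted ones at that precision
        config = default_bundle.config
        matrix, truth = default_bundle.matrix, default_bundle.truth
        se = config.noise_sd * np.sqrt(1 / config.n_case
                                       + 1 / config.n_control)
        case = matrix.values[matrix.samples_in_group("case")]
        control = matrix.values[matrix.samples_in_group("control")]
        diff = case.mean(axis=1) - control.mean(axis=1)
        errors = []
        within = 0
        for feature, fc in truth.planted_fc.items():
            planted_log2 = np.sign(fc) * np.log2(abs(fc))
            within += abs(diff[feature] - planted_log2) <= 2.5 * se
            errors.append(abs(2.0 ** abs(diff[feature]) - abs(fc)) / abs(fc))
        assert within / len(truth.planted_fc) >= 0.95
        assert np.mean(errors) <= 0.10  # ~7% expected at these conditions

    def test_noise_too_large_for_identifiable_decoys(self):
        # with this much noise no planted |FC| can sit reliably between
        # the 1.5 selection bar and the 4.0 cascade bar
        config = GeneratorConfig(n_coding=300, n_lnc=60, frac_de=0.2,
                                 module_count=3, module_size=6,
                                 n_case=4, n_control=4, noise_sd=0.5)
        with pytest.raises(ConfigError, match="noise_sd"):
            generate_cohort(config)

    def test_not_enough_de_genes_for_modules(self):
        config = GeneratorConfig(n_coding=100, frac_de=0.1,
                                 module_count=3, module_size=8)
        with pytest.raises(ConfigError, match="modules"):
            generate_cohort(config)

    @pytest.mark.parametrize("field, value", [
        ("frac_de", 0.6), ("fc_range", (1.4, 6.0)), ("driver_fc_min", 3.0),
        ("n_case", 0), ("module_edge_dropout", 0.5),
    ])
    def test_config_range_checks(self, field, value):
        with pytest.raises(ConfigError):
            dataclasses.replace(GeneratorConfig(), **{field: value}).validate()


class TestTruthInvariants:
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_planted_truth_consistency(self, seed):
        rng = np.random.default_rng(seed)
        # noise/sample-size combinations kept in the regime where the
        # decoy fold changes can sit clear of both selection boundaries
        config = GeneratorConfig(
            n_coding=int(rng.integers(300, 600)),
            n_lnc=int(rng.integers(40, 120)),
            n_case=int(rng.integers(6, 13)),
            n_control=int(rng.integers(6, 13)),
            frac_de=float(rng.uniform(0.15, 0.4)),
            module_count=int(rng.integers(2, 5)),
            module_size=int(rng.integers(6, 10)),
            noise_sd=float(rng.uniform(0.05, 0.25)),
            seed=seed)
        bundle = generate_all(config)
        truth = bundle.truth
        truth.validate()  # includes chain coverage for every driver
        assert not truth.de_up & truth.de_down
        de_coding = (truth.de_up | truth.de_down) & set(truth.coding_features)
        for module in truth.planted_modules:
            assert module <= de_coding
        assert len(truth.decoy_lncs) == 4
        assert set(truth.decoy_lncs.values()) == {"fc", "mirna", "deg",
                                                  "coverage"}

    def test_decoy_designs(self, default_bundle):
        truth = default_bundle.truth
        ann = default_bundle.annotation
        modes = {m: l for l, m in truth.decoy_lncs.items()}
        assert not {p for p in ann.lnc_to_mirna if p[0] == modes["mirna"]}
        assert abs(truth.planted_fc[modes["fc"]]) < 4
        deg_targets = set()
        for m in ann.mirnas_of(modes["deg"]):
            deg_targets |= ann.targets_of_mirna(m)
        assert not deg_targets & (truth.de_up | truth.de_down)
        covered = {i for i, mod in enumerate(truth.planted_modules)
                   if any(l == modes["coverage"] and g in mod
                          for l, _, g in truth.planted_chains)}
        assert covered and covered != set(range(len(truth.planted_modules)))


class TestGenerateNetwork:
    def test_no_dropout_no_background_gives_pure_cliques(self):
        config = GeneratorConfig(n_coding=300, n_lnc=50, frac_de=0.2,
                                 module_count=2, module_size=6,
                                 module_edge_dropout=0.0,
                                 background_edge_p=0.0, seed=7)
        _, truth = generate_cohort(config)
        graph = generate_network(truth, config)
        expected = set()
        for module in truth.planted_modules:
            members = sorted(module)
            expected |= {(a, b) for i, a in enumerate(members)
                         for b in members[i + 1:]}
        assert {tuple(sorted(e)) for e in graph.edges} == expected

    def test_every_planted_module_retains_a_4core(self, default_bundle):
        graph, truth = default_bundle.network, default_bundle.truth
        for module in truth.planted_modules:
            sub = graph.subgraph(module)
            core = k_core(sub, 4)
            assert core.number_of_nodes() > 0
            # independent exhaustive verification (module is small)
            assert set(core.nodes) == k_core_exhaustive(sub, 4)

    def test_module_size_below_six_rejected(self):
        config = GeneratorConfig(n_coding=300, n_lnc=50, frac_de=0.3,
                                 module_count=2, module_size=5)
        with pytest.raises(ConfigError, match="module_size"):
            generate_all(config)

    def test_score_ranges_split_by_edge_type(self, default_bundle):
        graph, truth = default_bundle.network, default_bundle.truth
        module_edges = set()
        for module in default_bundle.truth.planted_modules:
            members = sorted(module)
            module_edges |= {(a, b) for i, a in enumerate(members)
                             for b in members[i + 1:]}
        for a, b, score in graph.edges(data="score"):
            key = tuple(sorted((a, b)))
            if key in module_edges:
                assert 0.7 <= score <= 0.99
            else:
                assert 0.4 <= score <= 0.7


class TestWriteFixture:
    def test_round_trip_and_determinism(self, small_bundle, small_config,
                                        tmp_path):
        from lncnet import io as lio
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_fixture(d1, small_bundle)
        write_fixture(d2, generate_all(small_config))
        for name in ("expression.tsv", "edges.tsv", "truth.json",
                     "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        again = lio.read_expression(d1 / "expression.tsv", d1 / "groups.tsv",
                                    d1 / "classes.tsv")
        pd.testing.assert_frame_equal(again.values,
                                      small_bundle.matrix.values,
                                      check_exact=True)
        manifest = json.loads((d1 / "manifest.json").read_text())
        assert manifest["seed"] == small_config.seed

    def test_refuses_non_empty_directory(self, small_bundle, tmp_path):
        (tmp_path / "present.txt").write_text("x")
        with pytest.raises(ConfigError, match="non-empty"):
            write_fixture(tmp_path, small_bundle)
        write_fixture(tmp_path, small_bundle, force=True)  # force allows it
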