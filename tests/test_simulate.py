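import networkx as nx
import numpy as np
import pytest

from hifnet import (
    GeneratorConfig,
    ProbeAnnotation,
    TruthModel,
    estimate_mi,
    evaluate_recovery,
    generate_cohorts,
    generate_timecourse,
)
from tests.conftest import make_small_config


class TestGeneratorDeterminism:
    def test_same_seed_bitwise_identical(self, small_config):
        a1, b1, *_ = generate_cohorts(small_config)
        a2, b2, *_ = generate_cohorts(small_config)
        assert a1.values.equals(a2.values)
        assert b1.values.equals(b2.values)

    def test_seed_changes_values_not_structure(self, small_config, small_cohorts):
        a1, b1, _, _, t1 = small_cohorts
        cfg2 = make_small_config(seed=99)
        a2, b2, _, _, t2 = generate_cohorts(cfg2)
        assert a1.values.shape == a2.values.shape
        assert b1.values.shape == b2.values.shape
        assert t1.planted_edges == t2.planted_edges
        assert {m: len(s) for m, s in t1.modules.items()} == \
               {m: len(s) for m, s in t2.modules.items()}
        assert not np.allclose(a1.values.to_numpy(), a2.values.to_numpy())

    def test_dimensions_follow_config(self, small_config, small_cohorts):
        em_a, em_b, annotation, seeds, truth = small_cohorts
        assert em_a.n_samples == sum(small_config.samples_a.values())
        assert em_b.n_samples == sum(small_config.samples_b.values())
        assert set(em_a.probe_ids) <= set(em_b.probe_ids)  # platform nesting
        shared_frac = em_a.n_probes / em_b.n_probes
        assert shared_frac == pytest.approx(small_config.shared_probe_fraction, abs=0.02)
        assert len(seeds.genes) == small_config.n_seed_anchors
        assert all(p in annotation for p in em_b.probe_ids)


class TestPlantedEffects:
    def test_case_shift_recovered_within_three_se(self):
        # the module-mean profile removes gene-level noise correlation between
        # probes; its case-vs-rest difference has a clean two-sample SE
        cfg = GeneratorConfig(seed=11)
        em_a, _, annotation, _, truth = generate_cohorts(cfg)
        labels = em_a.require_labels()
        case = (labels == "M3").to_numpy()
        up_probes = [p for p in em_a.probe_ids
                     if annotation.gene_of(p) in truth.modules["apl_up"]]
        profile = em_a.values.loc[up_probes].to_numpy().mean(axis=0)
        diff = profile[case].mean() - profile[~case].mean()
        se = np.sqrt(profile[case].var(ddof=1) / case.sum()
                     + profile[~case].var(ddof=1) / (~case).sum())
        assert abs(diff - cfg.apl_shift) <= 3 * se

    def test_mi_matches_beta_implied_correlation(self):
        # with probe noise off, probe pairs realize rho = beta / sqrt(beta^2 +
        # sigma^2); compare against the estimator on an ideal Gaussian pair at
        # the same n so finite-sample estimator bias cancels
        cfg = make_small_config(sigma_probe=0.0, seed=12,
                                samples_a={"M0": 1000, "M3": 20},
                                samples_b={"M0": 50, "M3": 10})
        em_a, _, annotation, _, truth = generate_cohorts(cfg)
        rho = cfg.beta / np.sqrt(cfg.beta**2 + cfg.sigma_gene**2)
        member, anchor = next(
            (m, a) for m, a in truth.member_of.items()
            if m not in truth.apl_genes
        )
        mi = estimate_mi(
            em_a.values.loc[f"{anchor}_p1"], em_a.values.loc[f"{member}_p1"]
        )
        rng = np.random.default_rng(13)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        refs = [
            estimate_mi(*rng.multivariate_normal([0, 0], cov, size=em_a.n_samples).T)
            for _ in range(10)
        ]
        assert abs(mi - np.mean(refs)) <= 0.15

    def test_dead_probes_fall_to_entropy_filter(self, small_cohorts):
        from hifnet import entropy_filter, intersect_and_normalize

        em_a, em_b, annotation, _, truth = small_cohorts
        a, _ = intersect_and_normalize(em_a, em_b, log2=False)
        filtered = entropy_filter(a, 10)
        removed = set(a.probe_ids) - set(filtered.probe_ids)
        removed_genes = {annotation.gene_of(p) for p in removed}
        assert removed_genes <= truth.modules["dead"]


class TestTimecourse:
    def test_first_column_zero_and_decay(self, small_config, small_cohorts):
        *_, truth = small_cohorts
        tc = generate_timecourse(small_config, truth, timepoints=(0, 36, 72), tau=12.0,
                                 noise_sd=0.0)
        assert (tc[0.0] == 0).all()
        up = sorted(truth.modules["apl_up"])[0]
        # at t = 6 tau the remaining shift is e^-6 ~ 0.25% of the initial
        assert tc.loc[up, 72.0] == pytest.approx(-small_config.apl_shift, rel=3e-3)

    def test_contract_errors(self, small_config, small_cohorts):
        *_, truth = small_cohorts
        with pytest.raises(ValueError, match="tau"):
            generate_timecourse(small_config, truth, tau=0.0)
        with pytest.raises(ValueError, match="start at 0"):
            generate_timecourse(small_config, truth, timepoints=(6, 12))


class TestEvaluateRecovery:
    @staticmethod
    def _truth(edges, indirect=()):
        genes = {g for e in edges for g in e}
        return TruthModel(
            planted_edges=list(edges),
            indirect_pairs=list(indirect),
            modules={"seed": set(), "apl_up": set(), "apl_down": set(),
                     "background": set(), "dead": set()},
            member_of={},
            subtype_shifts={},
            regulators={"mir-reg-01": []},
        )

    @staticmethod
    def _graph(edges):
        g = nx.Graph()
        for u, v in edges:
            g.add_edge(f"{u}_p1", f"{v}_p1", mi=1.0)
        return g

    @staticmethod
    def _ann(genes):
        return ProbeAnnotation({f"{g}_p1": g for g in genes})

    def test_exact_recovery_scores_one(self):
        truth = self._truth([("A", "B"), ("B", "C")])
        rep = evaluate_recovery(self._graph([("A", "B"), ("B", "C")]), truth,
                                self._ann("ABC"))
        assert rep.edge_precision == 1.0 and rep.edge_recall == 1.0

    def test_disjoint_recovery_scores_zero(self):
        truth = self._truth([("A", "B")])
        rep = evaluate_recovery(self._graph([("C", "D")]), truth, self._ann("ABCD"))
        assert rep.edge_precision == 0.0 and rep.edge_recall == 0.0

    def test_half_right(self):
        truth = self._truth([("A", "B"), ("B", "C")])
        rep = evaluate_recovery(self._graph([("A", "B"), ("C", "D")]), truth,
                                self._ann("ABCD"))
        assert rep.edge_precision == 0.5 and rep.edge_recall == 0.5

    def test_indirect_pairs_counted_per_flag(self):
        truth = self._truth([("A", "B"), ("A", "C")], indirect=[("B", "C")])
        inferred = self._graph([("A", "B"), ("A", "C"), ("B", "C")])
        ann = self._ann("ABC")
        strict = evaluate_recovery(inferred, truth, ann)
        assert strict.edge_precision == pytest.approx(2 / 3)
        assert strict.n_indirect_recovered == 1
        lenient = evaluate_recovery(inferred, truth, ann, count_indirect_as_fp=False)
        assert lenient.edge_precision == 1.0

    def test_empty_truth_is_an_error(self):
        truth = self._truth([])
        with pytest.raises(ValueError, match="no planted edges"):
            evaluate_recovery(self._graph([("A", "B")]), truth, self._ann("AB"))


class TestConfigValidation:
    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValueError, match="targets exceed"):
            make_small_config(n_regulator_mirnas=5, targets_per_regulator=10)
        with pytest.raises(ValueError, match="shared_probe_fraction"):
            make_small_config(shared_probe_fraction=0.0)
        with pytest.raises(ValueError, match="anchor count"):
            make_small_config(apl_up_size=2, apl_up_anchors=2)
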