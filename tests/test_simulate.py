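"""Synthetic cohort generator: determinism, HWE, recovery metrics."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare

from codprov.cluster import hierarchical_assign
from codprov.interpret import TradeClassification, test_element_origin_association as element_origin_association
from codprov.inversions import genotype_all_inversions
from codprov.panel_io import INVERSION_NAMES
from codprov.simulate import (
    SimConfig,
    SimTruth,
    SimTruthEntry,
    evaluate_recovery,
    simulate_cohort,
    simulate_reference_panel,
    simulate_specimen,
)


def small_config(**kw):
    defaults = dict(n_specimens=12, n_genomewide_sites=10, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_gives_identical_cohort(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        assert [t.counts for t in a.counts] == [t.counts for t in b.counts]
        assert a.truth.entries == b.truth.entries
        assert [dataclasses.astuple(q) for q in a.qc] == [dataclasses.astuple(q) for q in b.qc]
        assert [m.bone_element for m in a.meta] == [m.bone_element for m in b.meta]

    def test_different_seed_changes_cohort(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        assert [t.counts for t in a.counts] != [t.counts for t in b.counts]


class TestPanelGeneration:
    def test_zero_divergence_makes_clusters_identical(self):
        panel = simulate_reference_panel(small_config(cluster_divergence=0.0))
        w, e, b = (panel.clusters[c] for c in ("western_atlantic", "eastern_atlantic", "baltic"))
        assert w == e == b

    def test_divergence_respected_at_every_site(self):
        cfg = small_config(cluster_divergence=0.6)
        panel = simulate_reference_panel(cfg)
        for site in panel.clusters["western_atlantic"]:
            spread = max(
                panel.clusters[c][site] for c in panel.clusters
            ) - min(panel.clusters[c][site] for c in panel.clusters)
            assert spread == pytest.approx(0.6)

    def test_degenerate_frequencies_make_fully_diagnostic_panel(self):
        freqs = {"popX": (0.0, 0.0, 0.0, 0.0), "popY": (1.0, 1.0, 1.0, 1.0)}
        cfg = small_config(
            inversion_freqs=freqs,
            population_clusters={"popX": "eastern_atlantic", "popY": "eastern_atlantic"},
            ecotype_merges={},
            haplogroups={},
        )
        panel = simulate_reference_panel(cfg)
        for locus in panel.inversions.values():
            assert locus.per_population_freq == {"popX": 0.0, "popY": 1.0}

    def test_generated_panel_passes_validation(self):
        simulate_reference_panel(SimConfig()).validate()


class TestSpecimenGeneration:
    def test_fixed_inverted_population_reads_all_alt(self):
        freqs = {"fixed": (1.0, 1.0, 1.0, 1.0)}
        cfg = small_config(
            inversion_freqs=freqs,
            population_clusters={"fixed": "eastern_atlantic"},
            ecotype_merges={},
            haplogroups={},
            err=0.0,
            depth_lambda=50.0,
        )
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(0)
        counts, truth = simulate_specimen("fixed", panel, cfg, rng, "F1")
        assert truth.dosages == (2, 2, 2, 2)
        diag_keys = set().union(*(l.site_keys for l in panel.inversions.values()))
        for site, (ref_n, alt_n) in counts.counts.items():
            if site.key in diag_keys:
                assert ref_n == 0 and alt_n > 0

    def test_zero_depth_keeps_truth(self):
        cfg = small_config(depth_lambda=0.0)
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(0)
        counts, truth = simulate_specimen("North Sea", panel, cfg, rng, "Z1")
        assert counts.counts == {}
        assert truth.true_population == "North Sea"

    def test_unknown_population_rejected(self):
        cfg = small_config()
        panel = simulate_reference_panel(cfg)
        with pytest.raises(KeyError):
            simulate_specimen("Atlantis", panel, cfg, np.random.default_rng(0), "X")

    def test_hwe_dosage_distribution(self):
        """Dosage frequencies over 10 000 specimens at f = 0.3 match the
        HWE closed form (0.49, 0.42, 0.09) within 0.01 and pass a chi-square
        goodness-of-fit check."""
        freqs = {"p": (0.3, 0.3, 0.3, 0.3)}
        cfg = small_config(
            inversion_freqs=freqs,
            population_clusters={"p": "eastern_atlantic"},
            ecotype_merges={},
            haplogroups={},
            depth_lambda=0.0,   # truth only; no reads needed
            n_genomewide_sites=1,
            seed=42,
        )
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(42)
        draws = np.array(
            [simulate_specimen("p", panel, cfg, rng, f"S{i}")[1].dosages for i in range(10_000)]
        ).ravel()
        observed = np.array([(draws == d).sum() for d in (0, 1, 2)])
        expected = np.array([0.49, 0.42, 0.09]) * draws.size
        assert np.all(np.abs(observed / draws.size - expected / draws.size) < 0.01)
        assert chisquare(observed, expected).pvalue > 0.001


class TestCohortAndMetadata:
    def test_full_association_detected_by_fisher(self):
        cfg = small_config(n_specimens=24, element_origin_association=1.0, seed=3)
        cohort = simulate_cohort(cfg)
        records = []
        local = {"North Sea", "Irish Sea"}
        for m in cohort.meta:
            pop = cohort.truth[m.specimen_id].true_population
            status = "local" if pop in local else "traded"
            records.append((m.bone_element, TradeClassification(m.specimen_id, status, "")))
        _, p = element_origin_association(records)
        assert p < 0.05

    def test_no_association_keeps_type_i_error_near_alpha(self):
        rejections = 0
        n_cohorts = 200
        for seed in range(n_cohorts):
            cfg = small_config(n_specimens=24, element_origin_association=0.0, seed=seed)
            cohort = simulate_cohort(cfg)
            records = []
            local = {"North Sea", "Irish Sea"}
            for m in cohort.meta:
                pop = cohort.truth[m.specimen_id].true_population
                status = "local" if pop in local else "traded"
                records.append((m.bone_element, TradeClassification(m.specimen_id, status, "")))
            try:
                _, p = element_origin_association(records)
            except ValueError:
                continue
            rejections += p <= 0.05
        assert rejections / n_cohorts <= 0.07

    def test_qc_includes_negative_controls(self):
        cohort = simulate_cohort(small_config())
        assert sum(q.is_negative_control for q in cohort.qc) == 2


class TestEvaluateRecovery:
    def _outputs(self, cohort, err=0.01):
        assigns, genos = {}, {}
        for t in cohort.counts:
            assigns[t.specimen_id] = hierarchical_assign(t, cohort.panel, err=err)
            genos[t.specimen_id] = genotype_all_inversions(t, cohort.panel, err=err)
        return assigns, genos

    @staticmethod
    def _outputs_from_truth(cohort, cluster_of=None):
        """Stage outputs copied verbatim from the generator's truth."""
        from codprov.cluster import ClusterAssignment
        from codprov.inversions import CompositeGenotype, InversionCall

        assigns, genos = {}, {}
        for sid, e in cohort.truth.entries.items():
            cl = cluster_of(e.true_cluster) if cluster_of else e.true_cluster
            stage1 = {
                "western_atlantic": 1.0 if cl == "western_atlantic" else 0.0,
                "eastern_atlantic": 0.0 if cl == "western_atlantic" else 1.0,
            }
            stage2 = None
            if cl != "western_atlantic":
                p_baltic = 1.0 if cl == "baltic" else 0.0
                stage2 = {"baltic": p_baltic, "eastern_nonbaltic": 1.0 - p_baltic}
            assigns[sid] = ClusterAssignment(sid, stage1, stage2, 50)
            per_inv = {
                name: InversionCall(tuple(1.0 if i == d else 0.0 for i in range(3)), d)
                for name, d in zip(INVERSION_NAMES, e.dosages)
            }
            genos[sid] = CompositeGenotype(sid, per_inv)
        return assigns, genos

    def test_outputs_equal_truth_score_one(self):
        cohort = simulate_cohort(small_config())
        assigns, genos = self._outputs_from_truth(cohort)
        m = evaluate_recovery(cohort.truth, assigns, genos)
        assert m.cluster_accuracy == 1.0
        assert m.genotype_accuracy == 1.0
        assert m.high_confidence_call_fraction == 1.0

    def test_permuted_cluster_labels_score_zero(self):
        rotate = {
            "western_atlantic": "eastern_atlantic",
            "eastern_atlantic": "baltic",
            "baltic": "western_atlantic",
        }
        cohort = simulate_cohort(small_config())
        assigns, genos = self._outputs_from_truth(cohort, cluster_of=rotate.get)
        m = evaluate_recovery(cohort.truth, assigns, genos)
        assert m.cluster_accuracy == 0.0
        assert m.genotype_accuracy == 1.0

    def test_unknown_specimen_id_rejected(self):
        cohort = simulate_cohort(small_config())
        assigns, _ = self._outputs(cohort)
        truth = SimTruth(entries={"OTHER": SimTruthEntry("baltic", "Baltic Sea", (0, 0, 0, 0))})
        with pytest.raises(KeyError, match="unknown specimens"):
            evaluate_recovery(truth, assigns)

    def test_accuracy_nondecreasing_in_depth(self):
        """Across a depth sweep the cluster and genotype accuracies do not
        degrade (within Monte-Carlo tolerance)."""
        accs = []
        for lam in (1.0, 5.0, 20.0):
            cohort = simulate_cohort(
                small_config(n_specimens=36, n_genomewide_sites=50, depth_lambda=lam, seed=7)
            )
            assigns, genos = self._outputs(cohort)
            m = evaluate_recovery(cohort.truth, assigns, genos)
            accs.append((m.cluster_accuracy, m.genotype_accuracy))
        tol = 0.1
        for (c1, g1), (c2, g2) in zip(accs, accs[1:]):
            assert c2 >= c1 - tol
            assert g2 >= g1 - tol
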