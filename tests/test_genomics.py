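"""Variant filtering rules, naive-Bayes cluster assignment, Hans algorithm."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autobcr.genomics import (
    ClusterAssignment,
    ClusterModel,
    VariantRecord,
    assign_consensus_cluster,
    confidence_call,
    filter_variants,
    hans_coo,
)
from autobcr.simulate import simulate_aberrations

from oracles import naive_bayes_posterior, variant_retained

GENES = ["MYD88", "CD79B", "CARD11", "PIM1", "TNFAIP3"]
CONSEQUENCES = ["missense", "frameshift", "stop_gained", "inframe_deletion"]


class TestFilterVariants:
    def test_sift_deleterious_whitelisted_retained(self):
        rec = VariantRecord(gene="MYD88", consequence="missense", sift_label="deleterious")
        assert filter_variants([rec], GENES, CONSEQUENCES) == [rec]

    def test_benign_rule_dominates_damaging_predictors(self):
        rec = VariantRecord(
            gene="MYD88", consequence="missense",
            sift_label="deleterious", clinical_significance="benign",
        )
        assert filter_variants([rec], GENES, CONSEQUENCES) == []

    def test_non_whitelisted_gene_or_consequence_discarded(self):
        r1 = VariantRecord(gene="TP53", consequence="missense", sift_label="deleterious")
        r2 = VariantRecord(gene="MYD88", consequence="intron_variant", sift_label="deleterious")
        assert filter_variants([r1, r2], GENES, CONSEQUENCES) == []

    def test_no_damaging_evidence_discarded(self):
        rec = VariantRecord(
            gene="MYD88", consequence="missense",
            sift_label="tolerated", polyphen_label="benign",
        )
        assert filter_variants([rec], GENES, CONSEQUENCES) == []

    def test_polyphen_and_clinsig_routes(self):
        r1 = VariantRecord(gene="CD79B", consequence="missense", polyphen_label="possibly damaging")
        r2 = VariantRecord(gene="PIM1", consequence="frameshift",
                           clinical_significance="likely pathogenic")
        assert filter_variants([r1, r2], GENES, CONSEQUENCES) == [r1, r2]

    def test_empty_whitelist_rejected(self):
        rec = VariantRecord(gene="MYD88", consequence="missense")
        with pytest.raises(ValueError, match="whitelist"):
            filter_variants([rec], [], CONSEQUENCES)

    def test_500_random_records_match_boolean_oracle(self):
        rng = np.random.default_rng(11)
        sift_opts = [None, "deleterious", "tolerated"]
        poly_opts = [None, "possibly damaging", "probably damaging", "benign"]
        clin_opts = [None, "benign", "likely benign", "likely pathogenic", "pathogenic",
                     "uncertain significance"]
        gene_opts = GENES + ["TP53", "KRAS"]
        cons_opts = CONSEQUENCES + ["intron_variant", "synonymous"]
        records = [
            VariantRecord(
                gene=gene_opts[rng.integers(len(gene_opts))],
                consequence=cons_opts[rng.integers(len(cons_opts))],
                sift_label=sift_opts[rng.integers(len(sift_opts))],
                polyphen_label=poly_opts[rng.integers(len(poly_opts))],
                clinical_significance=clin_opts[rng.integers(len(clin_opts))],
                case_id=f"case{i}",
            )
            for i in range(500)
        ]
        got = filter_variants(records, GENES, CONSEQUENCES)
        expected = [
            r for r in records
            if variant_retained(r.gene, r.consequence, r.sift_label, r.polyphen_label,
                                r.clinical_significance, set(GENES), CONSEQUENCES)
        ]
        assert got == expected

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        records = [
            VariantRecord(
                gene=GENES[rng.integers(len(GENES))],
                consequence=CONSEQUENCES[rng.integers(len(CONSEQUENCES))],
                sift_label="deleterious" if rng.random() < 0.5 else "tolerated",
                case_id=f"c{i}",
            )
            for i in range(50)
        ]
        once = filter_variants(records, GENES, CONSEQUENCES)
        assert filter_variants(once, GENES, CONSEQUENCES) == once
        reversed_out = filter_variants(records[::-1], GENES, CONSEQUENCES)
        assert set(reversed_out) == set(once)


def _random_model(rng, n_clusters=5, n_loci=8):
    return ClusterModel(
        clusters=tuple(f"C{i}" for i in range(n_clusters)),
        loci=tuple(f"L{i}" for i in range(n_loci)),
        frequencies=rng.random((n_loci, n_clusters)),
        priors=None,
    )


class TestClusterAssignment:
    def test_single_locus_bayes(self):
        eps = 0.01
        model = ClusterModel(
            clusters=("A", "B"), loci=("l",),
            frequencies=np.array([[1.0, 0.0]]), epsilon=eps,
        )
        a = assign_consensus_cluster({"l": 1}, model)
        assert a.posteriors["A"] == pytest.approx(1 - eps, abs=1e-12)
        assert a.posteriors["B"] == pytest.approx(eps, abs=1e-12)

    def test_empty_vector_returns_priors(self):
        model = ClusterModel(
            clusters=("A", "B"), loci=("l",),
            frequencies=np.array([[0.7, 0.2]]), priors=np.array([0.3, 0.7]),
        )
        a = assign_consensus_cluster({}, model)
        assert a.uninformative
        assert a.posteriors == pytest.approx({"A": 0.3, "B": 0.7})

    def test_unknown_locus_rejected(self):
        model = ClusterModel(("A",), ("l",), np.array([[0.5]]))
        with pytest.raises(ValueError, match="locus"):
            assign_consensus_cluster({"nope": 1}, model)

    def test_missing_loci_skipped(self):
        model = ClusterModel(
            clusters=("A", "B"), loci=("l1", "l2"),
            frequencies=np.array([[0.9, 0.1], [0.5, 0.5]]),
        )
        full = assign_consensus_cluster({"l1": 1, "l2": None}, model)
        partial = assign_consensus_cluster({"l1": 1}, model)
        assert full.posteriors == pytest.approx(partial.posteriors)

    def test_posteriors_match_direct_product_oracle(self):
        """Log-space posterior equals brute-force products to 1e-12."""
        rng = np.random.default_rng(23)
        model = _random_model(rng)
        for _ in range(100):
            vector = {
                locus: (None if rng.random() < 0.2 else int(rng.random() < 0.5))
                for locus in model.loci
            }
            got = assign_consensus_cluster(vector, model)
            exp = naive_bayes_posterior(
                vector, model.clusters, model.loci,
                model.frequencies.tolist(), model.priors.tolist(), model.epsilon,
            )
            for c, e in zip(model.clusters, exp):
                assert got.posteriors[c] == pytest.approx(e, abs=1e-12)
            assert sum(got.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    def test_label_recovery_well_separated(self):
        """Well-separated cluster-conditional frequencies give >= 95% recovery."""
        n_clusters, n_loci = 3, 9
        freqs = np.full((n_loci, n_clusters), 0.05)
        for c in range(n_clusters):
            freqs[3 * c : 3 * (c + 1), c] = 0.85  # three defining loci per cluster
        model = ClusterModel(
            clusters=tuple(f"C{i}" for i in range(n_clusters)),
            loci=tuple(f"L{i}" for i in range(n_loci)),
            frequencies=freqs,
        )
        mat, labels = simulate_aberrations(model, n_cases_per_cluster=70, seed=3)
        calls = [
            assign_consensus_cluster(row.to_dict(), model).cluster
            for _, row in mat.iterrows()
        ]
        assert (np.asarray(calls) == labels.to_numpy()).mean() >= 0.95

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        model = _random_model(rng, n_clusters=3, n_loci=4)
        path = model.to_json(tmp_path / "model.json")
        back = ClusterModel.from_json(path)
        assert back.clusters == model.clusters and back.loci == model.loci
        np.testing.assert_allclose(back.frequencies, model.frequencies)
        a = assign_consensus_cluster({"L0": 1, "L2": 0}, model)
        b = assign_consensus_cluster({"L0": 1, "L2": 0}, back)
        assert a.posteriors == pytest.approx(b.posteriors)


class TestConfidenceCall:
    def _assignment(self, p_max):
        return ClusterAssignment(
            posteriors={"A": p_max, "B": 1 - p_max}, cluster="A"
        )

    def test_strict_threshold(self):
        assert confidence_call(self._assignment(0.95)) == "assigned"
        assert confidence_call(self._assignment(0.9)) == "unclassified"  # strict >
        assert confidence_call(self._assignment(0.5)) == "unclassified"

    @given(st.floats(min_value=0.5, max_value=1.0), st.data())
    @settings(max_examples=50, deadline=None)
    def test_threshold_sweep_monotone(self, p_max, data):
        """Raising the threshold never converts unclassified to assigned."""
        t1 = data.draw(st.floats(min_value=0.5, max_value=0.99))
        t2 = data.draw(st.floats(min_value=t1, max_value=0.999))
        a = self._assignment(p_max)
        if confidence_call(a, threshold=t1) == "unclassified":
            assert confidence_call(a, threshold=t2) == "unclassified"


class TestHans:
    TRUTH = {
        # (cd10, bcl6, mum1) -> call, hand-enumerated decision tree
        (True, True, True): "GCB",
        (True, True, False): "GCB",
        (True, False, True): "GCB",
        (True, False, False): "GCB",
        (False, False, True): "non_GCB",
        (False, False, False): "non_GCB",
        (False, True, True): "non_GCB",
        (False, True, False): "GCB",
    }

    def test_all_eight_combinations(self):
        for combo in itertools.product([True, False], repeat=3):
            assert hans_coo(*combo) == self.TRUTH[combo], combo

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="mum1"):
            hans_coo(True, False, None)
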