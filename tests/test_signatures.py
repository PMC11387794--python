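import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cocusig import (
    DerivationParams,
    ExpressionMatrix,
    FoldChangeSignatureSelector,
    GeneSetCollection,
    SignatureDefinition,
    SignatureScorer,
    derive_foldchange_signature,
    derive_frequency_signature,
    score_signature,
)
from cocusig.enrichment import EnrichmentResult

from conftest import make_experiment


def enriched(name, leading, q=0.001, es=0.8):
    return EnrichmentResult(name, len(leading), es, 2.0, 0.005, q, list(leading), 200)


class TestSignatureDefinition:
    def test_union_cardinality_with_one_shared_gene(self):
        cancer = ["C1", "C2", "C3", "C4", "SHARED"]
        caf = ["F1", "F2", "F3", "SHARED"]
        sig = SignatureDefinition("eight", cancer, caf)
        assert len(sig) == 8

    def test_union_cardinality_two_and_twentynine(self):
        cancer = ["SHARED", "C1"]
        caf = ["SHARED"] + [f"F{i}" for i in range(28)]
        sig = SignatureDefinition("thirty", cancer, caf)
        assert len(sig) == 30

    def test_union_identity_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pool = [f"G{i}" for i in range(40)]
            cancer = list(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            caf = list(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            sig = SignatureDefinition("s", cancer, caf)
            assert len(sig) == len(cancer) + len(caf) - len(set(cancer) & set(caf))

    def test_json_round_trip(self, tmp_path):
        sig = SignatureDefinition("sig", ["A", "B"], ["B", "C"])
        path = tmp_path / "sig.json"
        sig.to_json(path, params={"route": "frequency"})
        back = SignatureDefinition.from_json(path)
        assert back.genes == sig.genes
        assert back.name == "sig"


class TestFrequencyDerivation:
    def test_boundary_two_of_ten_enriched_sets_kept(self):
        # gene in exactly 2 of 10 enriched sets meets the inclusive 20% rule
        sets = {f"S{i}": [f"FILL{i}_{j}" for j in range(4)] + ["TARGET"] * (i < 2)
                for i in range(10)}
        sets = {k: [g for g in v if g] for k, v in sets.items()}
        coll = GeneSetCollection.from_dict(sets)
        results = [enriched(k, v) for k, v in sets.items()]
        enrichments = {("D1", "cancer"): results}
        sig = derive_frequency_signature(enrichments, coll)
        assert "TARGET" in sig.cancer_list

    def test_one_of_ten_excluded(self):
        sets = {f"S{i}": [f"FILL{i}_{j}" for j in range(4)] + (["TARGET"] if i == 0 else [])
                for i in range(10)}
        coll = GeneSetCollection.from_dict(sets)
        enrichments = {("D1", "cancer"): [enriched(k, v) for k, v in sets.items()]}
        sig = derive_frequency_signature(enrichments, coll)
        assert "TARGET" not in sig.cancer_list

    def test_requires_presence_in_all_datasets(self):
        coll = GeneSetCollection.from_dict({"S": ["A", "B", "C"]})
        enrichments = {
            ("D1", "cancer"): [enriched("S", ["A", "B"])],
            ("D2", "cancer"): [enriched("S", ["A"])],
        }
        sig = derive_frequency_signature(enrichments, coll)
        assert sig.cancer_list == ["A"]

    def test_non_significant_sets_ignored(self):
        coll = GeneSetCollection.from_dict({"GOOD": ["A", "B"], "BAD": ["X", "Y"]})
        enrichments = {("D1", "caf"): [
            enriched("GOOD", ["A", "B"]),
            enriched("BAD", ["X", "Y"], q=0.5),
        ]}
        sig = derive_frequency_signature(enrichments, coll)
        assert "X" not in sig.caf_list and "A" in sig.caf_list

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            genes = [f"G{i}" for i in range(30)]
            n_sets = int(rng.integers(2, 9))
            sets = {
                f"S{i}": list(rng.choice(genes, size=rng.integers(3, 12), replace=False))
                for i in range(n_sets)
            }
            coll = GeneSetCollection.from_dict(sets)
            enrichments = {}
            truth = {}
            for d in ("D1", "D2", "D3"):
                results = []
                for name, members in sets.items():
                    q = float(rng.uniform(0, 0.1))
                    n_lead = int(rng.integers(1, len(members) + 1))
                    lead = list(rng.choice(members, size=n_lead, replace=False))
                    results.append(enriched(name, lead, q=q))
                    truth[(d, name)] = (q, lead, members)
                enrichments[(d, "cancer")] = results
            sig = derive_frequency_signature(enrichments, coll)

            # independent exhaustive recount
            kept_per_dataset = []
            for d in ("D1", "D2", "D3"):
                sig_sets = [name for name in sets if truth[(d, name)][0] < 0.05]
                pool = set()
                for name in sig_sets:
                    pool |= set(truth[(d, name)][1])
                need = math.ceil(0.2 * len(sig_sets))
                kept = {
                    g for g in pool
                    if sum(g in truth[(d, name)][2] for name in sig_sets) >= need
                }
                kept_per_dataset.append(kept)
            expected = set.intersection(*kept_per_dataset)
            assert set(sig.cancer_list) == expected

    def test_antitone_in_frequency_threshold(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(20)]
        sets = {f"S{i}": list(rng.choice(genes, size=8, replace=False)) for i in range(6)}
        coll = GeneSetCollection.from_dict(sets)
        enrichments = {("D1", "cancer"): [enriched(k, v) for k, v in sets.items()]}
        loose = derive_frequency_signature(
            enrichments, coll, DerivationParams(pathway_frequency_threshold=0.2))
        tight = derive_frequency_signature(
            enrichments, coll, DerivationParams(pathway_frequency_threshold=0.6))
        assert set(tight.genes) <= set(loose.genes)

    def test_zero_enriched_sets_yields_empty_with_warning(self, caplog):
        coll = GeneSetCollection.from_dict({"S": ["A", "B"]})
        enrichments = {("D1", "cancer"): [enriched("S", ["A"], q=0.9)]}
        with caplog.at_level("WARNING"):
            sig = derive_frequency_signature(enrichments, coll)
        assert len(sig) == 0


class TestFoldChangeDerivation:
    def test_exact_threshold_selected(self):
        exp = make_experiment(co={"G": [1.5, 1.5], "H": [1.4, 1.4]},
                              mono={"G": [1.0, 1.0], "H": [1.0, 1.0]})
        sig = derive_foldchange_signature([exp])
        assert sig.cancer_list == ["G"]

    def test_gene_in_two_of_three_datasets_excluded(self):
        exps = []
        for d, fc in (("D1", 2.0), ("D2", 2.0), ("D3", 1.0)):
            exps.append(make_experiment(co={"G": [fc, fc]}, mono={"G": [1.0, 1.0]},
                                        dataset_id=d))
        sig = derive_foldchange_signature(exps)
        assert "G" not in sig.genes

    def test_union_of_cell_types(self):
        cancer = make_experiment(co={"A": [2, 2], "B": [1, 1]},
                                 mono={"A": [1, 1], "B": [1, 1]}, cell_type="cancer")
        caf = make_experiment(co={"A": [2, 2], "B": [3, 3]},
                              mono={"A": [1, 1], "B": [1, 1]}, cell_type="caf")
        sig = derive_foldchange_signature([cancer, caf])
        assert sig.cancer_list == ["A"]
        assert sig.caf_list == ["A", "B"]
        assert len(sig) == 2

    def test_selector_is_sklearn_compatible(self):
        sel = FoldChangeSignatureSelector(fold_change_threshold=2.0)
        assert sel.get_params()["fold_change_threshold"] == 2.0
        cloned = clone(sel)
        exp = make_experiment(co={"G": [4, 4]}, mono={"G": [1, 1]})
        cloned.fit([exp])
        assert cloned.signature_.genes == ["G"]
        assert not hasattr(sel, "signature_")  # clone does not share fitted state


class TestScoring:
    def test_constant_matrix_scores_zero(self):
        df = pd.DataFrame(np.full((3, 4), 7.0), index=["A", "B", "C"],
                          columns=list("wxyz"))
        scores = score_signature(ExpressionMatrix(df), ["A", "B"])
        assert np.allclose(scores, 0.0)

    def test_single_gene_equals_zscore(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 100, (5, 6)),
                          index=[f"G{i}" for i in range(5)],
                          columns=[f"S{i}" for i in range(6)])
        mat = ExpressionMatrix(df)
        scores = score_signature(mat, ["G2"])
        log = np.log2(df.loc["G2"] + 1)
        expected = (log - log.mean()) / log.std(ddof=1)
        assert np.allclose(scores, expected)

    def test_three_gene_hand_computation(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(0, 50, (4, 5)),
                          index=["A", "B", "C", "D"],
                          columns=[f"S{i}" for i in range(5)])
        mat = ExpressionMatrix(df)
        scores = score_signature(mat, ["A", "C", "D"])
        log = np.log2(df + 1)
        z = log.sub(log.mean(axis=1), axis=0).div(log.std(axis=1, ddof=1), axis=0)
        expected = z.loc[["A", "C", "D"]].mean(axis=0)
        assert np.allclose(scores, expected, atol=1e-9)

    def test_affine_invariance_of_log_expression(self):
        rng = np.random.default_rng(5)
        log = pd.DataFrame(rng.uniform(1, 10, (3, 6)), index=["A", "B", "C"],
                           columns=[f"S{i}" for i in range(6)])
        mat1 = ExpressionMatrix(log, scale="log2p1")
        shifted = ExpressionMatrix(log * 3.0 + 2.0, scale="log2p1")
        s1 = score_signature(mat1, ["A", "B", "C"])
        s2 = score_signature(shifted, ["A", "B", "C"])
        assert np.allclose(s1, s2, atol=1e-9)

    def test_missing_genes_tolerated_but_not_all(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"], columns=["x", "y"])
        mat = ExpressionMatrix(df)
        scores = score_signature(mat, ["A", "ABSENT"])
        assert len(scores) == 2
        with pytest.raises(ValueError, match="no signature gene"):
            score_signature(mat, ["ABSENT"])

    def test_scorer_transform_on_new_samples(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(0, 20, (3, 8)), index=["A", "B", "C"],
                          columns=[f"S{i}" for i in range(8)])
        scorer = SignatureScorer(["A", "C"]).fit(ExpressionMatrix(df))
        new = ExpressionMatrix(df[["S0", "S1"]])
        scores = scorer.transform(new)
        full = scorer.transform(ExpressionMatrix(df))
        assert np.allclose(scores, full[["S0", "S1"]])
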