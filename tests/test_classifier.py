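import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from archetrack import (
    ExpressionMatrix,
    SimConfig,
    ValidationError,
    generate_cohort,
    lognormalize,
    reclassify_undefined,
    train_reference_classifier,
)


from _oracles import brute_force_auc


def _marker_block_cohort(n_per_class=60, n_genes=80, flip_labels=False, seed=0):
    """Two ploidy classes with disjoint exclusive marker blocks."""
    rng = np.random.default_rng(seed)
    base = rng.poisson(3.0, size=(2 * n_per_class, n_genes)) + 1
    base[:n_per_class, :15] += 60  # diploid markers
    base[n_per_class:, 15:30] += 60  # aneuploid markers
    labels = ["diploid"] * n_per_class + ["aneuploid"] * n_per_class
    if flip_labels:
        labels = list(rng.permutation(labels))
    cells = [f"c{i}" for i in range(2 * n_per_class)]
    expr = lognormalize(
        ExpressionMatrix(sp.csr_matrix(base), [f"g{i}" for i in range(n_genes)], cells)
    )
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "patient": "P1",
            "cycle": 1,
            "biopsy_site": "s",
            "cell_type": "epithelial",
            "ploidy": labels,
            "n_features": 500,
            "pct_mt": 1.0,
        }
    )
    return expr, meta


class TestTraining:
    def test_separable_markers_give_perfect_auc(self):
        expr, meta = _marker_block_cohort()
        model = train_reference_classifier(expr, meta, n_variable_genes=40, seed=0)
        assert model.cv_auc == pytest.approx(1.0)
        assert model.accepted

    def test_permuted_labels_hover_at_chance(self):
        aucs = []
        for seed in range(3):
            expr, meta = _marker_block_cohort(n_per_class=150, flip_labels=True, seed=seed)
            model = train_reference_classifier(expr, meta, n_variable_genes=40, seed=seed)
            aucs.append(model.cv_auc)
            assert not model.accepted
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_cv_auc_matches_brute_force_oracle(self):
        expr, meta = _marker_block_cohort(n_per_class=25)
        model = train_reference_classifier(expr, meta, n_variable_genes=40, seed=1)
        y = model.cv_truth
        oracle = np.mean(
            [
                brute_force_auc(
                    (y == lab).astype(int).to_numpy(),
                    model.cv_margins[lab].to_numpy(),
                )
                for lab in model.labels
            ]
        )
        assert model.cv_auc == pytest.approx(oracle, abs=1e-10)

    def test_single_label_rejected(self):
        expr, meta = _marker_block_cohort(n_per_class=20)
        meta["ploidy"] = "aneuploid"
        with pytest.raises(ValidationError):
            train_reference_classifier(expr, meta)

    def test_small_class_reduces_folds_with_warning(self, caplog):
        expr, meta = _marker_block_cohort(n_per_class=30)
        meta.loc[meta["ploidy"] == "diploid", "ploidy"] = "not.defined"
        meta.iloc[:3, meta.columns.get_loc("ploidy")] = "diploid"
        with caplog.at_level("WARNING"):
            model = train_reference_classifier(expr, meta, cv_folds=5, seed=0)
        assert any("reducing folds" in r.message for r in caplog.records)
        assert 0 <= model.cv_auc <= 1

    def test_seed_determinism(self):
        expr, meta = _marker_block_cohort()
        a = train_reference_classifier(expr, meta, seed=5)
        b = train_reference_classifier(expr, meta, seed=5)
        assert a.cv_auc == b.cv_auc and a.panel == b.panel

    def test_gate_monotone_in_separation(self):
        # stronger marker contrast never lowers mean cv AUC
        mean_aucs = []
        for boost in (0, 2, 8):
            aucs = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                base = rng.poisson(3.0, size=(80, 50)) + 1
                base[:40, :10] += boost
                base[40:, 10:20] += boost
                cells = [f"c{i}" for i in range(80)]
                expr = lognormalize(
                    ExpressionMatrix(
                        sp.csr_matrix(base), [f"g{i}" for i in range(50)], cells
                    )
                )
                meta = pd.DataFrame(
                    {
                        "cell_id": cells, "patient": "P1", "cycle": 1,
                        "biopsy_site": "s", "cell_type": "epithelial",
                        "ploidy": ["diploid"] * 40 + ["aneuploid"] * 40,
                        "n_features": 500, "pct_mt": 1.0,
                    }
                )
                aucs.append(
                    train_reference_classifier(
                        expr, meta, n_variable_genes=30, seed=seed
                    ).cv_auc
                )
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] <= mean_aucs[1] + 0.05 <= mean_aucs[2] + 0.1
        assert mean_aucs[2] == pytest.approx(1.0, abs=1e-6)


class TestReclassification:
    def test_rescues_only_undefined_and_flags_them(self):
        expr, meta = _marker_block_cohort()
        hidden = meta.sample(n=12, random_state=0).index
        truth = meta.loc[hidden, "ploidy"].copy()
        meta.loc[hidden, "ploidy"] = "not.defined"
        model = train_reference_classifier(expr, meta, n_variable_genes=40, seed=0)
        out = reclassify_undefined(model, expr, meta)
        assert out.loc[hidden, "ploidy_rescued"].all()
        assert (out.loc[hidden, "ploidy"] == truth).all()
        untouched = out.index.difference(hidden)
        assert (out.loc[untouched, "ploidy"] == meta.loc[untouched, "ploidy"]).all()
        assert not out.loc[untouched, "ploidy_rescued"].any()

    def test_rejected_model_changes_nothing(self):
        expr, meta = _marker_block_cohort(n_per_class=100, flip_labels=True, seed=3)
        meta.loc[meta.index[:10], "ploidy"] = "not.defined"
        model = train_reference_classifier(expr, meta, n_variable_genes=40, seed=3)
        assert not model.accepted
        out = reclassify_undefined(model, expr, meta)
        assert (out["ploidy"] == meta["ploidy"]).all()
        assert not out["ploidy_rescued"].any()

    def test_synthetic_cohort_rescue_accuracy(self, small_cohort):
        _, (expr, meta, _, truth) = small_cohort
        ln = lognormalize(expr)
        model = train_reference_classifier(ln, meta, n_variable_genes=500, seed=2)
        assert model.accepted
        out = reclassify_undefined(model, ln, meta)
        rescued = out[out["ploidy_rescued"]]
        agreement = (
            rescued["ploidy"].to_numpy()
            == truth.ploidy.loc[rescued["cell_id"]].to_numpy()
        ).mean()
        assert agreement >= 0.9
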