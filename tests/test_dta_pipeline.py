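"""Prediction head, training loop, evaluation and case-study ranking."""

import numpy as np
import pytest

from submdta import (DtaConfig, DtaModel, FixtureSpec, evaluate_model, fit,
                     generate_synthetic_dta, percentile_counts,
                     rank_candidates, split_records)
from submdta.dta_pipeline import PredictionHead, predict_affinity
from submdta.metrics import compute_report


def _tiny_config(**kw):
    base = dict(hidden_dim=12, n_layers=2, embed_dim=8, protein_hidden=4,
                head_dims=(16, 8), batch_size=16, epochs=2, lr=2e-2,
                dropout=0.0, seed=0)
    base.update(kw)
    return DtaConfig(**base)


def _tiny_records(noise_sd=0.0, n_mol=20, n_prot=4, seed=3, effects=(1.0, 1.0)):
    spec = FixtureSpec(n_molecules=n_mol, n_proteins=n_prot, seed=seed,
                       noise_sd=noise_sd, effect_sizes=effects,
                       protein_length_range=(8, 16))
    return generate_synthetic_dta(spec)


class TestPredictAffinity:
    def test_zero_head_predicts_zero(self, rng):
        head = PredictionHead(rng, 6, (4,), dropout=0.0)
        for W, b in head.layers:
            W.data[:] = 0
            b.data[:] = 0
        assert predict_affinity(np.ones(3), np.ones(3), head) == 0.0

    def test_final_stage_linearity(self, rng):
        head = PredictionHead(rng, 4, (3,), dropout=0.0)
        x_d, x_p = rng.uniform(0.5, 1, 2), rng.uniform(0.5, 1, 2)
        base = predict_affinity(x_d, x_p, head)
        W_out, b_out = head.layers[-1]
        bias = float(b_out.data[0])
        W_out.data *= 2.0
        doubled = predict_affinity(x_d, x_p, head)
        assert doubled - bias == pytest.approx(2 * (base - bias))

    def test_repeatable(self, rng):
        head = PredictionHead(rng, 4, (3,), dropout=0.5)  # dropout off at inference
        x_d, x_p = rng.normal(size=2), rng.normal(size=2)
        assert predict_affinity(x_d, x_p, head) == predict_affinity(x_d, x_p, head)


class TestFit:
    def test_learns_noiseless_planted_affinity(self):
        records, _ = _tiny_records(noise_sd=0.0, n_mol=30, n_prot=5)
        model, history = fit(records, _tiny_config(epochs=50))
        assert history["train_mse"][-1] < 0.1 * history["train_mse"][0]

    def test_constant_target_learned(self):
        records, _ = _tiny_records(noise_sd=0.0, effects=(0.0, 0.0))
        model, history = fit(records, _tiny_config(epochs=40))
        assert history["train_mse"][-1] < 0.05

    def test_deterministic_histories(self):
        records, _ = _tiny_records(n_mol=10, n_prot=3)
        _, h1 = fit(records, _tiny_config(epochs=2))
        _, h2 = fit(records, _tiny_config(epochs=2))
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], _tiny_config())

    def test_model_round_trip_through_checkpoint(self, tmp_path):
        records, _ = _tiny_records(n_mol=10, n_prot=3)
        model, _ = fit(records, _tiny_config(epochs=1))
        model.save(tmp_path / "model")
        restored = DtaModel.load(tmp_path / "model")
        sample = records[:10]
        assert np.allclose(model.predict(sample), restored.predict(sample))


class TestEvaluate:
    def test_matches_metrics_module_on_exported_predictions(self):
        records, _ = _tiny_records(n_mol=12, n_prot=3)
        model, _ = fit(records, _tiny_config(epochs=1))
        report = evaluate_model(model, records)
        manual = compute_report([r.affinity for r in records],
                                model.predict(records))
        assert report == manual

    def test_pure_function_of_model_and_data(self):
        records, _ = _tiny_records(n_mol=10, n_prot=3)
        model, _ = fit(records, _tiny_config(epochs=1))
        assert evaluate_model(model, records) == evaluate_model(model, records)

    def test_empty_test_set_rejected(self):
        records, _ = _tiny_records(n_mol=10, n_prot=3)
        model, _ = fit(records, _tiny_config(epochs=1))
        with pytest.raises(ValueError):
            evaluate_model(model, [])


class TestSplitRecords:
    def test_partition_is_disjoint_and_complete(self):
        # noise makes every record's label distinct almost surely
        records, _ = _tiny_records(noise_sd=0.3, n_mol=15, n_prot=4)
        train, test = split_records(records, 0.25, seed=1)
        assert len(train) + len(test) == len(records)
        assert len(test) == round(0.25 * len(records))
        seen = {(r.drug_smiles, r.target_sequence, r.affinity) for r in train}
        assert all((r.drug_smiles, r.target_sequence, r.affinity) not in seen
                   for r in test)


@pytest.fixture(scope="module")
def ranking_model():
    records, _ = _tiny_records(n_mol=12, n_prot=3)
    model, _ = fit(records, _tiny_config(epochs=1))
    return model


class TestRankCandidates:
    TARGET = "MKVLHTRWQACDEFHKLMW"

    @pytest.fixture()
    def model(self, ranking_model):
        return ranking_model

    def test_single_drug_gets_rank_one(self, model):
        result = rank_candidates(model, self.TARGET, ["CCO"])
        assert result.ranks == (1,)

    def test_ranks_are_permutation(self, model):
        drugs = ["CCO", "CCN", "c1ccccc1", "CC(C)C", "c1ccncc1O"]
        result = rank_candidates(model, self.TARGET, drugs)
        assert sorted(result.ranks) == list(range(1, 6))

    def test_duplicate_of_top_drug_ties_in_input_order(self, model):
        drugs = ["CCO", "CCN", "c1ccccc1"]
        first = rank_candidates(model, self.TARGET, drugs)
        top = first.records[first.ranks.index(1)][0]
        result = rank_candidates(model, self.TARGET, drugs + [top])
        idx_orig = drugs.index(top)
        assert result.ranks[idx_orig] == 1
        assert result.ranks[-1] == 2

    def test_input_order_invariance_up_to_ties(self, model):
        drugs = ["CCO", "CCN", "c1ccccc1", "CC(C)C"]
        a = rank_candidates(model, self.TARGET, drugs)
        rev = rank_candidates(model, self.TARGET, drugs[::-1])
        assert a.ranks == tuple(reversed(rev.ranks))

    def test_unparseable_drugs_excluded_and_counted(self, model):
        result = rank_candidates(model, self.TARGET,
                                 ["CCO", "not_a_molecule", "CCN"])
        assert result.n_invalid == 1
        assert len(result.ranks) == 2
        assert result.invalid_entries[0][1] == "not_a_molecule"


class TestPercentileCounts:
    # ranks of the nine known binders of the type-1 angiotensin II receptor
    # in a 1781-drug library, counted at two percentile cutoffs
    BINDER_RANKS = [21, 24, 28, 30, 42, 51, 74, 224, 1130]

    def test_top_thirteen_percent(self):
        assert percentile_counts(self.BINDER_RANKS, 1781, 13) == 8

    def test_top_four_percent(self):
        assert percentile_counts(self.BINDER_RANKS, 1781, 4) == 7

    def test_rank_one_of_hundred(self):
        assert percentile_counts([1], 100, 1) == 1

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError):
            percentile_counts([0], 10, 50)
        with pytest.raises(ValueError):
            percentile_counts([11], 10, 50)
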