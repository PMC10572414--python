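"""Search-loop bookkeeping, consolidation, and final cross-validated runs."""

import dataclasses

import numpy as np
import pytest

from octaug import ControllerConfig, ModelConfig, build_model
from octaug.augment import ImageMaskPair, OpInstance, Strategy, SubStrategy
from octaug.search import (RewardTrace, SearchConfig, SegDataset, TraceRecord,
                           consolidate_top_strategies, evaluate_validation_loss,
                           final_train_and_eval, run_search, train_child)


def _tiny_dataset(prefix, n=4, size=8, seed=0):
    rng = np.random.default_rng(seed)
    pairs, patients = [], []
    for i in range(n):
        image = rng.integers(0, 256, (size, size)).astype(np.uint8)
        mask = np.zeros((size, size), np.uint8)
        mask[2:5, 2:5] = 1
        pairs.append(ImageMaskPair(image, mask))
        patients.append(f"{prefix}{i % 2}")
    return SegDataset(pairs, patients)


def _identity_strategy():
    sub = SubStrategy(OpInstance("Invert", None, 0), OpInstance("Invert", None, 0))
    return Strategy([sub] * 5)


def _strategy_of(iteration):
    sub = SubStrategy(OpInstance("Rotate", iteration % 10, 1),
                      OpInstance("Invert", None, 1))
    return Strategy([sub] * 5)


# -------------------------------------------------------------- train_child
def test_identity_strategy_reproduces_unaugmented_trajectory():
    cfg = dataclasses.replace(SearchConfig.desk(child_epochs=3),
                              child=ModelConfig("unet", 2, 4))
    data = _tiny_dataset("A")
    m1 = build_model(cfg.child, seed=9)
    m2 = build_model(cfg.child, seed=9)
    train_child(m1, data, _identity_strategy(), cfg, seed=5)
    train_child(m2, data, None, cfg, seed=5)
    for a, b in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(a.data, b.data)


def test_minibatch_substrategy_draws_are_uniform():
    """Sub-strategy indices drawn during training are uniform over the five
    sub-strategies within 3 binomial SEs across >= 500 batches."""
    cfg = dataclasses.replace(SearchConfig.desk(child_epochs=125, batch_size=2),
                              child=ModelConfig("unet", 2, 2), learning_rate=0.0)
    data = _tiny_dataset("A", n=8)
    log = []
    model = build_model(cfg.child, seed=0)
    train_child(model, data, _strategy_of(0), cfg, seed=1, batch_log=log)
    assert len(log) >= 500
    counts = np.bincount(log, minlength=5)
    p = 1 / 5
    se = np.sqrt(p * (1 - p) / len(log))
    assert (np.abs(counts / len(log) - p) < 3 * se).all()


def test_empty_training_set_is_rejected():
    cfg = SearchConfig.desk(child_epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train_child(build_model(cfg.child, 0), SegDataset([], []), None, cfg, 0)


# --------------------------------------------------------------- run_search
def test_single_iteration_reward_equals_negative_validation_loss():
    cfg = dataclasses.replace(SearchConfig.desk(time_horizon=1, child_epochs=1),
                              child=ModelConfig("unet", 2, 2))
    train = _tiny_dataset("A")
    valid = _tiny_dataset("B", seed=1)
    trace, controller = run_search(train, valid, cfg, ControllerConfig.desk())
    assert len(trace) == 1
    rec = trace.records[0]
    assert rec.reward == pytest.approx(-rec.validation_loss, abs=1e-12)
    # recompute the loss from scratch with the same child seed and strategy
    ss = np.random.SeedSequence(cfg.seed)
    _, _, child_root = ss.spawn(3)
    child_seed = int(child_root.generate_state(1)[0] % 2**31)
    model = build_model(cfg.child, seed=child_seed)
    train_child(model, train, rec.strategy, cfg, seed=child_seed)
    assert evaluate_validation_loss(model, valid) == pytest.approx(
        rec.validation_loss, abs=1e-9)


def test_identical_seeds_give_identical_traces(tmp_path):
    cfg = dataclasses.replace(SearchConfig.desk(time_horizon=2, child_epochs=1),
                              child=ModelConfig("unet", 2, 2))
    train = _tiny_dataset("A")
    valid = _tiny_dataset("B", seed=1)
    t1, _ = run_search(train, valid, cfg, ControllerConfig.desk(),
                       trace_path=tmp_path / "trace.csv")
    t2, _ = run_search(train, valid, cfg, ControllerConfig.desk())
    assert np.array_equal(t1.rewards(), t2.rewards())
    assert (tmp_path / "trace.csv").read_text().count("\n") == 3  # header + 2


def test_patient_overlap_between_train_and_valid_refused():
    cfg = SearchConfig.desk(time_horizon=1, child_epochs=1)
    data = _tiny_dataset("A")
    with pytest.raises(ValueError, match="overlap"):
        run_search(data, data, cfg, ControllerConfig.desk())


def test_search_reads_only_train_and_valid_images():
    """Instrumented datasets record accesses; test-fold pairs are never
    touched by the search."""
    touched = []

    class Spy(list):
        def __getitem__(self, i):
            touched.append(id(self))
            return super().__getitem__(i)

    cfg = dataclasses.replace(SearchConfig.desk(time_horizon=1, child_epochs=1),
                              child=ModelConfig("unet", 2, 2))
    train = _tiny_dataset("A")
    valid = _tiny_dataset("B", seed=1)
    test = _tiny_dataset("C", seed=2)
    train.pairs = Spy(train.pairs)
    test.pairs = Spy(test.pairs)
    run_search(train, valid, cfg, ControllerConfig.desk())
    assert id(train.pairs) in set(touched)
    assert id(test.pairs) not in set(touched)


# ------------------------------------------------------------ consolidation
def test_top5_of_5_record_trace_concatenates_to_25():
    trace = RewardTrace([TraceRecord(t, _strategy_of(t), -0.1 * t, 0.1 * t)
                         for t in range(1, 6)])
    merged = consolidate_top_strategies(trace, k=5)
    assert len(merged) == 25


def test_consolidation_matches_sort_and_slice_oracle():
    rng = np.random.default_rng(7)
    rewards = rng.normal(size=20).round(3)
    trace = RewardTrace([TraceRecord(t + 1, _strategy_of(t), float(r), -float(r))
                         for t, r in enumerate(rewards)])
    merged = consolidate_top_strategies(trace, k=5)
    oracle = sorted(trace.records, key=lambda rec: (-rec.reward, rec.iteration))[:5]
    expected = [sub for rec in oracle for sub in rec.strategy.substrategies]
    assert merged.substrategies == expected


def test_consolidation_tie_breaks_by_earlier_iteration():
    recs = [TraceRecord(1, _strategy_of(1), 0.5, -0.5),
            TraceRecord(2, _strategy_of(2), 0.5, -0.5),
            TraceRecord(3, _strategy_of(3), 0.1, -0.1)]
    merged = consolidate_top_strategies(RewardTrace(recs), k=2)
    assert merged.substrategies[:5] == recs[0].strategy.substrategies


def test_consolidation_needs_k_records():
    with pytest.raises(ValueError, match="need at least"):
        consolidate_top_strategies(RewardTrace([]), k=5)


# ------------------------------------------------------- final train + eval
def test_two_fold_desk_run_emits_valid_records(shifted_sets):
    train, valid = shifted_sets
    cfg = SearchConfig.desk(child_epochs=5, seed=0)
    folds = [{"train": train, "test": valid},
             {"train": valid, "test": train}]
    records = final_train_and_eval(folds, _identity_strategy(), cfg)
    assert len(records) == 2
    for rec in records:
        for name in ("accuracy", "dice", "precision", "recall",
                     "specificity", "jaccard"):
            assert 0.0 <= getattr(rec, name) <= 1.0


def test_identity_policy_equals_no_augmentation_baseline(shifted_sets):
    train, valid = shifted_sets
    cfg = SearchConfig.desk(child_epochs=3, seed=1)
    folds = [{"train": train, "test": valid}]
    a = final_train_and_eval(folds, _identity_strategy(), cfg)[0]
    b = final_train_and_eval(folds, None, cfg)[0]
    assert a.as_dict() == b.as_dict()


def test_consolidated_photometric_policy_beats_baseline_under_shift(
        shifted_sets, tmp_path):
    """The shipped 25-sub-strategy policy (photometric-heavy) yields test
    Dice >= the unaugmented baseline in >= 3 of 5 seeded repeats on the
    photometric-shift task."""
    from pathlib import Path

    from octaug.augment import load_strategy

    policy = load_strategy(Path(__file__).resolve().parents[1] / "policies"
                           / "unetpp_consolidated.json")
    train, valid = shifted_sets
    folds = [{"train": train, "test": valid}]
    wins = 0
    for seed in range(5):
        cfg = SearchConfig.desk(seed=seed)
        aug = final_train_and_eval(folds, policy, cfg)[0].dice
        base = final_train_and_eval(folds, None, cfg)[0].dice
        wins += aug >= base
    assert wins >= 3
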