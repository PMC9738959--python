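"""Scoring, fusion, partitioning, and the five decoding strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p300speller import (
    ClassifierSpec,
    OracleScorer,
    SimulationConfig,
    SymbolMatrix,
    decide_symbol,
    fuse_scores,
    generate_dataset,
    partition_horizontal,
    partition_vertical,
    predict_symbol,
    score_selection,
    score_sequence,
    target_codes,
    train_strategy,
)
from p300speller.strategies import (
    TrainedStrategy,
    score_selection_single,
)


class TableScorer:
    """Scorer driven by a lookup table keyed by (sequence rank, code)."""

    def __init__(self, table):
        self.table = table
        self.rank = 0  # set externally before scoring each sequence

    def score_epoch(self, epoch):
        return self.table[(self.rank, epoch.code)]


def _oracle_selection(seed=0, n=2, m=2, alpha=3):
    cfg = SimulationConfig(n=n, m=m, alpha=alpha, beta=1, n_channels=2, seed=seed)
    return generate_dataset(cfg).selections[0]


def test_score_sequence_oracle_hits_target_codes():
    sel = _oracle_selection()
    seq = sel.sequences[0]
    u = score_sequence(OracleScorer(), seq)
    tcodes = target_codes(sel.true_symbol, 2, 2)
    for code in range(1, 5):
        assert u[code - 1] == (1.0 if code in tcodes else 0.0)


def test_score_sequence_is_order_free():
    sel = _oracle_selection(seed=3)
    seq = sel.sequences[0]
    u1 = score_sequence(OracleScorer(), seq)
    shuffled = type(seq)(epochs=list(reversed(seq.epochs)))
    np.testing.assert_array_equal(u1, score_sequence(OracleScorer(), shuffled))


def test_score_selection_single_averages_sequences():
    """v_j is the plain mean of the per-sequence scores for code j."""
    sel = _oracle_selection(seed=5)

    # per-sequence constant scores 0.2, 0.4, 0.6 average to 0.4
    class PerRank:
        def __init__(self):
            self.count = -1

        def score_epoch(self, epoch):
            self.count += 1
            return [0.2, 0.4, 0.6][self.count // 4]

    v = score_selection_single(PerRank(), sel)
    np.testing.assert_allclose(v, 0.4)
    # k=1 truncation equals the first sequence's scores alone
    v1 = score_selection_single(PerRank(), sel, k=1)
    np.testing.assert_allclose(v1, 0.2)


def test_fuse_scores_examples():
    a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    np.testing.assert_allclose(fuse_scores([a, b]), [0.5, 0.5])
    np.testing.assert_allclose(fuse_scores([a, b], [1.0, 0.0]), [0.5, 0.0])
    np.testing.assert_allclose(fuse_scores([a]), a)
    with pytest.raises(ValueError):
        fuse_scores([a, np.zeros(3)])
    with pytest.raises(ValueError):
        fuse_scores([a, b], [1.0, -0.5])


def test_decide_symbol_argmax_and_ties(matrix):
    r = np.zeros(12)
    r[2] = 0.9   # column 3
    r[7] = 0.8   # row 2
    assert decide_symbol(r, matrix)[:2] == (2, 3)
    # all-equal scores break ties to the lowest code on both axes
    assert decide_symbol(np.full(12, 0.3), matrix)[:2] == (1, 1)
    assert decide_symbol(np.full(12, 0.3), matrix)[2] == "A"


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 100.0))
def test_decide_symbol_scale_invariant(seed, c):
    mat = SymbolMatrix()
    r = np.random.default_rng(seed).uniform(size=12)
    assert decide_symbol(r, mat) == decide_symbol(c * r, mat)


def test_brute_force_oracle_psi_and_fusion():
    """All aggregation paths match naive direct averaging of a random rho table."""
    rng = np.random.default_rng(42)
    n = m = 2
    alpha = 3
    sel = _oracle_selection(seed=9, n=n, m=m, alpha=alpha)
    N = 3  # learners
    # rho[i][(rank, code)] for learner i
    tables = [
        {(q, c): rng.uniform() for q in range(alpha) for c in range(1, n + m + 1)}
        for _ in range(N)
    ]

    def psi(table):  # independent brute-force averaging
        return np.array(
            [np.mean([table[(q, c)] for q in range(alpha)]) for c in range(1, n + m + 1)]
        )

    def run_scorer(table):
        s = TableScorer(table)
        vecs = []
        for q, seq in enumerate(sel.sequences):
            s.rank = q
            vecs.append(score_sequence(s, seq))
        return np.mean(vecs, axis=0)

    # single-classifier Psi
    np.testing.assert_allclose(run_scorer(tables[0]), psi(tables[0]), atol=1e-12)

    # unweighted fusion over N learners
    fused = fuse_scores([run_scorer(t) for t in tables])
    expected = np.mean([psi(t) for t in tables], axis=0)
    np.testing.assert_allclose(fused, expected, atol=1e-12)

    # weighted fusion, division by N as printed
    w = [0.9, 0.5, 0.7]
    fused_w = fuse_scores([run_scorer(t) for t in tables], w)
    expected_w = sum(wi * psi(t) for wi, t in zip(w, tables)) / N
    np.testing.assert_allclose(fused_w, expected_w, atol=1e-12)

    # horizontal-homogeneous scoring: learner q scores only sequence rank q
    vecs = []
    for q, seq in enumerate(sel.sequences):
        s = TableScorer(tables[q])
        s.rank = q
        vecs.append(score_sequence(s, seq))
    homo = fuse_scores(vecs)
    expected_h = np.array(
        [np.mean([tables[q][(q, c)] for q in range(alpha)]) for c in range(1, n + m + 1)]
    )
    np.testing.assert_allclose(homo, expected_h, atol=1e-12)


# --- partitioning -----------------------------------------------------------


def _epoch_ids(ds):
    return {id(e) for e in ds.epochs()}


def test_partition_horizontal_structure(tiny_dataset):
    parts = partition_horizontal(tiny_dataset)
    p = tiny_dataset.paradigm
    assert len(parts) == p.alpha
    for part in parts:
        assert part.n_epochs() == tiny_dataset.beta * (p.n + p.m)
    # partition i holds exactly the i-th sequence of every selection
    assert parts[0].selections[0].sequences[0] is tiny_dataset.selections[0].sequences[0]
    assert parts[2].selections[1].sequences[0] is tiny_dataset.selections[1].sequences[2]


def test_partition_vertical_blocks(tiny_dataset):
    parts = partition_vertical(tiny_dataset, 3)
    assert [p.beta for p in parts] == [2, 2, 2]
    assert parts[0].selections[0] is tiny_dataset.selections[0]
    assert parts[2].selections[-1] is tiny_dataset.selections[-1]
    with pytest.raises(ValueError):
        partition_vertical(tiny_dataset, 7)


def test_partition_vertical_remainder_warns(tiny_dataset):
    with pytest.warns(UserWarning, match="remainder"):
        parts = partition_vertical(tiny_dataset, 4)
    assert [p.beta for p in parts] == [1, 1, 1, 3]
    assert sum(p.beta for p in parts) == tiny_dataset.beta


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    st.integers(1, 3), st.integers(1, 3), st.integers(1, 4), st.integers(1, 5),
    st.integers(0, 99),
)
def test_partition_laws(n, m, alpha, beta, seed):
    """Both schemes: pairwise disjoint, union = D, exact sizes."""
    cfg = SimulationConfig(
        n=n, m=m, alpha=alpha, beta=beta, n_channels=2, seed=seed, noise_sd=0.0
    )
    ds = generate_dataset(cfg)
    all_ids = _epoch_ids(ds)

    hparts = partition_horizontal(ds)
    hids = [_epoch_ids(p) for p in hparts]
    assert set.union(*hids) == all_ids
    assert sum(len(s) for s in hids) == len(all_ids)  # pairwise disjoint
    assert all(p.n_epochs() == beta * (n + m) for p in hparts)

    N = max(1, beta // 2)
    if beta % N == 0:
        vparts = partition_vertical(ds, N)
        vids = [_epoch_ids(p) for p in vparts]
        assert set.union(*vids) == all_ids
        assert sum(len(s) for s in vids) == len(all_ids)
        assert all(p.n_epochs() == (beta // N) * alpha * (n + m) for p in vparts)


# --- trained strategies -----------------------------------------------------


def test_train_strategy_learner_counts(tiny_dataset):
    spec = ClassifierSpec("lda", seed=0)
    assert train_strategy(tiny_dataset, "single", spec).n_learners == 1
    assert (
        train_strategy(tiny_dataset, "homo_horizontal", spec).n_learners
        == tiny_dataset.paradigm.alpha
    )
    assert train_strategy(tiny_dataset, "homo_vertical", spec, N=2).n_learners == 2
    both = [ClassifierSpec("lda", seed=0), ClassifierSpec("logreg", seed=0)]
    assert train_strategy(tiny_dataset, "hetero_unweighted", both).n_learners == 2


def test_train_strategy_spec_validation(tiny_dataset):
    spec = ClassifierSpec("lda")
    with pytest.raises(ValueError, match="distinct"):
        train_strategy(tiny_dataset, "hetero_unweighted", [spec, ClassifierSpec("lda")])
    with pytest.raises(ValueError, match="at least two"):
        train_strategy(tiny_dataset, "hetero_unweighted", [spec])
    with pytest.raises(ValueError, match="requires N"):
        train_strategy(tiny_dataset, "homo_vertical", spec)
    with pytest.raises(ValueError, match="unknown variant"):
        train_strategy(tiny_dataset, "stacking", spec)


def test_homo_vertical_n1_equals_single(tiny_dataset):
    """With one partition the vertical ensemble is exactly the single classifier."""
    spec = ClassifierSpec("lda", seed=0)
    single = train_strategy(tiny_dataset, "single", spec)
    vert = train_strategy(tiny_dataset, "homo_vertical", spec, N=1)
    for sel in tiny_dataset.selections[:3]:
        np.testing.assert_array_equal(
            score_selection(single, sel), score_selection(vert, sel)
        )


def test_homo_horizontal_with_identical_learners_equals_single(tiny_dataset):
    """If every rank's learner is the same model, per-rank scoring collapses to Psi."""
    spec = ClassifierSpec("lda", seed=0)
    single = train_strategy(tiny_dataset, "single", spec)
    cloned = TrainedStrategy(
        variant="homo_horizontal",
        learners=[single.learners[0]] * tiny_dataset.paradigm.alpha,
        paradigm=single.paradigm,
        preprocess=single.preprocess,
    )
    for sel in tiny_dataset.selections[:3]:
        np.testing.assert_allclose(
            score_selection(cloned, sel), score_selection(single, sel), atol=1e-12
        )


def test_equal_weight_hetero_matches_unweighted(tiny_dataset):
    specs = [ClassifierSpec("lda", seed=0), ClassifierSpec("logreg", seed=0)]
    unw = train_strategy(tiny_dataset, "hetero_unweighted", specs)
    wtd = train_strategy(tiny_dataset, "hetero_weighted", specs)
    # force equal weights to isolate the fusion rule
    wtd.weights = [1.0, 1.0]
    mat = SymbolMatrix([["A", "B"], ["C", "D"]])
    for sel in tiny_dataset.selections:
        np.testing.assert_allclose(
            score_selection(unw, sel), score_selection(wtd, sel), atol=1e-12
        )
        assert predict_symbol(unw, sel, mat) == predict_symbol(wtd, sel, mat)


def test_hetero_weighted_computes_cv_weights(tiny_dataset):
    specs = [ClassifierSpec("lda", seed=0), ClassifierSpec("logreg", seed=0)]
    strat = train_strategy(tiny_dataset, "hetero_weighted", specs)
    assert strat.weights is not None and len(strat.weights) == 2
    assert all(0.0 <= w <= 1.0 for w in strat.weights)


def test_truncated_decoding_recovery_curve(lda_strategy, matrix):
    """Symbol accuracy does not degrade as more sequences are decoded."""
    test = generate_dataset(SimulationConfig(beta=6, seed=55))
    alpha = test.paradigm.alpha
    accs = []
    for k in (1, 5, alpha):
        hits = sum(
            lda_strategy.predict_symbol(sel, matrix, k=k)[:2] == sel.true_symbol
            for sel in test.selections
        )
        accs.append(hits / test.beta)
    assert accs[-1] >= accs[0] - 0.02
    assert accs[-1] >= 0.95  # high-SNR end-to-end recovery


def test_oracle_strategy_predicts_true_symbol():
    sel = _oracle_selection(seed=12)
    mat = SymbolMatrix([["A", "B"], ["C", "D"]])
    v = score_selection_single(OracleScorer(), sel)
    assert decide_symbol(v, mat)[:2] == sel.true_symbol
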