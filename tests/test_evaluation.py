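"""Confusion metrics, cross-validation protocol, Kruskal–Wallis."""

import numpy as np
import pytest

from sdcae.dataset import SegmentDataset, NormalizationParams
from sdcae.evaluation import (
    ConfusionCounts,
    CVSummary,
    FoldMetrics,
    UndefinedMetricWarning,
    compute_metrics,
    confusion_from_probs,
    cross_validate,
    kruskal_wallis,
    render_report,
)
from sdcae.nn.functional import ShapeError
from sdcae.training import TrainingConfig

from .oracles import kruskal_oracle_h, metrics_oracle


class TestConfusion:
    def test_basic_tally(self):
        c = confusion_from_probs(np.array([1, 0]), np.array([0.9, 0.1]))
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_tie_predicts_positive(self):
        c = confusion_from_probs(np.array([1, 0]), np.array([0.5, 0.5]))
        assert (c.tp, c.fp) == (1, 1)
        assert (c.tn, c.fn) == (0, 0)

    def test_matches_counting_loop(self, rng):
        y = (rng.random(500) < 0.4).astype(int)
        p = rng.random(500)
        c = confusion_from_probs(y, p, threshold=0.3)
        tp = sum(1 for yi, pi in zip(y, p) if pi >= 0.3 and yi == 1)
        tn = sum(1 for yi, pi in zip(y, p) if pi < 0.3 and yi == 0)
        fp = sum(1 for yi, pi in zip(y, p) if pi >= 0.3 and yi == 0)
        fn = sum(1 for yi, pi in zip(y, p) if pi < 0.3 and yi == 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.positives == tp + fn and c.negatives == tn + fp

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_from_probs(np.ones(3), np.full(2, 0.5))


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert m.accuracy == pytest.approx(90.0)
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.precision == pytest.approx(83.333, abs=1e-3)
        assert m.f1 == pytest.approx(90.909, abs=1e-3)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=7, tn=9, fp=0, fn=0))
        assert all(v == 100.0 for v in m.as_dict().values())

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            expected = metrics_oracle(tp, tn, fp, fn)
            np.testing.assert_allclose(
                [m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1],
                expected, atol=1e-10)

    def test_zero_denominator_yields_nan_with_warning(self):
        with pytest.warns(UndefinedMetricWarning):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m.sensitivity)
        assert not np.isnan(m.specificity)

    def test_class_swap_exchanges_sensitivity_specificity(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        p = rng.random(200)
        m = compute_metrics(confusion_from_probs(y, p))
        # swap classes and mirror probabilities around the 0.5 threshold
        swapped = compute_metrics(confusion_from_probs(1 - y, np.nextafter(1 - p, 1)))
        assert m.sensitivity == pytest.approx(swapped.specificity)
        assert m.specificity == pytest.approx(swapped.sensitivity)

    def test_accuracy_consistency_identity(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 40, size=4))
            c = ConfusionCounts(tp, tn, fp, fn)
            m = compute_metrics(c)
            expected = (m.sensitivity * c.positives + m.specificity * c.negatives) / c.total
            assert m.accuracy == pytest.approx(expected)


def _stub_dataset(n_per_class=40, k=10, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([1] * n_per_class + [0] * n_per_class)
    # one informative pixel so a stub "oracle" can be exact
    X = rng.random((n, 16, 24, 1)) * 0.2
    X[y == 1, 0, 0, 0] = 0.9
    fold_of = np.tile(np.arange(k), n // k)
    norm = NormalizationParams(0.0, 1.0, 0.0, 1.0)
    return SegmentDataset(X=X, y=y, norm=norm, subject_ids=["s"] * n,
                          start_s=np.zeros(n), fold_of=fold_of)


class _OracleStub:
    """Perfect classifier reading the informative pixel directly."""

    decoder = None

    def predict_proba(self, X):
        return (X[:, 0, 0, 0] > 0.5).astype(float)


class TestCrossValidate:
    def _run(self, ds):
        return cross_validate(
            {1: ds}, ["DCNN_MLP"], TrainingConfig(epochs=1, seed=0),
            config_for=lambda v, d: None,
            trainer=lambda model, X, y: None,
        )

    def test_protocol_counts_and_perfect_stub(self, monkeypatch):
        ds = _stub_dataset()
        import sdcae.evaluation as ev
        monkeypatch.setattr(ev, "build_model", lambda cfg, seed: _OracleStub())
        summaries = self._run(ds)
        assert len(summaries) == 1
        s = summaries[0]
        assert len(s.fold_metrics) == 10
        for metric in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert s.mean(metric) == pytest.approx(100.0)
            assert s.std(metric) == 0.0

    def test_summary_within_fold_range(self, monkeypatch):
        ds = _stub_dataset(seed=3)

        class NoisyStub(_OracleStub):
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def predict_proba(self, X):
                p = super().predict_proba(X)
                flip = self.rng.random(len(p)) < 0.2
                return np.where(flip, 1 - p, p)

        import sdcae.evaluation as ev
        monkeypatch.setattr(ev, "build_model", lambda cfg, seed: NoisyStub(seed))
        s = self._run(ds)[0]
        for metric in ("accuracy", "f1"):
            vals = [getattr(m, metric) for m in s.fold_metrics]
            assert min(vals) <= s.mean(metric) <= max(vals)


class TestKruskalWallis:
    def test_two_group_hand_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups_convention(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_hand_ranked_formula(self, rng):
        for _ in range(25):
            groups = [rng.integers(0, 12, size=rng.integers(3, 8)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle_h(groups), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=6), rng.normal(1.0, 1.0, size=5), rng.normal(size=4)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_permutation_oracle_agreement(self, rng):
        """The chi-square p-value approximates the exact permutation null."""
        a = np.array([81.0, 84.0, 86.0, 88.0, 90.0])
        b = np.array([85.0, 89.0, 91.0, 93.0, 95.0])
        h_obs, p_chi2 = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h, _ = kruskal_wallis([perm[:5], perm[5:]])
            if h >= h_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert abs(p_perm - p_chi2) < 0.05  # Monte-Carlo + chi-square slack

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestRenderReport:
    def _summaries(self):
        out = []
        for d in (1, 2, 4):
            for v in ("DCAE_MLP", "DCAE_BiLSTM", "DCNN_MLP", "DCNN_BiLSTM"):
                fm = [FoldMetrics(90 + i, 90, 90, 90, 90) for i in range(3)]
                out.append(CVSummary(variant=v, duration_s=d, fold_metrics=fm))
        return out

    def test_twelve_row_grid(self):
        df = render_report(self._summaries())
        assert len(df) == 12
        assert {"accuracy_mean", "accuracy_std", "f1_mean"} <= set(df.columns)

    def test_nan_renders_as_na_and_csv_round_trip(self, tmp_path):
        import pandas as pd

        s = CVSummary("DCAE_MLP", 1,
                      [FoldMetrics(90.0, float("nan"), 80.0, 80.0, float("nan"))] * 2)
        df = render_report([s])
        path = tmp_path / "report.csv"
        df.to_csv(path, index=False, na_rep="NA")
        assert "NA" in path.read_text()
        back = pd.read_csv(path, na_values="NA")
        assert np.isnan(back["sensitivity_mean"][0])
        assert back["accuracy_mean"][0] == pytest.approx(90.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            render_report([])
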