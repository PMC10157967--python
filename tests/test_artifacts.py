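"""Epoch quality metrics and the automatic rejection procedure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planeeg import RejectionCriteria, autoreject, compute_epoch_metrics

from conftest import make_epochs


def spike_train(n_epochs=21, n_samples=3000, spike_epoch=7, spike_sd=50.0,
                seed=0):
    """Clean unit-variance Gaussian epochs with one spike-contaminated epoch."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, 1, n_samples))
    data[spike_epoch, 0, n_samples // 2] += spike_sd
    return make_epochs(data)


class TestMetrics:
    def test_constant_epoch_degenerate_conventions(self):
        data = np.full((1, 1, 100), 3.0)
        with pytest.warns(UserWarning):
            df = compute_epoch_metrics(make_epochs(data))
        row = df.iloc[0]
        assert row["peak"] == 3.0
        assert row["variance"] == 0.0
        assert row["kurtosis"] == 0.0
        assert row["zvalue"] == 0.0

    def test_gaussian_kurtosis_near_three(self, rng):
        data = rng.standard_normal((1, 1, 3000))
        df = compute_epoch_metrics(make_epochs(data))
        # oracle: direct standardized fourth moment
        x = data[0, 0] - data[0, 0].mean()
        expected = (x**4).mean() / (x**2).mean() ** 2
        assert df["kurtosis"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert df["kurtosis"].iloc[0] == pytest.approx(3.0, abs=0.3)

    def test_square_wave_closed_form_moments(self):
        # two-point distribution at +/-1: variance 1, Pearson kurtosis 1
        data = np.tile([1.0, -1.0], 1500)[None, None, :]
        df = compute_epoch_metrics(make_epochs(data))
        assert df["variance"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert df["kurtosis"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_excess_convention_shifts_by_three(self, rng):
        data = rng.standard_normal((4, 1, 1000))
        pearson = compute_epoch_metrics(make_epochs(data), kurtosis="pearson")
        excess = compute_epoch_metrics(make_epochs(data), kurtosis="excess")
        np.testing.assert_allclose(pearson["kurtosis"] - 3.0,
                                   excess["kurtosis"], atol=1e-12)

    def test_zvalue_uses_pooled_channel_statistics(self, rng):
        data = rng.standard_normal((5, 2, 400))
        df = compute_epoch_metrics(make_epochs(data))
        pooled = np.swapaxes(data, 0, 1).reshape(2, -1)
        mean0, sd0 = pooled[0].mean(), pooled[0].std(ddof=1)
        expected = np.abs(data[2, 0] - mean0).mean() / sd0
        got = df.query("channel == 0 and epoch == 2")["zvalue"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)


class TestAutoreject:
    def test_zero_spread_removes_nothing(self, rng):
        one = rng.standard_normal((1, 1, 500))
        data = np.repeat(one, 8, axis=0)  # identical epochs, zero spread
        report = autoreject(make_epochs(data))
        assert report.removed_epochs.size == 0
        assert report.removed_channels.size == 0

    def test_spike_epoch_detected_exactly(self):
        report = autoreject(spike_train())
        assert report.removed_epochs.tolist() == [7]
        assert report.retained

    def test_spike_detection_against_brute_force_oracle(self):
        """Recompute all four metrics and thresholds by direct enumeration."""
        epochs = spike_train()
        report = autoreject(epochs)
        removed = set()
        metrics = {m: [] for m in ("peak", "variance", "zvalue", "kurtosis")}
        pooled = epochs.data[:, 0, :].ravel()
        for e in range(epochs.n_epochs):
            x = epochs.data[e, 0]
            metrics["peak"].append(np.abs(x).max())
            metrics["variance"].append(x.var(ddof=1))
            metrics["zvalue"].append(
                np.abs(x - pooled.mean()).mean() / pooled.std(ddof=1))
            c = x - x.mean()
            metrics["kurtosis"].append((c**4).mean() / (c**2).mean() ** 2)
        for name, vals in metrics.items():
            vals = np.array(vals)
            mu, sd = vals.mean(), vals.std(ddof=1)
            if name == "peak":
                bad = np.abs(vals - mu) > 5.0 * sd
            else:
                bad = vals - mu > 2.5 * sd
            removed |= set(np.flatnonzero(bad))
        assert set(report.removed_epochs) == removed

    @pytest.mark.parametrize("n_surviving,expect_retained", [(5, False),
                                                             (6, True)])
    def test_retention_needs_more_than_five_epochs(self, n_surviving,
                                                   expect_retained):
        # clean datasets: nothing is removed, so survivors = epoch count
        rng = np.random.default_rng(1)
        data = rng.standard_normal((n_surviving, 1, 3000))
        report = autoreject(make_epochs(data))
        assert report.removed_epochs.size == 0
        assert report.retained is expect_retained

    def test_permutation_equivariance(self, rng):
        epochs = spike_train(seed=5)
        perm = rng.permutation(epochs.n_epochs)
        permuted = make_epochs(epochs.data[perm])
        r1 = autoreject(epochs)
        r2 = autoreject(permuted)
        mapped = sorted(np.flatnonzero(np.isin(perm, r1.removed_epochs)))
        assert sorted(r2.removed_epochs) == mapped

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        epochs = spike_train(seed=3)
        scaled = make_epochs(epochs.data * scale)
        r1 = autoreject(epochs)
        r2 = autoreject(scaled)
        np.testing.assert_array_equal(r1.removed_epochs, r2.removed_epochs)

    def test_growing_spike_never_unremoves(self):
        removed_at = []
        for amp in [30.0, 100.0, 300.0, 1000.0, 10_000.0]:
            report = autoreject(spike_train(spike_sd=amp, seed=2))
            removed_at.append(7 in report.removed_epochs)
        assert removed_at == sorted(removed_at)  # once removed, stays removed
        assert removed_at[-1]

    def test_false_removal_rate_on_clean_data_below_5_percent(self):
        rng = np.random.default_rng(99)
        removed = total = 0
        for _ in range(1000):
            data = rng.standard_normal((20, 1, 500))
            report = autoreject(make_epochs(data))
            removed += report.removed_epochs.size
            total += 20
        assert removed / total < 0.05

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            RejectionCriteria(peak_k=-1.0)
        with pytest.raises(ValueError):
            RejectionCriteria(min_epochs=0)
        with pytest.raises(ValueError):
            RejectionCriteria(kurtosis="other")
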