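"""Gradient correctness, SGD behavior and label transforms."""

import numpy as np
import pytest

import pepgnn as pg
from conftest import random_model, random_peptide


def finite_difference_gradient(model, sample, lam, h=1e-6):
    """Central finite differences of the per-sample loss, every component."""
    def f():
        pred, _ = pg.forward(model, sample.peptide)
        return pg.loss(pred, sample.label, model, lam)

    gphi = np.zeros_like(model.phi)
    gomega = np.zeros_like(model.omega)
    for arr, grad in ((model.phi, gphi), (model.omega, gomega)):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + h
            fp = f()
            arr[ix] = orig - h
            fm = f()
            arr[ix] = orig
            grad[ix] = (fp - fm) / (2 * h)
    return gphi, gomega


def max_symmetric_rel_error(a, b, floor=1e-4):
    """Element-wise |a-b| / (|a|+|b|+floor).

    Central differences at h=1e-6 carry ~1e-10 of round-off noise, which
    would dominate the ratio on components that are themselves ~1e-6; the
    additive floor (tiny against typical gradient magnitudes of 1e-2..1)
    absorbs that without loosening the check anywhere it is informative.
    """
    return float(np.max(np.abs(a - b) / (np.abs(a) + np.abs(b) + floor)))


class TestLoss:
    def test_zero_at_perfect_prediction_without_decay(self, alphabet, rng):
        m = random_model(alphabet, rng)
        assert pg.loss(0.37, 0.37, m, 0.0) == 0.0

    def test_squared_error(self, alphabet, rng):
        m = random_model(alphabet, rng)
        assert pg.loss(1.0, 0.0, m, 0.0) == 1.0

    def test_weight_decay_term_hand_computed(self, small_alphabet):
        # single nonzero weight 2.0 and lambda 0.01 contribute 0.04
        phi = np.zeros(6)
        phi[0] = 2.0
        m = pg.GNNModel(small_alphabet, phi, np.zeros((6, 1)), 0, 1)
        assert pg.loss(0.5, 0.5, m, 0.01) == pytest.approx(0.04, abs=1e-15)

    def test_non_finite_inputs_rejected(self, alphabet, rng):
        m = random_model(alphabet, rng)
        with pytest.raises(pg.InvalidInputError):
            pg.loss(float("nan"), 0.0, m, 0.0)


class TestBackpropGradient:
    def test_matches_finite_differences(self, small_alphabet, rng):
        """Backward accumulation vs central differences over >= 50 random
        configurations, including the N=0 and T=1 edge cases."""
        checked = 0
        configs = [(0, 1), (0, 3), (2, 1), (1, 2)] + [
            (int(rng.integers(0, 4)), int(rng.integers(1, 5))) for _ in range(48)
        ]
        for N, T in configs:
            m = random_model(small_alphabet, rng, N=N, T=T)
            p = random_peptide(small_alphabet, int(rng.integers(1, 8)), rng)
            sample = pg.TrainingSample(p, float(rng.normal()))
            lam = float(rng.choice([0.0, 1e-3]))
            g = pg.backprop_gradient(m, sample, lam)
            fphi, fomega = finite_difference_gradient(m, sample, lam)
            assert max_symmetric_rel_error(g.phi, fphi) < 1e-5
            assert max_symmetric_rel_error(g.omega, fomega) < 1e-5
            checked += 1
        assert checked >= 50

    def test_absent_types_have_zero_gradient(self, alphabet, rng):
        m = random_model(alphabet, rng)
        p = pg.encode_peptide("YFPGQFAFS", alphabet)
        g = pg.backprop_gradient(m, pg.TrainingSample(p, 1.0), lam=0.0)
        present = set(p.type_indices.tolist())
        absent = [i for i in range(alphabet.size) if i not in present]
        assert np.all(g.phi[absent] == 0.0)
        assert np.all(g.omega[absent] == 0.0)

    def test_linear_single_residue_closed_form(self, small_alphabet):
        """Identity activation, T=1, one residue: d loss / d phi = 2 (pred - y)."""
        m = pg.init_model(small_alphabet, 0, 1, seed=5, activation="identity")
        p = pg.Peptide(small_alphabet, np.array([2]))
        label = 0.3
        pred, _ = pg.forward(m, p)  # pred = phi[2]
        g = pg.backprop_gradient(m, pg.TrainingSample(p, label), lam=0.0)
        assert g.phi[2] == pytest.approx(2 * (pred - label), rel=1e-12)


class TestSGDStep:
    def test_zero_step_size_leaves_model_unchanged(self, alphabet, rng):
        m = random_model(alphabet, rng)
        p = random_peptide(alphabet, 9, rng)
        out = pg.sgd_step(m, pg.TrainingSample(p, 0.5), mu=0.0)
        assert np.array_equal(out.phi, m.phi) and np.array_equal(out.omega, m.omega)

    def test_small_step_decreases_sample_loss(self, alphabet, rng):
        for _ in range(10):
            m = random_model(alphabet, rng)
            p = random_peptide(alphabet, 9, rng)
            sample = pg.TrainingSample(p, float(rng.normal()))
            before = pg.loss(pg.forward(m, p)[0], sample.label, m, 0.0)
            stepped = pg.sgd_step(m, sample, mu=1e-3)
            after = pg.loss(pg.forward(stepped, p)[0], sample.label, stepped, 0.0)
            assert after <= before

    def test_only_present_residue_types_updated(self, alphabet, rng):
        """Weight sharing means an update touches exactly the rows of the
        residue types occurring in the sample (lambda = 0)."""
        m = random_model(alphabet, rng)
        p = pg.encode_peptide("YFPGQFAFS", alphabet)
        stepped = pg.sgd_step(m, pg.TrainingSample(p, 2.0), mu=0.01, lam=0.0)
        present = sorted(set(p.type_indices.tolist()))
        assert len(present) == 7  # Y F P G Q A S
        absent = [i for i in range(alphabet.size) if i not in present]
        assert np.array_equal(stepped.phi[absent], m.phi[absent])
        assert np.array_equal(stepped.omega[absent], m.omega[absent])
        changed = [
            i for i in present
            if not np.array_equal(stepped.omega[i], m.omega[i])
            or stepped.phi[i] != m.phi[i]
        ]
        assert changed == present

    def test_weight_decay_shrinks_norm_toward_zero(self, alphabet, rng):
        """With the error term silenced, repeated decay steps contract Omega."""
        m = random_model(alphabet, rng, activation="tanh")
        p = random_peptide(alphabet, 9, rng)
        # a label equal to the current prediction zeroes the error gradient
        norms = []
        for _ in range(20):
            label = pg.forward(m, p)[0]
            m = pg.sgd_step(m, pg.TrainingSample(p, label), mu=0.05, lam=0.1)
            norms.append(np.sqrt(m.phi @ m.phi + (m.omega**2).sum()))
        assert all(b < a for a, b in zip(norms, norms[1:]))


class TestTrain:
    def test_gamma_one_keeps_step_size_constant(self):
        cfg = pg.TrainConfig(mu0=0.02, lr_decay=1.0, epochs=5)
        assert [cfg.step_size(e) for e in range(5)] == [0.02] * 5

    def test_decay_schedule_strictly_decreasing(self):
        cfg = pg.TrainConfig(mu0=0.01, lr_decay=0.99, epochs=5)
        steps = [cfg.step_size(e) for e in range(5)]
        assert all(b < a for a, b in zip(steps, steps[1:]))

    def test_single_sample_error_monotone(self, alphabet, rng):
        p = random_peptide(alphabet, 9, rng)
        data = [pg.TrainingSample(p, 0.4)]
        _, curve = pg.train(
            data, pg.TrainConfig(mu0=1e-3, lr_decay=1.0, epochs=50, weight_decay=0.0),
            init_seed=3,
        )
        assert all(b <= a + 1e-15 for a, b in zip(curve, curve[1:]))

    def test_noise_free_teacher_fit(self, alphabet):
        """Training error on 60 noise-free teacher-labeled nonamers falls
        below 0.01 well within 500 epochs."""
        world = pg.make_teacher(alphabet, seed=11, noise_sd=0.0)
        rng = np.random.default_rng(11)
        samples = [
            s for s in pg.sample_dataset(world, 60, 9, rng)
            if s.property_name == "activity"
        ]
        _, curve = pg.train(
            samples, pg.TrainConfig(epochs=300, shuffle_seed=1), init_seed=1
        )
        assert min(curve) < 0.01

    def test_reproducible_given_seeds(self, alphabet, rng):
        world = pg.make_teacher(alphabet, seed=2)
        samples = [
            s for s in pg.sample_dataset(world, 12, 9, np.random.default_rng(4))
            if s.property_name == "stability"
        ]
        cfg = pg.TrainConfig(epochs=20, shuffle_seed=9)
        m1, c1 = pg.train(samples, cfg, init_seed=7)
        m2, c2 = pg.train(samples, cfg, init_seed=7)
        assert np.array_equal(m1.phi, m2.phi) and np.array_equal(m1.omega, m2.omega)
        assert c1 == c2

    def test_empty_data_rejected(self):
        with pytest.raises(pg.InvalidInputError):
            pg.train([], pg.TrainConfig(epochs=1), init_seed=0)


class TestLabelTransform:
    def test_constant_labels_map_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            y, _ = pg.transform_labels([10.0, 10.0, 10.0], "stability")
        assert np.all(y == 0.0)

    def test_lower_ec50_maps_to_larger_label(self):
        y, _ = pg.transform_labels([0.49, 1.29, 5.0], "activity")
        assert y[0] > y[1] > y[2]

    def test_higher_half_life_maps_to_larger_label(self):
        y, _ = pg.transform_labels([24.0, 1693.0, 135.0], "stability")
        assert y[1] > y[2] > y[0]

    @pytest.mark.parametrize("assay", ["activity", "stability"])
    def test_round_trip_inversion(self, assay, rng):
        raw = 10 ** rng.uniform(-1, 3, size=30)
        y, tf = pg.transform_labels(raw, assay)
        np.testing.assert_allclose(tf.inverse_transform(y), raw, rtol=1e-12)

    def test_labels_standardized(self, rng):
        raw = 10 ** rng.uniform(-1, 3, size=100)
        y, _ = pg.transform_labels(raw, "activity")
        assert np.mean(y) == pytest.approx(0.0, abs=1e-12)
        assert np.std(y) == pytest.approx(1.0, rel=1e-12)

    def test_non_positive_raw_rejected(self):
        with pytest.raises(pg.InvalidInputError):
            pg.transform_labels([1.0, 0.0], "activity")
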