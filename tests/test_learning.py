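"""Training objectives, gradient correctness, and meta-learning contracts."""

import numpy as np
import pytest

from neopain._autodiff import Parameter, SGD, Tensor
from neopain.errors import InsufficientBatchError, LeakageError, ValidationError
from neopain.fusion_net import PainFusionModel
from neopain.learning import (LossWeights, MetaTask, component_losses,
                              concept_bce, contrastive_loss, evidential_loss,
                              maml_adapt, meta_train, ordinal_loss,
                              sparsity_loss, total_loss)


def numeric_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    flat, gf = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


class TestContrastiveLoss:
    def test_n2_batch_matches_brute_force(self, rng):
        """Four anchors, hand-evaluated NT-Xent term by term."""
        z = rng.normal(size=(4, 8))
        pair = np.array([1, 0, 3, 2])
        tau = 0.1
        zn = z / np.linalg.norm(z, axis=1, keepdims=True)
        sim = zn @ zn.T / tau
        expected = 0.0
        for i in range(4):
            negs = [np.exp(sim[i, k]) for k in range(4) if k != i]
            expected += -np.log(np.exp(sim[i, pair[i]]) / np.sum(negs))
        expected /= 4
        got = contrastive_loss(Tensor(z), pair, tau).item()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_raising_positive_similarity_lowers_loss(self, rng):
        z = rng.normal(size=(4, 8))
        pair = np.array([1, 0, 3, 2])
        base = contrastive_loss(Tensor(z), pair).item()
        z2 = z.copy()
        z2[1] = z[1] + 0.5 * (z[0] - z[1])     # move partner closer
        assert contrastive_loss(Tensor(z2), pair).item() < base

    def test_batch_permutation_invariance(self, rng):
        z = rng.normal(size=(6, 8))
        pair = np.array([1, 0, 3, 2, 5, 4])
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        a = contrastive_loss(Tensor(z), pair).item()
        b = contrastive_loss(Tensor(z[perm]), inv[pair][perm]).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_sample_batch_rejected(self, rng):
        with pytest.raises(InsufficientBatchError):
            contrastive_loss(Tensor(rng.normal(size=(2, 8))), np.array([1, 0]))


class TestComponentLosses:
    def test_perfect_concept_predictions_give_zero_bce(self):
        labels = np.array([[1.0, 0.0] * 6] * 3)
        loss = concept_bce(Tensor(labels), labels)
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_one_hot_match_gives_zero_ordinal_loss(self):
        p = Tensor(np.eye(4)[[0, 2, 3]])
        assert ordinal_loss(p, np.array([0, 2, 3])).item() == pytest.approx(0.0)

    def test_distant_errors_cost_more_than_adjacent(self):
        y = np.array([0])
        near = ordinal_loss(Tensor(np.eye(4)[[1]]), y).item()
        far = ordinal_loss(Tensor(np.eye(4)[[3]]), y).item()
        assert far > near

    def test_zero_graph_gives_zero_sparsity(self):
        assert sparsity_loss(Tensor(np.zeros((5, 12, 12)))).item() == 0.0

    def test_batch_without_pain_labels_rejected(self, rng):
        model = PainFusionModel(seed=0)
        with pytest.raises(ValidationError):
            component_losses(model, {"activations": rng.uniform(0, 1, (2, 12)),
                                     "available": np.ones((2, 12), bool),
                                     "pain": np.array([])})


class TestTotalLoss:
    def test_all_ones_with_default_weights_is_4_7(self):
        comps = {k: Tensor(1.0) for k in
                 ("concept", "ordinal", "evidential", "sparsity", "meta",
                  "contrast")}
        assert total_loss(comps).item() == pytest.approx(4.7)

    def test_all_zeros_is_zero(self):
        comps = {k: Tensor(0.0) for k in
                 ("concept", "ordinal", "evidential", "sparsity", "meta",
                  "contrast")}
        assert total_loss(comps).item() == 0.0

    def test_linearity_in_each_component(self):
        w = LossWeights()
        coef = {"concept": w.alpha, "ordinal": w.beta, "evidential": w.gamma,
                "sparsity": w.delta, "meta": w.epsilon, "contrast": w.zeta}
        base = {k: Tensor(1.0) for k in coef}
        for key, c in coef.items():
            doubled = dict(base, **{key: Tensor(2.0)})
            delta = total_loss(doubled).item() - total_loss(base).item()
            assert delta == pytest.approx(c)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(beta=-1.0)


class TestGradientCorrectness:
    """Every custom loss against central finite differences."""

    def test_contrastive_gradient(self, rng):
        z = Parameter(rng.normal(size=(4, 6)))
        pair = np.array([1, 0, 3, 2])
        contrastive_loss(z, pair).backward()
        num = numeric_grad(lambda: contrastive_loss(z, pair).item(), z.data)
        np.testing.assert_allclose(z.grad, num, atol=1e-4)

    def test_ordinal_gradient(self, rng):
        logits = Parameter(rng.normal(size=(3, 4)))
        y = np.array([0, 2, 3])

        def loss():
            return ordinal_loss(logits.softmax(axis=1), y)

        loss().backward()
        num = numeric_grad(lambda: loss().item(), logits.data)
        np.testing.assert_allclose(logits.grad, num, atol=1e-4)

    def test_evidential_gradient_including_kl(self, rng):
        raw = Parameter(rng.uniform(0.5, 3.0, size=(3, 4)))
        y = np.array([1, 0, 3])

        def loss():
            return evidential_loss(raw.relu() + 1.0, y, kl_weight=0.3)

        loss().backward()
        num = numeric_grad(lambda: loss().item(), raw.data)
        np.testing.assert_allclose(raw.grad, num, atol=1e-4)

    def test_sparsity_gradient(self, rng):
        e = Parameter(rng.normal(size=(2, 12, 12)))
        sparsity_loss(e).backward()
        num = numeric_grad(lambda: sparsity_loss(e).item(), e.data)
        np.testing.assert_allclose(e.grad, num, atol=1e-5)

    def test_concept_bce_gradient(self, rng):
        logits = Parameter(rng.normal(size=(3, 12)))
        labels = (rng.random((3, 12)) < 0.5).astype(float)

        def loss():
            return concept_bce(logits.sigmoid(), labels)

        loss().backward()
        num = numeric_grad(lambda: loss().item(), logits.data)
        np.testing.assert_allclose(logits.grad, num, atol=1e-4)


class TestMamlAdapt:
    def _support(self, rng, n=5):
        return {"activations": rng.uniform(0, 1, (n, 12)),
                "available": np.ones((n, 12), bool),
                "pain": rng.integers(0, 4, n)}

    def test_concept_and_graph_parameters_bit_frozen(self, rng):
        model = PainFusionModel(seed=1)
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        adapted = maml_adapt(model, self._support(rng), steps=3)
        after = adapted.parameters()
        changed = set()
        for k in before:
            if not np.array_equal(before[k], after[k].data):
                changed.add(k)
            if k not in model.meta_parameter_names:
                assert np.array_equal(before[k], after[k].data), k
        assert changed <= set(model.meta_parameter_names)
        # base model itself is untouched
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v.data, before[k])

    def test_zero_gradient_leaves_parameters_identical(self, rng):
        model = PainFusionModel(seed=1)
        adapted = maml_adapt(model, self._support(rng), inner_lr=0.0, steps=2)
        for (k, p), (_, q) in zip(model.parameters().items(),
                                  adapted.parameters().items()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_empty_support_rejected(self):
        with pytest.raises(ValidationError):
            maml_adapt(PainFusionModel(seed=1), {"pain": np.array([])})

    def test_one_sgd_step_matches_closed_form_on_quadratic(self):
        """phi - lr * grad on a hand-built quadratic objective."""
        phi = Parameter(np.array([3.0, -2.0]))
        target = np.array([1.0, 1.0])
        opt = SGD([phi], lr=0.1)
        loss = ((phi - Tensor(target)) ** 2).sum()
        loss.backward()
        opt.step()
        expected = np.array([3.0, -2.0]) - 0.1 * 2 * (np.array([3.0, -2.0])
                                                      - target)
        np.testing.assert_allclose(phi.data, expected, atol=1e-12)


class TestMetaTrain:
    def _task(self, rng, iid, n_support=5, n_query=5):
        def block(n, offset):
            return {"activations": rng.uniform(0, 1, (n, 12)),
                    "available": np.ones((n, 12), bool),
                    "pain": rng.integers(0, 4, n),
                    "clip_ids": [f"{iid}_c{offset + i}" for i in range(n)]}
        return MetaTask(infant_id=iid, support=block(n_support, 0),
                        query=block(n_query, 100))

    def test_support_query_overlap_rejected(self, rng):
        block = {"activations": rng.uniform(0, 1, (3, 12)),
                 "available": np.ones((3, 12), bool),
                 "pain": np.array([0, 1, 2]), "clip_ids": ["a", "b", "c"]}
        with pytest.raises(LeakageError):
            MetaTask(infant_id="i1", support=block, query=block)

    def test_evaluation_infant_in_tasks_rejected(self, rng):
        model = PainFusionModel(seed=1)
        tasks = [self._task(rng, "inf1"), self._task(rng, "inf2")]
        with pytest.raises(LeakageError):
            meta_train(model, tasks, eval_infant_ids={"inf2"})

    def test_outer_loop_touches_only_meta_parameters(self, rng):
        model = PainFusionModel(seed=1)
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        meta_train(model, [self._task(rng, "inf1"), self._task(rng, "inf2")])
        for k, v in model.parameters().items():
            if k not in model.meta_parameter_names:
                np.testing.assert_array_equal(v.data, before[k])
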