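"""Loss components against independent direct-summation oracles."""

import numpy as np
import pytest

from lungmet.loss import (
    LossConfig,
    combined_loss,
    focal_loss,
    lovasz_softmax,
    weighted_cross_entropy,
)

EPS = 1e-7
W = (1.0, 5.0, 15.0)


def random_probs(rng, shape=(3, 8, 8)):
    logits = rng.normal(size=shape)
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def one_hot(target, num_classes=3):
    return np.moveaxis(np.eye(num_classes)[target], -1, 0)


# ---------------------------------------------------------------- oracles


def oracle_wce(probs, target, weights=W):
    total = 0.0
    H, Wd = target.shape
    for r in range(H):
        for c in range(Wd):
            y = target[r, c]
            total += -weights[y] * np.log(np.clip(probs[y, r, c], EPS, 1.0))
    return total / (H * Wd)


def oracle_focal(probs, target, gamma=2.0, weights=W):
    total = 0.0
    H, Wd = target.shape
    for r in range(H):
        for c in range(Wd):
            y = target[r, c]
            p = probs[y, r, c]
            total += -weights[y] * (1 - p) ** gamma * np.log(np.clip(p, EPS, 1.0))
    return total / (H * Wd)


def oracle_lovasz(probs, target):
    """Lovasz extension via direct set-function evaluation of the Jaccard loss.

    For each class the extension is sum_k e_(k) * (D(M_k) - D(M_{k-1}))
    where M_k is the set of the k largest errors and
    D(M) = 1 - |FG \\ M| / |FG u M| is the Jaccard loss of predicting
    exactly the pixels FG xor M as foreground.
    """

    def jaccard_loss_of_set(fg, member):
        fg_minus = np.logical_and(fg, ~member).sum()
        union = np.logical_or(fg, member).sum()
        return 1.0 - (fg_minus / union if union else 1.0)

    classes = np.unique(target)
    total = 0.0
    for c in classes:
        fg = (target == c).ravel()
        errors = np.abs(fg.astype(float) - probs[c].ravel())
        order = np.argsort(-errors, kind="stable")
        member = np.zeros_like(fg)
        prev = jaccard_loss_of_set(fg, member)
        acc = 0.0
        for idx in order:
            member[idx] = True
            cur = jaccard_loss_of_set(fg, member)
            acc += errors[idx] * (cur - prev)
            prev = cur
        total += acc
    return total / len(classes)


# ------------------------------------------------------------ cross entropy


def test_wce_zero_for_perfect_prediction(rng):
    target = rng.integers(0, 3, size=(6, 6))
    assert weighted_cross_entropy(one_hot(target), target, W).item() == pytest.approx(
        0.0, abs=1e-5
    )


def test_wce_single_metastasis_pixel():
    probs = np.array([[[0.25]], [[0.25]], [[0.5]]])
    target = np.array([[2]])
    expect = 15.0 * -np.log(0.5)
    assert weighted_cross_entropy(probs, target, W).item() == pytest.approx(expect)


def test_wce_uniform_probs_closed_form():
    # B background + L lung pixels under uniform 1/3 probabilities
    target = np.zeros((4, 4), dtype=int)
    target[:2] = 1  # L = 8, B = 8
    probs = np.full((3, 4, 4), 1.0 / 3.0)
    expect = (8 * 1.0 + 8 * 5.0) * np.log(3.0) / 16
    assert weighted_cross_entropy(probs, target, W).item() == pytest.approx(expect)


# ------------------------------------------------------------------ focal


def test_focal_zero_for_perfect_prediction(rng):
    target = rng.integers(0, 3, size=(5, 5))
    assert focal_loss(one_hot(target), target, 2.0, W).item() == pytest.approx(
        0.0, abs=1e-5
    )


def test_focal_gamma_zero_equals_wce(rng):
    probs = random_probs(rng)
    target = rng.integers(0, 3, size=(8, 8))
    assert focal_loss(probs, target, 0.0, W).item() == pytest.approx(
        weighted_cross_entropy(probs, target, W).item(), rel=1e-12
    )


def test_focal_single_pixel_hand_value():
    probs = np.array([[[0.9]], [[0.05]], [[0.05]]])
    target = np.array([[0]])
    expect = 1.0 * (0.1**2) * -np.log(0.9)
    assert focal_loss(probs, target, 2.0, (1.0, 1.0, 1.0)).item() == pytest.approx(expect)


# ----------------------------------------------------------------- lovasz


def test_lovasz_zero_for_perfect_hard_prediction(rng):
    target = rng.integers(0, 3, size=(6, 6))
    assert lovasz_softmax(one_hot(target), target).item() == pytest.approx(0.0, abs=1e-12)


def test_lovasz_hard_prediction_equals_one_minus_iou(rng):
    for _ in range(10):
        target = rng.integers(0, 3, size=(7, 7))
        pred = rng.integers(0, 3, size=(7, 7))
        probs = one_hot(pred)
        expect = []
        for c in np.unique(target):
            inter = np.logical_and(pred == c, target == c).sum()
            union = np.logical_or(pred == c, target == c).sum()
            expect.append(1.0 - inter / union)
        assert lovasz_softmax(probs, target).item() == pytest.approx(
            float(np.mean(expect)), abs=1e-9
        )


def test_lovasz_toy_matches_set_function_oracle():
    probs = np.array(
        [
            [[0.6, 0.1, 0.3, 0.8]],
            [[0.3, 0.7, 0.4, 0.1]],
            [[0.1, 0.2, 0.3, 0.1]],
        ]
    )
    target = np.array([[0, 1, 2, 0]])
    assert lovasz_softmax(probs, target).item() == pytest.approx(
        oracle_lovasz(probs, target), abs=1e-9
    )


# ------------------------------------------------------- component oracles


def test_all_components_match_oracles_on_random_maps(rng):
    for _ in range(15):
        h, w = rng.integers(2, 9, size=2)
        probs = random_probs(rng, (3, h, w))
        target = rng.integers(0, 3, size=(h, w))
        assert weighted_cross_entropy(probs, target, W).item() == pytest.approx(
            oracle_wce(probs, target), abs=1e-6
        )
        assert focal_loss(probs, target, 2.0, W).item() == pytest.approx(
            oracle_focal(probs, target), abs=1e-6
        )
        assert lovasz_softmax(probs, target).item() == pytest.approx(
            oracle_lovasz(probs, target), abs=1e-6
        )


# ---------------------------------------------------------------- combined


def test_combined_is_linear_combination(rng):
    probs = random_probs(rng)
    target = rng.integers(0, 3, size=(8, 8))
    cfg = LossConfig()
    ce = weighted_cross_entropy(probs, target, cfg.class_weights).item()
    lv = lovasz_softmax(probs, target).item()
    fl = focal_loss(probs, target, cfg.focal_gamma, cfg.class_weights).item()
    assert combined_loss(probs, target, cfg).item() == pytest.approx(
        0.7 * ce + 0.4 * lv + 0.2 * fl, rel=1e-12
    )


def test_combined_reduces_to_wce(rng):
    probs = random_probs(rng)
    target = rng.integers(0, 3, size=(8, 8))
    cfg = LossConfig(alpha=1.0, beta=0.0, gamma_mix=0.0)
    assert combined_loss(probs, target, cfg).item() == pytest.approx(
        weighted_cross_entropy(probs, target, cfg.class_weights).item(), rel=1e-12
    )


def test_combined_zero_for_perfect_and_nonnegative(rng):
    target = rng.integers(0, 3, size=(6, 6))
    assert combined_loss(one_hot(target), target).item() == pytest.approx(0.0, abs=1e-4)
    for _ in range(5):
        probs = random_probs(rng)
        t = rng.integers(0, 3, size=(8, 8))
        assert combined_loss(probs, t).item() >= 0.0


def test_higher_met_weight_increases_loss_of_met_errors(rng):
    target = np.full((4, 4), 2)
    probs = random_probs(rng, (3, 4, 4))  # errs on metastasis pixels
    low = LossConfig(class_weights=(1.0, 5.0, 15.0))
    high = LossConfig(class_weights=(1.0, 5.0, 30.0))
    assert combined_loss(probs, target, high).item() > combined_loss(
        probs, target, low
    ).item()


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(alpha=-0.1)
    with pytest.raises(ValueError):
        LossConfig(class_weights=(1.0, 0.0, 5.0))


def test_shape_mismatch_rejected(rng):
    probs = random_probs(rng, (3, 4, 4))
    with pytest.raises(ValueError):
        weighted_cross_entropy(probs, np.zeros((5, 5), dtype=int), W)
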