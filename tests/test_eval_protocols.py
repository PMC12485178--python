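"""Splits, quadratic weighted kappa oracles, classification metrics,
linear/fine-tune contracts, attention maps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from conftest import tiny_run_config
from msssl.eval_protocols import (
    SplitSpec,
    attention_map,
    classification_metrics,
    finetune,
    linear_eval,
    quadratic_weighted_kappa,
    split_dataset,
)
from msssl.mfee import ViTConfig, ViTEncoder
from msssl.ssl_train import init_state
from msssl.synthetic import SyntheticConfig, generate_dataset, generate_fundus


def kappa_oracle(y_true, y_pred, k=5):
    """Explicit double-sum contingency-table implementation."""
    n = len(y_true)
    observed = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        observed[t, p] += 1
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            num += w * observed[i, j]
            den += w * row[i] * col[j] / n
    return 1.0 if den == 0 else 1.0 - num / den


# -- splitting ----------------------------------------------------------------

def make_manifest(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": [f"img{i:03d}" for i in range(n)],
        "grade": rng.integers(0, 5, n),
        "view": "single",
    })


def test_split_sizes_are_rounded_fractions():
    manifest = make_manifest(100)
    tr, va, te = split_dataset(manifest, SplitSpec(stratified=False, seed=0))
    assert (len(tr), len(va), len(te)) == (70, 15, 15)


def test_split_is_disjoint_exhaustive_partition():
    manifest = make_manifest(53)
    tr, va, te = split_dataset(manifest, SplitSpec(stratified=False, seed=3))
    ids = [set(m["id"]) for m in (tr, va, te)]
    assert ids[0] | ids[1] | ids[2] == set(manifest["id"])
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])


def test_split_determinism_and_seed_sensitivity():
    manifest = make_manifest(40)
    a = split_dataset(manifest, SplitSpec(seed=1, stratified=False))
    b = split_dataset(manifest, SplitSpec(seed=1, stratified=False))
    c = split_dataset(manifest, SplitSpec(seed=2, stratified=False))
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
    assert any(set(x["id"]) != set(y["id"]) for x, y in zip(a, c))


def test_stratified_split_keeps_grade_balance():
    rows = [{"id": f"g{g}_{i}", "grade": g, "view": "single"}
            for g in range(5) for i in range(20)]
    manifest = pd.DataFrame(rows)
    tr, va, te = split_dataset(manifest, SplitSpec(seed=0, stratified=True))
    assert (tr.groupby("grade").size() == 14).all()
    assert (va.groupby("grade").size() == 3).all()
    assert (te.groupby("grade").size() == 3).all()


def test_stratified_split_needs_three_per_grade():
    manifest = pd.DataFrame({"id": ["a", "b", "c"], "grade": [0, 0, 1], "view": "single"})
    with pytest.raises(ValueError, match="stratify"):
        split_dataset(manifest, SplitSpec(stratified=True))


def test_split_spec_validation():
    with pytest.raises(ValueError):
        SplitSpec(fractions=(0.5, 0.5, 0.1))
    with pytest.raises(ValueError):
        split_dataset(pd.DataFrame(columns=["id", "grade", "view"]), SplitSpec())


# -- quadratic weighted kappa ---------------------------------------------------

def test_kappa_identical_vectors_give_one(rng):
    y = rng.integers(0, 5, 30)
    assert quadratic_weighted_kappa(y, y) == 1.0


def test_kappa_matches_double_sum_oracle_on_extreme_disagreement():
    y_true = [0, 0, 4, 4]
    y_pred = [4, 4, 0, 0]
    assert abs(quadratic_weighted_kappa(y_true, y_pred) - kappa_oracle(y_true, y_pred)) < 1e-12


def test_kappa_matches_independent_textbook_implementation(rng):
    for _ in range(50):
        n = int(rng.integers(5, 200))
        yt = rng.integers(0, 5, n)
        yp = rng.integers(0, 5, n)
        if len(np.unique(yt)) < 2 or len(np.unique(yp)) < 2:
            continue
        ours = quadratic_weighted_kappa(yt, yp)
        theirs = cohen_kappa_score(yt, yp, labels=range(5), weights="quadratic")
        assert abs(ours - theirs) < 1e-12
        assert abs(ours - kappa_oracle(yt, yp)) < 1e-12


def test_kappa_symmetry_and_order_invariance(rng):
    yt = rng.integers(0, 5, 60)
    yp = rng.integers(0, 5, 60)
    assert abs(quadratic_weighted_kappa(yt, yp) - quadratic_weighted_kappa(yp, yt)) < 1e-12
    perm = rng.permutation(60)
    assert abs(quadratic_weighted_kappa(yt, yp)
               - quadratic_weighted_kappa(yt[perm], yp[perm])) < 1e-12


def test_kappa_input_validation():
    with pytest.raises(ValueError):
        quadratic_weighted_kappa([], [])
    with pytest.raises(ValueError):
        quadratic_weighted_kappa([0, 1], [0])
    with pytest.raises(ValueError):
        quadratic_weighted_kappa([0, 5], [0, 1])


# -- classification metrics ------------------------------------------------------

def test_perfect_predictions_give_hundreds(rng):
    y = rng.integers(0, 5, 40)
    rep = classification_metrics(y, y)
    assert rep.accuracy == 100.0
    assert rep.f1_weighted == rep.f1_macro == rep.f1_micro == 100.0
    assert rep.kappa == 1.0


def test_micro_f1_equals_accuracy_and_confusion_conserves(rng):
    yt = rng.integers(0, 5, 80)
    yp = rng.integers(0, 5, 80)
    rep = classification_metrics(yt, yp)
    assert abs(rep.f1_micro - rep.accuracy) < 1e-9
    assert rep.confusion.sum() == 80
    # row sums equal per-class truth counts; accuracy = trace/total
    for g in range(5):
        assert rep.confusion[g].sum() == (yt == g).sum()
    assert abs(rep.accuracy - 100.0 * np.trace(rep.confusion) / 80) < 1e-9


def test_metrics_match_counting_oracle(rng):
    yt = rng.integers(0, 5, 60)
    yp = rng.integers(0, 5, 60)
    rep = classification_metrics(yt, yp)
    f1s, support = [], []
    for g in range(5):
        tp = ((yt == g) & (yp == g)).sum()
        fp = ((yt != g) & (yp == g)).sum()
        fn = ((yt == g) & (yp != g)).sum()
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        support.append((yt == g).sum())
    assert abs(rep.f1_macro - 100 * np.mean(f1s)) < 1e-9
    assert abs(rep.f1_weighted - 100 * np.average(f1s, weights=support)) < 1e-9


# -- protocols -------------------------------------------------------------------

@pytest.fixture(scope="module")
def eval_setup():
    cfg = tiny_run_config(data=dict(n_per_grade=6))
    syn = SyntheticConfig(image_size=64, lesion_rate_per_grade=(0, 4, 10, 18, 30), seed=3)
    images, manifest = generate_dataset(syn, 6)
    splits = split_dataset(manifest, SplitSpec(seed=0))
    state = init_state(cfg)
    return cfg, images, splits, state


def test_linear_eval_freezes_encoder(eval_setup):
    cfg, images, splits, state = eval_setup
    digest = state.student.param_digest()
    rep = linear_eval(state, images, splits, cfg, seed=0)
    assert state.student.param_digest() == digest
    assert rep.confusion.sum() == len(splits[2])


def test_finetune_zero_epochs_is_noop_and_deterministic(eval_setup):
    cfg, images, splits, state = eval_setup
    a = finetune(state, images, splits, cfg, seed=0, epochs=0)
    b = finetune(state, images, splits, cfg, seed=0, epochs=0)
    assert a.to_dict() == b.to_dict()


def test_finetune_improves_over_its_initialization(eval_setup):
    cfg, images, splits, state = eval_setup
    init_rep = finetune(state, images, splits, cfg, seed=0, epochs=0)
    tuned = finetune(state, images, splits, cfg, seed=0, epochs=3)
    # best-val selection can only pick the init snapshot or something better
    assert tuned.kappa >= init_rep.kappa - 0.5


# -- attention maps ---------------------------------------------------------------

def test_attention_map_grid_and_head_average():
    vit = ViTEncoder(ViTConfig(input_size=64, patch_size=16, embed_dim=32,
                               depth=2, num_heads=4), np.random.default_rng(0))
    img = generate_fundus(SyntheticConfig(image_size=64), 2, 5)
    res = attention_map(vit, img, resolution=256)
    assert res.grid.shape == (16, 16)
    assert res.grid.min() == 0.0 and res.grid.max() == 1.0
    # head average oracle
    import msssl.nn as nn_mod
    from msssl.preprocess import extract_green_channel, normalize_for_model
    from msssl.synthetic import FundusImage
    from PIL import Image

    pixels = np.asarray(Image.fromarray(img.pixels).resize((256, 256), Image.BILINEAR))
    raster = normalize_for_model(extract_green_channel(FundusImage(pixels, img.id)))
    with nn_mod.no_grad():
        emb = vit(raster[None], store_attention=True)
    rows = emb.attentions[-1][0][:, 0, 1:]
    manual = rows.mean(axis=0).reshape(16, 16)
    manual = (manual - manual.min()) / (manual.max() - manual.min())
    np.testing.assert_allclose(res.grid, manual, atol=1e-6)


def test_attention_map_patch_divisibility_check():
    vit = ViTEncoder(ViTConfig(input_size=64, patch_size=16, embed_dim=32,
                               depth=1, num_heads=2), np.random.default_rng(0))
    img = generate_fundus(SyntheticConfig(image_size=64), 0, 1)
    with pytest.raises(ValueError):
        attention_map(vit, img, resolution=100)
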