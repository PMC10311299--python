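"""Splits, schedule, training loop, metrics, baselines."""

import numpy as np
import pytest
from scipy import stats

from tsapred import preprocess as pp
from tsapred.model import ModelConfig, SpatialModel
from tsapred.preprocess import TargetTrack
from tsapred.train import (Adam, CellDataset, TrainConfig, WindowSampler,
                           autosome_number, average_baseline,
                           cross_cell_type_protocol, evaluate, grl_lambda,
                           lr_schedule, make_baseline, make_splits, n_folds,
                           predict_track, train)
from tsapred.autodiff import Tensor


def tiny_dataset(n_per_chrom=30, n_chroms=4, seed=0, seq_dim=3, epi_dim=2,
                 target_fn=None):
    sizes = {f"chr{i+1}": n_per_chrom * 25_000 for i in range(n_chroms)}
    bins = pp.make_bins(sizes, 25_000)
    rng = np.random.default_rng(seed)
    seq = rng.normal(size=(bins.n_bins, seq_dim))
    epi = rng.normal(size=(bins.n_bins, epi_dim))
    if target_fn is None:
        target_fn = lambda s, e: np.tanh(0.8 * s[:, 0] - 0.5 * e[:, 0])
    vals = target_fn(seq, epi)
    t = TargetTrack(values=vals, mask=np.ones(bins.n_bins, bool))
    return CellDataset(bins=bins, seq=seq, epi=epi, target=t, cell_type="CT")


def tiny_model_cfg(seq_dim=3, epi_dim=2, **kw):
    base = dict(seq_dim=seq_dim, epi_dim=epi_dim, encoder_hidden=8,
                encoder_out=4, n_heads=2, n_layers=1, ffn_dim=16,
                dropout=0.0, window=2)
    base.update(kw)
    return ModelConfig(**base)


# ------------------------------------------------------------------ splits
def test_make_splits_example():
    bins = pp.make_bins({f"chr{i}": 50_000 for i in range(1, 7)}, 25_000)
    s = make_splits(bins, fold=1)  # second odd autosome = chr3
    assert set(s.val_chroms) == {"chr3"}
    assert set(s.train_chroms) == {"chr1", "chr5"}
    assert set(s.test_chroms) == {"chr2", "chr4", "chr6"}


def test_splits_partition_every_fold():
    bins = pp.make_bins({f"chr{i}": 50_000 for i in range(1, 9)}, 25_000)
    autos = set(bins.chrom_order)
    assert n_folds(bins) == 4
    for fold in range(n_folds(bins)):
        s = make_splits(bins, fold)
        parts = [set(s.train_chroms), set(s.val_chroms), set(s.test_chroms)]
        assert set().union(*parts) == autos
        for i in range(3):
            for j in range(i + 1, 3):
                assert not parts[i] & parts[j]
        assert set(s.test_chroms) == {"chr2", "chr4", "chr6", "chr8"}


def test_splits_excludes_non_autosomes():
    bins = pp.make_bins({"chr1": 50_000, "chr2": 50_000, "chrX": 50_000}, 25_000)
    with pytest.warns(UserWarning, match="non-autosomal"):
        s = make_splits(bins, 0)
    assert "chrX" not in s.all_chroms()
    assert autosome_number("chrX") is None
    assert autosome_number("chr12") == 12
    assert autosome_number("7") == 7


def test_splits_fold_out_of_range():
    bins = pp.make_bins({"chr1": 50_000, "chr2": 50_000}, 25_000)
    with pytest.raises(ValueError):
        make_splits(bins, 5)


# ---------------------------------------------------------------- schedule
def test_lr_schedule_peak_at_warmup():
    d, w = 64, 100
    lrs = [lr_schedule(s, d, w) for s in range(1, 500)]
    assert int(np.argmax(lrs)) + 1 == w


def test_lr_schedule_step1_value():
    assert lr_schedule(1, 64, 100, scale=2.0) == pytest.approx(
        2.0 * 64 ** -0.5 * 100 ** -1.5)


def test_lr_schedule_monotone_branches():
    d, w = 32, 50
    lrs = np.array([lr_schedule(s, d, w) for s in range(1, 301)])
    assert (np.diff(lrs[:w]) > 0).all()
    assert (np.diff(lrs[w:]) < 0).all()
    with pytest.raises(ValueError):
        lr_schedule(0, d, w)


def test_grl_lambda_schedule():
    assert grl_lambda(0.0) == 0.0
    assert grl_lambda(1.0) == pytest.approx(2 / (1 + np.exp(-10)) - 1)
    ps = np.linspace(0, 1, 20)
    vals = [grl_lambda(p) for p in ps]
    assert (np.diff(vals) > 0).all()


# ---------------------------------------------------------------- sampler
def test_window_sampler_edges_and_center():
    ds = tiny_dataset(n_per_chrom=10, n_chroms=2)
    s = WindowSampler(ds, window=3, chroms=["chr1"])
    assert len(s) == 10
    seq, epi, km, y, ym = s.batch([0])  # center = first bin
    assert km[0, :3].sum() == 0        # left pad masked
    assert np.all(seq[0, :3] == 0)
    assert km[0, 3]
    np.testing.assert_array_equal(seq[0, 3], ds.seq[0])
    assert y[0, 3] == ds.target.values[0]


def test_window_sampler_invalid_bins_masked():
    ds = tiny_dataset(n_per_chrom=10, n_chroms=2)
    ds.bins.valid[4] = False
    s = WindowSampler(ds, window=2, chroms=["chr1"])
    # bin 4 no longer a center
    centers = [i for _, i in s.centers]
    assert 4 not in centers
    # and masked as a key inside neighbours' windows
    j = centers.index(3)
    _, _, km, _, _ = s.batch([j])
    assert not km[0, 3]  # position of bin 4 within the window of bin 3


# ---------------------------------------------------------------- training
def test_training_reduces_loss_and_is_deterministic():
    ds = tiny_dataset()
    split = make_splits(ds.bins, 0)
    cfg = tiny_model_cfg()
    tcfg = TrainConfig(batch_size=16, max_epochs=6, patience=10,
                       warmup_steps=20, seed=0)
    m1 = SpatialModel(cfg, seed=0)
    h1 = train(m1, {"CT": ds}, split, tcfg)
    m0 = SpatialModel(cfg, seed=0).eval()
    p_untrained = predict_track(m0, ds, split.train_chroms)
    p_trained = predict_track(m1, ds, split.train_chroms)
    y, msk = ds.target.values, ds.target.mask
    sl = np.concatenate([np.arange(ds.bins.chrom_slice(c).start,
                                   ds.bins.chrom_slice(c).stop)
                         for c in split.train_chroms])
    mse = lambda p: np.nanmean((p[sl][msk[sl]] - y[sl][msk[sl]]) ** 2)
    assert mse(p_trained) < mse(p_untrained)

    m2 = SpatialModel(cfg, seed=0)
    h2 = train(m2, {"CT": ds}, split, tcfg)
    assert h1.train_loss == h2.train_loss
    assert h1.val_loss == h2.val_loss


def test_checkpoint_is_argmin_validation():
    ds = tiny_dataset()
    split = make_splits(ds.bins, 0)
    m = SpatialModel(tiny_model_cfg(), seed=0)
    h = train(m, {"CT": ds}, split,
              TrainConfig(batch_size=16, max_epochs=8, patience=10,
                          warmup_steps=20, seed=0))
    assert h.val_loss[h.best_epoch] == min(h.val_loss)


def test_masked_bins_do_not_affect_loss():
    ds1 = tiny_dataset(seed=3)
    ds2 = tiny_dataset(seed=3)
    # poison half of chr1's targets but mask them out
    sl = ds2.bins.chrom_slice("chr1")
    poison = np.arange(sl.start, sl.start + 15)
    ds2.target.values[poison] = 1e6
    ds2.target.mask[poison] = False
    ds1.target.mask[poison] = False
    split = make_splits(ds1.bins, 0)
    cfgs = [TrainConfig(batch_size=16, max_epochs=3, patience=10,
                        warmup_steps=20, seed=0) for _ in range(2)]
    h1 = train(SpatialModel(tiny_model_cfg(), seed=0), {"CT": ds1}, split, cfgs[0])
    h2 = train(SpatialModel(tiny_model_cfg(), seed=0), {"CT": ds2}, split, cfgs[1])
    assert h1.train_loss == h2.train_loss
    assert h1.val_loss == h2.val_loss


def test_empty_validation_raises():
    ds = tiny_dataset()
    split = make_splits(ds.bins, 0)
    ds.target.mask[ds.bins.chrom_slice(split.val_chroms[0])] = False
    with pytest.raises(ValueError, match="validation"):
        train(SpatialModel(tiny_model_cfg(), seed=0), {"CT": ds}, split,
              TrainConfig(batch_size=16, max_epochs=2, warmup_steps=10, seed=0))


# ----------------------------------------------------------------- metrics
def test_evaluate_identity_and_anticorrelation():
    ds = tiny_dataset()
    rep = evaluate(ds.target.values.copy(), ds.target, ds.bins)
    assert rep.median_mse == 0.0
    assert rep.median_pcc == pytest.approx(1.0)
    rep2 = evaluate(-ds.target.values, ds.target, ds.bins)
    assert rep2.median_pcc == pytest.approx(-1.0)


def test_evaluate_closed_form_oracle():
    p = np.array([0.1, 0.4, -0.2, 0.9, 0.3])
    t = np.array([0.2, 0.1, -0.4, 0.8, 0.0])
    bins = pp.make_bins({"chr1": 5 * 25_000}, 25_000)
    track = TargetTrack(values=t, mask=np.ones(5, bool))
    rep = evaluate(p, track, bins, ["chr1"])
    mse = np.mean((p - t) ** 2)
    pcc = (np.mean(p * t) - p.mean() * t.mean()) / (p.std() * t.std())
    assert abs(rep.per_chrom["chr1"]["mse"] - mse) < 1e-12
    assert abs(rep.per_chrom["chr1"]["pcc"] - pcc) < 1e-10


def test_evaluate_too_few_bins_gives_nan_pcc():
    bins = pp.make_bins({"chr1": 5 * 25_000}, 25_000)
    mask = np.zeros(5, bool)
    mask[0] = True
    track = TargetTrack(values=np.ones(5), mask=mask)
    rep = evaluate(np.ones(5), track, bins, ["chr1"])
    assert np.isnan(rep.per_chrom["chr1"]["pcc"])


def test_average_baseline():
    mk = lambda v, m: TargetTrack(values=np.asarray(v, float),
                                  mask=np.asarray(m, bool))
    t1 = mk([0.2, 0.4], [1, 1])
    t2 = mk([0.4, 0.6], [1, 1])
    avg = average_baseline([t1, t2])
    assert np.allclose(avg.values, [0.3, 0.5])
    single = average_baseline([t1])
    assert np.array_equal(single.values, t1.values)
    # masked-mean rule: bin valid in 2 of 3
    t3 = mk([9.0, 0.5], [0, 1])
    avg3 = average_baseline([t1, t2, t3])
    assert avg3.values[0] == pytest.approx(0.3)
    assert avg3.values[1] == pytest.approx(0.5)
    # bin invalid everywhere stays masked
    t4 = mk([1.0, 1.0], [0, 1])
    t5 = mk([2.0, 1.0], [0, 1])
    avg45 = average_baseline([t4, t5])
    assert not avg45.mask[0] and avg45.mask[1]


# --------------------------------------------------------------- baselines
def test_dnn_zero_hidden_is_linear_regression():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 5))
    w = np.array([0.5, -1.0, 0.2, 0.0, 0.8])
    y = X @ w + 0.3
    dnn = make_baseline("dnn", 5, window=0, hidden=())
    dnn.fit(X, y, epochs=400, lr=3e-2, seed=0)
    assert np.mean((dnn.predict(X) - y) ** 2) <= 1e-3


def test_receptive_fields():
    cnn = make_baseline("cnn", 4, window=10)
    dil = make_baseline("dilated_cnn", 4, window=10)
    L = 21
    assert cnn.receptive_field() == 1 + 4 * 8
    assert cnn.receptive_field() <= 2 * L - 1
    # dilated variant has a strictly larger receptive field per layer depth
    cnn6 = make_baseline("cnn", 4, window=10, kernel=3, dilations=(1,) * 6)
    assert dil.receptive_field() > cnn6.receptive_field()


def test_gtb_baseline_fits():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 4))
    y = np.tanh(X[:, 0])
    gtb = make_baseline("gtb", 4, window=0, n_estimators=50)
    gtb.fit(X, y)
    assert np.corrcoef(gtb.predict(X), y)[0, 1] > 0.9


def test_unknown_baseline_kind():
    with pytest.raises(ValueError):
        make_baseline("mystery", 4, window=0)


def test_adam_weight_decay_shrinks_params():
    p = Tensor(np.ones(3), requires_grad=True)
    opt = Adam([p], lr=0.1, weight_decay=0.5)
    p.grad = np.zeros(3)
    opt.step()
    assert (p.data < 1.0).all()


# ------------------------------------------------------------- cross cells
def test_cross_protocol_canary_leakage():
    # garbage in the held-out cell type must not influence training
    cfg = tiny_model_cfg()
    tcfg = TrainConfig(batch_size=16, max_epochs=2, patience=5,
                       warmup_steps=10, seed=0, domain_adaptation=True)
    histories = []
    for canary in (1e6, -1e6):
        datasets = {f"CT{i}": tiny_dataset(seed=i) for i in range(3)}
        datasets["CT2"].target.values[:] = canary
        _, rep, _, hist = cross_cell_type_protocol(
            datasets, "CT2", cfg, tcfg, model_seed=0)
        histories.append(hist)
    assert histories[0].train_loss == histories[1].train_loss
    assert histories[0].val_loss == histories[1].val_loss


def test_cross_protocol_structure():
    cfg = tiny_model_cfg()
    tcfg = TrainConfig(batch_size=16, max_epochs=2, patience=5,
                       warmup_steps=10, seed=0, domain_adaptation=True)
    datasets = {f"CT{i}": tiny_dataset(seed=i) for i in range(3)}
    model, rep, avg_rep, _ = cross_cell_type_protocol(
        datasets, "CT1", cfg, tcfg, model_seed=0)
    assert model.config.n_domains == 2  # one logit per training cell type
    assert rep.protocol == "cross"
    with pytest.raises(ValueError, match="held-out"):
        cross_cell_type_protocol(datasets, "CT9", cfg, tcfg)
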