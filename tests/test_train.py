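"""Episodic trainer: episode construction, hygiene, determinism, learning."""

import numpy as np
import pytest

from protoerp import nn
from protoerp.data_io import SubjectCollection, ValidationError
from protoerp.encoder import EncoderConfig
from protoerp.protonet import AttentionProtoNet, classification_loss
from protoerp.simulate import SimConfig, make_cohort
from protoerp.train import (EpisodeSpec, TrainConfig, _episode_tensors, fit,
                            make_episodes, train_step)

from conftest import TINY_ENC


def small_config(**kw):
    base = dict(epochs=2, query_size=8, lr=1e-3, seed=9,
                early_stopping=False, support_cap=30)
    base.update(kw)
    return TrainConfig(**base)


class TestMakeEpisodes:
    def test_rotation_contract(self, tiny_cohort):
        rng = np.random.default_rng(0)
        eps = make_episodes(tiny_cohort, 0, small_config(), rng)
        assert len(eps) == len(tiny_cohort)
        assert sorted(e.query_subject for e in eps) == tiny_cohort.subject_ids

    def test_query_subject_not_in_support(self, tiny_cohort):
        rng = np.random.default_rng(0)
        for ep in make_episodes(tiny_cohort, 0, small_config(), rng):
            assert ep.query_subject not in ep.support_subjects
            assert len(ep.support_subjects) == len(tiny_cohort) - 1

    def test_fixed_seed_reproducible(self, tiny_cohort):
        a = make_episodes(tiny_cohort, 0, small_config(),
                          np.random.default_rng(5))
        b = make_episodes(tiny_cohort, 0, small_config(),
                          np.random.default_rng(5))
        for x, y in zip(a, b):
            assert x.query_subject == y.query_subject
            np.testing.assert_array_equal(x.query_trial_indices,
                                          y.query_trial_indices)

    def test_query_batch_stratified(self, tiny_cohort):
        rng = np.random.default_rng(1)
        for ep in make_episodes(tiny_cohort, 0, small_config(), rng):
            labels = tiny_cohort[ep.query_subject].labels[ep.query_trial_indices]
            assert labels.sum() >= 1

    def test_episode_spec_invariants(self):
        with pytest.raises(ValidationError, match="own support"):
            EpisodeSpec("A", ["A", "B"], np.array([0, 1]))
        with pytest.raises(ValidationError, match="unique"):
            EpisodeSpec("A", ["B"], np.array([0, 0]))


class TestTrainStep:
    def test_class_loss_matches_recomputation(self, tiny_cohort, tiny_model):
        """lambda=0: the returned class loss equals independently recomputed
        cross-entropy from the same forward pass."""
        cfg = small_config(lambda_metric=0.0)
        rng = np.random.default_rng(2)
        episode = make_episodes(tiny_cohort, 0, cfg, rng)[0]
        state_rng = np.random.default_rng(3)
        cms, qf, q_labels = _episode_tensors(tiny_model, episode, tiny_cohort,
                                             cfg, state_rng, training=True)
        dists, _, _ = tiny_model.episode_forward(cms, qf)
        cl, _, tot = tiny_model.losses(dists, q_labels, 0.0)
        d = dists.data
        shift = d.min(axis=1, keepdims=True)
        e = np.exp(-(d - shift))
        probs = e / e.sum(axis=1, keepdims=True)
        expect = classification_loss(probs, q_labels)
        assert cl.item() == pytest.approx(expect, rel=1e-6)
        assert tot.item() == pytest.approx(expect, rel=1e-6)

    def test_query_subject_never_reaches_prototypes(self, tiny_cohort,
                                                    tiny_model):
        """Zeroing the query subject's data leaves support class means
        untouched (zero-calibration hygiene inside an episode)."""
        cfg = small_config()
        episode = make_episodes(tiny_cohort, 0, cfg, np.random.default_rng(2))[0]
        rng_state = np.random.default_rng(4)
        cms_a, _, _ = _episode_tensors(tiny_model, episode, tiny_cohort, cfg,
                                       rng_state, training=False)
        zeroed = {}
        for sid in tiny_cohort.subject_ids:
            es = tiny_cohort[sid]
            if sid == episode.query_subject:
                es = es.replace_data(np.zeros_like(es.data))
            zeroed[sid] = es
        cms_b, _, _ = _episode_tensors(tiny_model, episode,
                                       SubjectCollection(zeroed), cfg,
                                       np.random.default_rng(4), training=False)
        np.testing.assert_allclose(cms_a.data, cms_b.data, atol=1e-6)

    def test_support_subject_missing_class_rejected(self, tiny_model,
                                                    tiny_cohort):
        cfg = small_config()
        episode = make_episodes(tiny_cohort, 0, cfg, np.random.default_rng(2))[0]
        broken = {}
        for sid in tiny_cohort.subject_ids:
            es = tiny_cohort[sid]
            if sid == episode.support_subjects[0]:
                from protoerp.data_io import EpochSet
                es = EpochSet(data=es.data, labels=np.zeros_like(es.labels),
                              subject_id=sid, sfreq=es.sfreq,
                              channel_names=es.channel_names)
            broken[sid] = es
        with pytest.raises(ValidationError, match="lacks"):
            _episode_tensors(tiny_model, episode, SubjectCollection(broken),
                             cfg, np.random.default_rng(0), training=True)


class TestFit:
    def test_zero_epochs_returns_initial_model(self, tiny_cohort,
                                               tiny_encoder_config):
        cfg = small_config(epochs=0)
        res = fit(tiny_cohort, cfg, tiny_encoder_config)
        ref = fit(tiny_cohort, cfg, tiny_encoder_config)
        assert res.log == []
        for (_, a), (_, b) in zip(sorted(res.model.named_parameters()),
                                  sorted(ref.model.named_parameters())):
            np.testing.assert_array_equal(a.data, b.data)

    def test_log_bookkeeping_and_csv(self, tiny_cohort, tiny_encoder_config,
                                     tmp_path):
        cfg = small_config(epochs=3)
        res = fit(tiny_cohort, cfg, tiny_encoder_config)
        assert len(res.log) == 3 * len(tiny_cohort)
        res.write_log(tmp_path / "log.csv")
        import csv

        with open(tmp_path / "log.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(res.log)
        assert set(rows[0]) == {"epoch", "episode", "query_subject",
                                "class_loss", "metric_loss", "total", "lr"}

    def test_seeded_runs_bit_identical(self, tiny_cohort, tiny_encoder_config):
        cfg = small_config(epochs=2)
        a = fit(tiny_cohort, cfg, tiny_encoder_config)
        b = fit(tiny_cohort, cfg, tiny_encoder_config)
        assert [r["total"] for r in a.log] == [r["total"] for r in b.log]

    def test_cosine_schedule_reaches_floor(self, tiny_cohort,
                                           tiny_encoder_config):
        cfg = small_config(epochs=4, lr=1e-2)
        res = fit(tiny_cohort, cfg, tiny_encoder_config)
        lrs = sorted({r["lr"] for r in res.log}, reverse=True)
        assert lrs[0] == pytest.approx(1e-2)
        assert lrs[-1] == pytest.approx(1e-4, rel=1e-6)

    def test_loss_decreases_on_learnable_cohort(self):
        """Median episode loss in the last epoch is below the first epoch,
        for every seed tried, on a detectable synthetic cohort."""
        for seed in (0, 1, 2):
            cfg = SimConfig(n_subjects=4, trials_per_subject=120, n_channels=8,
                            sfreq=125.0, window_s=0.6, target_ratio=0.2,
                            erp_latency_mean_s=0.3, erp_width_s=0.06,
                            erp_latency_subject_sd_s=0.02,
                            erp_latency_trial_sd_s=0.01,
                            ar_coeff=0.3, erp_amplitude_mean=8.0,
                            erp_amplitude_subject_sd=0.5, noise_sd=4.0,
                            seed=seed)
            coll = make_cohort(cfg)
            enc = EncoderConfig(temporal_kernels_s=[0.12, 0.06], pool1=2,
                                pool2=4, filters_per_branch=4, dropout=0.1)
            res = fit(coll, TrainConfig(epochs=6, lr=3e-3, seed=seed,
                                        early_stopping=False, support_cap=48),
                      enc)
            per_epoch = {}
            for row in res.log:
                per_epoch.setdefault(row["epoch"], []).append(row["total"])
            first = np.median(per_epoch[0])
            last = np.median(per_epoch[max(per_epoch)])
            assert last < first, f"seed {seed}: {first} -> {last}"

    def test_nonfinite_loss_aborts_with_diagnostic(self, tiny_cohort,
                                                   tiny_model):
        cfg = small_config()
        episode = make_episodes(tiny_cohort, 0, cfg, np.random.default_rng(0))[0]
        # poison a weight so the forward pass blows up
        tiny_model.encoder.head.bias.data[:] = np.inf
        opt = nn.Adam(tiny_model.parameters(), lr=cfg.lr)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_step(tiny_model, episode, tiny_cohort, cfg, opt,
                       np.random.default_rng(0))


def test_early_stopping_on_validation_plateau(tiny_cohort,
                                              tiny_encoder_config):
    """With patience 1 and an unlearnable rate the rotating-validation BA
    plateaus and fit stops well before the scheduled epoch count."""
    cfg = TrainConfig(epochs=30, query_size=6, lr=1e-8, seed=2,
                      early_stopping=True, patience=1, support_cap=16)
    res = fit(tiny_cohort, cfg, tiny_encoder_config)
    assert res.stopped_epoch is not None
    assert res.stopped_epoch < 29
    epochs_run = max(r["epoch"] for r in res.log) + 1
    assert epochs_run == res.stopped_epoch + 1
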