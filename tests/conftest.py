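"""Shared fixtures: the toy signal and a session-scoped synthetic study.

The expensive end-to-end study (generate 1,500 beats, train the full
model, a label-permuted null and a features-only ablation, evaluate on
the held-out beats) runs once per session and is shared by every test
that asserts on it.
"""

from __future__ import annotations

import numpy as np
import pytest

TOY = np.array([6.0, 4.0, 2.0, 0.0, 2.0, 12.0])

#: the printed left-PMAT matrix of the toy signal, ascending window size
TOY_LPMAT = np.array([
    [6, 4, 2, 0, 2, 12],
    [5, 5, 3, 1, 1, 7],
    [4, 4, 4, 2, 4 / 3, 14 / 3],
    [3, 3, 3, 3, 2, 4],
], dtype=float)


@pytest.fixture(scope="session")
def toy_signal():
    return TOY.copy()


@pytest.fixture(scope="session")
def e2e_study():
    """Synthetic 1,500-beat study with trained models and held-out metrics."""
    from pmat.classifier import HeartbeatClassifier, ModelConfig
    from pmat.datasets import beats_to_arrays, map_aami
    from pmat.evaluation import evaluate
    from pmat.preprocessing import extract_beats, remove_baseline
    from pmat.synthetic import RhythmSpec, synth_record

    spec = RhythmSpec(n_beats=1500, seed=7)
    record, _ = synth_record(spec)
    filtered = remove_baseline(record)
    labels = [map_aami(s) for s in filtered.beat_symbols]
    beats, exclusions = extract_beats(filtered, labels,
                                      database="synth", record_id="s0")
    images, features, y = beats_to_arrays(beats)
    n_train = 900
    train = (images[:n_train], features[:n_train], y[:n_train])
    test = (images[n_train:], features[n_train:], y[n_train:])

    def fit_and_eval(config, train_labels):
        model = HeartbeatClassifier(config)
        im = train[0] if config.use_image_branch else None
        ft = train[1] if config.use_handcrafted else None
        model.fit(im, ft, train_labels)
        t_im = test[0] if config.use_image_branch else None
        t_ft = test[1] if config.use_handcrafted else None
        probs = model.predict_proba(t_im, t_ft)
        preds = model.predict(t_im, t_ft)
        return model, evaluate(test[2], preds, probs)

    full_cfg = ModelConfig(epochs=5, batch_size=64, seed=3)
    full_model, full_results = fit_and_eval(full_cfg, train[2])

    perm = np.random.default_rng(11).permutation(n_train)
    _, permuted_results = fit_and_eval(full_cfg, train[2][perm])

    featonly_cfg = ModelConfig(use_image_branch=False, epochs=30, seed=3)
    featonly_model, featonly_results = fit_and_eval(featonly_cfg, train[2])

    return {
        "spec": spec,
        "beats": beats,
        "exclusions": exclusions,
        "train": train,
        "test": test,
        "full_model": full_model,
        "full": full_results,
        "permuted": permuted_results,
        "featonly_model": featonly_model,
        "featonly": featonly_results,
    }
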