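"""1-NN DTW classification and experiment protocols.

The classifier assigns each test series the label of its DTW-nearest
training series (ties broken by lowest training index), with a Sakoe-Chiba
window of 5 by default.  Protocols: subject-independent 50-50 splits and
k-fold cross-validation, repeated over seeded runs and averaged; an
(r1, r2) grid sweep; and a small-training-set curve comparing raw vs
augmented accuracy as the per-class training budget grows.

Augmentation, class statistics and representatives are always recomputed
on the training split of each run only, so no test information leaks into
the generated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .augment import AugmentationConfig, augment
from .dtw import dtw
from .timeseries import Dataset, split_by_subject

__all__ = [
    "ExperimentResult",
    "nn_dtw_classify",
    "accuracy",
    "run_experiment",
    "sweep_r1_r2",
    "small_sample_curve",
]

#: default classification band (frames)
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class ExperimentResult:
    accuracies: tuple[float, ...]
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def nn_dtw_classify(
    train: Dataset, test: Dataset, window: int | None = DEFAULT_WINDOW
) -> list[str]:
    """Predict each test label as the label of the DTW-nearest training series."""
    if len(train) == 0:
        raise ValueError("empty training set")
    import warnings as _warnings

    preds = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # band widening on unequal lengths
        for t in test:
            dists = np.array(
                [dtw(tr.values, t.values, window).distance for tr in train]
            )
            preds.append(train[int(np.argmin(dists))].label)
    return preds


def accuracy(predicted: list[str], test: Dataset) -> float:
    truth = [s.label for s in test]
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def _augmented_train(
    train: Dataset, augmenter: str, config: AugmentationConfig | None, seed: int
) -> Dataset:
    if augmenter == "none":
        return train
    if augmenter != "arspawner":
        raise ValueError(f"unknown augmenter {augmenter!r}")
    cfg = config or AugmentationConfig()
    cfg = AugmentationConfig(
        r1=cfg.r1,
        r2=cfg.r2,
        seed=seed,
        window=cfg.window,
        candidates_per_pair=cfg.candidates_per_pair,
        mode=cfg.mode,
        symmetric_d1=cfg.symmetric_d1,
        dba_max_iter=cfg.dba_max_iter,
        dba_tol=cfg.dba_tol,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        augmented, _ = augment(train, cfg)
    return augmented


def _run_once_subject_split(
    data: Dataset,
    augmenter: str,
    config: AugmentationConfig | None,
    window: int | None,
    rng: np.random.Generator,
    run_seed: int,
) -> float:
    subjects = list(data.subjects)
    rng.shuffle(subjects)
    train_subj = subjects[: len(subjects) // 2]
    train, test = split_by_subject(data, train_subj)
    assert not set(train.subjects) & set(test.subjects)
    train = _augmented_train(train, augmenter, config, run_seed)
    return accuracy(nn_dtw_classify(train, test, window), test)


def _run_once_kfold(
    data: Dataset,
    augmenter: str,
    config: AugmentationConfig | None,
    window: int | None,
    k: int,
    run_seed: int,
) -> float:
    idx = np.arange(len(data))
    accs = []
    for fold, (tr_idx, te_idx) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=run_seed).split(idx)
    ):
        train = Dataset([data[i] for i in tr_idx], name="fold-train")
        test = Dataset([data[i] for i in te_idx], name="fold-test")
        train = _augmented_train(train, augmenter, config, run_seed * 1000 + fold)
        accs.append(accuracy(nn_dtw_classify(train, test, window), test))
    return float(np.mean(accs))


def run_experiment(
    data: Dataset,
    protocol: str = "subject-split",
    augmenter: str = "none",
    config: AugmentationConfig | None = None,
    n_runs: int = 10,
    window: int | None = DEFAULT_WINDOW,
    k: int = 10,
    seed: int = 0,
) -> ExperimentResult:
    """Repeat a protocol over seeded runs and average the accuracies.

    ``protocol`` is ``"subject-split"`` (random subject-disjoint 50-50
    split per run) or ``"k-fold"``.  ``augmenter`` is ``"none"`` or
    ``"arspawner"``; when enabled, the augmenter is fit on and applied to
    the training side of each run only.
    """
    if protocol == "subject-split" and len(data.subjects) < 2:
        raise ValueError("subject-split requires at least two subjects")
    accs = []
    for run in range(n_runs):
        run_seed = seed + run
        if protocol == "subject-split":
            rng = np.random.default_rng(run_seed)
            accs.append(
                _run_once_subject_split(data, augmenter, config, window, rng, run_seed)
            )
        elif protocol == "k-fold":
            accs.append(
                _run_once_kfold(data, augmenter, config, window, k, run_seed)
            )
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return ExperimentResult(
        accuracies=tuple(accs),
        config={
            "protocol": protocol,
            "augmenter": augmenter,
            "r1": config.r1 if config else None,
            "r2": config.r2 if config else None,
            "n_runs": n_runs,
            "window": window,
            "seed": seed,
        },
    )


def sweep_r1_r2(
    data: Dataset,
    r1_values=None,
    r2_values=None,
    protocol: str = "subject-split",
    n_runs: int = 3,
    window: int | None = DEFAULT_WINDOW,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy over a full factorial (r1, r2) grid.

    Defaults to the 10 x 10 grid over [0.1, 1.0] in steps of 0.1.  Returns
    a long-form frame with columns r1, r2, mean_accuracy.
    """
    if r1_values is None:
        r1_values = np.round(np.arange(0.1, 1.01, 0.1), 2)
    if r2_values is None:
        r2_values = np.round(np.arange(0.1, 1.01, 0.1), 2)
    rows = []
    for r1 in r1_values:
        for r2 in r2_values:
            cfg = AugmentationConfig(r1=float(r1), r2=float(r2))
            res = run_experiment(
                data, protocol, "arspawner", cfg, n_runs, window, seed=seed
            )
            rows.append({"r1": float(r1), "r2": float(r2),
                         "mean_accuracy": res.mean_accuracy})
    return pd.DataFrame(rows)


def small_sample_curve(
    data: Dataset,
    sizes=range(3, 16),
    n_draws: int = 10,
    config: AugmentationConfig | None = None,
    window: int | None = DEFAULT_WINDOW,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw vs augmented accuracy as the per-class training budget grows.

    Per draw: a random subject-disjoint 50-50 split, the training side
    subsampled to ``size`` series per class, classified against the test
    side with and without augmentation.  Returns one row per size with the
    means over draws.
    """
    rows = []
    for size in sizes:
        raw_accs, aug_accs = [], []
        for draw in range(n_draws):
            run_seed = seed + 1009 * size + draw
            rng = np.random.default_rng(run_seed)
            subjects = list(data.subjects)
            rng.shuffle(subjects)
            train, test = split_by_subject(data, subjects[: len(subjects) // 2])
            picked = []
            for label, members in sorted(train.by_class().items()):
                if len(members) < size:
                    raise ValueError(
                        f"class {label!r} has only {len(members)} training series "
                        f"for requested size {size}"
                    )
                sel = rng.choice(len(members), size=size, replace=False)
                picked.extend(members[i] for i in sorted(sel))
            small = Dataset(picked, name="small-train")
            aug = _augmented_train(small, "arspawner", config, run_seed)
            assert all(
                s.series_id in {t.series_id for t in small} or s.series_id.startswith("aug:")
                for s in aug
            )
            raw_accs.append(accuracy(nn_dtw_classify(small, test, window), test))
            aug_accs.append(accuracy(nn_dtw_classify(aug, test, window), test))
        rows.append(
            {
                "size": int(size),
                "mean_accuracy_raw": float(np.mean(raw_accs)),
                "mean_accuracy_augmented": float(np.mean(aug_accs)),
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(rows)
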