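"""Windowed sample assembly and split/fold planning.

The classifier's sample unit is a univariate window: each channel of each
recording is denoised through the wavelet stage and cut into non-overlapping
windows (optionally per reconstructed frequency band), every window
inheriting the recording's binary label.  Splitting follows the outer 70/30
train/test, inner 70/30 train/validation protocol; folds come from stratified
k-fold.  Splits are at window level by default (mirroring the evaluated
protocol, which leaks subjects across partitions); ``group_by_subject=True``
gives leakage-free plans instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)

from . import wavelet as wv
from .signal_io import Recording, to_binary_label

__all__ = [
    "WindowSample",
    "SplitPlan",
    "FoldPlan",
    "make_windows",
    "make_split",
    "make_folds",
    "stack_windows",
    "write_manifest",
]


@dataclass
class WindowSample:
    values: np.ndarray  # (window_length,) float64
    label: int
    subject_id: int | None
    channel: str
    band: str  # "wideband" or a band display name (Delta..Gamma)
    window_index: int


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    stratified: bool = True

    def partitions(self) -> dict[str, np.ndarray]:
        return {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}


@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # fold id per sample
    seed: int
    stratified: bool = True

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]


def make_windows(
    recordings: list[Recording],
    wavelet_config: wv.WaveletConfig | None = None,
    window_length: int = 128,
    mode: str = "wideband",
    label_policy: str = "by_condition",
    rating_threshold: int = 7,
    denoise: bool = True,
) -> list[WindowSample]:
    """Cut denoised channel signals into labelled non-overlapping windows.

    In ``wideband`` mode each channel yields floor(len / window_length)
    windows of the denoised signal; in ``per_band`` mode each of the five
    reconstructed band signals is windowed separately (5x as many windows).
    """
    if mode not in ("wideband", "per_band"):
        raise ValueError(f"unknown mode {mode!r}")
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    wavelet_config = wavelet_config or wv.WaveletConfig()

    samples: list[WindowSample] = []
    for rec in recordings:
        if window_length > rec.n_samples:
            raise ValueError(
                f"window_length {window_length} exceeds recording length {rec.n_samples}"
            )
        label = to_binary_label(rec, policy=label_policy, threshold=rating_threshold)
        for ch_idx, ch_name in enumerate(rec.channel_names):
            sig = rec.data[ch_idx]
            decomp = wv.decompose(sig, wavelet_config, fs=rec.fs)
            if denoise:
                decomp = wv.fdr_denoise(decomp)
            if mode == "wideband":
                series = {"wideband": wv.reconstruct(decomp)}
            else:
                series = decomp.band_signals
            for band, s in series.items():
                n_win = s.size // window_length
                for w in range(n_win):
                    samples.append(
                        WindowSample(
                            values=s[w * window_length : (w + 1) * window_length].copy(),
                            label=label,
                            subject_id=rec.subject_id,
                            channel=ch_name,
                            band=band,
                            window_index=w,
                        )
                    )
    return samples


def stack_windows(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (X, y) with X shaped (n, window_length, 1)."""
    X = np.stack([s.values for s in samples])[..., None]
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


def _labels_and_groups(samples) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.label for s in samples])
    groups = np.array([-1 if s.subject_id is None else s.subject_id for s in samples])
    return y, groups


def make_split(
    samples: list[WindowSample],
    seed: int = 0,
    stratified: bool = True,
    test_fraction: float = 0.3,
    val_fraction: float = 0.3,
    group_by_subject: bool = False,
) -> SplitPlan:
    """Outer test split then inner validation split of the remaining pool."""
    n = len(samples)
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    y, groups = _labels_and_groups(samples)
    if stratified and len(np.unique(y)) < 2:
        raise ValueError("stratified split needs both classes present")
    idx = np.arange(n)
    if group_by_subject:
        outer = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        pool, test = next(outer.split(idx, y, groups))
        inner = GroupShuffleSplit(n_splits=1, test_size=val_fraction, random_state=seed + 1)
        tr, va = next(inner.split(pool, y[pool], groups[pool]))
        train, val = pool[tr], pool[va]
    else:
        pool, test = train_test_split(
            idx,
            test_size=test_fraction,
            random_state=seed,
            stratify=y if stratified else None,
        )
        train, val = train_test_split(
            pool,
            test_size=val_fraction,
            random_state=seed + 1,
            stratify=y[pool] if stratified else None,
        )
    return SplitPlan(
        train_idx=np.sort(train),
        val_idx=np.sort(val),
        test_idx=np.sort(test),
        seed=seed,
        stratified=stratified,
    )


def make_folds(
    samples: list[WindowSample], k: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    n = len(samples)
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    y, _ = _labels_and_groups(samples)
    if stratified:
        counts = np.bincount(y)
        if np.any(counts[counts > 0] < k):
            raise ValueError("each class needs at least k members for stratified folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test) in enumerate(splitter.split(np.zeros(n), y)):
        assignment[test] = fold
    return FoldPlan(k=k, assignment=assignment, seed=seed, stratified=stratified)


def write_manifest(
    path,
    samples: list[WindowSample],
    split: SplitPlan | None = None,
    folds: FoldPlan | None = None,
) -> None:
    """Columnar text manifest: one row per sample with its assignments."""
    part = np.full(len(samples), "-", dtype=object)
    if split is not None:
        for name, idx in split.partitions().items():
            part[idx] = name
    with open(path, "w") as fh:
        fh.write("sample\tsubject\tchannel\tband\twindow\tlabel\tpartition\tfold\n")
        for i, s in enumerate(samples):
            fold = folds.assignment[i] if folds is not None else "-"
            subj = "-" if s.subject_id is None else s.subject_id
            fh.write(
                f"{i}\t{subj}\t{s.channel}\t{s.band}\t{s.window_index}\t{s.label}"
                f"\t{part[i]}\t{fold}\n"
            )
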