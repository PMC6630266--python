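"""Leave-one-subject-out evaluation and the method-comparison harness.

Folds are subject-wise: each fold holds out every recording of one subject,
preventing identity leakage. Within each fold, everything data-dependent is
recomputed from the training subjects only: the static segmentation
thresholds (from a 20% calibration split of each training subject's
recordings, with ground-truth burst annotations standing in for manual
segmentation, and the peak energy of the remaining training data), and the
frequency-direction PCA. The held-out subject's recordings are segmented
and projected with those frozen statistics.

Metrics follow the fall-detection convention: falls are the positive class,
the three daily activities collapse into the negative class, and

    Ac = (TP + TN) / (TP + FP + TN + FN) * 100
    Se = TP / (TP + FN) * 100
    Sp = TN / (FP + TN) * 100

computed over held-out segments pooled per fold; the full 4 x 4 gesture
confusion table is retained alongside.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import models as mdl
from .features import (
    PcaModel,
    WindowingConfig,
    build_feature_tensor,
    compute_spectrogram,
    fit_pca,
)
from .preprocessing import FilterSpec, apply_filter, design_bandpass
from .segmentation import (
    calibrate_dataset,
    combine_channels,
    detect_segments,
    segmentation_params,
    short_term_energy,
)
from .types import EmgRecording, gesture_index

__all__ = [
    "CvSplit",
    "ConfusionSummary",
    "MetricsReport",
    "loso_split",
    "confusion",
    "metrics",
    "FoldData",
    "prepare_fold",
    "run_experiment",
]

FALL_IDX = gesture_index("falling")


@dataclass(frozen=True)
class CvSplit:
    """Subject-wise folds: (training subject ids, held-out subject id)."""

    folds: tuple[tuple[tuple[int, ...], int], ...]

    def __len__(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary fall-vs-daily counts plus the full 4-class table."""

    tp: int
    fp: int
    tn: int
    fn: int
    table: np.ndarray  # (4, 4): rows true gesture, cols predicted

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / sensitivity / specificity in percent (None when undefined)."""

    ac: float | None
    se: float | None
    sp: float | None
    diagnostics: tuple[str, ...] = ()


def loso_split(recordings: list[EmgRecording]) -> CvSplit:
    """One fold per subject, ordered by subject id."""
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    folds = tuple(
        (tuple(s for s in subjects if s != held_out), held_out) for held_out in subjects
    )
    return CvSplit(folds=folds)


def confusion(predictions, labels) -> ConfusionSummary:
    """4-class confusion table plus its binary fall-vs-daily collapse.

    ``predictions`` and ``labels`` are gesture labels (strings) or integer
    codes of equal length.
    """
    preds = [p if isinstance(p, (int, np.integer)) else gesture_index(p) for p in predictions]
    true = [t if isinstance(t, (int, np.integer)) else gesture_index(t) for t in labels]
    if len(preds) != len(true):
        raise ValueError(f"length mismatch: {len(preds)} predictions vs {len(true)} labels")
    table = np.zeros((4, 4), dtype=int)
    for t, p in zip(true, preds):
        table[t, p] += 1
    tp = int(table[FALL_IDX, FALL_IDX])
    fn = int(table[FALL_IDX].sum() - tp)
    fp = int(table[:, FALL_IDX].sum() - tp)
    tn = int(table.sum() - tp - fn - fp)
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, table=table)


def metrics(cs: ConfusionSummary) -> MetricsReport:
    """Accuracy, sensitivity and specificity in percent.

    A metric whose denominator is zero is reported as None with a
    diagnostic rather than silently as 0.
    """
    diags: list[str] = []
    total = cs.total
    ac = 100.0 * (cs.tp + cs.tn) / total if total else None
    if total == 0:
        diags.append("no evaluated samples: accuracy undefined")
    if cs.tp + cs.fn > 0:
        se = 100.0 * cs.tp / (cs.tp + cs.fn)
    else:
        se, diags = None, diags + ["no positive (fall) samples: sensitivity undefined"]
    if cs.fp + cs.tn > 0:
        sp = 100.0 * cs.tn / (cs.fp + cs.tn)
    else:
        sp, diags = None, diags + ["no negative (daily-activity) samples: specificity undefined"]
    return MetricsReport(ac=ac, se=se, sp=sp, diagnostics=tuple(diags))


# ---------------------------------------------------------------------------
# fold preparation
# ---------------------------------------------------------------------------


@dataclass
class FoldData:
    """Everything one fold needs, with training statistics frozen.

    ``train``/``test`` are lists of per-segment feature bundles, each the
    dict from :func:`emgfall.features.build_feature_tensor` plus ``label``
    (gesture code) and ``rec_id``.
    """

    test_subject: int
    train_subjects: tuple[int, ...]
    train: list[dict]
    test: list[dict]
    pca: PcaModel
    sts: float
    ste: float
    train_fingerprint: str
    n_missed_train: int = 0
    n_missed_test: int = 0


def _segment_recordings(recs, calib, params, n, lookahead_mode):
    out = {}
    for rec in recs:
        energy = short_term_energy(combine_channels(rec), n)
        out[rec.rec_id] = detect_segments(energy, calib, params, lookahead_mode=lookahead_mode)
    return out


def prepare_fold(
    filtered: list[EmgRecording],
    train_subjects: tuple[int, ...],
    test_subject: int,
    *,
    n_energy: int = 100,
    pca_k: int = 8,
    calibration_fraction: float = 0.2,
    lookahead_mode: str = "mean",
    windowing: WindowingConfig | None = None,
) -> FoldData:
    """Calibrate, segment and featurise one LOSO fold.

    All recordings must already be band-pass filtered. Thresholds and PCA
    come from the training subjects only.
    """
    fs = filtered[0].fs_hz
    windowing = windowing or WindowingConfig(fs_hz=fs)
    params = segmentation_params(fs, n_energy)
    train_recs = [r for r in filtered if r.subject_id in train_subjects]
    test_recs = [r for r in filtered if r.subject_id == test_subject]
    if not train_recs or not test_recs:
        raise ValueError("fold has empty train or test side")

    # threshold calibration: 20% of each training subject's recordings, with
    # annotated bursts as the manual intervals; peak energy from the rest
    calib, _series = calibrate_dataset(train_recs, n_energy, calibration_fraction=calibration_fraction)
    seg_by_rec = _segment_recordings(train_recs + test_recs, calib, params, n_energy, lookahead_mode)

    # --- PCA on training frames only
    train_frames = []
    for rec in train_recs:
        for seg in seg_by_rec[rec.rec_id]:
            sl = rec.samples[seg.start_sample : seg.end_sample]
            if sl.shape[0] < windowing.window_samples:
                continue
            for ch in range(rec.n_channels):
                spec = compute_spectrogram(sl[:, ch], fs, windowing)
                train_frames.append(spec.magnitudes)
    if not train_frames:
        raise ValueError("no usable training segments in fold")
    pca = fit_pca(np.vstack(train_frames), k=pca_k)

    def bundles(recs):
        out, missed = [], 0
        for rec in recs:
            segs = seg_by_rec[rec.rec_id]
            items = build_feature_tensor(rec, segs, pca, windowing)
            if not items:
                missed += 1
            for item in items:
                item["label"] = gesture_index(rec.gesture)
                item["rec_id"] = rec.rec_id
                out.append(item)
        return out, missed

    train_items, missed_tr = bundles(train_recs)
    test_items, missed_te = bundles(test_recs)
    fingerprint = hashlib.sha256(
        ("|".join(sorted(r.rec_id for r in train_recs))).encode()
    ).hexdigest()
    return FoldData(
        test_subject=test_subject,
        train_subjects=tuple(train_subjects),
        train=train_items,
        test=test_items,
        pca=pca,
        sts=calib.sts,
        ste=calib.ste,
        train_fingerprint=fingerprint,
        n_missed_train=missed_tr,
        n_missed_test=missed_te,
    )


# ---------------------------------------------------------------------------
# feature views
# ---------------------------------------------------------------------------

_TILE_FRAMES = 8
_TILE_STEP = 4
_RMS_ROW = 3  # index of RMS in the time-domain feature table


def _tiles_from_map(fmap: np.ndarray) -> np.ndarray:
    """Fixed-height tiles from an (n_frames, w, c) map; edge-pad short maps."""
    n = fmap.shape[0]
    if n < _TILE_FRAMES:
        pad = np.repeat(fmap[-1:], _TILE_FRAMES - n, axis=0)
        return np.stack([np.concatenate([fmap, pad], axis=0)])
    starts = list(range(0, n - _TILE_FRAMES + 1, _TILE_STEP))
    if starts[-1] != n - _TILE_FRAMES:
        starts.append(n - _TILE_FRAMES)
    return np.stack([fmap[s : s + _TILE_FRAMES] for s in starts])


def _cnn_map(item: dict, mode: str) -> np.ndarray:
    if mode == "spm":
        return item["spm"]
    # rms "image": windows x channels, single depth plane, min-max per segment
    rms = item["td"][:, _RMS_ROW, :]  # (n_frames, n_ch)
    lo, hi = rms.min(), rms.max()
    if hi > lo:
        rms = (rms - lo) / (hi - lo)
    return rms[:, :, None]


def _cnn_dataset(items: list[dict], mode: str):
    xs, ys, seg_ids = [], [], []
    for i, item in enumerate(items):
        tiles = _tiles_from_map(_cnn_map(item, mode))
        xs.append(tiles)
        ys.extend([item["label"]] * len(tiles))
        seg_ids.extend([i] * len(tiles))
    return np.concatenate(xs), np.asarray(ys), np.asarray(seg_ids)


def _flat_features(item: dict, mode: str) -> np.ndarray:
    """Per-segment summary vector for the classical baselines."""
    if mode == "spm":
        spm = item["spm"]  # (n_frames, k, c)
        return np.concatenate([spm.mean(axis=0).ravel(), spm.std(axis=0).ravel()])
    td = item["td"]  # (n_frames, 6, c)
    return np.concatenate([td.mean(axis=0).ravel(), td.std(axis=0).ravel()])


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------


def _evaluate_cnn(fold: FoldData, variant: str, mode: str, cfg: mdl.TrainingConfig):
    x_tr, y_tr, _ = _cnn_dataset(fold.train, mode)
    x_te, _, seg_te = _cnn_dataset(fold.test, mode)
    _, net = mdl.build_network(variant, x_tr.shape[1:], seed=cfg.seed)
    history = mdl.train(net, x_tr, y_tr, cfg)
    probs = mdl.predict(net, x_te)
    preds = []
    for i in range(len(fold.test)):
        seg_probs = probs[seg_te == i]
        preds.append(int(np.argmax(mdl.aggregate_windows(seg_probs))))
    return preds, history


def _evaluate_baseline(fold: FoldData, kind: str, mode: str, seed: int):
    x_tr = np.stack([_flat_features(it, mode) for it in fold.train])
    y_tr = np.asarray([it["label"] for it in fold.train])
    x_te = np.stack([_flat_features(it, mode) for it in fold.test])
    clf = make_pipeline(StandardScaler(), mdl.baseline_classifier(kind, seed))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(x_tr, y_tr)
    return list(clf.predict(x_te)), []


def run_experiment(
    recordings: list[EmgRecording],
    *,
    methods: tuple[str, ...] = ("idpc", "dpc1", "dpc2", "single", "svm_rbf"),
    feature_modes: tuple[str, ...] = ("spm", "rms"),
    seed: int = 0,
    training: mdl.TrainingConfig | None = None,
    filter_spec: FilterSpec | None = None,
    pca_k: int = 8,
    n_energy: int = 100,
) -> dict:
    """Run the full LOSO comparison grid and return a machine-readable report.

    For every method x feature mode: per-fold and mean Ac/Se/Sp, the pooled
    confusion counts, wall-clock per method (informational only — never an
    acceptance quantity), seeds, and per-fold training-set fingerprints for
    leakage audits.
    """
    known = mdl.VARIANTS + mdl.BASELINES
    for m in methods:
        if m not in known:
            raise ValueError(f"unknown method {m!r}; expected one of {known}")
    for mode in feature_modes:
        if mode not in ("spm", "rms"):
            raise ValueError(f"unknown feature mode {mode!r}")
    training = training or mdl.TrainingConfig(seed=seed)
    fs = recordings[0].fs_hz
    filter_spec = filter_spec or design_bandpass(fs)
    filtered = [apply_filter(r, filter_spec) for r in recordings]
    split = loso_split(filtered)
    folds = [
        prepare_fold(filtered, tr, te, n_energy=n_energy, pca_k=pca_k)
        for tr, te in split.folds
    ]

    report: dict = {
        "seed": seed,
        "n_recordings": len(recordings),
        "n_folds": len(folds),
        "folds": [
            {
                "test_subject": f.test_subject,
                "train_subjects": list(f.train_subjects),
                "train_fingerprint": f.train_fingerprint,
                "sts": f.sts,
                "ste": f.ste,
                "n_train_segments": len(f.train),
                "n_test_segments": len(f.test),
                "n_missed_test_recordings": f.n_missed_test,
            }
            for f in folds
        ],
        "results": {},
    }
    for method in methods:
        for mode in feature_modes:
            t0 = time.perf_counter()
            per_fold = []
            pooled_pred, pooled_true = [], []
            for fold in folds:
                true = [it["label"] for it in fold.test]
                if method in mdl.VARIANTS:
                    preds, _hist = _evaluate_cnn(fold, method, mode, training)
                else:
                    preds, _hist = _evaluate_baseline(fold, method, mode, training.seed)
                cs = confusion(preds, true)
                rep = metrics(cs)
                per_fold.append(
                    {
                        "test_subject": fold.test_subject,
                        "tp": cs.tp,
                        "fp": cs.fp,
                        "tn": cs.tn,
                        "fn": cs.fn,
                        "ac": rep.ac,
                        "se": rep.se,
                        "sp": rep.sp,
                    }
                )
                pooled_pred.extend(preds)
                pooled_true.extend(true)
            pooled = metrics(confusion(pooled_pred, pooled_true))
            mean_of = lambda key: float(np.mean([f[key] for f in per_fold if f[key] is not None]))
            report["results"][f"{method}/{mode}"] = {
                "method": method,
                "feature_mode": mode,
                "per_fold": per_fold,
                "mean_ac": mean_of("ac"),
                "mean_se": mean_of("se") if any(f["se"] is not None for f in per_fold) else None,
                "mean_sp": mean_of("sp") if any(f["sp"] is not None for f in per_fold) else None,
                "pooled_ac": pooled.ac,
                "pooled_se": pooled.se,
                "pooled_sp": pooled.sp,
                "runtime_s_informational": time.perf_counter() - t0,
            }
    return report
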