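"""Sliding-window spatiotemporal decoding with PCA + LDA.

Features are raw low-frequency EEG amplitudes: for each 400 ms analysis
window, 9 samples per channel are concatenated over the 30-channel montage
into a 270-dimensional vector.  Dimensionality is reduced by PCA keeping
the smallest number of components explaining at least 85% of the variance
of the trial pool, and the component loadings are classified with a
pooled-covariance linear discriminant.

Three decoding configurations are supported:

* within-hand — repeated stratified k-fold cross-validation on a pool of
  two same-hand conditions;
* normal cross-hand — train on two conditions of one hand, test on two
  conditions of the other hand, same electrode montage;
* mirror cross-hand — as above, but the test trials are re-indexed with
  the mirrored montage, so each channel position carries the signal of
  its cross-midline partner electrode.

The mirrored montage favors spatial patterns that are shared between
hands across ipsilateral/contralateral hemispheres; the standard montage
favors patterns fixed in head coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

from .task_model import ClassifierSpec, ClassLabeling, TrialCondition

__all__ = [
    "STANDARD_MONTAGE",
    "MIRRORED_MONTAGE",
    "Montage",
    "DEFAULT_MONTAGE",
    "mirror_permutation",
    "mirror_channels",
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "window_starts",
    "extract_features",
    "PcaProjector",
    "fit_pca",
    "LdaModel",
    "lda_train",
    "lda_predict",
    "DecodeResult",
    "within_hand_cv",
    "cross_hand_eval",
    "run_classifier",
]

# Standard 30-channel montage order (left-hemisphere block, then right).
STANDARD_MONTAGE: Tuple[str, ...] = (
    "F1", "F3", "F5", "FC5", "FC3", "FC1", "C1", "C3", "C5", "CP5", "CP3", "CP1",
    "P1", "P3", "P5",
    "F2", "F4", "F6", "FC6", "FC4", "FC2", "C2", "C4", "C6", "CP6", "CP4", "CP2",
    "P2", "P4", "P6",
)


def _mirror_label(name: str) -> str:
    """Cross-midline partner of a 10-20 label: odd digit <-> even digit."""
    digit = int(name[-1])
    partner = digit + 1 if digit % 2 == 1 else digit - 1
    return name[:-1] + str(partner)


# Mirrored order: position i carries the cross-midline partner of
# STANDARD_MONTAGE[i].
MIRRORED_MONTAGE: Tuple[str, ...] = tuple(_mirror_label(ch) for ch in STANDARD_MONTAGE)


@dataclass(frozen=True)
class Montage:
    """Ordered 30-channel montage with its midline-mirror permutation."""

    names: Tuple[str, ...] = STANDARD_MONTAGE

    @property
    def mirror_perm(self) -> np.ndarray:
        index = {ch: i for i, ch in enumerate(self.names)}
        return np.array([index[_mirror_label(ch)] for ch in self.names])

    @property
    def mirrored_names(self) -> Tuple[str, ...]:
        return tuple(_mirror_label(ch) for ch in self.names)

    @property
    def n_channels(self) -> int:
        return len(self.names)


DEFAULT_MONTAGE = Montage()
_MIRROR_PERM = DEFAULT_MONTAGE.mirror_perm


def mirror_permutation() -> np.ndarray:
    """Channel permutation mapping the standard order onto the mirrored one."""
    return _MIRROR_PERM.copy()


def mirror_channels(x: np.ndarray) -> np.ndarray:
    """Permute data so each channel position carries its cross-midline partner.

    Accepts epoch arrays ``(..., 30, n_times)`` or feature matrices
    ``(n_trials, 270)`` (channel-major layout).  Involution: applying it
    twice is the identity.
    """
    x = np.asarray(x)
    n_ch = len(STANDARD_MONTAGE)
    if x.ndim >= 2 and x.shape[-2] == n_ch:
        return x[..., _MIRROR_PERM, :]
    if x.ndim == 2 and x.shape[-1] == n_ch * SAMPLES_PER_CHANNEL:
        n = x.shape[0]
        return x.reshape(n, n_ch, SAMPLES_PER_CHANNEL)[:, _MIRROR_PERM, :].reshape(n, -1)
    raise ValueError(
        f"cannot infer channel axis from shape {x.shape}; expected a "
        f"(..., {n_ch}, n_times) epoch array or (n_trials, {n_ch * SAMPLES_PER_CHANNEL}) features"
    )


WINDOW_LENGTH = 0.4  # s
WINDOW_STEP = 0.1  # s
N_WINDOWS = 15
SAMPLES_PER_CHANNEL = 9
# 9 equally spaced sample offsets spanning the 400 ms window (endpoints
# inclusive), rounded onto the 50 Hz grid (nominal spacing 0.05 s = 2.5
# samples).
WINDOW_SAMPLE_OFFSETS = np.round(np.linspace(0.0, WINDOW_LENGTH * 50, SAMPLES_PER_CHANNEL)).astype(int)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis-window layout relative to the alignment event."""

    length: float = WINDOW_LENGTH
    step: float = WINDOW_STEP
    n_windows: int = N_WINDOWS
    samples_per_channel: int = SAMPLES_PER_CHANNEL

    @property
    def starts(self) -> np.ndarray:
        return np.round(np.arange(self.n_windows) * self.step, 10)


DEFAULT_WINDOWS = WindowSpec()


def window_starts(phase: str = "planning") -> np.ndarray:
    """The 15 analysis-window start times (s) for a phase.

    Starts run 0.0-1.4 s in 0.1 s steps relative to the task cue
    (planning) or to movement onset (execution); every 400 ms window ends
    by 1.8 s, inside the [-1, 2] s epoch.
    """
    if phase not in ("planning", "execution"):
        raise ValueError(f"phase must be 'planning' or 'execution', got {phase!r}")
    return DEFAULT_WINDOWS.starts


def _epoch_array(epochs) -> Tuple[np.ndarray, float, float]:
    """Accept an EpochSet-like object or a bare (n, ch, t) array."""
    if hasattr(epochs, "t_start"):
        return np.asarray(epochs.data), float(epochs.t_start), float(epochs.rate)
    return np.asarray(epochs), -1.0, 50.0


def extract_features(epochs, start: float, t_start: Optional[float] = None,
                     rate: Optional[float] = None) -> np.ndarray:
    """Spatiotemporal feature matrix for one analysis window.

    Per trial, 9 samples per channel over the 400 ms window starting at
    ``start`` (s, epoch time) are concatenated channel-major: the feature
    index of channel ``c``, sample ``s`` is ``c * 9 + s``.
    """
    data, t0, fs = _epoch_array(epochs)
    if t_start is not None:
        t0 = t_start
    if rate is not None:
        fs = rate
    i0 = int(round((start - t0) * fs))
    offsets = WINDOW_SAMPLE_OFFSETS
    if i0 < 0 or i0 + offsets[-1] >= data.shape[-1]:
        raise ValueError(
            f"window starting at {start} s falls outside the epoch "
            f"[{t0}, {t0 + data.shape[-1] / fs}] s"
        )
    win = data[:, :, i0 + offsets]  # (trials, channels, 9)
    return win.reshape(win.shape[0], -1)


@dataclass
class PcaProjector:
    """PCA projection retaining the smallest k components reaching the
    requested variance fraction."""

    mean: np.ndarray
    components: np.ndarray  # (k, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,)
    var_frac: float

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.mean) @ self.components.T


def fit_pca(features: np.ndarray, var_frac: float = 0.85) -> PcaProjector:
    """Fit PCA on a trial pool and keep components up to ``var_frac``."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("PCA requires at least 2 trials")
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must be in (0, 1]")
    total_var = features.var(axis=0).sum()
    if total_var <= 0:
        raise ValueError("zero-variance trial pool")
    pca = _SkPCA(svd_solver="full")
    pca.fit(features)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.argmax(cum >= var_frac - 1e-12)) + 1
    return PcaProjector(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        var_frac=var_frac,
    )


@dataclass
class LdaModel:
    """Two-class linear discriminant with pooled covariance and a small
    ridge for invertibility.  The decision value is antisymmetric under a
    class swap; exact ties predict class 0."""

    weights: np.ndarray
    bias: float
    means: np.ndarray  # (2, n_features)

    def decision(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.weights + self.bias


def lda_train(loadings: np.ndarray, labels: np.ndarray, ridge: float = 1e-6) -> LdaModel:
    """Fit a pooled-covariance LDA on (possibly PCA-reduced) features.

    ``ridge`` scales the mean covariance diagonal added to the pooled
    covariance (epsilon * trace/dim) so the solve is well posed.
    """
    x = np.asarray(loadings, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"LDA requires exactly two classes, got {classes.tolist()}")
    x0, x1 = x[y == classes[0]], x[y == classes[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("LDA requires at least 2 trials per class")
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    s0 = (x0 - mu0).T @ (x0 - mu0)
    s1 = (x1 - mu1).T @ (x1 - mu1)
    cov = (s0 + s1) / (len(x0) + len(x1) - 2)
    eps = ridge * np.trace(cov) / cov.shape[0]
    if eps == 0:  # exactly repeated trials (noise-free data): keep solvable
        eps = 1e-12
    cov = cov + eps * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -0.5 * (w @ (mu0 + mu1))
    return LdaModel(weights=w, bias=float(b), means=np.stack([mu0, mu1]))


def lda_predict(model: LdaModel, loadings: np.ndarray) -> np.ndarray:
    """Predict binary classes; the decision boundary value 0 maps to class 0."""
    return (model.decision(loadings) > 0).astype(int)


@dataclass
class DecodeResult:
    """Per-window accuracies for one classifier, with peak selection.

    The peak is the maximum of the window series; its timing is the start
    time of the argmax window (earliest window on ties).
    """

    window_starts: np.ndarray
    accuracies: np.ndarray
    n_test: np.ndarray
    spec: Optional[ClassifierSpec] = None
    pca_scope: str = "pool"

    @property
    def peak(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def peak_time(self) -> float:
        return float(self.window_starts[int(np.argmax(self.accuracies))])


def _select_pool(epochs, pair: Sequence[TrialCondition]) -> Tuple[np.ndarray, List[TrialCondition]]:
    conds = list(epochs.conditions)
    mask = np.array([c in pair for c in conds])
    if not mask.any():
        raise ValueError(f"no trials found for conditions {[c.code for c in pair]}")
    data = np.asarray(epochs.data)[mask]
    kept = [c for c in conds if c in pair]
    return data, kept


def _labels(conds: Sequence[TrialCondition], spec: ClassifierSpec) -> np.ndarray:
    return np.array([spec.class_of(c) for c in conds])


def within_hand_cv(
    epochs,
    spec: ClassifierSpec,
    reps: int = 10,
    folds: int = 10,
    seed: int = 0,
    pca_scope: str = "pool",
    var_frac: float = 0.85,
    windows: Optional[Iterable[float]] = None,
) -> DecodeResult:
    """Repeated stratified k-fold cross-validation on a same-hand pool.

    Per analysis window the accuracy is the mean over ``reps`` x ``folds``
    held-out fold accuracies; folds are reshuffled every repetition from a
    master seed.  ``pca_scope`` controls whether PCA is fitted on the full
    trial pool (``"pool"``, includes test trials) or refitted on each
    training split (``"train_only"``, leakage-free).
    """
    if not spec.is_within_hand:
        raise ValueError("spec has a test_pair; use cross_hand_eval")
    _check_scope(pca_scope)
    data, conds = _select_pool(epochs, spec.train_pair)
    y = _labels(conds, spec)
    min_class = int(np.bincount(y).min())
    k = folds
    if min_class < folds:
        k = max(2, min_class)
        warnings.warn(
            f"fewer than {folds} trials in the smallest class ({min_class}); "
            f"reducing to {k}-fold CV",
            stacklevel=2,
        )
    starts = np.asarray(list(windows)) if windows is not None else DEFAULT_WINDOWS.starts
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    t0, fs = _epoch_array(epochs)[1:]
    accs = np.empty(len(starts))
    for wi, start in enumerate(starts):
        feats = extract_features(data, start, t_start=t0, rate=fs)
        if pca_scope == "pool":
            proj = fit_pca(feats, var_frac)
            loadings = proj.transform(feats)
        fold_accs = []
        for r in range(reps):
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rep_seeds[r]))
            for tr, te in skf.split(feats, y):
                if pca_scope == "pool":
                    ltr, lte = loadings[tr], loadings[te]
                else:
                    proj = fit_pca(feats[tr], var_frac)
                    ltr, lte = proj.transform(feats[tr]), proj.transform(feats[te])
                model = lda_train(ltr, y[tr])
                fold_accs.append(float(np.mean(lda_predict(model, lte) == y[te])))
        accs[wi] = float(np.mean(fold_accs))
    return DecodeResult(
        window_starts=starts,
        accuracies=accs,
        n_test=np.full(len(starts), len(y)),
        spec=spec,
        pca_scope=pca_scope,
    )


def _check_scope(pca_scope: str) -> None:
    if pca_scope not in ("pool", "train_only"):
        raise ValueError(f"pca_scope must be 'pool' or 'train_only', got {pca_scope!r}")


def cross_hand_eval(
    train_epochs,
    test_epochs,
    spec: ClassifierSpec,
    pca_scope: str = "pool",
    var_frac: float = 0.85,
    windows: Optional[Iterable[float]] = None,
) -> DecodeResult:
    """Train on one hand's condition pair, test on the other hand's.

    In mirror mode the test trials are first re-indexed with the mirrored
    montage.  With ``pca_scope="pool"`` the PCA is fitted on the combined
    four-condition pool after any mirroring, then the LDA is trained on
    the training hand only and scored on the testing hand per window.

    ``train_epochs`` and ``test_epochs`` may be the same EpochSet; the
    condition pairs of ``spec`` select the pools and must come from
    opposite hands.
    """
    if spec.is_within_hand:
        raise ValueError("spec has no test_pair; use within_hand_cv")
    _check_scope(pca_scope)
    tr_data, tr_conds = _select_pool(train_epochs, spec.train_pair)
    te_data, te_conds = _select_pool(test_epochs, spec.test_pair)
    tr_hands = {c.hand for c in tr_conds}
    te_hands = {c.hand for c in te_conds}
    if tr_hands & te_hands:
        raise ValueError("train and test pools must come from opposite hands")
    y_tr = _labels(tr_conds, spec)
    y_te = _labels(te_conds, spec)
    if spec.montage_mode == "mirror":
        te_data = mirror_channels(te_data)
    starts = np.asarray(list(windows)) if windows is not None else DEFAULT_WINDOWS.starts
    t0_tr, fs_tr = _epoch_array(train_epochs)[1:]
    t0_te, fs_te = _epoch_array(test_epochs)[1:]
    accs = np.empty(len(starts))
    for wi, start in enumerate(starts):
        f_tr = extract_features(tr_data, start, t_start=t0_tr, rate=fs_tr)
        f_te = extract_features(te_data, start, t_start=t0_te, rate=fs_te)
        if pca_scope == "pool":
            proj = fit_pca(np.vstack([f_tr, f_te]), var_frac)
        else:
            proj = fit_pca(f_tr, var_frac)
        model = lda_train(proj.transform(f_tr), y_tr)
        pred = lda_predict(model, proj.transform(f_te))
        accs[wi] = float(np.mean(pred == y_te))
    return DecodeResult(
        window_starts=starts,
        accuracies=accs,
        n_test=np.full(len(starts), len(y_te)),
        spec=spec,
        pca_scope=pca_scope,
    )


def run_classifier(epochs, spec: ClassifierSpec, seed: int = 0, **kwargs) -> DecodeResult:
    """Dispatch a ClassifierSpec to within-hand CV or cross-hand transfer."""
    if spec.is_within_hand:
        return within_hand_cv(epochs, spec, seed=seed, **kwargs)
    return cross_hand_eval(epochs, epochs, spec, **kwargs)
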