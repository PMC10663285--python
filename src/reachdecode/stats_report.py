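"""Group-level aggregation, chance threshold, significance tests, and the
end-to-end pipeline driver.

Classifiers are organized in groups of four that decode the same
information (e.g. the four within-hand action pairs); the subject-level
unit of analysis is the mean peak accuracy (and mean peak timing) over
each group.  A peak accuracy counts as above chance when it exceeds the
exact-binomial threshold for the classifier's test-set size.  Group
contrasts use two-tail paired t-tests, reported uncorrected with
Holm-adjusted p-values alongside.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, fields as dc_fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import decoding
from .eeg_preprocess import PreprocessResult, preprocess_session
from .synthetic_session import SynthConfig, simulate_session
from .task_model import classifier_groups

__all__ = [
    "chance_threshold",
    "paired_t_test",
    "decode_session",
    "summarize_groups",
    "run_pipeline",
]

logger = logging.getLogger("reachdecode")

GROUP_KEYS = ["phase", "config", "target", "labeling", "montage_mode"]


def chance_threshold(
    n_test: int, alpha: float = 0.05, n_classes: int = 2, convention: str = "tail"
) -> float:
    """Smallest accuracy significantly above chance for ``n_test`` samples.

    ``"tail"`` (default): the smallest k with upper-tail binomial
    probability P(X >= k) < alpha under p = 1/n_classes, returned as
    k / n_test.  ``"cdf"``: the alternative inverse-CDF convention —
    largest k with CDF(k) < 1 - alpha, plus one.  Reports should record
    which convention was used.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = 1.0 / n_classes
    ks = np.arange(n_test + 1)
    if convention == "tail":
        upper_tail = sps.binom.sf(ks - 1, n_test, p)  # P(X >= k)
        qualifying = np.flatnonzero(upper_tail < alpha)
        k = int(qualifying[0]) if qualifying.size else n_test + 1
    elif convention == "cdf":
        cdf = sps.binom.cdf(ks, n_test, p)
        below = np.flatnonzero(cdf < 1.0 - alpha)
        k = (int(below[-1]) if below.size else -1) + 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return k / n_test


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-tail paired t-test; returns (t, p) with n-1 degrees of freedom.

    Identical samples return (0.0, 1.0); constant nonzero differences are
    degenerate (infinite t) and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero variance of nonzero differences; t is undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def decode_session(
    pre: PreprocessResult,
    seed: int = 0,
    pca_scope: str = "pool",
    phases: Sequence[str] = ("planning", "execution"),
    include_within: bool = True,
    include_cross: bool = True,
    groups: Optional[Dict] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run every classifier group on one preprocessed session.

    Returns (windows, peaks) tables.  ``windows`` has one row per
    classifier x analysis window; ``peaks`` one row per classifier with
    its peak accuracy and peak-window start time.
    """
    if groups is None:
        groups = classifier_groups()
    win_rows: List[dict] = []
    peak_rows: List[dict] = []
    for key, specs in groups.items():
        config_kind = key[0]
        if config_kind == "within" and not include_within:
            continue
        if config_kind == "cross" and not include_cross:
            continue
        target = key[1]
        labeling = key[2] if len(key) > 2 else specs[0].labeling.value
        montage_mode = key[3] if len(key) > 3 else "standard"
        for phase in phases:
            epochs = pre.planning if phase == "planning" else pre.execution
            for spec in specs:
                result = decoding.run_classifier(epochs, spec, seed=seed, pca_scope=pca_scope)
                base = {
                    "phase": phase,
                    "config": config_kind,
                    "target": target,
                    "labeling": labeling,
                    "montage_mode": montage_mode,
                    "train_hand": spec.train_hand.value,
                    "classifier": spec.name,
                }
                for start, acc, n in zip(result.window_starts, result.accuracies, result.n_test):
                    win_rows.append({**base, "window_start": float(start),
                                     "accuracy": float(acc), "n_test": int(n)})
                peak_rows.append({**base, "peak_acc": result.peak, "peak_time": result.peak_time,
                                  "n_test": int(result.n_test[0])})
    return pd.DataFrame(win_rows), pd.DataFrame(peak_rows)


def _holm(pvals: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="holm")[1]
    return adj


def summarize_groups(peaks: pd.DataFrame, threshold: float) -> Dict[str, pd.DataFrame]:
    """Subject-level group means, above-chance counts, and paired contrasts.

    ``peaks`` must contain a ``subject`` column plus one row per
    classifier; each (subject, group) cell must hold exactly four
    classifiers.  Returns ``group_means`` (per-subject means),
    ``above_chance`` (subjects whose group-mean peak exceeds the
    threshold), and ``comparisons`` (extrinsic vs intrinsic peak
    accuracy, direction vs action peak timing) with uncorrected and
    Holm-adjusted p-values; zero-variance contrasts are flagged.
    """
    if "subject" not in peaks.columns:
        raise ValueError("peaks table needs a 'subject' column")
    counts = peaks.groupby(["subject"] + GROUP_KEYS, as_index=False).size()
    bad = counts[counts["size"] != 4]
    if len(bad):
        raise ValueError(
            "each classifier group must contain exactly 4 classifiers per subject; "
            f"offending groups:\n{bad.to_string(index=False)}"
        )
    gm = (
        peaks.groupby(["subject"] + GROUP_KEYS, as_index=False)[["peak_acc", "peak_time"]]
        .mean()
        .sort_values(["subject"] + GROUP_KEYS)
        .reset_index(drop=True)
    )
    above = (
        gm.assign(above=gm["peak_acc"] > threshold)
        .groupby(GROUP_KEYS, as_index=False)
        .agg(n_subjects=("above", "size"), n_above_chance=("above", "sum"))
    )

    comp_rows: List[dict] = []

    def _contrast(sub_a: pd.DataFrame, sub_b: pd.DataFrame, value: str, label: str, where: dict):
        merged = sub_a.merge(sub_b, on="subject", suffixes=("_a", "_b"))
        if len(merged) < 2:
            return
        a = merged[f"{value}_a"].to_numpy()
        b = merged[f"{value}_b"].to_numpy()
        row = {**where, "contrast": label, "mean_a": a.mean(), "mean_b": b.mean(),
               "n": len(merged), "degenerate": bool(np.ptp(a - b) == 0)}
        try:
            t, p = paired_t_test(a, b)
        except ValueError:
            t, p = np.nan, np.nan
        row["t"], row["p"] = t, p
        comp_rows.append(row)

    for phase in gm["phase"].unique():
        cross = gm[(gm["phase"] == phase) & (gm["config"] == "cross")]
        for montage in cross["montage_mode"].unique():
            sub = cross[cross["montage_mode"] == montage]
            ext = sub[(sub["target"] == "direction") & (sub["labeling"] == "extrinsic")]
            intr = sub[(sub["target"] == "direction") & (sub["labeling"] == "intrinsic")]
            _contrast(ext, intr, "peak_acc", "direction acc: extrinsic vs intrinsic",
                      {"phase": phase, "config": "cross", "montage_mode": montage})
            for labeling in ("extrinsic", "intrinsic"):
                d = sub[(sub["target"] == "direction") & (sub["labeling"] == labeling)]
                a = sub[(sub["target"] == "action") & (sub["labeling"] == labeling)]
                _contrast(d, a, "peak_time", f"peak timing: direction vs action ({labeling})",
                          {"phase": phase, "config": "cross", "montage_mode": montage})
        within = gm[(gm["phase"] == phase) & (gm["config"] == "within")]
        if len(within):
            d = within[within["target"] == "direction"]
            a = within[within["target"] == "action"]
            _contrast(d, a, "peak_time", "peak timing: direction vs action",
                      {"phase": phase, "config": "within", "montage_mode": "standard"})
            _contrast(a, d, "peak_acc", "peak acc: action vs direction",
                      {"phase": phase, "config": "within", "montage_mode": "standard"})
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["p_holm"] = _holm(comparisons["p"])
    return {"group_means": gm, "above_chance": above, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# pipeline driver

DEFAULT_PIPELINE_CONFIG: Dict = {
    "n_subjects": 10,
    "seed": 0,
    "phases": ["planning", "execution"],
    "within": True,
    "cross": True,
    "pca_scope": "pool",
    "eog_mode": "regress",
    "alpha": 0.05,
    "threshold_convention": "tail",
    "synth": {},
}

_SYNTH_FIELDS = {f.name for f in dc_fields(SynthConfig)}


def validate_pipeline_config(config: Dict) -> Dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    unknown = set(config) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
    merged = {**DEFAULT_PIPELINE_CONFIG, **config}
    synth_unknown = set(merged["synth"]) - (_SYNTH_FIELDS - {"seed"})
    if synth_unknown:
        raise ValueError(f"unknown synth config key(s): {sorted(synth_unknown)}")
    for phase in merged["phases"]:
        if phase not in ("planning", "execution"):
            raise ValueError(f"unknown phase {phase!r}")
    return merged


def subject_seeds(master_seed: int, n_subjects: int) -> np.ndarray:
    """Stable per-subject seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_subjects) % (2**31 - 1)


def run_pipeline(config: Dict, run_dir) -> Dict:
    """Execute generation -> kinematics -> preprocessing -> decoding ->
    statistics for every synthetic subject and write the report bundle.

    Writes ``windows.csv``, ``peaks.csv``, ``group_means.csv``,
    ``above_chance.csv``, ``comparisons.csv`` and ``manifest.json`` under
    ``run_dir``.  A subject whose processing fails is skipped with a
    warning and recorded in the manifest.  Reruns with the same config
    produce identical CSVs.
    """
    cfg = validate_pipeline_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    seeds = subject_seeds(cfg["seed"], cfg["n_subjects"])
    all_windows, all_peaks = [], []
    excluded: List[int] = []
    for subject, s in enumerate(seeds):
        try:
            synth = SynthConfig(**cfg["synth"], seed=int(s))
            session = simulate_session(synth)
            pre = preprocess_session(session, eog_mode=cfg["eog_mode"])
            windows, peaks = decode_session(
                pre,
                seed=int(s),
                pca_scope=cfg["pca_scope"],
                phases=cfg["phases"],
                include_within=cfg["within"],
                include_cross=cfg["cross"],
            )
            windows.insert(0, "subject", subject)
            peaks.insert(0, "subject", subject)
            all_windows.append(windows)
            all_peaks.append(peaks)
            logger.info("subject %d done (seed %d)", subject, s)
        except Exception as exc:  # noqa: BLE001 - continue with remaining subjects
            warnings.warn(f"subject {subject} failed and was excluded: {exc}", stacklevel=2)
            excluded.append(subject)
    if not all_peaks:
        raise RuntimeError("every subject failed; nothing to report")

    windows = pd.concat(all_windows, ignore_index=True)
    peaks = pd.concat(all_peaks, ignore_index=True)
    n_test_typ = int(peaks["n_test"].median())
    threshold = chance_threshold(
        n_test_typ, alpha=cfg["alpha"], convention=cfg["threshold_convention"]
    )
    summary = summarize_groups(peaks, threshold)

    windows.to_csv(run_dir / "windows.csv", index=False)
    peaks.to_csv(run_dir / "peaks.csv", index=False)
    summary["group_means"].to_csv(run_dir / "group_means.csv", index=False)
    summary["above_chance"].to_csv(run_dir / "above_chance.csv", index=False)
    summary["comparisons"].to_csv(run_dir / "comparisons.csv", index=False)
    manifest = {
        "config": cfg,
        "subject_seeds": [int(s) for s in seeds],
        "excluded_subjects": excluded,
        "chance_threshold": threshold,
        "chance_threshold_n": n_test_typ,
        "threshold_convention": cfg["threshold_convention"],
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"windows": windows, "peaks": peaks, "threshold": threshold, **summary,
            "manifest": manifest}
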