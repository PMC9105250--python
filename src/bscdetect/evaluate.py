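"""Window-level evaluation: confusion counts, accuracy, ROC/AUC, CV sweep.

The positive class is "changed": a stimulation-phase window of a session
whose stimulated state differs from its baseline state.  ACC is the percent
of correctly labeled windows, 100*(TP+TN)/(TP+TN+FP+FN).  ROC curves sweep
the change-score threshold over all distinct scores; AUC is trapezoidal
(equivalently the tie-averaged rank statistic).

Cross-validation folds are *session-atomic*: all windows of one session land
in the same fold, because adjacent sliding windows overlap by cW-1 samples
and splitting them across folds would leak nearly identical rows between
train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .preprocess import ValidationError


def confusion(decisions, truth) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with positive = changed.

    ``decisions`` and ``truth`` are binary (1 = changed) of equal length.
    """
    d = np.asarray(decisions).astype(bool)
    t = np.asarray(truth).astype(bool)
    if d.size == 0:
        raise ValidationError("empty inputs")
    if d.shape != t.shape:
        raise ValidationError("decisions and truth must have equal length")
    tp = int(np.sum(d & t))
    tn = int(np.sum(~d & ~t))
    fp = int(np.sum(d & ~t))
    fn = int(np.sum(~d & t))
    return tp, tn, fp, fn


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """ACC percent = 100 * (TP+TN) / (TP+TN+FP+FN)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("negative counts")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("zero total count")
    return 100.0 * (tp + tn) / total


def roc_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC points (FPR, TPR, threshold) over all score thresholds, and AUC.

    Requires at least one positive and one negative in ``truth``; higher
    scores must indicate the positive (changed) class.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(int)
    if s.shape != t.shape:
        raise ValidationError("scores and truth must align")
    if t.min() == t.max():
        raise ValidationError("need both classes for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(t, s, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), \
        float(_sk_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Confusion counts + ACC + ROC/AUC for one stratification cell."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    roc: pd.DataFrame | None
    auc: float | None
    keys: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.acc <= 100.0):
            raise ValidationError("ACC out of [0, 100]")
        if self.auc is not None and not (0.0 <= self.auc <= 1.0):
            raise ValidationError("AUC out of [0, 1]")

    @property
    def n_windows(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        d = {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
             "ACC": self.acc, "AUC": self.auc, "n": self.n_windows}
        d.update(self.keys)
        return d


def report_from_series(series_list, **keys) -> EvalReport:
    """Pool ChangeScoreSeries objects into one report."""
    scores = np.concatenate([s.scores for s in series_list])
    truth = np.concatenate([s.truth for s in series_list])
    decisions = np.concatenate([s.decisions for s in series_list])
    tp, tn, fp, fn = confusion(decisions, truth)
    if truth.min() != truth.max():
        roc, a = roc_auc(scores, truth)
    else:
        roc, a = None, None
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn,
                      acc=accuracy(tp, tn, fp, fn), roc=roc, auc=a, keys=keys)


def session_folds(n_sessions: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seed-deterministic session-atomic fold assignment."""
    idx = np.random.default_rng(seed).permutation(n_sessions)
    return [np.sort(f) for f in np.array_split(idx, n_folds)]


def bootstrap_ci(values: np.ndarray, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    means = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return float(np.quantile(means, lo)), float(np.quantile(means, hi))


def crossval_sweep(sessions, factories: dict, window_set,
                   n_folds: int = 10, seed: int = 0,
                   ci_resamples: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean window-level ACC per detector x window duration, by CV folds.

    ``factories`` maps a detector name to a callable
    ``factory(train_sessions, cW, seed) -> scorer`` where the scorer has a
    ``score_session(session) -> ChangeScoreSeries`` method.  A factory that
    raises :class:`ValidationError` for a given cW (e.g. the handcrafted
    detector below the 15 s feature minimum) yields an NA cell.

    Returns ``(grid, folds)``: the wide mean-ACC grid and the long per-fold
    table with bootstrap CIs.
    """
    sessions = list(sessions)
    if len(sessions) < n_folds:
        import warnings
        warnings.warn(f"only {len(sessions)} sessions; reducing folds from "
                      f"{n_folds}", stacklevel=2)
        n_folds = len(sessions)
    folds = session_folds(len(sessions), n_folds, seed)
    rows = []
    for cW in window_set:
        for name, factory in factories.items():
            for k, test_idx in enumerate(folds):
                test = [sessions[i] for i in test_idx]
                train = [sessions[i] for i in range(len(sessions))
                         if i not in set(test_idx)]
                try:
                    scorer = factory(train, cW, seed + k)
                    series = [scorer.score_session(s) for s in test]
                except ValidationError:
                    rows.append({"detector": name, "cW": cW, "fold": k,
                                 "ACC": np.nan})
                    continue
                rep = report_from_series(series)
                rows.append({"detector": name, "cW": cW, "fold": k,
                             "ACC": rep.acc})
    long = pd.DataFrame(rows)
    agg = []
    for (name, cW), grp in long.groupby(["detector", "cW"]):
        accs = grp["ACC"].to_numpy()
        if np.all(np.isnan(accs)):
            agg.append({"detector": name, "cW": cW, "ACC": np.nan,
                        "ci_lo": np.nan, "ci_hi": np.nan})
        else:
            lo, hi = bootstrap_ci(accs[~np.isnan(accs)], ci_resamples, seed)
            agg.append({"detector": name, "cW": cW,
                        "ACC": float(np.nanmean(accs)),
                        "ci_lo": lo, "ci_hi": hi})
    agg = pd.DataFrame(agg)
    grid = agg.pivot(index="detector", columns="cW", values="ACC")
    return grid, agg


def plot_roc(reports: list[EvalReport], path) -> None:
    """Write a ROC plot (one curve per report) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        if rep.roc is None:
            continue
        label = ", ".join(f"{k}={v}" for k, v in rep.keys.items())
        ax.plot(rep.roc["fpr"], rep.roc["tpr"],
                label=f"{label} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
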