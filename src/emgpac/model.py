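"""Leave-one-subject-out (LOSO) classification and subject-level diagnosis.

:class:`LOSOClassifier` is the model object: it is built from a feature
table (one row per (channel, 500 ms epoch), metadata columns identifying
subject/group) and a network specification.  ``fit`` trains one
feedforward net per held-out subject — 28 nets for the default cohort —
and aggregates each subject's epoch probabilities into a diagnosis: the
subject is called a case when the *mean* epoch probability reaches the
0.5 cutoff.  The returned :class:`LOSOResults` carries per-subject
diagnoses, the cohort confusion table, accuracy/sensitivity/specificity
with confidence intervals, and uncertainty intervals for the mean
probabilities.

Leakage control: the held-out subject's rows appear only in the test
partition (asserted per dataset), and the per-feature z-scaler is fitted
on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import FNN, FNNSpec
from . import evaluate as ev
from .preprocess import META_COLUMNS

__all__ = ["LOSODataset", "DiagnosisResult", "LOSOClassifier", "LOSOResults",
           "make_loso_datasets", "feature_columns"]


def feature_columns(table: pd.DataFrame):
    """All non-metadata columns of a feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class LOSODataset:
    """Row-index partition for one held-out subject, plus the train scaler."""

    test_subject_id: str
    train_rows: np.ndarray
    val_rows: np.ndarray
    test_rows: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def assert_no_leakage(self, table: pd.DataFrame) -> None:
        test_set = set(self.test_rows.tolist())
        if test_set & set(self.train_rows.tolist()) or \
           test_set & set(self.val_rows.tolist()):
            raise AssertionError(
                f"leakage: test rows of {self.test_subject_id} in train/val")
        subjects = table.loc[np.concatenate([self.train_rows, self.val_rows]),
                             "subject_id"]
        if (subjects == self.test_subject_id).any():
            raise AssertionError(
                f"leakage: subject {self.test_subject_id} in train/val rows")


@dataclass
class DiagnosisResult:
    """Subject-level diagnosis from epoch probabilities."""

    subject_id: str
    epoch_probs: np.ndarray
    true_label: str
    cutoff: float = 0.5
    train_accuracy: float = np.nan
    val_accuracy: float = np.nan

    @property
    def mean_prob(self) -> float:
        return float(np.mean(self.epoch_probs))

    @property
    def predicted_label(self) -> str:
        # exact tie at the cutoff resolves to "case" (favouring sensitivity)
        return "case" if self.mean_prob >= self.cutoff else "control"

    @property
    def tie(self) -> bool:
        return self.mean_prob == self.cutoff

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


def make_loso_datasets(table: pd.DataFrame, features, seed: int = 0,
                       val_fraction: float = 0.2):
    """One dataset per subject: 80/20 row-level train/val split of the
    remaining subjects' rows, scaler fitted on the train rows only."""
    subjects = table["subject_id"].unique().tolist()
    groups = table.groupby("subject_id", sort=False)["group"].first()
    if min((groups == g).sum() for g in ("case", "control")) < 2:
        raise ValueError("need at least 2 subjects per class")
    counts = table.groupby("subject_id").size()
    empty = [s for s in subjects if counts.get(s, 0) == 0]
    if empty:
        raise ValueError(f"subjects without rows: {empty}")
    rng = np.random.default_rng(seed)
    X = table[list(features)].to_numpy(dtype=float)
    datasets = []
    for sid in subjects:
        is_test = (table["subject_id"] == sid).to_numpy()
        test_rows = np.flatnonzero(is_test)
        rest = np.flatnonzero(~is_test)
        perm = rng.permutation(len(rest))
        n_val = int(round(val_fraction * len(rest)))
        val_rows = rest[perm[:n_val]]
        train_rows = rest[perm[n_val:]]
        mean = X[train_rows].mean(axis=0)
        sd = X[train_rows].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        ds = LOSODataset(sid, train_rows, val_rows, test_rows, mean, sd)
        ds.assert_no_leakage(table)
        datasets.append(ds)
    return datasets


class LOSOResults:
    """Fit results: per-subject diagnoses plus cohort-level evaluation."""

    def __init__(self, model: "LOSOClassifier", diagnoses):
        self.model = model
        self.diagnoses = list(diagnoses)

    # ------------------------------------------------------------------
    @property
    def confusion(self) -> ev.ConfusionTable:
        tp = sum(d.true_label == "case" and d.predicted_label == "case"
                 for d in self.diagnoses)
        fn = sum(d.true_label == "case" and d.predicted_label == "control"
                 for d in self.diagnoses)
        tn = sum(d.true_label == "control" and d.predicted_label == "control"
                 for d in self.diagnoses)
        fp = sum(d.true_label == "control" and d.predicted_label == "case"
                 for d in self.diagnoses)
        return ev.ConfusionTable(tp, tn, fp, fn)

    @property
    def subject_accuracy(self) -> float:
        return float(np.mean([d.correct for d in self.diagnoses]))

    def metrics(self, ci_level: float = 0.95) -> dict:
        """Acc/Se/Sp (percent) with Wald confidence intervals."""
        ct = self.confusion
        out = ev.confusion_metrics(ct, percent=True)
        n_pos, n_neg, n = ct.TP + ct.FN, ct.TN + ct.FP, ct.N
        out["Se_CI"] = ev.wald_ci(ct.TP, n_pos, ci_level) if n_pos else None
        out["Sp_CI"] = ev.wald_ci(ct.TN, n_neg, ci_level) if n_neg else None
        out["Acc_CI"] = ev.wald_ci(ct.TP + ct.TN, n, ci_level)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "subject_id": d.subject_id,
            "true_label": d.true_label,
            "predicted_label": d.predicted_label,
            "mean_prob": d.mean_prob,
            "n_epoch_rows": len(d.epoch_probs),
            "train_accuracy": d.train_accuracy,
            "val_accuracy": d.val_accuracy,
        } for d in self.diagnoses]
        return pd.DataFrame(rows)

    def mean_prob_intervals(self, level: float = 0.999) -> pd.DataFrame:
        """Normal-theory CIs for each subject's mean epoch probability."""
        rows = []
        for d in self.diagnoses:
            lo, hi = ev.mean_prob_ci(d.epoch_probs, level)
            rows.append((d.subject_id, d.mean_prob, lo, hi))
        return pd.DataFrame(rows, columns=["subject_id", "mean_prob", "lo", "hi"])

    def credible_intervals(self, level: float = 0.999, prior=(1.0, 1.0),
                           cutoff: float = 0.5) -> pd.DataFrame:
        """Beta-posterior credible intervals on the per-subject proportion
        of epochs predicted as case."""
        rows = []
        for d in self.diagnoses:
            k = int(np.sum(d.epoch_probs >= cutoff))
            n = len(d.epoch_probs)
            lo, hi = ev.beta_credible_interval(k, n, prior, level)
            rows.append((d.subject_id, k, n, lo, hi))
        return pd.DataFrame(rows, columns=["subject_id", "k_case_epochs",
                                           "n_epochs", "lo", "hi"])

    def summary(self) -> str:
        ct = self.confusion
        m = self.metrics()
        lines = [
            "Leave-one-subject-out diagnosis summary",
            "=" * 47,
            f"subjects: {len(self.diagnoses)}   feature columns: "
            f"{len(self.model.features)}",
            f"confusion: TP={ct.TP} FN={ct.FN} TN={ct.TN} FP={ct.FP}",
            f"sensitivity: {m['Se']:6.2f}%  CI {_fmt_ci(m['Se_CI'])}",
            f"specificity: {m['Sp']:6.2f}%  CI {_fmt_ci(m['Sp_CI'])}",
            f"accuracy:    {m['Acc']:6.2f}%  CI {_fmt_ci(m['Acc_CI'])}",
            "-" * 47,
        ]
        for d in self.diagnoses:
            flag = " *tie*" if d.tie else ("" if d.correct else "  <-- wrong")
            lines.append(f"{d.subject_id:>8}  {d.true_label:>8} -> "
                         f"{d.predicted_label:<8} mean_prob={d.mean_prob:.3f}{flag}")
        return "\n".join(lines)


def _fmt_ci(ci):
    return "n/a" if ci is None else f"[{ci[0]:.2f}, {ci[1]:.2f}]"


class LOSOClassifier:
    """Feedforward-network diagnosis model under LOSO validation.

    Parameters
    ----------
    table : DataFrame
        Feature table with metadata columns (subject_id, group, ...) and
        feature columns.
    features : sequence of str, optional
        Feature columns to use; defaults to every non-metadata column.
    spec : FNNSpec
        Network architecture and training settings.
    """

    def __init__(self, table: pd.DataFrame, features=None,
                 spec: FNNSpec = FNNSpec()):
        self.table = table.reset_index(drop=True)
        self.features = list(features) if features is not None \
            else feature_columns(self.table)
        if not self.features:
            raise ValueError("feature table has no feature columns")
        self.spec = spec

    @classmethod
    def from_tables(cls, tables, spec: FNNSpec = FNNSpec()):
        """Join several feature tables (same rows, different features)."""
        base = tables[0]
        for t in tables[1:]:
            feats = [c for c in t.columns if c not in META_COLUMNS]
            base = pd.concat([base.reset_index(drop=True),
                              t[feats].reset_index(drop=True)], axis=1)
        return cls(base, spec=spec)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, cutoff: float = 0.5,
            progress: bool = False) -> LOSOResults:
        """Train one net per held-out subject and diagnose every subject."""
        table = self.table
        datasets = make_loso_datasets(table, self.features, seed)
        y = (table["group"] == "case").to_numpy(dtype=float)
        X = table[self.features].to_numpy(dtype=float)
        diagnoses = []
        for k, ds in enumerate(datasets):
            ds.assert_no_leakage(table)
            diagnoses.append(self._fit_one(ds, X, y, seed + 1000 * (k + 1),
                                           cutoff))
            if progress:
                d = diagnoses[-1]
                print(f"[{k + 1}/{len(datasets)}] {d.subject_id}: "
                      f"val_acc={d.val_accuracy:.3f} mean_prob={d.mean_prob:.3f}")
        return LOSOResults(self, diagnoses)

    def _fit_one(self, ds: LOSODataset, X, y, seed, cutoff) -> DiagnosisResult:
        scale = lambda A: (A - ds.scaler_mean) / ds.scaler_sd
        if len(np.unique(y[ds.train_rows])) < 2:
            raise ValueError(
                f"dataset {ds.test_subject_id}: single-class training rows")
        if len(ds.test_rows) == 0:
            raise ValueError(f"dataset {ds.test_subject_id}: no test rows")
        net = FNN(len(self.features), self.spec, seed=seed)
        net.fit(scale(X[ds.train_rows]), y[ds.train_rows],
                scale(X[ds.val_rows]), y[ds.val_rows])
        probs = net.predict_proba(scale(X[ds.test_rows]))
        true_label = self.table.loc[ds.test_rows[0], "group"]
        return DiagnosisResult(ds.test_subject_id, probs, true_label, cutoff,
                               net.history.get("train_accuracy", np.nan),
                               net.history.get("val_accuracy", np.nan))

    # ------------------------------------------------------------------
    def random_label_test(self, seed: int = 0, cutoff: float = 0.5,
                          identity: bool = False) -> LOSOResults:
        """Re-run LOSO after permuting the subject-level group labels.

        A control for spurious signal: with labels shuffled, subject-level
        LOSO accuracy should be near chance.  ``identity=True`` applies
        the identity permutation (then the run equals ``fit``).
        """
        rng = np.random.default_rng(seed)
        subjects = self.table["subject_id"].unique()
        labels = self.table.groupby("subject_id", sort=False)["group"].first()
        perm = np.arange(len(subjects)) if identity else rng.permutation(len(subjects))
        mapping = {sid: labels.iloc[perm[i]] for i, sid in enumerate(subjects)}
        shuffled = self.table.copy()
        shuffled["group"] = shuffled["subject_id"].map(mapping)
        clone = LOSOClassifier(shuffled, self.features, self.spec)
        results = clone.fit(seed=seed, cutoff=cutoff)
        results.label_mapping = mapping  # the permutation actually applied
        return results
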