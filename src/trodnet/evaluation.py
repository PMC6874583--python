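"""Subject-exclusive cross-validation, aggregation, and group statistics.

The unit of generalization is the subject: folds partition *subjects*
(class-stratified, k = 10), every observation of a subject lies on exactly
one side of each split, and a leakage audit runs on every execution. A
subject's 36 single-trial predictions are aggregated by majority: the
subject is called concussed iff strictly more than 50% of their trials are
classified concussed (a tie counts as control).

Longitudinal (second-session) observations are never trained on: each
returning subject's follow-up trials are evaluated by the model from the
fold in which that subject was a *test* subject, so the training set is
identical across the subject's two test dates.

The longitudinal accuracies feed a two-way mixed (split-plot) ANOVA with
Recovery (between subjects) and Testing Date (within subjects) as factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


from .assembly import DatasetTensor, Standardizer
from .model import ModelConfig, TRODNet, build_model, train

logger = logging.getLogger(__name__)

CONTROL_LABEL = 0
CONCUSSED_LABEL = 1


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldPlan:
    """Class-stratified subject-level partition into k folds."""

    folds: tuple  # tuple of tuples of subject ids
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def all_subjects(self) -> set:
        return {s for fold in self.folds for s in fold}

    def fold_of(self, subject_id) -> int:
        for i, fold in enumerate(self.folds):
            if subject_id in fold:
                return i
        raise KeyError(f"subject {subject_id} has no fold assignment")


def make_folds(subject_ids, labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition at the subject level.

    Each class is shuffled (seeded) and dealt round-robin across folds with
    a pointer that continues between classes, so per-fold counts of every
    class — and fold sizes overall — differ by at most one. Unlike
    scikit-learn's ``StratifiedKFold`` this accepts classes with fewer than
    k members, which small cohorts need. Deterministic under seed.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if subject_ids.size < k:
        raise ValueError(f"need at least k={k} subjects, got {subject_ids.size}")
    if subject_ids.size != np.unique(subject_ids).size:
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    pointer = 0
    for cls in np.unique(labels):
        members = subject_ids[labels == cls]
        for sid in rng.permutation(members):
            folds[pointer % k].append(sid)
            pointer += 1
    return FoldPlan(folds=tuple(tuple(f) for f in folds), seed=seed)


def audit_no_leakage(plan: FoldPlan, tensor: DatasetTensor) -> None:
    """Raise if the plan does not cleanly partition the tensor's subjects."""
    seen: dict = {}
    for i, fold in enumerate(plan.folds):
        for s in fold:
            if s in seen:
                raise RuntimeError(
                    f"subject {s} assigned to folds {seen[s]} and {i}: leakage"
                )
            seen[s] = i
    missing = set(tensor.subject_ids) - set(seen)
    if missing:
        raise RuntimeError(f"subjects without fold assignment: {sorted(missing)}")


# ---------------------------------------------------------------------------
# aggregation and confusion metrics


def aggregate_subject(trial_labels) -> int:
    """Majority rule: concussed iff > 50% of trials are labelled concussed."""
    trial_labels = np.asarray(trial_labels)
    if trial_labels.size == 0:
        raise ValueError("no trial labels to aggregate")
    frac = float((trial_labels == CONCUSSED_LABEL).mean())
    return CONCUSSED_LABEL if frac > 0.5 else CONTROL_LABEL


@dataclass
class SubjectPrediction:
    subject_id: str
    true_label: int
    probabilities: np.ndarray  # (n_trials, 2)
    trial_labels: np.ndarray  # (n_trials,)
    session: str = "first"

    @property
    def concussed_fraction(self) -> float:
        return float((self.trial_labels == CONCUSSED_LABEL).mean())

    @property
    def trial_accuracy(self) -> float:
        """Fraction of trials predicted as the subject's (first-test) class."""
        return float((self.trial_labels == self.true_label).mean())

    @property
    def aggregated_label(self) -> int:
        return aggregate_subject(self.trial_labels)


@dataclass
class ConfusionSummary:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        if total == 0:
            return float("nan")
        return (self.tp + self.tn) / total

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionSummary:
    """Subject-level confusion summary from raw counts."""
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


def summarize_subject_predictions(preds: list) -> ConfusionSummary:
    tp = sum(1 for p in preds if p.true_label == 1 and p.aggregated_label == 1)
    fn = sum(1 for p in preds if p.true_label == 1 and p.aggregated_label == 0)
    tn = sum(1 for p in preds if p.true_label == 0 and p.aggregated_label == 0)
    fp = sum(1 for p in preds if p.true_label == 0 and p.aggregated_label == 1)
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    predictions: list  # first-test SubjectPredictions
    confusion: ConfusionSummary
    trial_accuracy: float  # pooled over all first-test observations
    fold_plan: FoldPlan
    longitudinal_predictions: list = field(default_factory=list)
    fold_models: dict = field(default_factory=dict)  # fold index -> TRODNet

    @property
    def subject_accuracy(self) -> float:
        return self.confusion.accuracy

    def per_subject_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": p.subject_id,
                "group": "concussed" if p.true_label else "control",
                "session": p.session,
                "trial_accuracy": p.trial_accuracy,
                "concussed_fraction": p.concussed_fraction,
                "aggregated_label": p.aggregated_label,
            }
            for p in self.predictions + self.longitudinal_predictions
        ]
        return pd.DataFrame(rows)


def _predict_subjects(
    model: TRODNet, std: Standardizer, tensor: DatasetTensor, session: str
) -> list:
    preds = []
    Z = std.transform(tensor)
    proba = model.predict_proba(Z.X)
    labels = proba.argmax(axis=1)
    for sid in tensor.subject_ids:
        mask = tensor.subjects == sid
        preds.append(
            SubjectPrediction(
                subject_id=str(sid),
                true_label=tensor.subject_label(sid),
                probabilities=proba[mask],
                trial_labels=labels[mask],
                session=session,
            )
        )
    return preds


def run_cv(
    tensor: DatasetTensor,
    config: ModelConfig | None = None,
    fold_plan: FoldPlan | None = None,
    seed: int = 0,
    k: int = 10,
    second_tensor: DatasetTensor | None = None,
    keep_models: bool = False,
) -> CVResult:
    """Subject-exclusive stratified k-fold cross-validation.

    Per fold: fit the standardizer on the training split only, train a
    fresh model, and predict the held-out subjects' observations. If
    ``second_tensor`` holds follow-up observations, each returning
    subject's second-session trials are evaluated by the same fold model
    that tested the subject's first session (no training on follow-up
    data). Each subject is predicted exactly once per session.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    subject_ids = tensor.subject_ids
    subj_labels = np.array([tensor.subject_label(s) for s in subject_ids])
    if fold_plan is None:
        fold_plan = make_folds(subject_ids, subj_labels, k=k, seed=int(rng.integers(2**31)))
    audit_no_leakage(fold_plan, tensor)

    if second_tensor is not None:
        unknown = set(second_tensor.subject_ids) - set(subject_ids.tolist())
        if unknown:
            raise RuntimeError(
                f"second-test subjects without a fold assignment: {sorted(unknown)}"
            )

    all_preds: list = []
    second_preds: list = []
    fold_models: dict = {}
    for i, test_subjects in enumerate(fold_plan.folds):
        train_subjects = [s for s in subject_ids if s not in set(test_subjects)]
        overlap = set(train_subjects) & set(test_subjects)
        if overlap:
            raise RuntimeError(f"leakage: subjects {overlap} in both splits")
        train_t = tensor.subset(train_subjects)
        test_t = tensor.subset(test_subjects)
        std = Standardizer().fit(train_t)
        model = build_model(config, seed=int(rng.integers(2**31)))
        train(model, std.transform(train_t).X, train_t.labels, seed=int(rng.integers(2**31)))
        preds = _predict_subjects(model, std, test_t, session=tensor.session)
        all_preds.extend(preds)
        if second_tensor is not None:
            returning = [
                s for s in test_subjects if s in set(second_tensor.subject_ids.tolist())
            ]
            if returning:
                second_preds.extend(
                    _predict_subjects(
                        model, std, second_tensor.subset(returning), session="second"
                    )
                )
        if keep_models:
            fold_models[i] = (model, std)
        logger.info("fold %d/%d done (%d test subjects)", i + 1, fold_plan.k, len(test_subjects))

    confusion = summarize_subject_predictions(all_preds)
    # pooled single-trial accuracy = observation-count-weighted subject mean
    trial_acc = float(
        sum(p.trial_accuracy * p.trial_labels.size for p in all_preds)
        / sum(p.trial_labels.size for p in all_preds)
    )
    return CVResult(
        predictions=all_preds,
        confusion=confusion,
        trial_accuracy=trial_acc,
        fold_plan=fold_plan,
        longitudinal_predictions=second_preds,
        fold_models=fold_models,
    )


def evaluate_longitudinal(
    cv_result: CVResult, second_tensor: DatasetTensor, recovery: dict | None = None
) -> pd.DataFrame:
    """Per-returning-subject table of first- and second-test results.

    Requires ``run_cv(..., keep_models=True)``; each subject's follow-up
    observations are scored by the fold model that held that subject out.
    ``recovery`` optionally maps subject id -> "SR"/"NSR". Trial accuracy
    at both dates is computed against the subject's first-test label.
    """
    if not cv_result.fold_models:
        raise ValueError("run_cv must be called with keep_models=True")
    first = {p.subject_id: p for p in cv_result.predictions}
    rows = []
    for sid in second_tensor.subject_ids:
        sid = str(sid)
        if sid not in first:
            raise KeyError(f"subject {sid} was not evaluated at the first test")
        fold = cv_result.fold_plan.fold_of(sid)
        model, std = cv_result.fold_models[fold]
        (pred2,) = _predict_subjects(
            model, std, second_tensor.subset([sid]), session="second"
        )
        p1 = first[sid]
        rows.append(
            {
                "subject_id": sid,
                "recovery": (recovery or {}).get(sid, ""),
                "accuracy_t1": p1.trial_accuracy,
                "accuracy_t2": float(
                    (pred2.trial_labels == p1.true_label).mean()
                ),
                "concussed_fraction_t1": p1.concussed_fraction,
                "concussed_fraction_t2": pred2.concussed_fraction,
                "aggregated_t2": pred2.aggregated_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA


def _split_plot_anova(df: pd.DataFrame, ss_type: int) -> pd.DataFrame:
    """Explicit split-plot sums of squares (one between factor, two dates).

    Used for Type-III (unweighted means for the within-factor main effect);
    also exposes the Type-II (weighted grand mean) path.
    """
    groups = df["recovery"].unique()
    if len(groups) != 2:
        raise ValueError("exactly two recovery groups required")
    a = df[df["recovery"] == groups[0]]
    b = df[df["recovery"] == groups[1]]
    n1, n2 = len(a), len(b)
    n = n1 + n2
    d = np.concatenate([a["accuracy_t2"] - a["accuracy_t1"], b["accuracy_t2"] - b["accuracy_t1"]])
    s = np.concatenate([a["accuracy_t2"] + a["accuracy_t1"], b["accuracy_t2"] + b["accuracy_t1"]])
    d1, d2 = d[:n1], d[n1:]
    s1, s2 = s[:n1], s[n1:]

    sse_s = ((s1 - s1.mean()) ** 2).sum() + ((s2 - s2.mean()) ** 2).sum()
    ss_rec = ((s - s.mean()) ** 2).sum() - sse_s
    sse_d = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
    ss_int = ((d - d.mean()) ** 2).sum() - sse_d
    if ss_type == 2:
        ss_date = n * d.mean() ** 2
    else:  # unweighted marginal mean
        ss_date = ((d1.mean() + d2.mean()) / 2) ** 2 / ((1 / n1 + 1 / n2) / 4)
    # halve all within/between SS consistently (sum/diff scores carry factor 2);
    # F ratios are unaffected, so use the raw ratios directly
    from scipy import stats

    df2 = n - 2
    out = []
    for name, ss, err in (
        ("recovery", ss_rec, sse_s),
        ("date", ss_date, sse_d),
        ("interaction", ss_int, sse_d),
    ):
        F = ss / (err / df2)
        out.append(
            {
                "effect": name,
                "F": float(F),
                "df1": 1,
                "df2": df2,
                "p": float(stats.f.sf(F, 1, df2)),
            }
        )
    return pd.DataFrame(out)


def mixed_anova(table: pd.DataFrame, ss_type: int = 2) -> pd.DataFrame:
    """Two-way mixed ANOVA on per-subject accuracies.

    ``table`` needs columns ``subject_id``, ``recovery`` (two levels),
    ``accuracy_t1`` and ``accuracy_t2``. Returns F(1, n-2), and p for the
    between factor (Recovery), the within factor (Testing Date), and their
    interaction. The default Type-II computation delegates to pingouin's
    mixed ANOVA; Type III (``ss_type=3``) uses the explicit split-plot
    projections, which weight the two groups equally in the within-factor
    main effect.
    """
    required = {"subject_id", "recovery", "accuracy_t1", "accuracy_t2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = table["recovery"].value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need two recovery groups with at least 2 subjects each")
    if table["subject_id"].duplicated().any():
        raise ValueError("one row per subject required (both dates in columns)")

    if ss_type == 3:
        return _split_plot_anova(table, ss_type=3)

    import pingouin as pg

    long = table.melt(
        id_vars=["subject_id", "recovery"],
        value_vars=["accuracy_t1", "accuracy_t2"],
        var_name="date",
        value_name="accuracy",
    )
    res = pg.mixed_anova(
        data=long,
        dv="accuracy",
        within="date",
        subject="subject_id",
        between="recovery",
    )
    res = res.rename(columns={"Source": "effect", "DF1": "df1", "DF2": "df2", "p_unc": "p"})
    res["effect"] = res["effect"].map(
        {"recovery": "recovery", "date": "date", "Interaction": "interaction"}
    )
    return res[["effect", "F", "df1", "df2", "p"]]
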