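"""Per-timepoint orientation decoding with the orthogonal-pair scheme.

The cued and uncued orientations of a presentation are never informative
about each other: the 4 analysable orientations split into two pairs
(22.5 vs 112.5 and 67.5 vs 157.5), decoding runs within a pair, and within
any pair the non-decoded colour's orientations are exactly balanced across
the two classes.  Each physical epoch therefore yields one trial for the
cued-orientation task and one for the uncued-orientation task, evaluated
independently.

The classifier is a regularised linear discriminant: the pooled within-class
covariance S is shrunk as ``S + lambda * mean(diag(S)) * I`` (lambda = 0.01)
before inverting.  Cross-validation leaves one sequence out at a time, so
temporally correlated noise within a sequence can never leak between train
and test.  Features at each timepoint are the channel vector at that
timepoint; accuracies are pooled over folds (total correct / total tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUP1_ORIENTATIONS, GROUP2_ORIENTATIONS
from .preprocess import EpochSet

DEFAULT_LAMBDA: float = 0.01

ATTENTION_ROLES = ("cued", "uncued")
ISI_FILTERS = ("all", "constant", "varied")


@dataclass(frozen=True)
class DecodingTask:
    """One decoding problem: which orientation pair, read from which role."""

    attention_role: str  # "cued" or "uncued"
    analysis_group: int  # 1 or 2
    isi_filter: str = "all"

    def __post_init__(self) -> None:
        if self.attention_role not in ATTENTION_ROLES:
            raise ValueError(f"unknown attention role: {self.attention_role!r}")
        if self.analysis_group not in (1, 2):
            raise ValueError("analysis_group must be 1 or 2")
        if self.isi_filter not in ISI_FILTERS:
            raise ValueError(f"unknown ISI filter: {self.isi_filter!r}")

    @property
    def class_labels(self) -> tuple[float, float]:
        """The two decoded orientations.

        Trials of analysis group 1 show cued orientations 22.5/112.5 and
        uncued orientations 67.5/157.5; group 2 is the mirror image.
        """
        group_is_one = self.analysis_group == 1
        cued_task = self.attention_role == "cued"
        if group_is_one == cued_task:
            return GROUP1_ORIENTATIONS
        return GROUP2_ORIENTATIONS

    @property
    def label_column(self) -> str:
        return (
            "cued_orientation"
            if self.attention_role == "cued"
            else "uncued_orientation"
        )


@dataclass
class DecodingTimecourse:
    """Per-timepoint cross-validated accuracy for one participant and task."""

    participant_id: str
    attention_role: str
    analysis_group: int | str  # 1, 2, or "avg"
    isi_filter: str
    times_ms: np.ndarray
    accuracy: np.ndarray
    n_test_per_fold: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(sum(self.n_test_per_fold))


def fit_predict_lda(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Regularised LDA on a single timepoint's channel vectors.

    The discriminant is ``w = S_r^{-1} (mu1 - mu0)`` with
    ``S_r = S + lam * mean(diag(S)) * I``; the decision threshold is the
    midpoint of the projected class means (equal priors).  Deterministic.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if classes.size != 2:
        raise ValueError("training data must contain exactly 2 classes")
    x0 = train_X[train_y == classes[0]]
    x1 = train_X[train_y == classes[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each class needs at least 2 training trials")
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    scatter = (x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)
    s = scatter / (len(x0) + len(x1) - 2)
    s_r = s + lam * np.mean(np.diag(s)) * np.eye(s.shape[0])
    w = np.linalg.solve(s_r, mu1 - mu0)
    threshold = w @ (mu0 + mu1) / 2.0
    return np.where(np.asarray(test_X, dtype=float) @ w > threshold,
                    classes[1], classes[0])


def _task_trials(
    epochs: EpochSet, task: DecodingTask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    meta = epochs.metadata
    mask = (meta["analysable"] == 1) & meta[task.label_column].isin(
        task.class_labels
    )
    if task.isi_filter != "all":
        mask &= meta["isi_condition"] == task.isi_filter
    mask = mask.to_numpy()
    x = epochs.data[mask]
    labels = meta.loc[mask, task.label_column].to_numpy(dtype=float)
    y = (labels == task.class_labels[1]).astype(int)
    seq = meta.loc[mask, "sequence_id"].to_numpy()
    for c, lab in enumerate(task.class_labels):
        if (y == c).sum() == 0:
            raise ValueError(
                f"no trials for class {lab} in task {task}"
            )
    return x, y, seq


def training_label_balance(
    epochs: EpochSet, task: DecodingTask
) -> list[pd.DataFrame]:
    """Per training fold, the cross-table of decoded class x other-colour
    orientation — used to audit that the non-decoded feature is uninformative
    (counts identical across classes in the balanced design)."""
    meta = epochs.metadata
    mask = (meta["analysable"] == 1) & meta[task.label_column].isin(
        task.class_labels
    )
    if task.isi_filter != "all":
        mask &= meta["isi_condition"] == task.isi_filter
    sub = meta[mask]
    other = (
        "uncued_orientation"
        if task.attention_role == "cued"
        else "cued_orientation"
    )
    tables = []
    for held_out in np.unique(sub["sequence_id"]):
        train = sub[sub["sequence_id"] != held_out]
        tables.append(
            pd.crosstab(train[task.label_column], train[other])
        )
    return tables


def decode_task(
    epochs: EpochSet, task: DecodingTask, lam: float = DEFAULT_LAMBDA
) -> DecodingTimecourse:
    """Leave-one-sequence-out decoding of one task, all timepoints at once.

    Equivalent to calling :func:`fit_predict_lda` per fold and timepoint
    (asserted in the test suite) but computed from pooled per-class sums and
    second moments with the held-out sequence subtracted, which costs two
    passes over the data instead of one per fold.
    """
    x, y, seq = _task_trials(epochs, task)
    fold_ids = np.unique(seq)
    if fold_ids.size < 2:
        raise ValueError("leave-one-sequence-out needs at least 2 sequences")
    n_trials, n_ch, n_t = x.shape

    sums = np.zeros((2, n_ch, n_t))
    m2 = np.zeros((2, n_ch, n_ch, n_t))
    counts = np.zeros(2, dtype=int)
    for c in (0, 1):
        xc = x[y == c]
        counts[c] = len(xc)
        sums[c] = xc.sum(axis=0)
        m2[c] = np.einsum("ict,idt->cdt", xc, xc, optimize=True)

    eye = np.eye(n_ch)
    correct = np.zeros(n_t)
    total = 0
    n_test_per_fold = []
    for held_out in fold_ids:
        te = seq == held_out
        mus = np.empty((2, n_t, n_ch))
        scatter = np.zeros((n_t, n_ch, n_ch))
        n_train = np.zeros(2, dtype=int)
        for c in (0, 1):
            xc_te = x[te & (y == c)]
            n_train[c] = counts[c] - len(xc_te)
            if n_train[c] < 2:
                raise ValueError(
                    f"class {task.class_labels[c]} has fewer than 2 training "
                    f"trials in fold {held_out}"
                )
            sum_tr = sums[c] - xc_te.sum(axis=0)
            m2_tr = m2[c] - np.einsum("ict,idt->cdt", xc_te, xc_te, optimize=True)
            mu = sum_tr / n_train[c]  # (ch, t)
            mus[c] = mu.T
            scatter += np.transpose(
                m2_tr - n_train[c] * np.einsum("ct,dt->cdt", mu, mu),
                (2, 0, 1),
            )
        s = scatter / (n_train.sum() - 2)
        trace_mean = np.einsum("tcc->t", s) / n_ch
        s_r = s + (lam * trace_mean)[:, None, None] * eye
        w = np.linalg.solve(s_r, (mus[1] - mus[0])[..., None])[..., 0]  # (t, ch)
        threshold = np.einsum("tc,tc->t", w, (mus[0] + mus[1]) / 2.0)
        logits = np.einsum("tc,ict->it", w, x[te]) - threshold[None, :]
        correct += ((logits > 0).astype(int) == y[te][:, None]).sum(axis=0)
        total += int(te.sum())
        n_test_per_fold.append(int(te.sum()))

    return DecodingTimecourse(
        participant_id=str(epochs.metadata.get("participant_id", pd.Series(["?"])).iloc[0]),
        attention_role=task.attention_role,
        analysis_group=task.analysis_group,
        isi_filter=task.isi_filter,
        times_ms=epochs.times_ms.copy(),
        accuracy=correct / total,
        n_test_per_fold=n_test_per_fold,
    )


def average_analysis_groups(
    tc_group1: DecodingTimecourse, tc_group2: DecodingTimecourse
) -> DecodingTimecourse:
    """Pointwise mean of the two analysis groups' accuracy curves, so that
    chance stays at 50%."""
    same = (
        tc_group1.participant_id == tc_group2.participant_id
        and tc_group1.attention_role == tc_group2.attention_role
        and tc_group1.isi_filter == tc_group2.isi_filter
        and np.array_equal(tc_group1.times_ms, tc_group2.times_ms)
    )
    if not same:
        raise ValueError("timecourses differ in participant, task or time axis")
    return DecodingTimecourse(
        participant_id=tc_group1.participant_id,
        attention_role=tc_group1.attention_role,
        analysis_group="avg",
        isi_filter=tc_group1.isi_filter,
        times_ms=tc_group1.times_ms.copy(),
        accuracy=(tc_group1.accuracy + tc_group2.accuracy) / 2.0,
        n_test_per_fold=[
            a + b
            for a, b in zip(
                tc_group1.n_test_per_fold, tc_group2.n_test_per_fold
            )
        ],
    )


def run_all_conditions(
    epochs: EpochSet, participant_id: str, lam: float = DEFAULT_LAMBDA
) -> pd.DataFrame:
    """All pair-averaged accuracy curves and derived contrasts for one
    participant.

    Returns a tidy table with columns participant, measure, isi_condition,
    time_ms, value, n_test.  Measures: ``cued`` and ``uncued`` accuracy per
    ISI filter (all/constant/varied; 6 curves), ``attention`` = cued - uncued
    per ISI filter (3 curves), and ``expectation`` = constant - varied
    averaged over the cued and uncued conditions (1 curve).
    """
    curves: dict[tuple[str, str], DecodingTimecourse] = {}
    for role in ATTENTION_ROLES:
        for isi in ISI_FILTERS:
            tcs = [
                decode_task(
                    epochs,
                    DecodingTask(role, group, isi),
                    lam=lam,
                )
                for group in (1, 2)
            ]
            avg = average_analysis_groups(tcs[0], tcs[1])
            avg.participant_id = str(participant_id)
            curves[(role, isi)] = avg

    times = curves[("cued", "all")].times_ms
    rows = []

    def add(measure, isi, values, n_test):
        for t, v in zip(times, values):
            rows.append(
                {
                    "participant": str(participant_id),
                    "measure": measure,
                    "isi_condition": isi,
                    "time_ms": float(t),
                    "value": float(v),
                    "n_test": int(n_test),
                }
            )

    for (role, isi), tc in curves.items():
        add(role, isi, tc.accuracy, tc.n_trials)
    for isi in ISI_FILTERS:
        diff = curves[("cued", isi)].accuracy - curves[("uncued", isi)].accuracy
        add("attention", isi, diff, curves[("cued", isi)].n_trials)
    expectation = (
        curves[("cued", "constant")].accuracy
        + curves[("uncued", "constant")].accuracy
        - curves[("cued", "varied")].accuracy
        - curves[("uncued", "varied")].accuracy
    ) / 2.0
    add("expectation", "all", expectation, curves[("cued", "constant")].n_trials)
    return pd.DataFrame(rows)
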