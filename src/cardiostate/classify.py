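"""Distance-based state classification with a learned metric.

Each subject-state is summarised by a named attribute vector drawn from
three subsets — mean values, wavelet band powers, and interaction
measures (coherence, synchronisation) — z-scored per attribute over the
training set.  The squared distance between two subjects is the
quadratic form ``D(x1, x2)^2 = (x1 - x2)^T A (x1 - x2)`` with a positive
symmetric matrix A; here A is restricted to a diagonal of non-negative
weights learned by maximising internal leave-one-subject-out
nearest-neighbour accuracy (ties broken toward the identity).  States
are assigned by the nearest neighbour in the learned metric; evaluation
uses repeated stratified hold-out or leave-one-subject-out
cross-validation, with both records of a held-out subject excluded from
training to prevent identity leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import CoherenceSpectrum
from .errors import (
    ClassTooSmall,
    DimensionMismatch,
    EmptyTrainingSet,
    MissingAnalysis,
)
from .sync import SyncResult
from .timefreq import BandEnergyTable

__all__ = [
    "SubjectAnalysis",
    "FeatureTable",
    "DistanceMetric",
    "ConfusionMatrix",
    "EvaluationResult",
    "build_features",
    "distance",
    "learn_metric",
    "nn_classify",
    "evaluate_holdout",
    "evaluate_loocv",
    "attribute_cascade",
    "ATTRIBUTE_SUBSETS",
    "OPTIMAL12",
]

CLASS_ORDER = ["awake", "sevoflurane", "propofol", "anaesthetised"]

MEANS_SUBSET = [
    "heart_rate",
    "resp_rate",
    "skin_temperature",
    "skin_conductivity",
    "pulse_transit_time",
    "total_hrv_energy",
    "total_rfv_energy",
    "total_scond_energy",
    "total_temp_energy",
]
POWERS_SUBSET = [
    "hrv_energy_II",
    "hrv_energy_III",
    "hrv_energy_IV",
    "hrv_energy_V",
    "rfv_energy_III",
    "rfv_energy_IV",
    "rfv_energy_V",
    "scond_energy_III",
    "scond_energy_IV",
    "scond_energy_V",
    "scond_energy_VI",
    "temp_energy_III",
    "temp_energy_IV",
    "temp_energy_V",
    "temp_energy_VI",
]
INTERACTIONS_SUBSET = [
    "coh_hrv_scond_II",
    "coh_hrv_scond_III",
    "coh_hrv_scond_IV",
    "coh_scond_pulse_I",
    "coh_scond_pulse_III",
    "coh_scond_pulse_IV",
    "coh_scond_temp_I",
    "coh_scond_temp_II",
    "coh_pulse_temp_I",
    "sync_time",
    "sync_window_1n",
    "sync_window_2n",
]
# the 12 most discriminatory attributes (optimal reduced set)
OPTIMAL12 = [
    "resp_rate",
    "total_hrv_energy",
    "total_rfv_energy",
    "skin_temperature",
    "sync_time",
    "sync_window_1n",
    "sync_window_2n",
    "coh_pulse_temp_I",
    "hrv_energy_III",
    "hrv_energy_IV",
    "rfv_energy_V",
    "scond_energy_VI",
]
ATTRIBUTE_SUBSETS = {
    "means": MEANS_SUBSET,
    "powers": POWERS_SUBSET,
    "interactions": INTERACTIONS_SUBSET,
    "all": MEANS_SUBSET + POWERS_SUBSET + INTERACTIONS_SUBSET,
    "optimal12": OPTIMAL12,
}


@dataclass
class SubjectAnalysis:
    """Per-subject-state analysis results feeding the feature vector."""

    subject_id: str
    state: str  # awake | sevoflurane | propofol
    mean_heart_rate: float
    mean_resp_rate: float
    mean_temperature: float
    mean_conductivity: float
    mean_ptt: float
    band_energy: dict[str, BandEnergyTable]  # keyed hrv/rfv/scond/temp
    coherence: dict[str, CoherenceSpectrum]  # keyed "hrv_scond", "scond_pulse", ...
    sync: SyncResult


def build_features(analysis: SubjectAnalysis, subset: str = "all") -> pd.Series:
    """Assemble one named attribute vector from a subject-state analysis.

    Raises :class:`MissingAnalysis` naming the first attribute whose
    backing analysis is absent.
    """
    attrs = ATTRIBUTE_SUBSETS[subset]
    values: dict[str, float] = {}
    for attr in attrs:
        values[attr] = _extract_attribute(analysis, attr)
    s = pd.Series(values, name=(analysis.subject_id, analysis.state))
    return s


def _extract_attribute(a: SubjectAnalysis, attr: str) -> float:
    def band_table(kind: str) -> BandEnergyTable:
        if kind not in a.band_energy:
            raise MissingAnalysis(attr)
        return a.band_energy[kind]

    if attr == "heart_rate":
        return a.mean_heart_rate
    if attr == "resp_rate":
        return a.mean_resp_rate
    if attr == "skin_temperature":
        return a.mean_temperature
    if attr == "skin_conductivity":
        return a.mean_conductivity
    if attr == "pulse_transit_time":
        return a.mean_ptt
    if attr.startswith("total_") and attr.endswith("_energy"):
        return band_table(attr.removeprefix("total_").removesuffix("_energy")).total
    if "_energy_" in attr:
        kind, interval = attr.split("_energy_")
        table = band_table(kind)
        if interval not in table.energies:
            raise MissingAnalysis(attr)
        return table.energies[interval]
    if attr.startswith("coh_"):
        pair, interval = attr.removeprefix("coh_").rsplit("_", 1)
        if pair not in a.coherence:
            raise MissingAnalysis(attr)
        val = a.coherence[pair].band_mean(interval)
        if not np.isfinite(val):
            raise MissingAnalysis(attr)
        return val
    if attr == "sync_time":
        return a.sync.total_sync_time
    if attr == "sync_window_1n":
        return a.sync.window_1n
    if attr == "sync_window_2n":
        return a.sync.window_2n
    raise MissingAnalysis(attr)


@dataclass
class FeatureTable:
    """Feature matrix with state labels and subject identities."""

    X: pd.DataFrame  # rows: subject-states; columns: attributes
    state: np.ndarray
    subject: np.ndarray

    def __post_init__(self) -> None:
        if len(self.X) != len(self.state) or len(self.X) != len(self.subject):
            raise ValueError("X, state and subject must have equal length")
        self.state = np.asarray(self.state, dtype=object)
        self.subject = np.asarray(self.subject, dtype=object)

    @classmethod
    def from_rows(cls, rows: list[pd.Series], states: list[str], subjects: list[str]) -> "FeatureTable":
        return cls(X=pd.DataFrame(list(rows)).reset_index(drop=True), state=np.array(states, dtype=object), subject=np.array(subjects, dtype=object))

    @property
    def attributes(self) -> list[str]:
        return list(self.X.columns)

    def select(self, attrs: list[str]) -> "FeatureTable":
        return FeatureTable(X=self.X[attrs].copy(), state=self.state.copy(), subject=self.subject.copy())

    def take(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(X=self.X.iloc[idx].reset_index(drop=True), state=self.state[idx], subject=self.subject[idx])

    def merged_anaes(self) -> "FeatureTable":
        state = np.where(self.state == "awake", "awake", "anaesthetised")
        return FeatureTable(X=self.X.copy(), state=state.astype(object), subject=self.subject.copy())

    def sorted_canonical(self) -> "FeatureTable":
        """Order rows by (class order, subject id) for deterministic ties."""
        rank = np.array([CLASS_ORDER.index(s) for s in self.state])
        order = np.lexsort((self.subject.astype(str), rank))
        return self.take(order)


@dataclass
class DistanceMetric:
    """Diagonal positive symmetric metric: A = diag(weights)."""

    weights: np.ndarray
    attributes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("metric weights must be non-negative")

    @property
    def A(self) -> np.ndarray:
        return np.diag(self.weights)

    @classmethod
    def identity(cls, attributes: list[str]) -> "DistanceMetric":
        return cls(weights=np.ones(len(attributes)), attributes=list(attributes))


def distance(x1: np.ndarray, x2: np.ndarray, A: DistanceMetric | np.ndarray) -> float:
    """Squared distance ``(x1 - x2)^T A (x1 - x2)``."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise DimensionMismatch(f"{x1.shape} vs {x2.shape}")
    d = x1 - x2
    if isinstance(A, DistanceMetric):
        if A.weights.size != d.size:
            raise DimensionMismatch(f"metric dim {A.weights.size} vs vector dim {d.size}")
        return float(np.sum(A.weights * d * d))
    A = np.asarray(A, dtype=float)
    if A.shape != (d.size, d.size):
        raise DimensionMismatch(f"metric shape {A.shape} vs vector dim {d.size}")
    return float(d @ A @ d)


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


def _zscore_fit(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    mu = X.to_numpy().mean(axis=0)
    sd = X.to_numpy().std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _pairwise_sq_diffs(Z: np.ndarray) -> np.ndarray:
    """Per-attribute squared difference tensors, shape (d, n, n)."""
    return (Z[None, :, :].transpose(2, 1, 0) - Z.T[:, None, :]) ** 2


def _loso_accuracy(
    S: np.ndarray, y: np.ndarray, subjects: np.ndarray, weights: np.ndarray
) -> float:
    """Leave-one-subject-out NN accuracy given the squared-diff tensor.

    Rows/columns must already be in canonical (class order, subject) order
    so that ``argmin`` realises the declared tie-break.
    """
    D = np.tensordot(weights, S, axes=1)
    same = subjects[:, None] == subjects[None, :]
    D = np.where(same, np.inf, D)
    pred = y[np.argmin(D, axis=1)]
    return float(np.mean(pred == y))


def learn_metric(train: FeatureTable, seed: int = 0) -> DistanceMetric:
    """Learn non-negative diagonal metric weights on z-scored attributes.

    Coordinate-wise search over a logarithmic weight grid (plus exact
    zero), objective = internal leave-one-subject-out nearest-neighbour
    accuracy, ties broken toward the identity weight 1.  The search
    starts from the identity, so the learned metric never scores below
    the identity on its own training set.  Weights are normalised to
    trace = dimension.
    """
    classes, counts = np.unique(train.state, return_counts=True)
    if counts.min() < 4:
        raise ClassTooSmall(f"need >= 4 subjects per class, got {dict(zip(classes, counts))}")
    ft = train.sorted_canonical()
    mu, sd = _zscore_fit(ft.X)
    Z = (ft.X.to_numpy() - mu) / sd
    S = _pairwise_sq_diffs(Z)
    y, subjects = ft.state, ft.subject
    d = Z.shape[1]

    grid = np.array([0.0, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0, 16.0])
    # distance from identity used for tie-breaking (0 is "furthest")
    tie_cost = np.where(grid > 0, np.abs(np.log2(np.where(grid > 0, grid, 1.0))), np.inf)
    tie_cost[grid == 1.0] = 0.0

    rng = np.random.default_rng(seed)
    w = np.ones(d)
    best_acc = _loso_accuracy(S, y, subjects, w)
    for _ in range(2):
        improved = False
        for k in rng.permutation(d):
            cur_g = int(np.flatnonzero(grid == w[k])[0])
            cand_acc = np.full(grid.size, -1.0)
            for g, val in enumerate(grid):
                w_try = w.copy()
                w_try[k] = val
                if w_try.sum() > 0:
                    cand_acc[g] = _loso_accuracy(S, y, subjects, w_try)
            top = int(np.lexsort((tie_cost, -cand_acc))[0])
            better = cand_acc[top] > best_acc or (
                cand_acc[top] == best_acc and tie_cost[top] < tie_cost[cur_g]
            )
            if better and top != cur_g:
                w[k] = grid[top]
                best_acc = cand_acc[top]
                improved = True
        if not improved:
            break
    if w.sum() > 0:
        w = w * d / w.sum()
    return DistanceMetric(weights=w, attributes=ft.attributes)


def nn_classify(
    x: np.ndarray | pd.Series, train: FeatureTable, A: DistanceMetric
) -> str:
    """Label of the nearest training vector under the metric.

    Equidistant neighbours resolve by class order (awake < sevoflurane <
    propofol) then subject id.
    """
    if len(train.X) == 0:
        raise EmptyTrainingSet("no training vectors")
    ft = train.sorted_canonical()
    xv = np.asarray(x, dtype=float)
    dists = np.array([distance(xv, row, A) for row in ft.X.to_numpy()])
    return str(ft.state[int(np.argmin(dists))])


@dataclass
class ConfusionMatrix:
    """Actual (rows) vs predicted (columns) counts and row-percentages."""

    counts: pd.DataFrame

    @property
    def row_percent(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0) * 100.0

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.trace(self.counts.to_numpy()) / total) if total else float("nan")


@dataclass
class EvaluationResult:
    accuracy: float
    confusion: ConfusionMatrix
    classes: list[str]
    mode: str


def _classes_present(state: np.ndarray) -> list[str]:
    return [c for c in CLASS_ORDER if c in set(state)]


def _predict_fold(
    train: FeatureTable, test: FeatureTable, seed: int, learn: bool
) -> np.ndarray:
    mu, sd = _zscore_fit(train.X)
    ztr = FeatureTable(
        X=pd.DataFrame((train.X.to_numpy() - mu) / sd, columns=train.X.columns),
        state=train.state,
        subject=train.subject,
    )
    metric = learn_metric(ztr, seed=seed) if learn else DistanceMetric.identity(train.attributes)
    Zte = (test.X.to_numpy() - mu) / sd
    ftr = ztr.sorted_canonical()
    diffs = Zte[:, None, :] - ftr.X.to_numpy()[None, :, :]
    Dmat = np.tensordot(diffs**2, metric.weights, axes=([2], [0]))
    return ftr.state[np.argmin(Dmat, axis=1)]


def _subject_split(
    subjects: np.ndarray, arms: dict[str, str], fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (by agent arm) split of subject ids into train/test."""
    uniq = np.array(sorted(set(subjects), key=str))
    train_ids, test_ids = [], []
    for arm in sorted(set(arms.values())):
        arm_ids = np.array([s for s in uniq if arms[s] == arm])
        rng.shuffle(arm_ids)
        n_test = int(round(len(arm_ids) * fraction))
        n_test = min(max(n_test, 1), len(arm_ids) - 1) if len(arm_ids) > 1 else n_test
        test_ids.extend(arm_ids[:n_test])
        train_ids.extend(arm_ids[n_test:])
    return np.array(train_ids, dtype=object), np.array(test_ids, dtype=object)


def _subject_arms(features: FeatureTable) -> dict[str, str]:
    arms: dict[str, str] = {}
    for sid, st in zip(features.subject, features.state):
        if st != "awake":
            arms[sid] = str(st)
    for sid in features.subject:
        arms.setdefault(sid, "unknown")
    return arms


def evaluate_holdout(
    features: FeatureTable,
    n_repeats: int = 200,
    holdout_fraction: float = 0.5,
    seed: int = 0,
    learn: bool = True,
    merge_anaes: bool = False,
) -> EvaluationResult:
    """Repeated stratified subject-level hold-out validation.

    Both records of a subject fall on the same side of each split; the
    metric and z-scoring are fitted on the training half only.  Confusion
    counts are pooled over repeats and reported as row-percentages.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    ft = features.merged_anaes() if merge_anaes else features
    classes = _classes_present(ft.state)
    arms = _subject_arms(features)
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for _ in range(n_repeats):
        train_ids, test_ids = _subject_split(ft.subject, arms, holdout_fraction, rng)
        tr_idx = np.flatnonzero(np.isin(ft.subject, train_ids))
        te_idx = np.flatnonzero(np.isin(ft.subject, test_ids))
        tr, te = ft.take(tr_idx), ft.take(te_idx)
        tr_classes, tr_counts = np.unique(tr.state, return_counts=True)
        if len(tr_classes) < len(classes):
            raise ClassTooSmall("a class vanished from the training half")
        pred = _predict_fold(tr, te, seed=int(rng.integers(2**31)), learn=learn)
        for actual, p in zip(te.state, pred):
            counts.loc[actual, p] += 1
    cm = ConfusionMatrix(counts=counts)
    return EvaluationResult(accuracy=cm.accuracy, confusion=cm, classes=classes, mode="holdout")


def evaluate_loocv(
    features: FeatureTable,
    seed: int = 0,
    learn: bool = True,
    merge_anaes: bool = False,
) -> EvaluationResult:
    """Leave-one-subject-out cross-validation (both states held out together)."""
    ft = features.merged_anaes() if merge_anaes else features
    classes = _classes_present(ft.state)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    rng = np.random.default_rng(seed)
    for sid in sorted(set(ft.subject), key=str):
        te_idx = np.flatnonzero(ft.subject == sid)
        tr_idx = np.flatnonzero(ft.subject != sid)
        tr, te = ft.take(tr_idx), ft.take(te_idx)
        pred = _predict_fold(tr, te, seed=int(rng.integers(2**31)), learn=learn)
        for actual, p in zip(te.state, pred):
            counts.loc[actual, p] += 1
    cm = ConfusionMatrix(counts=counts)
    return EvaluationResult(accuracy=cm.accuracy, confusion=cm, classes=classes, mode="loocv")


@dataclass
class CascadeStage:
    name: str
    attributes: list[str]
    accuracy: float


def _identity_loocv_accuracy(ft: FeatureTable) -> float:
    ftc = ft.sorted_canonical()
    mu, sd = _zscore_fit(ftc.X)
    Z = (ftc.X.to_numpy() - mu) / sd
    S = _pairwise_sq_diffs(Z)
    return _loso_accuracy(S, ftc.state, ftc.subject, np.ones(Z.shape[1]))


def _backward_eliminate(ft: FeatureTable) -> tuple[list[str], float]:
    """Drop attributes greedily while LOSO accuracy does not decrease."""
    attrs = ft.attributes
    best = _identity_loocv_accuracy(ft)
    while len(attrs) > 1:
        scores = [
            _identity_loocv_accuracy(ft.select([x for x in attrs if x != a]))
            for a in attrs
        ]
        k = int(np.argmax(scores))
        if scores[k] < best:
            break
        best = scores[k]
        attrs = [x for x in attrs if x != attrs[k]]
    return attrs, best


def attribute_cascade(
    features: FeatureTable, subsets: dict[str, list[str]] | None = None, seed: int = 0
) -> list[CascadeStage]:
    """Controlled cascade of reductions and mergers of attribute sets.

    Within each subset, greedy backward elimination by leave-one-subject-
    out NN accuracy retains the most predictive attributes; the survivors
    of all subsets are merged and a final elimination pass is run.  The
    returned stages report each subset's surviving attributes and
    accuracy, then the merged set's.  The result is never empty.
    """
    if subsets is None:
        subsets = {k: ATTRIBUTE_SUBSETS[k] for k in ("means", "powers", "interactions")}
    stages: list[CascadeStage] = []
    survivors: list[str] = []
    for name, attrs in subsets.items():
        present = [a for a in attrs if a in features.attributes]
        if not present:
            continue
        kept, acc = _backward_eliminate(features.select(present))
        stages.append(CascadeStage(name=name, attributes=kept, accuracy=acc))
        survivors.extend(kept)
    merged_kept, merged_acc = _backward_eliminate(features.select(survivors))
    stages.append(CascadeStage(name="merged", attributes=merged_kept, accuracy=merged_acc))
    return stages
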