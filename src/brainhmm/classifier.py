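"""Two-group HMM classification with leave-one-out and repeated n-fold CV.

Pipeline per training set (refit inside every cross-validation round so a
held-out subject never touches any training artifact):

1. pool all training subjects' regularity-dimension vectors and train the
   hidden-state codebook (J = 2); pool semivariogram vectors and train the
   observable-symbol codebook (J = 32);
2. encode every subject's per-slice feature vectors to index sequences;
3. estimate one discrete HMM per group from the training subjects'
   (state, symbol) sequence pairs, initial distribution fixed uniform;
4. classify a held-out subject either by the higher forward likelihood of
   its symbol sequence under the two group models, or by the smaller
   symmetrized KLD between its own per-subject HMM and each group model.

Ties and double -inf likelihoods classify as the negative (control) group —
conservative toward "no disease" — and are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import complexity_features as cf
from . import vector_quantization as vq
from .contour_series import BoundarySeries, SeriesConfig, volume_to_series
from .discrete_hmm import (
    DiscreteHMM,
    baum_welch,
    estimate_supervised,
    forward_log_likelihood,
    kld,
)

log = logging.getLogger(__name__)

__all__ = [
    "FeatureParams",
    "SubjectFeatures",
    "SubjectRecord",
    "ConfusionCounts",
    "CrossValReport",
    "TrainedPair",
    "extract_subject_features",
    "features_from_volume",
    "cohort_features",
    "fit_pipeline",
    "classify_by_likelihood",
    "classify_by_kld",
    "confusion_metrics",
    "train_group_model",
    "loo_predictions",
    "loo_crossval",
    "stratified_split",
    "nfold_crossval",
    "detection_rate_by_severity",
    "symbol_size_sweep",
]


@dataclass(frozen=True)
class FeatureParams:
    """Feature-stage settings: SampEn embedding length, tolerance grid and
    maximum semivariogram lag."""

    m: int = 2
    r_grid: np.ndarray = field(default_factory=lambda: cf.DEFAULT_R_GRID.copy())
    k_h: int = 100


@dataclass
class SubjectFeatures:
    """Per-slice feature matrices for one subject (rows ordered top to bottom)."""

    subject_id: str
    group: str
    state_vectors: np.ndarray  # (n_slices, K_state) regularity-dimension slopes
    symbol_vectors: np.ndarray  # (n_slices, K_symbol) semivariogram values
    severity: str | None = None


@dataclass
class SubjectRecord:
    """One subject's VQ index sequences (one index pair per usable slice)."""

    subject_id: str
    group: str
    state_sequence: np.ndarray
    observation_sequence: np.ndarray

    def __post_init__(self) -> None:
        if len(self.state_sequence) != len(self.observation_sequence):
            raise ValueError("state and observation sequences must align per slice")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_metrics(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy); a zero denominator yields None."""
    sens = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    spec = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else None
    acc = (counts.TP + counts.TN) / counts.total if counts.total else None
    return sens, spec, acc


@dataclass
class CrossValReport:
    """Classification rates; for n-fold, mean +- sd over seeded repeats."""

    scheme: str  # "loo" | "nfold"
    rule: str
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    train_fraction: float | None = None
    repeats: int | None = None
    sensitivity_sd: float | None = None
    specificity_sd: float | None = None
    accuracy_sd: float | None = None
    per_repeat: list[tuple[float | None, float | None, float | None]] | None = None
    counts: ConfusionCounts | None = None
    n_ties: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "rule": self.rule,
            "train_fraction": self.train_fraction,
            "repeats": self.repeats,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_sd": self.specificity_sd,
            "accuracy_sd": self.accuracy_sd,
            "n_ties": self.n_ties,
            "seed": self.seed,
        }
        if self.counts is not None:
            d["counts"] = {
                "TP": self.counts.TP, "TN": self.counts.TN,
                "FP": self.counts.FP, "FN": self.counts.FN,
            }
        return d


# ---------------------------------------------------------------------------
# feature extraction


def extract_subject_features(
    series_list: list[BoundarySeries],
    subject_id: str,
    group: str,
    params: FeatureParams | None = None,
    severity: str | None = None,
) -> SubjectFeatures:
    """Per-slice regularity-dimension and semivariogram feature matrices.

    Slices whose SampEn profile is degenerate or whose boundary is too
    short for the full lag range are dropped (logged), keeping both
    matrices aligned slice for slice.
    """
    params = params or FeatureParams()
    state_rows, symbol_rows = [], []
    for s in series_list:
        try:
            reg = cf.regularity_profile(s.distances, m=params.m, r_grid=params.r_grid)
        except cf.FeatureError as err:
            log.info("subject %s slice %d dropped: %s", subject_id, s.slice_index, err)
            continue
        sv = cf.semivariogram(s.distances, k_h=params.k_h)
        if sv.truncated:
            log.info(
                "subject %s slice %d dropped: boundary of %d points shorter than "
                "lag range %d", subject_id, s.slice_index, len(s), params.k_h,
            )
            continue
        state_rows.append(reg.dr_values)
        symbol_rows.append(sv.gamma_values)
    if not state_rows:
        raise ValueError(f"subject {subject_id}: no usable slice")
    return SubjectFeatures(
        subject_id=subject_id,
        group=group,
        state_vectors=np.vstack(state_rows),
        symbol_vectors=np.vstack(symbol_rows),
        severity=severity,
    )


def features_from_volume(
    volume: np.ndarray,
    subject_id: str,
    group: str,
    series_config: SeriesConfig | None = None,
    params: FeatureParams | None = None,
    severity: str | None = None,
) -> SubjectFeatures:
    series = volume_to_series(volume, series_config)
    return extract_subject_features(series, subject_id, group, params, severity)


def cohort_features(
    spec,
    series_config: SeriesConfig | None = None,
    params: FeatureParams | None = None,
) -> list[SubjectFeatures]:
    """Generate a synthetic cohort and extract features, one volume at a time."""
    from .synthetic_data import sample_subject_stack, subject_seed

    series_config = series_config or SeriesConfig(
        gm_label=1, label_map={"background": 0, "gm": 1}
    )
    out = []
    for group in spec.groups:
        for i in range(spec.n_subjects_per_group):
            sid = f"{group}-{i:03d}"
            volume = sample_subject_stack(spec, group, subject_seed(spec, group, i))
            out.append(
                features_from_volume(volume, sid, group, series_config, params)
            )
    return out


# ---------------------------------------------------------------------------
# training


def train_group_model(
    records: list[SubjectRecord],
    N: int,
    M: int,
    pseudocount: float = 1e-3,
    refine: bool = False,
    refine_max_iter: int = 50,
) -> DiscreteHMM:
    """One representative HMM per group: supervised counts pooled over the
    group's subjects, optionally refined by Baum-Welch on the symbol
    sequences (off by default; see the methods note)."""
    if not records:
        raise ValueError("empty group")
    model = estimate_supervised(
        [r.state_sequence for r in records],
        [r.observation_sequence for r in records],
        N=N, M=M, pseudocount=pseudocount,
    )
    if refine:
        model = baum_welch(
            model, [r.observation_sequence for r in records],
            max_iter=refine_max_iter,
        ).model
    return model


@dataclass
class TrainedPair:
    """Training artifacts of one fold: shared codebooks + per-group HMMs."""

    state_codebook: vq.Codebook
    symbol_codebook: vq.Codebook
    models: dict[str, DiscreteHMM]
    positive_group: str
    negative_group: str
    pseudocount: float

    def encode(self, subject: SubjectFeatures) -> SubjectRecord:
        return SubjectRecord(
            subject_id=subject.subject_id,
            group=subject.group,
            state_sequence=vq.encode(subject.state_vectors, self.state_codebook),
            observation_sequence=vq.encode(
                subject.symbol_vectors, self.symbol_codebook
            ),
        )


def fit_pipeline(
    train_subjects: list[SubjectFeatures],
    positive_group: str,
    negative_group: str,
    j_state: int = 2,
    j_symbol: int = 32,
    pseudocount: float = 1e-3,
    refine: bool = False,
    vq_seed: int = 0,
) -> TrainedPair:
    """Fit codebooks and group HMMs on training subjects only.

    Codebooks are trained on the vectors of BOTH groups pooled (a shared
    quantizer keeps index sequences comparable across subjects).
    """
    groups = {s.group for s in train_subjects}
    if groups != {positive_group, negative_group}:
        raise ValueError(
            f"training set has groups {sorted(groups)}, expected "
            f"{{{positive_group!r}, {negative_group!r}}}"
        )
    state_pool = np.vstack([s.state_vectors for s in train_subjects])
    symbol_pool = np.vstack([s.symbol_vectors for s in train_subjects])
    cb_state = vq.lbg_codebook(state_pool, j_state, seed=vq_seed, standardize=True)
    cb_symbol = vq.lbg_codebook(symbol_pool, j_symbol, seed=vq_seed, standardize=True)
    pair = TrainedPair(
        state_codebook=cb_state,
        symbol_codebook=cb_symbol,
        models={},
        positive_group=positive_group,
        negative_group=negative_group,
        pseudocount=pseudocount,
    )
    records = [pair.encode(s) for s in train_subjects]
    for group in (positive_group, negative_group):
        pair.models[group] = train_group_model(
            [r for r in records if r.group == group],
            N=j_state, M=j_symbol, pseudocount=pseudocount, refine=refine,
        )
    return pair


# ---------------------------------------------------------------------------
# decision rules


def classify_by_likelihood(
    record: SubjectRecord,
    model_positive: DiscreteHMM,
    model_negative: DiscreteHMM,
    positive_label: str = "demented",
    negative_label: str = "control",
) -> tuple[str, bool]:
    """Higher forward likelihood of the symbol sequence wins.

    Returns (label, tie_flag); exact ties — including both likelihoods at
    -inf — go to the negative label.
    """
    lp = forward_log_likelihood(model_positive, record.observation_sequence)
    ln = forward_log_likelihood(model_negative, record.observation_sequence)
    if lp == ln:
        return negative_label, True
    return (positive_label if lp > ln else negative_label), False


def classify_by_kld(
    record: SubjectRecord,
    model_positive: DiscreteHMM,
    model_negative: DiscreteHMM,
    positive_label: str = "demented",
    negative_label: str = "control",
    pseudocount: float = 1e-3,
    T: int = 2000,
    seed: int = 0,
) -> tuple[str, bool]:
    """Smaller symmetrized KLD between the subject's own HMM and each group
    model wins.  Falls back to the likelihood rule (flagged) when the
    subject model is degenerate (non-finite divergence to both groups)."""
    n = model_positive.N
    m = model_positive.M
    subject_model = estimate_supervised(
        [record.state_sequence], [record.observation_sequence],
        N=n, M=m, pseudocount=pseudocount,
    )
    d_pos = kld(subject_model, model_positive, T1=T, T2=T, seed=seed)
    d_neg = kld(subject_model, model_negative, T1=T, T2=T, seed=seed)
    if d_pos.flagged and d_neg.flagged:
        label, _ = classify_by_likelihood(
            record, model_positive, model_negative, positive_label, negative_label
        )
        return label, True
    if d_pos.d_kl == d_neg.d_kl:
        return negative_label, True
    return (positive_label if d_pos.d_kl < d_neg.d_kl else negative_label), False


def _classify(
    rule: str,
    record: SubjectRecord,
    pair: TrainedPair,
    kld_T: int,
    kld_seed: int,
) -> tuple[str, bool]:
    mp = pair.models[pair.positive_group]
    mn = pair.models[pair.negative_group]
    if rule == "likelihood":
        return classify_by_likelihood(
            record, mp, mn, pair.positive_group, pair.negative_group
        )
    if rule == "kld":
        return classify_by_kld(
            record, mp, mn, pair.positive_group, pair.negative_group,
            pseudocount=pair.pseudocount, T=kld_T, seed=kld_seed,
        )
    raise ValueError(f"unknown rule {rule!r}")


def _tally(
    predictions: dict[str, str], truth: dict[str, str], positive_group: str
) -> ConfusionCounts:
    counts = ConfusionCounts()
    for sid, label in predictions.items():
        actual_pos = truth[sid] == positive_group
        predicted_pos = label == positive_group
        if actual_pos and predicted_pos:
            counts.TP += 1
        elif actual_pos:
            counts.FN += 1
        elif predicted_pos:
            counts.FP += 1
        else:
            counts.TN += 1
    return counts


def _group_labels(dataset: list[SubjectFeatures]) -> dict[str, str]:
    return {s.subject_id: s.group for s in dataset}


def _resolve_groups(
    dataset: list[SubjectFeatures],
    positive_group: str | None,
    negative_group: str | None,
) -> tuple[str, str]:
    groups = sorted({s.group for s in dataset})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if positive_group is None and negative_group is None:
        # convention: "demented"-style group is positive when recognizable
        if "demented" in groups:
            positive_group = "demented"
        else:
            positive_group = groups[0]
    if positive_group is None:
        positive_group = next(g for g in groups if g != negative_group)
    if negative_group is None:
        negative_group = next(g for g in groups if g != positive_group)
    if {positive_group, negative_group} != set(groups):
        raise ValueError(
            f"groups {positive_group!r}/{negative_group!r} do not match {groups}"
        )
    return positive_group, negative_group


# ---------------------------------------------------------------------------
# cross-validation


def loo_predictions(
    dataset: list[SubjectFeatures],
    rules: tuple[str, ...] = ("likelihood",),
    positive_group: str | None = None,
    negative_group: str | None = None,
    j_state: int = 2,
    j_symbol: int = 32,
    pseudocount: float = 1e-3,
    refine: bool = False,
    kld_T: int = 2000,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Leave-one-out labels per rule (codebooks and HMMs refit every round).

    Returns ``{rule: {subject_id: predicted_group}}``; running several
    rules at once shares the per-round training artifacts.
    """
    pos, neg = _resolve_groups(dataset, positive_group, negative_group)
    preds: dict[str, dict[str, str]] = {rule: {} for rule in rules}
    for i, held_out in enumerate(dataset):
        train = [s for s in dataset if s.subject_id != held_out.subject_id]
        if {t.subject_id for t in train} & {held_out.subject_id}:
            raise AssertionError("held-out subject leaked into training set")
        pair = fit_pipeline(
            train, pos, neg, j_state=j_state, j_symbol=j_symbol,
            pseudocount=pseudocount, refine=refine, vq_seed=seed,
        )
        record = pair.encode(held_out)
        for rule in rules:
            label, tie = _classify(rule, record, pair, kld_T, seed + i)
            if tie:
                log.info("LOO %s: tie for subject %s", rule, held_out.subject_id)
            preds[rule][held_out.subject_id] = label
    return preds


def loo_crossval(
    dataset: list[SubjectFeatures],
    rule: str = "likelihood",
    positive_group: str | None = None,
    negative_group: str | None = None,
    **options,
) -> CrossValReport:
    """Leave-one-out cross-validation aggregated into one confusion matrix."""
    pos, neg = _resolve_groups(dataset, positive_group, negative_group)
    per_group = min(
        sum(1 for s in dataset if s.group == g) for g in (pos, neg)
    )
    if per_group < 2:
        raise ValueError("need at least 2 subjects per group for LOO")
    preds = loo_predictions(
        dataset, (rule,), positive_group=pos, negative_group=neg, **options
    )[rule]
    counts = _tally(preds, _group_labels(dataset), pos)
    sens, spec, acc = confusion_metrics(counts)
    return CrossValReport(
        scheme="loo", rule=rule, sensitivity=sens, specificity=spec,
        accuracy=acc, counts=counts,
    )


def stratified_split(
    dataset: list[SubjectFeatures],
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[SubjectFeatures], list[SubjectFeatures]]:
    """Random split with the same training fraction in every group."""
    train, test = [], []
    for group in sorted({s.group for s in dataset}):
        members = [s for s in dataset if s.group == group]
        n_train = int(round(train_fraction * len(members)))
        if n_train >= len(members) or n_train < 1:
            raise ValueError(
                f"train fraction {train_fraction} leaves no test (or no train) "
                f"subject in group {group!r} of size {len(members)}"
            )
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


def nfold_crossval(
    dataset: list[SubjectFeatures],
    train_fraction: float = 0.5,
    repeats: int = 100,
    rule: str = "likelihood",
    seed: int = 0,
    positive_group: str | None = None,
    negative_group: str | None = None,
    j_state: int = 2,
    j_symbol: int = 32,
    pseudocount: float = 1e-3,
    refine: bool = False,
    kld_T: int = 2000,
) -> CrossValReport:
    """Repeated stratified random-split validation, mean +- sd over repeats."""
    pos, neg = _resolve_groups(dataset, positive_group, negative_group)
    truth = _group_labels(dataset)
    rng = np.random.default_rng(seed)
    per_repeat = []
    n_ties = 0
    for rep in range(repeats):
        train, test = stratified_split(dataset, train_fraction, rng)
        held_ids = {s.subject_id for s in test}
        if held_ids & {s.subject_id for s in train}:
            raise AssertionError("test subjects leaked into training set")
        pair = fit_pipeline(
            train, pos, neg, j_state=j_state, j_symbol=j_symbol,
            pseudocount=pseudocount, refine=refine, vq_seed=seed,
        )
        preds = {}
        for i, subj in enumerate(test):
            record = pair.encode(subj)
            label, tie = _classify(rule, record, pair, kld_T, seed + 1000 * rep + i)
            n_ties += int(tie)
            preds[subj.subject_id] = label
        per_repeat.append(confusion_metrics(_tally(preds, truth, pos)))
    def _stat(idx):
        vals = [r[idx] for r in per_repeat if r[idx] is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))
    sens, sens_sd = _stat(0)
    spec, spec_sd = _stat(1)
    acc, acc_sd = _stat(2)
    return CrossValReport(
        scheme="nfold", rule=rule, train_fraction=train_fraction, repeats=repeats,
        sensitivity=sens, specificity=spec, accuracy=acc,
        sensitivity_sd=sens_sd, specificity_sd=spec_sd, accuracy_sd=acc_sd,
        per_repeat=per_repeat, n_ties=n_ties, seed=seed,
    )


def detection_rate_by_severity(
    dataset: list[SubjectFeatures],
    predictions: dict[str, str],
    positive_group: str,
) -> dict[str, float]:
    """Fraction of positive-group subjects detected, per severity stratum.

    Post-hoc tabulation over the manifest's severity column; no separate
    training is involved.
    """
    rates: dict[str, float] = {}
    for severity in sorted(
        {s.severity for s in dataset if s.group == positive_group and s.severity}
    ):
        members = [
            s for s in dataset
            if s.group == positive_group and s.severity == severity
        ]
        hits = sum(predictions[s.subject_id] == positive_group for s in members)
        rates[severity] = hits / len(members)
    return rates


def symbol_size_sweep(
    dataset: list[SubjectFeatures],
    sizes: tuple[int, ...] = (4, 8, 16, 32, 64, 128, 256),
    rule: str = "likelihood",
    train_fraction: float = 0.5,
    repeats: int = 10,
    seed: int = 0,
    **options,
):
    """Classification rates as a function of the symbol-codebook size.

    Mirrors the design question of how many observable symbols to keep:
    state codebook fixed at 2, symbol codebook varied over ``sizes``.
    Returns a pandas DataFrame (size, sensitivity, specificity, accuracy).
    """
    import pandas as pd

    rows = []
    for j in sizes:
        report = nfold_crossval(
            dataset, train_fraction=train_fraction, repeats=repeats, rule=rule,
            seed=seed, j_symbol=j, **options,
        )
        rows.append((j, report.sensitivity, report.specificity, report.accuracy))
    return pd.DataFrame(
        rows, columns=["symbol_size", "sensitivity", "specificity", "accuracy"]
    )
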