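"""Observer-study statistics for the blinded phantom-vs-patient reading.

Readers classify each presented CT series as a 3D-printed phantom or a real
patient nodule (positive class = 3D-printed).  From the response table the
module computes confusion matrices and rates, percentile bootstrap
confidence intervals (resampling responses, readers, or cases), Conger's
multi-rater kappa, a chi-square goodness-of-fit test of the correct/incorrect
split against an explicit null proportion, and the per-level confidence
(Likert) summary with correct-vs-incorrect likelihood ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DomainError, EmptySelectionError, InputError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "RateSummary",
    "KappaResult",
    "GofResult",
    "load_responses",
    "validate_responses",
    "tabulate_confusion",
    "classification_rates",
    "bootstrap_ci",
    "conger_kappa",
    "ratings_table",
    "chi2_goodness_of_fit",
    "confidence_summary",
]

RESPONSE_COLUMNS = [
    "reader_id",
    "experience",
    "case_id",
    "presentation",
    "truth",
    "call",
    "confidence",
]
POSITIVE = "printed"
NEGATIVE = "patient"


def _round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive class = 3D-printed nodule."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix must contain at least one response")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RateSummary:
    """Percentages rounded half-up to 0.1; None marks an undefined rate."""

    accuracy: float
    tpr: float | None
    tnr: float | None
    fpr: float | None
    fnr: float | None
    ci: dict | None = None


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_raters: int
    n_items: int
    n_categories: int


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    null_spec: str


# ---------------------------------------------------------------- responses
def validate_responses(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"response table missing columns {missing}")
    bad_conf = ~df["confidence"].isin([1, 2, 3, 4, 5])
    if bad_conf.any():
        raise InputError("confidence must be an integer in 1..5")
    for col in ("truth", "call"):
        bad = ~df[col].isin([POSITIVE, NEGATIVE])
        if bad.any():
            raise InputError(f"{col} must be '{POSITIVE}' or '{NEGATIVE}'")
    return df


def load_responses(path: str) -> pd.DataFrame:
    """Read the reader-response CSV (columns: reader_id, experience, case_id,
    presentation, truth, call, confidence)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot read responses CSV {path}: {exc}") from exc
    return validate_responses(df)


def tabulate_confusion(responses: pd.DataFrame, experience: str | None = None) -> ConfusionMatrix:
    """Confusion counts, optionally restricted to one experience group."""
    df = responses
    if experience is not None:
        df = df[df["experience"] == experience]
    if len(df) == 0:
        raise EmptySelectionError(f"no responses for experience={experience!r}")
    truth_pos = df["truth"] == POSITIVE
    call_pos = df["call"] == POSITIVE
    return ConfusionMatrix(
        tp=int((truth_pos & call_pos).sum()),
        fp=int((~truth_pos & call_pos).sum()),
        fn=int((truth_pos & ~call_pos).sum()),
        tn=int((~truth_pos & ~call_pos).sum()),
    )


# -------------------------------------------------------------------- rates
def classification_rates(cm: ConfusionMatrix, ci: dict | None = None) -> RateSummary:
    """Accuracy and class-conditional rates in percent (half-up to 0.1).

    A class-conditional rate whose class is absent is reported as None
    (undefined), never as 0.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp

    def pct(num, den):
        return None if den == 0 else _round1(100.0 * num / den)

    return RateSummary(
        accuracy=_round1(100.0 * (cm.tp + cm.tn) / cm.total),
        tpr=pct(cm.tp, pos),
        tnr=pct(cm.tn, neg),
        fpr=pct(cm.fp, neg),
        fnr=pct(cm.fn, pos),
        ci=ci,
    )


_METRICS = {
    "accuracy": lambda tp, fp, fn, tn: (tp + tn) / (tp + fp + fn + tn),
    "tpr": lambda tp, fp, fn, tn: tp / (tp + fn),
    "tnr": lambda tp, fp, fn, tn: tn / (tn + fp),
    "fpr": lambda tp, fp, fn, tn: fp / (tn + fp),
    "fnr": lambda tp, fp, fn, tn: fn / (tp + fn),
}


def bootstrap_ci(
    responses: pd.DataFrame,
    metric: str = "accuracy",
    unit: str = "response",
    B: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI (percent) for a classification rate.

    ``unit`` selects the resampling unit: individual responses, whole
    readers, or whole cases (with replacement).  Replicates on which the
    metric is undefined (a class missing from the resample) are redrawn up to
    a cap of ``50 * B`` total draws, after which a :class:`DomainError` is
    raised.  Seeded and reproducible.
    """
    if metric not in _METRICS:
        raise DomainError(f"unknown metric {metric!r}")
    if B < 100:
        raise DomainError("at least 100 bootstrap replicates are required")
    if unit not in ("response", "reader", "case"):
        raise DomainError(f"unknown resampling unit {unit!r}")
    validate_responses(responses)
    fn_metric = _METRICS[metric]
    rng = np.random.default_rng(seed)

    truth_pos = (responses["truth"] == POSITIVE).to_numpy()
    call_pos = (responses["call"] == POSITIVE).to_numpy()
    if unit == "response":
        groups = [np.arange(len(responses))]
        group_of = None
    else:
        key = "reader_id" if unit == "reader" else "case_id"
        codes, _ = pd.factorize(responses[key])
        group_of = [np.nonzero(codes == g)[0] for g in range(codes.max() + 1)]

    values = np.empty(B)
    draws = 0
    cap = 50 * B
    b = 0
    while b < B:
        if draws >= cap:
            raise DomainError(
                f"exceeded {cap} bootstrap draws with degenerate resamples for {metric}"
            )
        draws += 1
        if unit == "response":
            idx = rng.integers(0, len(responses), len(responses))
        else:
            pick = rng.integers(0, len(group_of), len(group_of))
            idx = np.concatenate([group_of[g] for g in pick])
        tpos = truth_pos[idx]
        cpos = call_pos[idx]
        tp = int((tpos & cpos).sum())
        fp = int((~tpos & cpos).sum())
        fnn = int((tpos & ~cpos).sum())
        tn = int((~tpos & ~cpos).sum())
        try:
            values[b] = fn_metric(tp, fp, fnn, tn)
        except ZeroDivisionError:
            continue
        b += 1

    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return (_round1(100.0 * lo), _round1(100.0 * hi))


# -------------------------------------------------------------------- kappa
def ratings_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Pivot responses to an items x raters table of calls.

    Items are (case_id, presentation) pairs; cells are the readers' calls.
    Raises if any cell is missing (kappa requires a complete design).
    """
    table = responses.pivot_table(
        index=["case_id", "presentation"],
        columns="reader_id",
        values="call",
        aggfunc="first",
    )
    if table.isna().any().any():
        raise DomainError("ratings table has missing cells; kappa needs a complete design")
    return table


def conger_kappa(ratings) -> KappaResult:
    """Conger's exact multi-rater kappa for an items x raters category table.

    Observed agreement is the mean over items and rater pairs of the
    agreement indicator; expected agreement is the mean over rater pairs of
    the inner product of the two raters' category marginals.  For two raters
    this reduces exactly to Cohen's kappa.  A table in which every rating is
    one single category leaves chance agreement at 1 and kappa undefined
    (reported as NaN).
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2:
        raise DomainError("ratings must be a 2-D items x raters table")
    n_items, n_raters = arr.shape
    if n_items < 2 or n_raters < 2:
        raise DomainError("kappa requires >= 2 items and >= 2 raters")
    cats, coded = np.unique(arr, return_inverse=True)
    coded = coded.reshape(arr.shape)
    n_cats = len(cats)

    pairs = [(a, b) for a in range(n_raters) for b in range(a + 1, n_raters)]
    po = float(np.mean([np.mean(coded[:, a] == coded[:, b]) for a, b in pairs]))
    marg = np.stack(
        [np.bincount(coded[:, r], minlength=n_cats) / n_items for r in range(n_raters)]
    )
    pe = float(np.mean([marg[a] @ marg[b] for a, b in pairs]))
    kappa = np.nan if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(kappa), n_raters=n_raters, n_items=n_items, n_categories=n_cats)


# ---------------------------------------------------------------------- GOF
def chi2_goodness_of_fit(correct: int, incorrect: int, null_p: float = 0.5) -> GofResult:
    """Chi-square goodness of fit of the correct/incorrect split vs ``null_p``.

    ``null_p`` is the expected proportion correct under the null (default
    0.5 = guessing); df = 1.
    """
    if correct < 0 or incorrect < 0 or correct + incorrect == 0:
        raise DomainError("counts must be non-negative with a positive total")
    if not 0.0 < null_p < 1.0:
        raise DomainError("null_p must be strictly inside (0, 1)")
    total = correct + incorrect
    expected = np.array([null_p * total, (1.0 - null_p) * total])
    if np.any(expected == 0):
        raise DomainError("zero expected count")
    stat, p = sstats.chisquare([correct, incorrect], expected)
    return GofResult(
        statistic=float(stat),
        df=1,
        p_value=float(p),
        null_spec=f"P(correct) = {null_p}",
    )


# --------------------------------------------------------------- confidence
def confidence_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-confidence-level counts and correct-vs-incorrect likelihood ratios.

    For each Likert level 1..5: total count, proportion among correct calls,
    proportion among incorrect calls, and their ratio.  A level absent from
    one group yields an undefined (NaN) ratio — the counts remain reported.
    """
    validate_responses(responses)
    correct = responses["truth"] == responses["call"]
    levels = pd.Index([1, 2, 3, 4, 5], name="confidence")
    n_corr = int(correct.sum())
    n_inc = int((~correct).sum())
    count = responses["confidence"].value_counts().reindex(levels, fill_value=0)
    c_corr = responses.loc[correct, "confidence"].value_counts().reindex(levels, fill_value=0)
    c_inc = responses.loc[~correct, "confidence"].value_counts().reindex(levels, fill_value=0)
    p_corr = c_corr / n_corr if n_corr else pd.Series(np.nan, index=levels)
    p_inc = c_inc / n_inc if n_inc else pd.Series(np.nan, index=levels)
    lr = pd.Series(
        np.where((c_inc > 0) & (c_corr >= 0) & np.isfinite(p_inc) & (p_inc > 0),
                 p_corr / p_inc, np.nan),
        index=levels,
    )
    return pd.DataFrame(
        {
            "count": count,
            "prop_correct": p_corr,
            "prop_incorrect": p_inc,
            "likelihood_ratio": lr,
        }
    )
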