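"""Sample-level enumeration and clinical-correlation statistics.

Per-sample CTC burden is reported as cells per mL of blood, split by
phenotype (CAXII single-positive, double-positive, CK single-positive,
their sum, and the pooled CK+ group).  Group comparisons use Welch's
t-test or the Mann-Whitney U test (exact by full enumeration for small
cohorts, normal approximation with tie correction otherwise).  The
response/progression discrimination of a density is summarised by a ROC
curve whose candidate cutoffs sit at midpoints between observed values;
the reported optimal cutoff maximises the positive likelihood ratio
sensitivity / (1 - specificity), the criterion used to derive the
published 4.8 total-CTC/mL and 2.6 CK+/mL operating points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    CTC_LABELS,
    LABEL_CK_S,
    LABEL_DP,
    SUBPOP_ALL_CTC,
    SUBPOP_CK_PLUS,
    SUBPOPULATIONS,
)

__all__ = [
    "SampleSummary",
    "GroupTest",
    "ROCResult",
    "OptimalCutoff",
    "LongitudinalReport",
    "enumerate_sample",
    "density_table",
    "compare_groups",
    "roc",
    "optimal_cutoff",
    "longitudinal_report",
]

_COUNT_COLS = {label: f"n_{label.lower()}" for label in CTC_LABELS}


def _density_cols() -> dict[str, str]:
    return {s: f"density_{s.lower()}" for s in SUBPOPULATIONS}


@dataclass
class SampleSummary:
    """Per-sample CTC counts and densities by phenotype."""

    sample_id: str
    volume_ml: float
    counts: dict[str, int]
    response: str | None = None
    therapy: str | None = None
    week: float | None = None
    densities: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(f"volume must be > 0 mL, got {self.volume_ml}")
        counts = {label: int(self.counts.get(label, 0)) for label in CTC_LABELS}
        if any(v < 0 for v in counts.values()):
            raise ValueError("counts must be >= 0")
        self.counts = counts
        d = {label: counts[label] / self.volume_ml for label in CTC_LABELS}
        # pooled densities from summed counts: keeps rank ties exact when
        # every sample shares one volume
        self.densities = {
            SUBPOP_ALL_CTC: sum(counts.values()) / self.volume_ml,
            **d,
            SUBPOP_CK_PLUS: (counts[LABEL_CK_S] + counts[LABEL_DP])
            / self.volume_ml,
        }

    def density(self, subpopulation: str = SUBPOP_ALL_CTC) -> float:
        return self.densities[subpopulation]


def enumerate_sample(
    calls: pd.DataFrame,
    volume_ml: float,
    sample_id: str = "",
    response: str | None = None,
    therapy: str | None = None,
    week: float | None = None,
) -> SampleSummary:
    """Count countable CTCs per phenotype and convert to per-mL densities.

    Only cells the gating stage marked ``countable`` contribute:
    EXCLUDED, TRIPLE_NEG and QC-flagged cells never enter enumeration.
    """
    if volume_ml <= 0:
        raise ValueError(f"volume must be > 0 mL, got {volume_ml}")
    countable = calls.loc[calls["countable"]]
    counts = {
        label: int((countable["label"] == label).sum()) for label in CTC_LABELS
    }
    return SampleSummary(
        sample_id=sample_id,
        volume_ml=volume_ml,
        counts=counts,
        response=response,
        therapy=therapy,
        week=week,
    )


def density_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Append per-mL density columns to a per-sample count table.

    Expects ``volume_ml`` plus count columns ``n_caxii_s, n_dp, n_ck_s``
    (as written by the cohort/longitudinal generators and the CLI);
    adds ``density_<subpopulation>`` columns for every reporting
    subpopulation.
    """
    out = samples.copy()
    vol = out["volume_ml"].to_numpy(dtype=float)
    if np.any(vol <= 0):
        raise ValueError("volume_ml must be > 0 for every sample")
    counts = {
        label: out[col].to_numpy(dtype=float)
        for label, col in _COUNT_COLS.items()
    }
    dcols = _density_cols()
    out[dcols[SUBPOP_ALL_CTC]] = sum(counts.values()) / vol
    for label in CTC_LABELS:
        out[dcols[label]] = counts[label] / vol
    out[dcols[SUBPOP_CK_PLUS]] = (counts[LABEL_CK_S] + counts[LABEL_DP]) / vol
    return out


@dataclass
class GroupTest:
    """Result of a two-group comparison."""

    test: str
    statistic: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    exact: bool = False


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _exact_mw_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney p by full enumeration of group assignments.

    Midranks make the null distribution correct under ties.  Returns
    ``(U_a, p)`` where ``U_a`` is the U statistic of the first group.
    """
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    n1, n = len(a), len(combined)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    eps = 1e-9
    n_ge = n_le = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if u >= u_obs - eps:
            n_ge += 1
        if u <= u_obs + eps:
            n_le += 1
    p_greater = n_ge / total
    p_less = n_le / total
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(u_obs), float(p)


def compare_groups(
    a,
    b,
    test: str = "mannwhitney",
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> GroupTest:
    """Compare two groups of per-sample densities.

    ``test="mannwhitney"`` (default) or ``"welch_t"``.  The alternative
    refers to the first group ``a`` (``"less"`` means a is
    stochastically smaller than b).  The Mann-Whitney p-value is exact —
    full enumeration of all C(n, n_a) group assignments with midranks —
    when the combined sample size is at most ``exact_max_n``; larger
    cohorts use the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    summary = dict(
        n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        range_a=(float(a.min()), float(a.max())),
        range_b=(float(b.min()), float(b.max())),
    )
    if test == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch_t requires n >= 2 per group")
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return GroupTest(
            test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
            alternative=alternative, **summary,
        )
    if test != "mannwhitney":
        raise ValueError(f"unknown test {test!r}")
    if a.size + b.size <= exact_max_n:
        u, p = _exact_mw_p(a, b, alternative)
        return GroupTest(
            test=test, statistic=u, p_value=p, alternative=alternative,
            exact=True, **summary,
        )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return GroupTest(
        test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
        alternative=alternative, exact=False, **summary,
    )


@dataclass
class ROCResult:
    """ROC curve of a per-sample score against a binary response label."""

    cutoffs: np.ndarray  # candidate cutoffs, ascending (with +-inf sentinels)
    sensitivity: np.ndarray  # P(score > cutoff | positive class)
    specificity: np.ndarray  # P(score <= cutoff | negative class)
    auc: float
    p_value: float  # vs AUC = 0.5, normal approximation of the U test
    n_positive: int
    n_negative: int
    positive_label: str


def roc(scores, labels, positive_label: str = "progressing") -> ROCResult:
    """ROC of a density/score for discriminating the positive class.

    Progressing samples are the positive class and higher scores point
    toward progression: at cutoff c a sample is called positive when its
    score exceeds c.  Candidate cutoffs are the midpoints between
    consecutive distinct scores plus -inf/+inf sentinels, so a reported
    cutoff always falls between observed sample values.  The AUC is the
    trapezoidal area of the resulting curve, which (by the midpoint
    construction) equals the midrank Mann-Whitney U / (n+ * n-), ties
    included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"both classes required: {pos.size} positive "
            f"({positive_label!r}), {neg.size} negative"
        )
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > c).mean() for c in cutoffs])
    spec = np.array([(neg <= c).mean() for c in cutoffs])

    # walk the curve in descending-cutoff order so fpr ascends with the
    # correct tie structure (tied scores produce diagonal segments)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    p_value = float(
        sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue
    )
    return ROCResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        p_value=p_value,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        positive_label=str(positive_label),
    )


@dataclass
class OptimalCutoff:
    """Likelihood-ratio-optimal operating point of a ROC curve."""

    cutoff: float
    sensitivity: float
    specificity: float
    likelihood_ratio: float
    lr_infinite: bool = False  # perfect-specificity operating point


def optimal_cutoff(result: ROCResult) -> OptimalCutoff:
    """Operating point with the highest positive likelihood ratio.

    LR = sensitivity / (1 - specificity), maximised over candidate
    cutoffs with sensitivity > 0.  Cutoffs achieving specificity 1 with
    non-zero sensitivity have infinite LR and win whenever present; the
    result is then flagged ``lr_infinite``.  Ties are broken toward
    higher sensitivity, then toward the lower cutoff.
    """
    sens, spec, cuts = result.sensitivity, result.specificity, result.cutoffs
    usable = sens > 0
    if not usable.any():
        raise ValueError("no candidate cutoff has sensitivity > 0")
    perfect = usable & (spec >= 1.0)
    if perfect.any():
        idx = _pick(perfect, sens, cuts, key=sens)
        return OptimalCutoff(
            cutoff=float(cuts[idx]),
            sensitivity=float(sens[idx]),
            specificity=float(spec[idx]),
            likelihood_ratio=math.inf,
            lr_infinite=True,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(usable, sens / (1.0 - spec), -np.inf)
    idx = _pick(usable, sens, cuts, key=lr)
    return OptimalCutoff(
        cutoff=float(cuts[idx]),
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        likelihood_ratio=float(lr[idx]),
    )


def _pick(mask: np.ndarray, sens: np.ndarray, cuts: np.ndarray, key: np.ndarray) -> int:
    """Argmax of ``key`` over ``mask``; ties to higher sens, then lower cutoff."""
    best = None
    for i in np.nonzero(mask)[0]:
        cand = (key[i], sens[i], -cuts[i])
        if best is None or cand > best[0]:
            best = (cand, i)
    return int(best[1])


@dataclass
class LongitudinalReport:
    """Threshold-crossing events along a serial-timepoint series."""

    events: pd.DataFrame  # week, subpopulation, direction
    table: pd.DataFrame  # per-week densities, all phenotypes
    cutoff: float
    subpopulation: str


def longitudinal_report(
    series: pd.DataFrame,
    cutoff: float,
    subpopulation: str = SUBPOP_CK_PLUS,
) -> LongitudinalReport:
    """Flag timepoints where a density crosses a clinical cutoff.

    ``series`` is a per-week count table (``week``, ``volume_ml``,
    ``n_<subtype>`` columns) with strictly increasing weeks.  A value
    exactly at the cutoff counts as below it, so an at-cutoff to above
    transition is one upward crossing.  Events carry the week of the
    later timepoint.
    """
    weeks = series["week"].to_numpy(dtype=float)
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError(f"weeks must be strictly increasing, got {list(weeks)}")
    table = density_table(series)
    dens = table[_density_cols()[subpopulation]].to_numpy(dtype=float)
    above = dens > cutoff  # at-cutoff treated as below
    events = []
    for i in range(1, len(above)):
        if above[i] and not above[i - 1]:
            events.append({"week": weeks[i], "subpopulation": subpopulation,
                           "direction": "up"})
        elif above[i - 1] and not above[i]:
            events.append({"week": weeks[i], "subpopulation": subpopulation,
                           "direction": "down"})
    events_df = pd.DataFrame(events, columns=["week", "subpopulation", "direction"])
    return LongitudinalReport(
        events=events_df, table=table, cutoff=float(cutoff),
        subpopulation=subpopulation,
    )
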