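"""Positivity cutoffs, phenotype calls and biomarker scoring.

Cutoffs follow the "principles of clustering as in flow cytometry": the
default method partitions the 1-D background-subtracted intensities into
two clusters minimising within-cluster variance and places the cutoff
at the midpoint of the cluster means; when the two clusters are not
meaningfully separated (unimodal channel, e.g. a biomarker nobody
expresses) it falls back to negative-population mean + 3 SD.

The phenotype rule set is fixed: a cell at or above the exclusion
cutoff is EXCLUDED no matter what else it expresses; remaining cells
are CAXII_S (CAXII+/CK−), DP (CAXII+/CK+), CK_S (CAXII−/CK+) or
TRIPLE_NEG (CAXII−/CK−).  Only CAXII_S, DP and CK_S are CTCs;
TRIPLE_NEG cells are never counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BIOMARKER,
    CAXII,
    CK,
    CTC_LABELS,
    EXCLUSION,
    LABEL_CAXII_S,
    LABEL_CK_S,
    LABEL_DP,
    LABEL_EXCLUDED,
    LABEL_TRIPLE_NEG,
    SUBPOP_ALL_CTC,
    SUBPOP_CK_PLUS,
    SUBPOPULATIONS,
    bgsub_col,
)

__all__ = [
    "GatingConfig",
    "CompositionResult",
    "fit_cutoff",
    "fit_gating_config",
    "classify_cells",
    "score_biomarker",
    "composition_table",
]

_QC_COLUMNS = ("qc_saturated", "qc_size", "qc_border")


@dataclass(frozen=True)
class GatingConfig:
    """Per-channel positivity cutoffs plus provenance tags."""

    cutoffs: dict[str, float]
    method: str = "cluster"
    rules_version: str = "exclusion-caxii-ck-v1"
    scope: str = "per_sample"  # or "cohort_pooled"; audit metadata

    def __post_init__(self) -> None:
        for role, value in self.cutoffs.items():
            if not np.isfinite(value):
                raise ValueError(f"cutoff for {role!r} is not finite: {value}")

    def __getitem__(self, role: str) -> float:
        try:
            return self.cutoffs[role]
        except KeyError:
            raise KeyError(
                f"no cutoff for role {role!r} (present: {sorted(self.cutoffs)})"
            ) from None


def _best_split(x: np.ndarray):
    """Exhaustive optimal 2-cluster split of sorted 1-D data.

    Returns ``(k, left_mean, right_mean, sse)`` where the left cluster is
    ``x[:k]``.  O(n) over sorted values via prefix sums; identical to the
    brute-force scan over all split points.
    """
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)
    left_sum, left_sq = csum[k - 1], csq[k - 1]
    right_sum, right_sq = csum[-1] - left_sum, csq[-1] - left_sq
    sse = (left_sq - left_sum**2 / k) + (right_sq - right_sum**2 / (n - k))
    best = int(np.argmin(sse))
    kb = best + 1
    return kb, left_sum[best] / kb, right_sum[best] / (n - kb), float(sse[best])


def fit_cutoff(
    values,
    method: str = "cluster",
    *,
    min_cluster_separation: float = 3.0,
) -> float:
    """Fit a positivity cutoff on 1-D background-subtracted intensities.

    ``method="cluster"`` (default): minimum-within-variance two-cluster
    partition; cutoff = midpoint of the two cluster means.  If the
    clusters are not separated (Ashman-style separation
    ``|m2-m1| / sqrt((s1^2+s2^2)/2)`` below ``min_cluster_separation``,
    i.e. the channel looks unimodal) the method falls back to
    ``method="mean_plus_3sd"``: negative-population mean + 3 SD.

    The cutoff is translation-equivariant: adding a constant to every
    value shifts the cutoff by exactly that constant.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"need >= 2 finite values to fit a cutoff, got {x.size}")
    if method == "mean_plus_3sd":
        return float(x.mean() + 3.0 * x.std(ddof=0))
    if method != "cluster":
        raise ValueError(f"unknown cutoff method {method!r}")

    if np.ptp(x) == 0:
        warnings.warn(
            "all intensities identical; falling back to mean + 3 SD cutoff",
            stacklevel=2,
        )
        return float(x[0])

    xs = np.sort(x)
    k, m_left, m_right, _ = _best_split(xs)
    s_left = xs[:k].std(ddof=0)
    s_right = xs[k:].std(ddof=0)
    pooled = np.sqrt((s_left**2 + s_right**2) / 2.0)
    separation = np.inf if pooled == 0 else (m_right - m_left) / pooled
    if separation < min_cluster_separation:
        return float(x.mean() + 3.0 * x.std(ddof=0))
    return float((m_left + m_right) / 2.0)


def fit_gating_config(
    table: pd.DataFrame,
    roles: tuple[str, ...] = (CAXII, CK, EXCLUSION, BIOMARKER),
    method: str = "cluster",
    scope: str = "per_sample",
    **fit_kwargs,
) -> GatingConfig:
    """Fit per-role cutoffs from the ``bgsub_<role>`` columns of a table."""
    cutoffs = {}
    for role in roles:
        col = bgsub_col(role)
        if col not in table.columns:
            raise ValueError(f"cell table has no column {col!r} for role {role!r}")
        cutoffs[role] = fit_cutoff(table[col].to_numpy(), method=method, **fit_kwargs)
    return GatingConfig(cutoffs=cutoffs, method=method, scope=scope)


def _rule_label(exclusion: bool, caxii: bool, ck: bool) -> str:
    if exclusion:
        return LABEL_EXCLUDED
    if caxii and ck:
        return LABEL_DP
    if caxii:
        return LABEL_CAXII_S
    if ck:
        return LABEL_CK_S
    return LABEL_TRIPLE_NEG


def classify_cells(table: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Assign every cell a phenotype call.

    Gate logic: a channel is positive when its background-subtracted
    mean is at or above the configured cutoff; exclusion positivity
    overrides everything.  QC-flagged cells are still labeled but marked
    non-countable, as are EXCLUDED and TRIPLE_NEG cells.

    Returns a DataFrame with ``cell_id``, the three gate flags, the
    phenotype ``label``, the biomarker value and flag, and ``countable``.
    """
    for role in (EXCLUSION, CAXII, CK):
        if bgsub_col(role) not in table.columns:
            raise ValueError(
                f"cell table is missing column {bgsub_col(role)!r} "
                f"required for role {role!r}"
            )
        config[role]  # raises if the cutoff is absent

    excl = table[bgsub_col(EXCLUSION)].to_numpy() >= config[EXCLUSION]
    caxii = table[bgsub_col(CAXII)].to_numpy() >= config[CAXII]
    ck = table[bgsub_col(CK)].to_numpy() >= config[CK]
    labels = np.array(
        [_rule_label(e, a, c) for e, a, c in zip(excl, caxii, ck)], dtype=object
    )

    qc_fail = np.zeros(len(table), dtype=bool)
    for col in _QC_COLUMNS:
        if col in table.columns:
            qc_fail |= table[col].to_numpy().astype(bool)

    calls = pd.DataFrame(
        {
            "cell_id": table["cell_id"].to_numpy()
            if "cell_id" in table.columns
            else np.arange(len(table)),
            "exclusion_positive": excl,
            "caxii_positive": caxii,
            "ck_positive": ck,
            "label": labels,
            "qc_fail": qc_fail,
            "countable": ~qc_fail & np.isin(labels, CTC_LABELS),
        }
    )
    bcol = bgsub_col(BIOMARKER)
    if bcol in table.columns:
        values = table[bcol].to_numpy(dtype=float)
        calls[bcol] = values
        if BIOMARKER in config.cutoffs:
            calls["biomarker_positive"] = values > config[BIOMARKER]
    return calls


def _subpop_mask(calls: pd.DataFrame, subpop: str) -> np.ndarray:
    countable = calls["countable"].to_numpy()
    labels = calls["label"].to_numpy()
    if subpop == SUBPOP_ALL_CTC:
        return countable
    if subpop == SUBPOP_CK_PLUS:
        return countable & np.isin(labels, (LABEL_CK_S, LABEL_DP))
    return countable & (labels == subpop)


def score_biomarker(calls: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Per-subpopulation biomarker summary over countable CTCs.

    For each of ALL_CTC, CAXII_S, DP, CK_S and the pooled CK_PLUS
    (CK_S plus DP): cell count, percent of cells above the cutoff, and
    mean background-subtracted expression.  The two statistics are
    independent — the mean is reported regardless of the cutoff.  Empty
    subpopulations keep ``n_cells`` 0 with missing (NaN) statistics.
    """
    bcol = bgsub_col(BIOMARKER)
    if bcol not in calls.columns:
        raise ValueError(f"calls table has no biomarker column {bcol!r}")
    values = calls[bcol].to_numpy(dtype=float)
    rows = []
    for subpop in SUBPOPULATIONS:
        mask = _subpop_mask(calls, subpop)
        n = int(mask.sum())
        if n == 0:
            rows.append({"subpopulation": subpop, "n_cells": 0,
                         "pct_positive": np.nan, "mean_expression": np.nan})
            continue
        v = values[mask]
        rows.append(
            {
                "subpopulation": subpop,
                "n_cells": n,
                "pct_positive": 100.0 * float((v > cutoff).mean()),
                "mean_expression": float(v.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("subpopulation")


@dataclass
class CompositionResult:
    """Marker co-expression frequencies among exclusion-negative cells."""

    combinations: pd.DataFrame  # one row per marker combination, pct sums to 100
    ck_strata_marginals: pd.DataFrame | None  # per-marker pct within CK+/CK-


def composition_table(
    markers: pd.DataFrame,
    marker_columns: list[str] | None = None,
    exclusion_column: str | None = None,
) -> CompositionResult:
    """Co-expression frequency of marker combinations.

    ``markers`` holds one boolean column per identification marker
    (e.g. CK, EpCAM, CAIX, CAXII) and optionally a boolean exclusion
    column; exclusion-positive cells are dropped before tabulation.
    Frequencies over all 2^k combinations sum to 100%.  When a ``CK``
    column is present, per-marker marginal frequencies within the CK+
    and CK− strata are tabulated as well.
    """
    df = markers
    if exclusion_column is not None:
        df = df.loc[~df[exclusion_column].astype(bool)]
    if marker_columns is None:
        marker_columns = [c for c in df.columns if c != exclusion_column]
    if not len(df):
        raise ValueError("no exclusion-negative cells to tabulate")
    if not marker_columns:
        raise ValueError("no marker columns given")

    flags = df[marker_columns].astype(bool)
    n = len(flags)
    combos = []
    for combo in range(2**len(marker_columns)):
        pattern = {
            m: bool((combo >> i) & 1) for i, m in enumerate(marker_columns)
        }
        match = np.ones(n, dtype=bool)
        for m, want in pattern.items():
            match &= flags[m].to_numpy() == want
        combos.append({**pattern, "pct": 100.0 * match.sum() / n})
    combinations = pd.DataFrame(combos, columns=[*marker_columns, "pct"])

    marginals = None
    if "CK" in marker_columns:
        others = [m for m in marker_columns if m != "CK"]
        rows = []
        ck = flags["CK"].to_numpy()
        for stratum, mask in (("CK+", ck), ("CK-", ~ck)):
            for m in others:
                sub = flags[m].to_numpy()[mask]
                rows.append(
                    {
                        "stratum": stratum,
                        "marker": m,
                        "n_cells": int(mask.sum()),
                        "pct_positive": (100.0 * sub.mean()) if mask.any() else np.nan,
                    }
                )
        marginals = pd.DataFrame(rows)
    return CompositionResult(combinations=combinations, ck_strata_marginals=marginals)
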