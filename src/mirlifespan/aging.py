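"""Adult aging analyses: young/middle-aged contrast, FDR, correlations, patterns.

Adults are split at 35 years (inclusive on the young side) into young and
middle-aged strata.  Each adult-detectable assay is compared between the two
strata with a two-sided rank-sum test; discoveries are controlled by
Benjamini–Hochberg at a (liberal) 20 % FDR.  Discoveries are followed up
with Pearson correlation against age, optionally partialled on gender, under
a Bonferroni correction over the follow-up family.  A separate caller labels
each assay's lifespan trajectory over the four ordered strata (preterm →
child → young adult → middle-aged adult) with one of four transition
patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    DEFAULT_MAX_EXACT_ARRANGEMENTS,
    UntestableError,
    signed_fold_change,
    wilcoxon_two_group,
)
from .ct_matrix import DeltaCtMatrix

logger = logging.getLogger(__name__)

ADULT_AGE_CUTOFF = 35.0

ADULT_ONSET = "adult_onset"
STABLE_DOWN_DIMINISH = "stable_then_down_then_diminish"
STABLE_UP_DIMINISH = "stable_then_up_then_diminish"
DOWN_UP_DIMINISH = "down_then_up_then_diminish"
UNCLASSIFIED = "unclassified"

_PATTERN_BY_SIGNS = {
    ("flat", "down", "down"): STABLE_DOWN_DIMINISH,
    ("flat", "up", "down"): STABLE_UP_DIMINISH,
    ("down", "up", "down"): DOWN_UP_DIMINISH,
}


def split_adults(meta: pd.DataFrame, cutoff: float = ADULT_AGE_CUTOFF) -> pd.Series:
    """Label adult samples ``young`` (age ≤ cutoff) or ``middle_aged`` (> cutoff).

    Returns a Series indexed by sample_id covering adult samples only;
    non-adult rows are excluded with a logged count.
    """
    n_dropped = int((meta["group"] != "adult").sum())
    if n_dropped:
        logger.info("split_adults: excluded %d non-adult sample(s)", n_dropped)
    adults = meta.loc[meta["group"] == "adult"]
    ages = adults["age"].astype(float)
    if not np.isfinite(ages).all():
        raise ValueError("adult samples must have finite ages")
    labels = np.where(ages <= cutoff, "young", "middle_aged")
    return pd.Series(labels, index=adults["sample_id"].to_numpy(), name="age_stratum")


@dataclass
class BHResult:
    """Benjamini–Hochberg step-up outcome over a declared test universe."""

    pass_flags: np.ndarray  # aligned with the input p-vector
    threshold: float  # realized crude-p cutoff q*k/m (0 when no discovery)
    n_discoveries: int
    q: float
    universe_size: int


def bh_select(p_values, q: float = 0.20, universe_size: int | None = None) -> BHResult:
    """Benjamini–Hochberg step-up selection at FDR level *q*.

    *universe_size* is the number of tests m the correction accounts for; it
    defaults to ``len(p_values)`` but may exceed it when only a subset of a
    larger test family is supplied (the remaining tests are then implicitly
    non-discoveries).  The realized crude-p cutoff ``q·k/m`` for k
    discoveries is returned alongside the flags.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) <= 0.0 or np.nanmax(p) > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if universe_size is None else int(universe_size)
    if m < len(p):
        raise ValueError("universe_size cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_max = rank
    flags = np.zeros(p.size, dtype=bool)
    if k_max:
        flags[order[:k_max]] = True
    threshold = q * k_max / m if k_max else 0.0
    return BHResult(flags, float(threshold), int(k_max), q, m)


@dataclass
class CorrelationResult:
    """Pearson (and gender-partialled) correlation of expression with age."""

    r: float
    p_value: float
    partial_r: float | None
    partial_p: float | None
    n: int
    alpha: float  # per-test Bonferroni threshold 0.05/k_tests


def _pearson_with_p(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0:
        return r, np.nan
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def age_correlation(
    expression,
    ages,
    gender=None,
    k_tests: int = 6,
    alpha_family: float = 0.05,
) -> CorrelationResult:
    """Correlate expression (−ΔCt scale) with age in adults.

    The crude association is Pearson's r with its two-sided p.  When a
    gender covariate is supplied, the partial correlation is computed by
    residualizing both expression and age on the gender indicator (with
    intercept) and correlating the residuals; its p uses ``df = n − 3``.
    The per-test threshold is ``alpha_family / k_tests``.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = _pearson_with_p(x, y, df=x.size - 2)

    partial_r = partial_p = None
    if gender is not None:
        g = pd.Categorical(np.asarray(gender)).codes.astype(float)
        if len(np.unique(g)) < 2:
            raise ValueError("both genders must be present for partial correlation")
        design = np.column_stack([np.ones_like(g), g])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        partial_r, partial_p = _pearson_with_p(rx, ry, df=x.size - 3)
    return CorrelationResult(r, p, partial_r, partial_p, int(x.size),
                             alpha_family / k_tests)


@dataclass
class AnovaResult:
    """One-way ANOVA over three cohorts with Bonferroni-adjusted pairwise tests."""

    f_statistic: float
    p_value: float
    pairwise_p: dict  # (group_i, group_j) -> Bonferroni-adjusted two-sample p


def three_group_compare(values_by_group: dict) -> AnovaResult:
    """One-way ANOVA across three cohorts plus α/3-adjusted pairwise t-tests."""
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[n], dtype=float) for n in names]
    if len(arrays) != 3:
        raise ValueError("exactly three groups required")
    for n, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 samples")
    f, p = stats.f_oneway(*arrays)
    pairwise = {}
    n_pairs = 3
    for i in range(3):
        for j in range(i + 1, 3):
            tp = stats.ttest_ind(arrays[i], arrays[j]).pvalue
            pairwise[(names[i], names[j])] = float(min(1.0, n_pairs * tp))
    return AnovaResult(float(f), float(p), pairwise)


@dataclass
class TransitionPattern:
    """Lifespan trajectory call for one assay over four ordered strata."""

    mirna_id: str | None
    pattern: str
    stratum_means: tuple  # mean expression (−ΔCt) per stratum, NaN if undetected
    detection_fractions: tuple
    contrast_p: tuple  # successive-stratum rank-test p-values (NaN if not run)
    contrast_signs: tuple  # "flat" | "up" | "down" per successive contrast


def call_transition_pattern(
    strata_values,
    alpha: float = 0.05,
    min_frac: float = 0.30,
    mirna_id: str | None = None,
    max_exact_arrangements: int = DEFAULT_MAX_EXACT_ARRANGEMENTS,
) -> TransitionPattern:
    """Call one of four lifespan transition patterns from four ordered strata.

    *strata_values* holds ΔCt observations for the strata preterm → child →
    young adult → middle-aged adult in that order; NaN marks censored wells.
    Detection below *min_frac* in both pre-adult strata together with
    detection in both adult strata is called ``adult_onset``.  Otherwise the
    three successive contrasts are rank-tested at ``alpha/3`` each and their
    expression-scale signs matched against the three remaining templates:
    (flat, down, down), (flat, up, down), (down, up, down).  Anything else is
    ``unclassified``.
    """
    strata = [np.asarray(v, dtype=float) for v in strata_values]
    if len(strata) != 4:
        raise ValueError("exactly four ordered strata are required")
    fracs = tuple(float(np.isfinite(v).mean()) if v.size else 0.0 for v in strata)
    means = tuple(
        float(-np.nanmean(v)) if np.isfinite(v).any() else float("nan") for v in strata
    )

    if fracs[0] < min_frac and fracs[1] < min_frac and fracs[2] >= min_frac and fracs[3] >= min_frac:
        return TransitionPattern(mirna_id, ADULT_ONSET, means, fracs,
                                 (np.nan,) * 3, ("na",) * 3)

    per_contrast_alpha = alpha / 3.0
    signs, pvals = [], []
    for lo, hi in ((0, 1), (1, 2), (2, 3)):
        try:
            res = wilcoxon_two_group(
                strata[lo], strata[hi], censor_policy="drop",
                max_exact_arrangements=max_exact_arrangements,
            )
        except UntestableError:
            signs.append("na")
            pvals.append(np.nan)
            continue
        pvals.append(res.p_value)
        if res.p_value >= per_contrast_alpha or res.direction == "tie":
            signs.append("flat")
        else:
            # expression rises when the later stratum is the higher-expressed one
            signs.append("up" if res.direction == "higher_in_b" else "down")
    pattern = _PATTERN_BY_SIGNS.get(tuple(signs), UNCLASSIFIED)
    return TransitionPattern(mirna_id, pattern, means, fracs, tuple(pvals), tuple(signs))


def aging_analysis(
    delta: DeltaCtMatrix,
    meta: pd.DataFrame,
    min_frac: float = 0.30,
    cutoff: float = ADULT_AGE_CUTOFF,
    q: float = 0.20,
    alpha_corr_family: float = 0.05,
    censor_policy: str = "impute",
    universe: str = "adult_detectable",
) -> pd.DataFrame:
    """Per-assay aging-diminution analysis over the adult cohort.

    The test universe defaults to assays detectable (≥ *min_frac*) across
    all adults pooled.  For each, the young vs middle-aged rank-sum p and the
    middle-over-young signed fold change (negative = declining with age) are
    computed; Benjamini–Hochberg at level *q* flags discoveries, and the
    discoveries are followed up with age correlation and gender-partialled
    correlation under Bonferroni ``alpha_corr_family / k`` where k is the
    number of discoveries.

    Returns a DataFrame indexed by miRNA id with columns
    ``signed_fold_change, p_value, bh_pass, pearson_r, pearson_p, partial_r,
    partial_p, bonferroni_alpha``; the realized BH cutoff and universe size
    are in ``.attrs``.
    """
    strata = split_adults(meta, cutoff=cutoff)
    adult_ids = [s for s in strata.index if s in delta.sample_ids]
    if not adult_ids:
        raise ValueError("no adult samples in the ΔCt matrix")
    adult_meta = meta.set_index("sample_id").loc[adult_ids]

    detected = delta.detected().loc[adult_ids]
    if universe == "adult_detectable":
        panel = [m for m in delta.mirna_ids if detected[m].mean() >= min_frac]
    elif universe == "all":
        panel = list(delta.mirna_ids)
    else:
        raise ValueError(f"unknown universe {universe!r}")

    filled = delta.imputed(censor_policy).loc[adult_ids]
    young_ids = [s for s in adult_ids if strata[s] == "young"]
    middle_ids = [s for s in adult_ids if strata[s] == "middle_aged"]

    records = []
    for mirna in panel:
        vy = filled.loc[young_ids, mirna].to_numpy()
        vm = filled.loc[middle_ids, mirna].to_numpy()
        try:
            res = wilcoxon_two_group(vy, vm, censor_policy="drop")
        except UntestableError:
            records.append({"mirna_id": mirna, "signed_fold_change": np.nan,
                            "p_value": np.nan})
            continue
        fc = signed_fold_change(float(np.nanmean(vm)), float(np.nanmean(vy)))
        records.append({"mirna_id": mirna, "signed_fold_change": fc,
                        "p_value": res.p_value})
    table = pd.DataFrame(records).set_index("mirna_id")

    testable = table["p_value"].notna()
    bh = bh_select(table.loc[testable, "p_value"].to_numpy(), q=q,
                   universe_size=len(panel))
    table["bh_pass"] = False
    table.loc[testable, "bh_pass"] = bh.pass_flags

    k = max(bh.n_discoveries, 1)
    for col in ("pearson_r", "pearson_p", "partial_r", "partial_p"):
        table[col] = np.nan
    table["bonferroni_alpha"] = alpha_corr_family / k
    ages = adult_meta["age"].astype(float).to_numpy()
    genders = adult_meta["gender"].to_numpy()
    for mirna in table.index[table["bh_pass"]]:
        expr = -filled[mirna].to_numpy()  # −ΔCt: log2 expression scale
        try:
            corr = age_correlation(expr, ages, gender=genders, k_tests=k,
                                   alpha_family=alpha_corr_family)
        except ValueError:
            continue
        table.loc[mirna, ["pearson_r", "pearson_p", "partial_r", "partial_p"]] = [
            corr.r, corr.p_value, corr.partial_r, corr.partial_p,
        ]
    table.attrs.update(
        bh_threshold=bh.threshold, bh_q=q, universe_size=bh.universe_size,
        n_discoveries=bh.n_discoveries, adult_cutoff=cutoff,
        n_young=len(young_ids), n_middle_aged=len(middle_ids),
    )
    return table
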