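"""Detectability filtering, rank-sum testing, and five-class assignment.

The core taxonomy compares two cohorts (canonically preterm infants, group
A, against adults, group B) and sorts every assay on the panel into one of
five classes:

``nonexpressed``
    detectable in neither cohort (below the detectability rule in both);
``age_constant``
    detectable in both, no significant difference;
``<A>_only`` / ``<B>_only``
    detectable in exactly one cohort (age-limited expression);
``down_in_<B>`` / ``up_in_<B>``
    detectable in both and significantly lower / higher expressed in B.

Detectability uses the ≥ 30 %-of-samples rule: an assay enters the analysis
only if it amplified in at least ``min_frac`` of the samples of at least one
cohort.  Differential testing is a two-sided Wilcoxon rank-sum test with a
Bonferroni family correction whose denominator is the number of detectable
assays on the analyzed panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ct_matrix import DeltaCtMatrix

logger = logging.getLogger(__name__)

NONEXPRESSED = "nonexpressed"
AGE_CONSTANT = "age_constant"
UNTESTABLE = "untestable"

#: Arrangement-count ceiling below which the exact permutation null of the
#: rank-sum statistic is enumerated; larger instances use the normal
#: approximation with midrank tie correction.
DEFAULT_MAX_EXACT_ARRANGEMENTS = 20_000


class UntestableError(ValueError):
    """Raised when a group has no usable values under the censor policy."""


def class_labels(group_a: str, group_b: str) -> tuple[str, ...]:
    """The five class labels for a concrete cohort pair, in display order."""
    return (
        NONEXPRESSED,
        AGE_CONSTANT,
        f"{group_a}_only",
        f"{group_b}_only",
        f"down_in_{group_b}",
        f"up_in_{group_b}",
    )


@dataclass
class DetectionProfile:
    """Per-assay detection fractions and detectability flags for two cohorts."""

    table: pd.DataFrame  # index = mirna_id; columns n_a, det_a, frac_a, flag_a, n_b, ...
    group_a: str
    group_b: str
    min_frac: float

    @property
    def detectable_any(self) -> pd.Index:
        """Assays detectable in at least one cohort (the analyzed panel)."""
        return self.table.index[self.table["flag_a"] | self.table["flag_b"]]

    @property
    def detectable_both(self) -> pd.Index:
        return self.table.index[self.table["flag_a"] & self.table["flag_b"]]


def detection_profile(
    matrix,
    meta: pd.DataFrame,
    groups: tuple[str, str] = ("preterm", "adult"),
    min_frac: float = 0.30,
) -> DetectionProfile:
    """Compute per-cohort detection fractions and apply the detectability rule.

    *matrix* may be a :class:`~mirlifespan.ct_matrix.CtMatrix` or
    :class:`~mirlifespan.ct_matrix.DeltaCtMatrix`; a cell counts as detected
    when its value is finite.  The boundary is inclusive: a fraction exactly
    equal to *min_frac* is detectable.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must lie in [0, 1], got {min_frac}")
    group_a, group_b = groups
    detected = matrix.detected()
    cols = {}
    for tag, grp in (("a", group_a), ("b", group_b)):
        ids = meta.loc[meta["group"] == grp, "sample_id"]
        ids = [s for s in ids if s in detected.index]
        if not ids:
            raise ValueError(f"group {grp!r} has no samples in the matrix")
        sub = detected.loc[ids]
        cols[f"n_{tag}"] = len(ids)
        cols[f"det_{tag}"] = sub.sum(axis=0).astype(int)
        cols[f"frac_{tag}"] = sub.mean(axis=0)
        cols[f"flag_{tag}"] = cols[f"frac_{tag}"] >= min_frac
    table = pd.DataFrame(cols, index=matrix.mirna_ids)
    return DetectionProfile(table, group_a=group_a, group_b=group_b, min_frac=min_frac)


@dataclass
class DifferentialResult:
    """Two-sided rank-sum comparison of one assay between two cohorts."""

    statistic: float  # midrank sum of group A
    p_value: float
    direction: str  # "higher_in_a" | "higher_in_b" | "tie" (expression scale)
    exact: bool
    n_a: int
    n_b: int


def _ranksum_exact_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p by full enumeration of group-A index choices.

    The two-sided p is the doubled smaller tail of the permutation null of
    the group-A midrank sum, capped at 1.  Rank sums are multiples of 0.5 so
    float comparisons are exact.
    """
    n = ranks.size
    w_obs = float(ranks[:n_a].sum())
    lo = hi = total = 0
    for idx in combinations(range(n), n_a):
        w = float(ranks.take(idx).sum())
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_two_group(
    values_a,
    values_b,
    censor_policy: str = "drop",
    max_exact_arrangements: int = DEFAULT_MAX_EXACT_ARRANGEMENTS,
) -> DifferentialResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test on ΔCt values.

    NaN entries are censored observations; under policy ``"drop"`` they are
    discarded (callers wanting detection-limit imputation substitute before
    calling, see :meth:`DeltaCtMatrix.imputed`).  When the number of
    arrangements ``C(n_a+n_b, n_a)`` is at most *max_exact_arrangements* the
    permutation null of the midrank-sum statistic is enumerated exactly;
    otherwise the normal approximation with midrank tie correction is used.

    Direction is reported on the expression scale: lower mean ΔCt = higher
    expression.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if censor_policy == "drop":
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    elif censor_policy != "none":
        raise ValueError(f"unknown censor policy {censor_policy!r}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise UntestableError("censored values present; apply a censor policy first")
    if a.size < 2 or b.size < 2:
        raise UntestableError(
            f"need >= 2 usable values per group, got {a.size} and {b.size}"
        )
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())

    if np.all(pooled == pooled[0]):
        # every observation tied: the statistic is degenerate and p = 1
        return DifferentialResult(w, 1.0, "tie", True, a.size, b.size)
    if math.comb(a.size + b.size, a.size) <= max_exact_arrangements:
        p = _ranksum_exact_p(ranks, a.size)
        exact = True
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        exact = False

    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a < mean_b:
        direction = "higher_in_a"  # lower ΔCt = more abundant
    elif mean_a > mean_b:
        direction = "higher_in_b"
    else:
        direction = "tie"
    return DifferentialResult(w, p, direction, exact, a.size, b.size)


def signed_fold_change(mean_delta_ct_num: float, mean_delta_ct_den: float) -> float:
    """Signed expression fold change of the numerator cohort over the denominator.

    The raw ratio is ``r = 2**(−ΔCt_num) / 2**(−ΔCt_den)`` computed from the
    cohort mean ΔCt (geometric-mean expression).  It is reported as ``r``
    when ``r ≥ 1`` and as ``−1/r`` otherwise, so the magnitude is always
    ≥ 1 and a negative sign means the numerator cohort is the
    *lower*-expressed one.  Calling with the older cohort as numerator makes
    a negative value mean decreasing expression with age.
    """
    if not (np.isfinite(mean_delta_ct_num) and np.isfinite(mean_delta_ct_den)):
        raise ValueError("both cohort mean ΔCt values must be finite")
    r = 2.0 ** (mean_delta_ct_den - mean_delta_ct_num)
    return float(r) if r >= 1.0 else float(-1.0 / r)


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold ``alpha_family / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha_family / n_tests


def assign_expression_classes(
    profile: DetectionProfile,
    delta: DeltaCtMatrix,
    meta: pd.DataFrame,
    alpha_family: float = 0.05,
    censor_policy: str = "impute",
    max_exact_arrangements: int = DEFAULT_MAX_EXACT_ARRANGEMENTS,
) -> pd.DataFrame:
    """Assign every panel assay to one of the five expression classes.

    Decision tree per assay:

    1. detectable in neither cohort → ``nonexpressed``;
    2. detectable in exactly one cohort → ``<that cohort>_only``;
    3. detectable in both → two-sided rank-sum test at the per-test
       Bonferroni threshold ``alpha_family / n_detectable``; non-significant
       → ``age_constant``, significant → ``down_in_<B>`` / ``up_in_<B>`` by
       the sign of the B-over-A fold change.

    Returns a DataFrame indexed by miRNA id with the class label, test
    p-value (present iff tested), per-test threshold, signed fold change of
    B relative to A, cohort mean ΔCt and detection fractions.  Assays that
    are detectable in both cohorts but untestable under the censor policy
    are kept under the distinct label ``untestable`` and logged.
    """
    if set(profile.table.index) != set(delta.mirna_ids):
        raise ValueError("detection profile and ΔCt matrix cover different panels")
    group_a, group_b = profile.group_a, profile.group_b
    lab_a_only, lab_b_only = f"{group_a}_only", f"{group_b}_only"
    lab_down, lab_up = f"down_in_{group_b}", f"up_in_{group_b}"

    n_detectable = len(profile.detectable_any)
    per_test_alpha = bonferroni_threshold(alpha_family, max(n_detectable, 1))

    filled = delta.imputed(censor_policy)
    ids_a = [s for s in meta.loc[meta["group"] == group_a, "sample_id"] if s in filled.index]
    ids_b = [s for s in meta.loc[meta["group"] == group_b, "sample_id"] if s in filled.index]

    rows = []
    n_untestable = 0
    for mirna in delta.mirna_ids:
        prof = profile.table.loc[mirna]
        rec = {
            "mirna_id": mirna,
            "class_label": None,
            "p_value": np.nan,
            "bonferroni_alpha": per_test_alpha,
            "signed_fold_change": np.nan,
            f"mean_dct_{group_a}": np.nan,
            f"mean_dct_{group_b}": np.nan,
            f"frac_{group_a}": prof["frac_a"],
            f"frac_{group_b}": prof["frac_b"],
        }
        flag_a, flag_b = bool(prof["flag_a"]), bool(prof["flag_b"])
        if not flag_a and not flag_b:
            rec["class_label"] = NONEXPRESSED
        elif flag_a != flag_b:
            rec["class_label"] = lab_a_only if flag_a else lab_b_only
        else:
            va = filled.loc[ids_a, mirna].to_numpy()
            vb = filled.loc[ids_b, mirna].to_numpy()
            try:
                res = wilcoxon_two_group(
                    va, vb, censor_policy="drop",
                    max_exact_arrangements=max_exact_arrangements,
                )
            except UntestableError:
                n_untestable += 1
                rec["class_label"] = UNTESTABLE
                rows.append(rec)
                continue
            mean_a = float(np.nanmean(va))
            mean_b = float(np.nanmean(vb))
            fc = signed_fold_change(mean_b, mean_a)  # B relative to A
            rec.update(
                p_value=res.p_value,
                signed_fold_change=fc,
                **{f"mean_dct_{group_a}": mean_a, f"mean_dct_{group_b}": mean_b},
            )
            if res.p_value < per_test_alpha:
                rec["class_label"] = lab_up if fc > 0 else lab_down
            else:
                rec["class_label"] = AGE_CONSTANT
        rows.append(rec)
    if n_untestable:
        logger.warning("%d assay(s) untestable under censor policy; labeled %r",
                       n_untestable, UNTESTABLE)
    out = pd.DataFrame(rows).set_index("mirna_id")
    out.attrs.update(
        group_a=group_a, group_b=group_b,
        n_detectable=n_detectable, per_test_alpha=per_test_alpha,
        alpha_family=alpha_family,
    )
    return out


def classification_summary(assignments: pd.DataFrame) -> dict:
    """Class counts plus the expressed/differential super-category breakdown.

    The *differential* super-category pools the age-limited and
    age-related classes (everything detectable except ``age_constant``);
    its per-class shares are percentages of that pool, so e.g. 81
    up-regulated of {1, 22, 20, 81} differential assays is 65 %.
    """
    if assignments.empty:
        raise ValueError("empty assignment set")
    group_a = assignments.attrs.get("group_a", "preterm")
    group_b = assignments.attrs.get("group_b", "adult")
    labels = class_labels(group_a, group_b)
    counts = {lab: int((assignments["class_label"] == lab).sum()) for lab in labels}
    n_untestable = int((assignments["class_label"] == UNTESTABLE).sum())
    if n_untestable:
        counts[UNTESTABLE] = n_untestable
    panel = len(assignments)
    differential = [lab for lab in labels if lab not in (NONEXPRESSED, AGE_CONSTANT)]
    diff_total = sum(counts[lab] for lab in differential)
    summary = {
        "panel_size": panel,
        "counts": counts,
        "percent_of_panel": {lab: 100.0 * c / panel for lab, c in counts.items()},
        "expressed_total": panel - counts[NONEXPRESSED] - n_untestable,
        "differential_total": diff_total,
        "differential_shares_percent": {
            lab: (100.0 * counts[lab] / diff_total if diff_total else 0.0)
            for lab in differential
        },
    }
    return summary
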