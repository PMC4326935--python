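"""Ct-table data model, readers/writers, and ΔCt normalization.

A qPCR panel run yields one threshold-cycle (Ct) value per (sample, assay)
well; wells that never cross the fluorescence threshold are reported by the
instrument as "Undetermined".  Those non-amplifying wells are *censored*
observations (the transcript is below the detection limit), not missing
data, and are carried through the pipeline as a distinct state rather than
silently dropped.

Internally a censored cell is stored as ``NaN`` inside an otherwise finite
float matrix; the :class:`CtMatrix` invariants guarantee the two readings
never mix (every cell is either a finite Ct in ``(0, ct_max]`` or censored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default detection-limit cycle count: microfluidic qPCR cards stop cycling
#: at 40, so a Ct at or above 40 cannot be distinguished from no amplification.
DEFAULT_CT_MAX = 40.0

#: Default instrument token for a well that never amplified.
DEFAULT_CENSORED_TOKEN = "Undetermined"

GROUP_LABELS = ("preterm", "child", "adult")


class FormatError(ValueError):
    """Raised when an input table violates the expected layout or content."""


class CensoredControlError(ValueError):
    """Raised when the endogenous control failed to amplify in some sample."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise FormatError(f"duplicate {what} id(s): {sorted(set(map(str, dups)))}")


@dataclass
class CtMatrix:
    """Rectangular samples × miRNAs threshold-cycle matrix.

    Parameters
    ----------
    values
        Float DataFrame, rows = samples, columns = miRNA assays.  ``NaN``
        marks a censored (non-amplifying) well.
    ct_max
        Detection-limit cycle count; all finite entries must lie in
        ``(0, ct_max]``.
    """

    values: pd.DataFrame
    ct_max: float = DEFAULT_CT_MAX

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        self.values = self.values.astype(float)
        self.values.index.name = "sample_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "miRNA")
        finite = self.values.to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() <= 0 or finite.max() > self.ct_max):
            raise FormatError(
                f"finite Ct values must lie in (0, {self.ct_max}]; "
                f"observed range [{finite.min():g}, {finite.max():g}]"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns

    def censored(self) -> pd.DataFrame:
        """Boolean mask of censored (non-amplifying) cells."""
        return self.values.isna()

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (finite Ct) cells."""
        return self.values.notna()


@dataclass
class DeltaCtMatrix:
    """ΔCt matrix normalized against an endogenous control.

    ``delta_ct[s, m] = Ct(s, m) − Ct(s, control)``; lower ΔCt means higher
    abundance, and relative expression is ``2**(−ΔCt)``.  Censoring in the
    target assay propagates (the control must be finite everywhere, enforced
    at construction).  The per-sample control Ct is retained so the
    detection-limit ΔCt (``ct_max − Ct(control)``) remains computable for
    censored-value imputation downstream.
    """

    values: pd.DataFrame
    control_id: str
    control_ct: pd.Series
    ct_max: float = DEFAULT_CT_MAX

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "miRNA")
        if not self.values.index.equals(self.control_ct.index):
            raise ValueError("control_ct index must match the sample axis")
        if self.control_ct.isna().any():
            bad = self.control_ct.index[self.control_ct.isna()].tolist()
            raise CensoredControlError(f"control Ct censored in sample(s) {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns

    def censored(self) -> pd.DataFrame:
        return self.values.isna()

    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def detection_limit(self) -> pd.Series:
        """Per-sample ΔCt at the detection limit, ``ct_max − Ct(control)``."""
        return self.ct_max - self.control_ct

    def imputed(self, policy: str = "impute") -> pd.DataFrame:
        """ΔCt values with censored cells resolved by *policy*.

        ``"impute"`` substitutes the per-sample detection-limit ΔCt (the
        standard censored-qPCR convention: the transcript is at most at the
        detection limit, so its ΔCt is at least ``ct_max − Ct(control)``);
        ``"drop"`` leaves censored cells as NaN for the caller to discard.
        """
        if policy == "drop":
            return self.values.copy()
        if policy == "impute":
            limit = self.detection_limit()
            return self.values.apply(lambda col: col.fillna(limit))
        raise ValueError(f"unknown censor policy {policy!r}")


def read_ct_table(
    path,
    censored_token: str = DEFAULT_CENSORED_TOKEN,
    ct_max: float = DEFAULT_CT_MAX,
    sep: str = "\t",
    samples_in_rows: bool = True,
) -> CtMatrix:
    """Read a delimited Ct table into a :class:`CtMatrix`.

    The canonical layout has sample ids in the first column and miRNA ids in
    the header; ``samples_in_rows=False`` transposes a vendor export with
    assays in rows.  Cells equal to *censored_token* become censored, as do
    finite values above *ct_max* (counted and logged).
    """
    with open(path) as fh:  # pandas mangles duplicate header ids; check raw
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "header")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if not samples_in_rows:
        raw = raw.T
    _check_unique(raw.index, "sample")
    _check_unique(raw.columns, "miRNA")

    def parse(cell: str, row: str, col: str) -> float:
        cell = cell.strip()
        if cell == censored_token:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise FormatError(
                f"non-numeric cell {cell!r} at sample {row!r}, miRNA {col!r} "
                f"(censored token is {censored_token!r})"
            ) from None

    values = pd.DataFrame(
        [
            [parse(raw.iat[i, j], str(raw.index[i]), str(raw.columns[j])) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    over = values > ct_max
    n_over = int(over.to_numpy().sum())
    if n_over:
        logger.warning("%d Ct value(s) above ct_max=%g coerced to censored", n_over, ct_max)
        values = values.mask(over)
    return CtMatrix(values, ct_max=ct_max)


def write_ct_table(
    matrix: CtMatrix,
    path,
    censored_token: str = DEFAULT_CENSORED_TOKEN,
    sep: str = "\t",
) -> None:
    """Write a :class:`CtMatrix` in the layout :func:`read_ct_table` accepts.

    Finite Ct values are written with ``repr`` precision so a write/read
    round-trip is bit-exact.
    """
    out = matrix.values.map(lambda v: censored_token if np.isnan(v) else repr(float(v)))
    out.to_csv(path, sep=sep, index_label="sample_id")


def read_sample_meta(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a sample-metadata table.

    Required columns: ``sample_id``, ``group`` (preterm/child/adult),
    ``age`` (years), ``gender`` (F/M).  Any further columns are kept as
    clinical flags.
    """
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame, matrix: CtMatrix | None = None) -> pd.DataFrame:
    required = {"sample_id", "group", "age", "gender"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing column(s) {sorted(missing)}")
    _check_unique(meta["sample_id"], "sample")
    bad_group = set(meta["group"]) - set(GROUP_LABELS)
    if bad_group:
        raise FormatError(f"unknown group label(s) {sorted(bad_group)}; allowed: {GROUP_LABELS}")
    if (meta["age"].astype(float) < 0).any():
        raise FormatError("ages must be non-negative")
    bad_gender = set(meta["gender"]) - {"F", "M"}
    if bad_gender:
        raise FormatError(f"gender must be 'F' or 'M'; found {sorted(bad_gender)}")
    if matrix is not None:
        absent = set(matrix.sample_ids) - set(meta["sample_id"])
        if absent:
            raise FormatError(f"samples without metadata: {sorted(absent)}")
    return meta.reset_index(drop=True)


def delta_ct(matrix: CtMatrix, control_id: str) -> DeltaCtMatrix:
    """Normalize a Ct matrix against an endogenous-control assay.

    The control column is consumed (excluded from the output); censored
    target wells stay censored.  A censored control in any sample makes
    normalization impossible for that sample and raises
    :class:`CensoredControlError` naming it.
    """
    if control_id not in matrix.mirna_ids:
        raise KeyError(f"control assay {control_id!r} not on the panel")
    control = matrix.values[control_id]
    if control.isna().any():
        bad = control.index[control.isna()].tolist()
        raise CensoredControlError(f"control Ct censored in sample(s) {bad}")
    targets = matrix.values.drop(columns=[control_id])
    delta = targets.sub(control, axis=0)
    return DeltaCtMatrix(delta, control_id=control_id, control_ct=control.copy(), ct_max=matrix.ct_max)


def expression_value(dct):
    """Relative expression ``2**(−ΔCt)`` (dimensionless, strictly positive).

    Accepts scalars or arrays; censored (NaN) inputs stay censored — a
    non-amplifying well bounds expression from above, it does not mean zero.
    """
    return np.exp2(np.negative(dct))
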