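"""Synthetic qPCR-panel simulator with planted ground truth.

Emulates the structure of a lifespan blood-miRNA screening study run on a
365-assay TaqMan low-density array: four age strata (preterm infants,
children, young adults ≤ 35 y, middle-aged adults > 35 y), an endogenous
small-RNA control, detection-limit censoring at 40 cycles, planted
expression classes with effects in ΔCt cycles, a subset of adult-expressed
assays whose expression declines linearly with adult age, and genomic
annotations with planted cytoband clusters.  Every generated artifact comes
with the truth used to plant it, so class recovery, aging-slope recovery and
hot-spot recovery can be scored exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_matrix import CtMatrix
from .hotspots import MiRNALocus

logger = logging.getLogger(__name__)

CONTROL_ID = "RNU48"

#: Planted class labels; the two-cohort labels match what
#: :func:`mirlifespan.classify.assign_expression_classes` emits for the
#: cohort pair ("preterm", "adult"), so recovery is a direct string match.
TRUTH_CLASSES = (
    "nonexpressed",
    "age_constant",
    "preterm_only",
    "adult_only",
    "down_in_adult",
    "up_in_adult",
)

#: Default planting fractions: the observed class split of a 365-assay panel
#: (137 nonexpressed, 104 constant, 1 preterm-only, 22 adult-only, 20 down,
#: 81 up), expressed as exact ratios so they sum to 1.
DEFAULT_CLASS_FRACTIONS = {
    "nonexpressed": 137 / 365,
    "age_constant": 104 / 365,
    "preterm_only": 1 / 365,
    "adult_only": 22 / 365,
    "down_in_adult": 20 / 365,
    "up_in_adult": 81 / 365,
}

ADULT_EXPRESSED_CLASSES = ("age_constant", "adult_only", "down_in_adult", "up_in_adult")

TRANSITION_TEMPLATES = (
    "adult_onset",
    "stable_then_down_then_diminish",
    "stable_then_up_then_diminish",
    "down_then_up_then_diminish",
)


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the screening-cohort design: 30 preterm infants, 66
    children, 32 young and 28 middle-aged adults; a 365-assay panel of which
    roughly a third is undetectable; planted between-cohort effects of 1.5
    ΔCt cycles against a within-cohort SD of 1.0 cycle; and six of the
    adult-expressed assays declining at +0.03 ΔCt cycles/year of adult age
    (ΔCt rising = expression falling).
    """

    panel_size: int = 365
    n_preterm: int = 30
    n_children: int = 66
    n_young_adults: int = 32
    n_middle_adults: int = 28
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    effect_size: float = 1.5  # ΔCt cycles between cohorts for planted classes
    sigma: float = 1.0  # within-cohort ΔCt SD, cycles
    aging_fraction: float = 6 / 227  # of adult-expressed assays
    aging_slope: float = 0.03  # ΔCt cycles per year of adult age (decline)
    control_ct_mean: float = 25.0
    control_ct_sd: float = 0.5
    ct_max: float = 40.0
    dropout_steepness: float = 0.0  # 0 disables the extra logistic dropout
    baseline_dct_low: float = 2.0
    baseline_dct_high: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions must sum to 1, got {total!r}")
        unknown = set(self.class_fractions) - set(TRUTH_CLASSES)
        if unknown:
            raise ConfigError(f"unknown class(es) in fractions: {sorted(unknown)}")
        for name in ("panel_size", "n_preterm", "n_children",
                     "n_young_adults", "n_middle_adults"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def undetected_dct(self) -> float:
        """Planted ΔCt mean for a non-amplifying assay (well past ct_max)."""
        return self.ct_max - self.control_ct_mean + 5.0


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a simulated dataset."""

    table: pd.DataFrame  # per miRNA: class_label, per-stratum mean ΔCt, slope, template
    config: SimulationConfig
    control_id: str = CONTROL_ID


def _apportion(panel_size: int, fractions: dict) -> dict:
    """Largest-remainder apportionment of the panel into class counts."""
    raw = {k: panel_size * v for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = panel_size - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def transition_template_means(
    template: str, base: float = 5.0, effect: float = 3.0, undetected: float = 20.0
) -> tuple[float, float, float, float]:
    """Planted per-stratum ΔCt means realizing one of the four trajectories.

    Strata are ordered preterm, child, young adult, middle-aged adult;
    remember ΔCt moves opposite to expression.
    """
    if template == "adult_onset":
        return (undetected, undetected, base, base)
    if template == "stable_then_down_then_diminish":
        return (base, base, base + effect, base + 2 * effect)
    if template == "stable_then_up_then_diminish":
        return (base, base, base - effect, base)
    if template == "down_then_up_then_diminish":
        return (base, base + effect, base, base + effect)
    raise ValueError(f"unknown template {template!r}")


def build_truth_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plant per-assay classes, stratum mean ΔCt values and aging slopes."""
    counts = _apportion(config.panel_size, config.class_fractions)
    labels = [lab for lab in TRUTH_CLASSES for _ in range(counts.get(lab, 0))]
    rng.shuffle(labels)
    und = config.undetected_dct
    eff = config.effect_size

    ids = [f"syn-miR-{i + 1:03d}" for i in range(config.panel_size)]
    base = rng.uniform(config.baseline_dct_low, config.baseline_dct_high,
                       size=config.panel_size)
    rows = []
    for mirna, lab, b in zip(ids, labels, base):
        if lab == "nonexpressed":
            means = (und, und, und, und)
        elif lab == "age_constant":
            means = (b, b, b, b)
        elif lab == "preterm_only":
            means = (b, und, und, und)
        elif lab == "adult_only":
            means = (und, und, b, b)
        elif lab == "down_in_adult":
            means = (b, b, b + eff, b + eff)
        else:  # up_in_adult
            means = (b, b, b - eff, b - eff)
        rows.append({
            "mirna_id": mirna, "class_label": lab,
            "dct_preterm": means[0], "dct_child": means[1],
            "dct_young": means[2], "dct_middle": means[3],
            "aging_slope": 0.0,
            "template": "adult_onset" if lab == "adult_only" else "",
        })
    table = pd.DataFrame(rows).set_index("mirna_id")

    adult_expressed = table.index[table["class_label"].isin(ADULT_EXPRESSED_CLASSES)]
    n_aging = int(round(config.aging_fraction * len(adult_expressed)))
    if n_aging:
        chosen = rng.choice(adult_expressed, size=min(n_aging, len(adult_expressed)),
                            replace=False)
        table.loc[chosen, "aging_slope"] = config.aging_slope
        # the slope is centred at the young-stratum mean age (28 y), so the
        # middle-aged stratum mean shifts by slope * (48.25 - 28) years
        mid_shift = config.aging_slope * (48.25 - 28.0)
        table.loc[chosen, "dct_middle"] = table.loc[chosen, "dct_young"] + mid_shift
    return table


def _sample_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_preterm):
        rows.append({"sample_id": f"PT{i + 1:03d}", "group": "preterm", "age": 0.0,
                     "gestational_weeks": float(rng.uniform(24.0, 32.0))})
    for i in range(config.n_children):
        rows.append({"sample_id": f"CH{i + 1:03d}", "group": "child",
                     "age": float(rng.uniform(1.0, 12.0)),
                     "gestational_weeks": np.nan})
    for i in range(config.n_young_adults):
        rows.append({"sample_id": f"AD{i + 1:03d}", "group": "adult",
                     "age": float(rng.uniform(21.0, 35.0)),
                     "gestational_weeks": np.nan})
    for i in range(config.n_middle_adults):
        rows.append({"sample_id": f"AD{config.n_young_adults + i + 1:03d}",
                     "group": "adult",
                     "age": float(rng.uniform(35.5, 61.0)),
                     "gestational_weeks": np.nan})
    meta = pd.DataFrame(rows)
    meta["gender"] = rng.choice(["F", "M"], size=len(meta))
    return meta[["sample_id", "group", "age", "gender", "gestational_weeks"]]


_STRATUM_COL = {"preterm": "dct_preterm", "child": "dct_child",
                "young": "dct_young", "middle": "dct_middle"}


def generate_dataset(
    config: SimulationConfig,
    truth_table: pd.DataFrame | None = None,
) -> tuple[CtMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a full Ct matrix, sample metadata and the planted truth.

    The control assay Ct is drawn per sample around its configured mean;
    each target well is ``Ct(control) + planted stratum mean ΔCt (+ aging
    slope term for adults) + N(0, σ)``, censored at the detection limit
    ``ct_max`` (plus an optional logistic extra dropout near the limit when
    ``dropout_steepness > 0``).  Fully deterministic under ``config.seed``.

    *truth_table* may override the planted per-stratum means (same columns
    as :func:`build_truth_table` produces), e.g. to realize an explicit
    transition-pattern template.
    """
    rng = np.random.default_rng(config.seed)
    truth = build_truth_table(config, rng) if truth_table is None else truth_table.copy()
    meta = _sample_metadata(config, rng)

    stratum = np.where(
        meta["group"] == "preterm", "preterm",
        np.where(meta["group"] == "child", "child",
                 np.where(meta["age"] <= 35.0, "young", "middle")),
    )
    n_s, n_m = len(meta), len(truth)

    control_ct = rng.normal(config.control_ct_mean, config.control_ct_sd, size=n_s)
    mean_cols = truth[[_STRATUM_COL[s] for s in ("preterm", "child", "young", "middle")]]
    stratum_idx = pd.Index(["preterm", "child", "young", "middle"]).get_indexer(stratum)
    mean_dct = mean_cols.to_numpy().T[stratum_idx, :]  # samples × miRNAs

    slopes = truth["aging_slope"].to_numpy()
    is_adult = (meta["group"] == "adult").to_numpy()
    age_dev = np.where(is_adult, meta["age"].to_numpy() - 28.0, 0.0)
    mean_dct = mean_dct + np.outer(age_dev, slopes)

    ct = control_ct[:, None] + mean_dct + rng.normal(0.0, config.sigma, size=(n_s, n_m))
    censored = ct >= config.ct_max
    if config.dropout_steepness > 0:
        from scipy.special import expit

        p_drop = expit(config.dropout_steepness * (ct - (config.ct_max - 2.0)))
        censored |= rng.random(size=ct.shape) < p_drop
    ct = np.where(censored, np.nan, np.maximum(ct, 1e-3))

    values = pd.DataFrame(ct, index=meta["sample_id"], columns=truth.index)
    values[CONTROL_ID] = np.clip(control_ct, 1e-3, config.ct_max)
    matrix = CtMatrix(values, ct_max=config.ct_max)
    return matrix, meta, SyntheticTruth(truth, config)


# ---------------------------------------------------------------------------
# Genomic annotation with planted cytoband clusters


DEFAULT_HOTSPOT_SPEC = (
    ("14q32.31", "age_constant", 16),
    ("9q22.32", "up_in_adult", 6),
)

_BAND_RE = re.compile(r"^([0-9]+|[XY])([pq].*)$")
_BAND_WIDTH = 2_000_000
_LOCUS_LEN = 80
_LOCUS_SPACING = 10_000


@dataclass
class SyntheticAnnotation:
    """Generated loci plus the matching UCSC-style cytoband windows."""

    loci: list
    cytobands: pd.DataFrame  # chrom, start (0-based), end (half-open), band, stain

    def write_annotation_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"mirna_id": l.mirna_id, "chromosome": l.chromosome,
                 "start": l.start, "end": l.end, "strand": l.strand,
                 "cytoband": l.cytoband}
                for l in self.loci
            ]
        ).to_csv(path, sep="\t", index=False)

    def write_cytoband_map(self, path) -> None:
        out = self.cytobands.copy()
        out["chrom"] = "chr" + out["chrom"].astype(str)
        out.to_csv(path, sep="\t", index=False, header=False)


class _BandAllocator:
    """Hands out non-overlapping band windows and locus coordinates."""

    def __init__(self):
        self._cursor: dict[str, int] = {}
        self._bands: dict[str, tuple[str, int, int]] = {}  # band -> chrom, start0, end0
        self._used: dict[str, int] = {}
        self._filler_i = 0

    def ensure_band(self, band: str) -> None:
        if band in self._bands:
            return
        m = _BAND_RE.match(band)
        if not m:
            raise ConfigError(f"cannot parse chromosome from band name {band!r}")
        chrom = m.group(1)
        start0 = self._cursor.get(chrom, 0)
        self._bands[band] = (chrom, start0, start0 + _BAND_WIDTH)
        self._cursor[chrom] = start0 + _BAND_WIDTH
        self._used[band] = 0

    def next_filler_band(self) -> str:
        chroms = [str(c) for c in range(1, 23)] + ["X"]
        chrom = chroms[self._filler_i % len(chroms)]
        arm = "p" if (self._filler_i // len(chroms)) % 2 else "q"
        band = f"{chrom}{arm}{11 + self._filler_i // (2 * len(chroms))}.{1 + self._filler_i % 9}"
        self._filler_i += 1
        self.ensure_band(band)
        return band

    def place(self, mirna_id: str, band: str, strand: str) -> MiRNALocus:
        chrom, band_start0, band_end0 = self._bands[band]
        offset = self._used[band] * _LOCUS_SPACING
        if band_start0 + offset + _LOCUS_LEN >= band_end0:
            raise ConfigError(f"band {band} is full")
        self._used[band] += 1
        start = band_start0 + offset + 1  # 1-based inclusive
        return MiRNALocus(mirna_id, chrom, start, start + _LOCUS_LEN - 1, strand, band)

    def cytoband_frame(self) -> pd.DataFrame:
        rows = []
        for band, (chrom, s0, e0) in sorted(self._bands.items()):
            m = _BAND_RE.match(band)
            rows.append({"chrom": chrom, "start": s0, "end": e0,
                         "band": m.group(2), "stain": "gneg"})
        return pd.DataFrame(rows)


def generate_annotation(
    classes: pd.Series,
    hotspot_spec=DEFAULT_HOTSPOT_SPEC,
    n_extra_loci: int = 36,
    max_per_band: int = 3,
    seed: int = 0,
) -> SyntheticAnnotation:
    """Place miRNAs on synthetic cytobands with planted same-class clusters.

    *classes* maps mirna_id → class label (e.g. ``truth.table['class_label']``).
    Each ``(band, class, count)`` entry of *hotspot_spec* plants that many
    same-class miRNAs on the named band; everything else is scattered at
    most *max_per_band* per filler band (far below the >5 hot-spot rule).
    *n_extra_loci* miRNAs receive a second locus on a filler band, so total
    placements exceed the panel size, as with real multi-copy miRNA genes.
    """
    rng = np.random.default_rng(seed)
    alloc = _BandAllocator()
    assigned: set[str] = set()
    loci: list[MiRNALocus] = []

    for band, class_label, count in hotspot_spec:
        pool = [m for m in classes.index
                if classes[m] == class_label and m not in assigned]
        if len(pool) < count:
            raise ConfigError(
                f"hotspot spec wants {count} {class_label!r} miRNAs on {band}, "
                f"only {len(pool)} available"
            )
        members = list(rng.choice(pool, size=count, replace=False))
        alloc.ensure_band(band)
        for m in members:
            loci.append(alloc.place(m, band, strand=str(rng.choice(["+", "-"]))))
        assigned.update(members)

    remaining = [m for m in classes.index if m not in assigned]
    band = None
    used_in_band = 0
    for m in remaining:
        if band is None or used_in_band >= max_per_band:
            band = alloc.next_filler_band()
            used_in_band = 0
        loci.append(alloc.place(m, band, strand=str(rng.choice(["+", "-"]))))
        used_in_band += 1

    if n_extra_loci:
        if n_extra_loci > len(remaining):
            raise ConfigError("n_extra_loci exceeds the number of scatterable miRNAs")
        extras = rng.choice(remaining, size=n_extra_loci, replace=False)
        band = None
        used_in_band = 0
        for m in extras:
            if band is None or used_in_band >= max_per_band:
                band = alloc.next_filler_band()
                used_in_band = 0
            loci.append(alloc.place(m, band, strand=str(rng.choice(["+", "-"]))))
            used_in_band += 1

    return SyntheticAnnotation(loci, alloc.cytoband_frame())


def generate_clinical_flags(
    matrix: CtMatrix,
    meta: pd.DataFrame,
    mirna_id: str,
    flag_name: str = "PVL",
    group: str = "preterm",
    p_detected: float = 0.10,
    p_undetected: float = 0.50,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a clinical outcome flag whose risk depends on detection state.

    Within *group*, each sample's outcome is Bernoulli with probability
    *p_detected* when the named miRNA amplified in that sample and
    *p_undetected* otherwise (e.g. 10 % leukomalacia risk with the marker
    detected vs 50 % without).  Samples outside the group get a missing
    flag.  Returns a copy of *meta* with the new nullable-boolean column.
    """
    for name, p in (("p_detected", p_detected), ("p_undetected", p_undetected)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {p}")
    if mirna_id not in matrix.mirna_ids:
        raise KeyError(f"{mirna_id!r} not on the panel")
    rng = np.random.default_rng(seed)
    detected = matrix.detected()[mirna_id]
    out = meta.copy()
    flags = pd.array([pd.NA] * len(out), dtype="boolean")
    for i, row in out.iterrows():
        if row["group"] != group:
            continue
        p = p_detected if detected.get(row["sample_id"], False) else p_undetected
        flags[i] = bool(rng.random() < p)
    out[flag_name] = flags
    return out


def score_class_recovery(truth: SyntheticTruth, assignments: pd.DataFrame) -> dict:
    """Macro-averaged recovery of planted classes by the classifier.

    Per planted class, recall = fraction of its assays the pipeline labeled
    identically; macro accuracy is the unweighted mean over planted classes
    present in the truth.
    """
    planted = truth.table["class_label"]
    called = assignments["class_label"].reindex(planted.index)
    per_class = {}
    for lab in TRUTH_CLASSES:
        mask = planted == lab
        if mask.any():
            per_class[lab] = float((called[mask] == lab).mean())
    macro = float(np.mean(list(per_class.values())))
    return {"per_class_recall": per_class, "macro_accuracy": macro,
            "overall_accuracy": float((called == planted).mean())}
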