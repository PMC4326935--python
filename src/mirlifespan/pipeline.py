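"""Study-level model object tying the analysis stages together.

:class:`LifespanStudy` wraps a Ct matrix, its sample metadata and optional
genomic annotation; :meth:`LifespanStudy.fit` runs normalization →
detectability filtering → five-class assignment → adult aging analysis →
transition-pattern calling → hot-spot scanning and returns a
:class:`StudyResults` carrying every table, the thresholds actually applied,
and writers for the on-disk report (classes.tsv, aging.tsv, hotspots.tsv,
patterns.tsv, summary.json).  Every stage is re-runnable in isolation from
those files — there is no hidden state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aging import aging_analysis, call_transition_pattern, split_adults
from .classify import (
    assign_expression_classes,
    classification_summary,
    detection_profile,
)
from .ct_matrix import (
    CtMatrix,
    DeltaCtMatrix,
    delta_ct,
    read_ct_table,
    read_sample_meta,
    validate_sample_meta,
)
from .hotspots import (
    chromosome_class_table,
    find_hotspots,
    hotspots_to_frame,
    load_annotation,
)
from .synthetic import CONTROL_ID, SimulationConfig, generate_dataset


class LifespanStudy:
    """A lifespan miRNA expression study: Ct data, metadata, annotation.

    Parameters
    ----------
    ct
        Raw threshold-cycle matrix including the endogenous-control assay.
    meta
        Sample metadata (sample_id, group, age, gender, clinical flags).
    control_id
        Endogenous-control assay used for ΔCt normalization.
    loci
        Optional genomic placements (:class:`~mirlifespan.hotspots.MiRNALocus`)
        enabling hot-spot scanning.
    """

    def __init__(self, ct: CtMatrix, meta: pd.DataFrame, control_id: str = CONTROL_ID,
                 loci=None):
        self.ct = ct
        self.meta = validate_sample_meta(meta, matrix=ct)
        self.control_id = control_id
        self.loci = list(loci) if loci is not None else None
        self.truth = None  # populated by from_simulation

    @classmethod
    def from_files(
        cls,
        ct_path,
        meta_path,
        annotation_path=None,
        cytoband_path=None,
        control_id: str = CONTROL_ID,
        censored_token: str = "Undetermined",
        ct_max: float = 40.0,
    ) -> "LifespanStudy":
        ct = read_ct_table(ct_path, censored_token=censored_token, ct_max=ct_max)
        meta = read_sample_meta(meta_path)
        loci = None
        if annotation_path is not None:
            loci = load_annotation(annotation_path, cytoband_map=cytoband_path)
        return cls(ct, meta, control_id=control_id, loci=loci)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig | None = None, with_annotation: bool = True
    ) -> "LifespanStudy":
        """Simulate a study-shaped dataset and keep the planted truth."""
        from .synthetic import generate_annotation

        config = config or SimulationConfig()
        matrix, meta, truth = generate_dataset(config)
        loci = None
        if with_annotation:
            ann = generate_annotation(truth.table["class_label"], seed=config.seed)
            loci = ann.loci
        study = cls(matrix, meta, control_id=truth.control_id, loci=loci)
        study.truth = truth
        return study

    def fit(
        self,
        groups: tuple[str, str] = ("preterm", "adult"),
        min_frac: float = 0.30,
        alpha_family: float = 0.05,
        adult_cutoff: float = 35.0,
        q: float = 0.20,
        cluster_threshold: int = 5,
        censor_policy: str = "impute",
        call_patterns: bool = True,
    ) -> "StudyResults":
        """Run the full analysis and return the results object."""
        delta = delta_ct(self.ct, self.control_id)
        profile = detection_profile(delta, self.meta, groups=groups, min_frac=min_frac)
        assignments = assign_expression_classes(
            profile, delta, self.meta,
            alpha_family=alpha_family, censor_policy=censor_policy,
        )
        summary = classification_summary(assignments)

        aging = None
        if (self.meta["group"] == "adult").sum() >= 4:
            aging = aging_analysis(
                delta, self.meta, min_frac=min_frac, cutoff=adult_cutoff, q=q,
                censor_policy=censor_policy,
            )

        patterns = None
        if call_patterns and set(self.meta["group"]) >= {"preterm", "child", "adult"}:
            patterns = self._call_patterns(delta, adult_cutoff, min_frac)

        hotspot_list = band_table = None
        if self.loci is not None:
            detectable = assignments.loc[
                assignments["class_label"] != "nonexpressed"
            ]
            band_table = chromosome_class_table(detectable, self.loci)
            hotspot_list = find_hotspots(band_table, cluster_threshold=cluster_threshold)

        params = {
            "groups": list(groups),
            "min_frac": min_frac,
            "alpha_family": alpha_family,
            "n_detectable": summary_n_detectable(assignments),
            "per_test_alpha": assignments.attrs["per_test_alpha"],
            "adult_cutoff": adult_cutoff,
            "bh_q": q,
            "bh_threshold": None if aging is None else aging.attrs["bh_threshold"],
            "bh_universe_size": None if aging is None else aging.attrs["universe_size"],
            "cluster_threshold": cluster_threshold,
            "censor_policy": censor_policy,
            "control_id": self.control_id,
            "version": __version__,
        }
        return StudyResults(
            study=self, delta=delta, profile=profile, assignments=assignments,
            class_summary=summary, aging=aging, patterns=patterns,
            band_table=band_table, hotspots=hotspot_list, params=params,
        )

    def _call_patterns(self, delta: DeltaCtMatrix, adult_cutoff: float,
                       min_frac: float) -> pd.DataFrame:
        strata_ids = {"preterm": [], "child": [], "young": [], "middle": []}
        adult_strata = split_adults(self.meta, cutoff=adult_cutoff)
        for _, row in self.meta.iterrows():
            sid = row["sample_id"]
            if sid not in delta.sample_ids:
                continue
            if row["group"] == "preterm":
                strata_ids["preterm"].append(sid)
            elif row["group"] == "child":
                strata_ids["child"].append(sid)
            elif adult_strata.get(sid) == "young":
                strata_ids["young"].append(sid)
            else:
                strata_ids["middle"].append(sid)
        order = ("preterm", "child", "young", "middle")
        rows = []
        for mirna in delta.mirna_ids:
            values = [delta.values.loc[strata_ids[s], mirna].to_numpy() for s in order]
            if not any(np.isfinite(v).any() for v in values):
                continue  # nothing detectable anywhere: no trajectory to call
            call = call_transition_pattern(values, min_frac=min_frac, mirna_id=mirna)
            rows.append({
                "mirna_id": mirna,
                "pattern": call.pattern,
                **{f"mean_expr_{s}": m for s, m in zip(order, call.stratum_means)},
                **{f"frac_{s}": f for s, f in zip(order, call.detection_fractions)},
                "contrast_p": ";".join(f"{p:.6g}" for p in call.contrast_p),
                "contrast_signs": ";".join(call.contrast_signs),
            })
        return pd.DataFrame(rows).set_index("mirna_id") if rows else None


def summary_n_detectable(assignments: pd.DataFrame) -> int:
    return int(assignments.attrs["n_detectable"])


@dataclass
class StudyResults:
    """Fitted study: per-assay tables, thresholds applied, report writers."""

    study: LifespanStudy
    delta: DeltaCtMatrix
    profile: object
    assignments: pd.DataFrame
    class_summary: dict
    aging: pd.DataFrame | None
    patterns: pd.DataFrame | None
    band_table: pd.DataFrame | None
    hotspots: list | None
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable run summary (class counts, thresholds, hot spots)."""
        s = self.class_summary
        lines = [
            "Lifespan miRNA expression study",
            "=" * 47,
            f"panel size:            {s['panel_size']}",
            f"detectable (>= {self.params['min_frac']:.0%} in a cohort): "
            f"{self.params['n_detectable']}",
            f"per-test Bonferroni threshold: "
            f"{self.params['alpha_family']}/{self.params['n_detectable']}"
            f" = {self.params['per_test_alpha']:.6g}",
            "",
            "class counts",
            "-" * 47,
        ]
        for lab, n in s["counts"].items():
            lines.append(f"  {lab:<22s} {n:4d}  ({s['percent_of_panel'][lab]:5.1f}% of panel)")
        if s["differential_total"]:
            lines.append("")
            lines.append(f"differential super-category: {s['differential_total']} assays")
            for lab, share in s["differential_shares_percent"].items():
                lines.append(f"  {lab:<22s} {share:5.1f}% of differential")
        if self.aging is not None:
            n_dim = int(self.aging["bh_pass"].sum())
            lines += [
                "",
                f"aging-diminished (BH q={self.params['bh_q']}, universe "
                f"{self.params['bh_universe_size']}): {n_dim} assays "
                f"(realized crude-p cutoff {self.params['bh_threshold']:.4g})",
            ]
        if self.hotspots is not None:
            lines.append("")
            lines.append(f"cytoband hot spots (> {self.params['cluster_threshold']} "
                         "same-class members):")
            for h in self.hotspots:
                lines.append(
                    f"  {h.cytoband:<10s} {h.class_label:<18s} "
                    f"{h.n_members}/{h.band_total} on band "
                    f"({100 * h.band_proportion:.1f}% vs "
                    f"{100 * h.genome_proportion:.1f}% genome-wide)"
                )
        return "\n".join(lines)

    def to_files(self, outdir) -> dict:
        """Write the report tables; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        self.assignments.to_csv(outdir / "classes.tsv", sep="\t")
        paths["classes"] = outdir / "classes.tsv"
        if self.aging is not None:
            self.aging.to_csv(outdir / "aging.tsv", sep="\t")
            paths["aging"] = outdir / "aging.tsv"
        if self.patterns is not None:
            self.patterns.to_csv(outdir / "patterns.tsv", sep="\t")
            paths["patterns"] = outdir / "patterns.tsv"
        if self.hotspots is not None:
            hotspots_to_frame(self.hotspots).to_csv(
                outdir / "hotspots.tsv", sep="\t", index=False
            )
            paths["hotspots"] = outdir / "hotspots.tsv"
        summary = {
            "params": {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                       for k, v in self.params.items()},
            "classification": self.class_summary,
        }
        if self.aging is not None:
            summary["aging"] = {
                "n_diminished": int(self.aging["bh_pass"].sum()),
                "bh_threshold": self.params["bh_threshold"],
            }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        paths["summary"] = outdir / "summary.json"
        return paths


def run_pipeline(config: dict, outdir=None) -> StudyResults:
    """One-shot dict-configured run (the CLI's engine).

    *config* either carries ``simulate: true`` plus ``simulation`` keyword
    overrides for :class:`~mirlifespan.synthetic.SimulationConfig`, or the
    input paths ``ct``, ``meta`` and optionally ``annotation`` /
    ``cytobands``.  Analysis parameters (min_frac, alpha_family,
    adult_cutoff, q, cluster_threshold, censor_policy) are passed through to
    :meth:`LifespanStudy.fit`.
    """
    if config.get("simulate"):
        sim = SimulationConfig(**config.get("simulation", {}))
        study = LifespanStudy.from_simulation(sim)
    else:
        for key in ("ct", "meta"):
            if key not in config:
                raise ValueError(f"config missing required input path {key!r}")
            if not Path(config[key]).exists():
                raise FileNotFoundError(f"{key} path does not exist: {config[key]}")
        study = LifespanStudy.from_files(
            config["ct"], config["meta"],
            annotation_path=config.get("annotation"),
            cytoband_path=config.get("cytobands"),
            control_id=config.get("control_id", CONTROL_ID),
            censored_token=config.get("censored_token", "Undetermined"),
            ct_max=config.get("ct_max", 40.0),
        )
    fit_keys = ("min_frac", "alpha_family", "adult_cutoff", "q",
                "cluster_threshold", "censor_policy")
    results = study.fit(**{k: config[k] for k in fit_keys if k in config})
    if outdir is not None:
        results.to_files(outdir)
    return results
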