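"""Genomic placement of classified miRNAs and cytoband hot-spot scanning.

A miRNA gene may be encoded at several genomic loci, and the cohort-level
expression classes cluster on certain cytogenetic bands.  A *hot spot* is a
band carrying a cluster of more than ``cluster_threshold`` (default 5, i.e.
≥ 6) miRNAs of the same expression class.  Coordinates are 1-based
inclusive throughout, the convention of miRBase GFF3; UCSC cytoband files
(0-based half-open) are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .ct_matrix import FormatError

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_THRESHOLD = 5  # "more than five" same-class members
GFF_FEATURE_TYPE = "miRNA_primary_transcript"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class MiRNALocus:
    """One genomic placement of a miRNA gene (a miRNA may own several)."""

    mirna_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"{self.mirna_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.mirna_id}: strand must be '+' or '-'")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class CytobandMap:
    """Interval lookup from genomic position to cytogenetic band name.

    Built from a UCSC ``cytoBand.txt``-style table (chrom, 0-based start,
    half-open end, band, stain); bands are reported fully qualified, e.g.
    ``14q32.31``.
    """

    def __init__(self, table: pd.DataFrame):
        self._trees: dict[str, IntervalTree] = {}
        for _, row in table.iterrows():
            chrom = _norm_chrom(str(row["chrom"]))
            start, end = int(row["start"]), int(row["end"])
            if end <= start:
                continue
            tree = self._trees.setdefault(chrom, IntervalTree())
            tree[start:end] = f"{chrom}{row['band']}"

    @classmethod
    def from_file(cls, path) -> "CytobandMap":
        table = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "band", "stain"],
            usecols=[0, 1, 2, 3],
        )
        return cls(table)

    def lookup(self, chromosome: str, position_1based: int) -> str | None:
        """Band containing a 1-based position, or None."""
        tree = self._trees.get(_norm_chrom(chromosome))
        if tree is None:
            return None
        hits = tree[position_1based - 1]  # convert to 0-based point
        return sorted(h.data for h in hits)[0] if hits else None


def _parse_gff3(path, feature_type: str) -> list[MiRNALocus]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type(feature_type):
        name = feat.attributes.get("Name", [feat.id])[0]
        loci.append(MiRNALocus(name, _norm_chrom(feat.seqid),
                               int(feat.start), int(feat.end), feat.strand))
    return loci


_TSV_REQUIRED = ("mirna_id", "chromosome", "start", "end", "strand")


def _parse_tsv(path) -> list[MiRNALocus]:
    table = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "chromosome": str})
    missing = set(_TSV_REQUIRED) - set(table.columns)
    if missing:
        raise FormatError(f"annotation TSV missing column(s) {sorted(missing)}")
    loci = []
    for _, row in table.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise FormatError(
                f"malformed coordinates for {row['mirna_id']!r}: "
                f"{row['start']!r}-{row['end']!r}"
            ) from None
        band = row.get("cytoband")
        band = None if (band is None or (isinstance(band, float) and np.isnan(band))) else str(band)
        loci.append(MiRNALocus(str(row["mirna_id"]), _norm_chrom(str(row["chromosome"])),
                               start, end, str(row["strand"]), band))
    return loci


def load_annotation(
    path,
    cytoband_map=None,
    feature_type: str = GFF_FEATURE_TYPE,
) -> list[MiRNALocus]:
    """Load miRNA genomic placements from miRBase-style GFF3 or a flat TSV.

    GFF3 input keeps only *feature_type* records (primary transcripts by
    default, so each record is one gene placement).  *cytoband_map* — a
    :class:`CytobandMap` or a path to a UCSC cytoband file — assigns bands
    by interval lookup at the locus start; a TSV may instead carry an
    explicit ``cytoband`` column.  Loci that cannot be banded when banding
    was requested are kept but warned about (band-level analyses skip them).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    first = next(line for line in text.splitlines() if line.strip())
    is_gff = first.startswith("##gff") or (
        len(first.split("\t")) == 9 and "=" in first.split("\t")[8]
    )
    loci = _parse_gff3(path, feature_type) if is_gff else _parse_tsv(path)

    if cytoband_map is not None:
        if not isinstance(cytoband_map, CytobandMap):
            cytoband_map = CytobandMap.from_file(cytoband_map)
        banded = []
        n_unresolved = 0
        for loc in loci:
            band = loc.cytoband or cytoband_map.lookup(loc.chromosome, loc.start)
            if band is None:
                n_unresolved += 1
            banded.append(MiRNALocus(loc.mirna_id, loc.chromosome, loc.start,
                                     loc.end, loc.strand, band))
        if n_unresolved:
            logger.warning("%d locus/loci without a resolvable cytoband; "
                           "excluded from band-level analyses", n_unresolved)
        loci = banded
    return loci


_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24}


def _chrom_key(chrom):
    return (_CHROM_ORDER.get(str(chrom), 99), str(chrom))


def chromosome_class_table(
    assignments: pd.DataFrame,
    loci: list[MiRNALocus],
) -> pd.DataFrame:
    """Distinct-miRNA class composition per chromosome and cytoband.

    Each miRNA contributes once per band it maps to, so the sum of band
    counts equals the number of banded placements (a 2-locus miRNA counts
    twice genome-wide, as in per-location accounting).  Classified miRNAs
    with no locus at all are pooled under the ``unplaced`` band.
    """
    class_of = assignments["class_label"]
    placed: dict[tuple, set] = {}
    seen_mirnas = set()
    for loc in loci:
        if loc.mirna_id not in class_of.index:
            continue
        seen_mirnas.add(loc.mirna_id)
        if loc.cytoband is None:
            continue
        key = (loc.chromosome, loc.cytoband, class_of[loc.mirna_id])
        placed.setdefault(key, set()).add(loc.mirna_id)
    for mirna in class_of.index:
        if mirna not in seen_mirnas:
            key = (UNPLACED, UNPLACED, class_of[mirna])
            placed.setdefault(key, set()).add(mirna)
    rows = [
        {
            "chromosome": chrom,
            "cytoband": band,
            "class_label": label,
            "n_mirnas": len(members),
            "mirna_ids": tuple(sorted(members)),
        }
        for (chrom, band, label), members in placed.items()
    ]
    table = pd.DataFrame(
        rows, columns=["chromosome", "cytoband", "class_label", "n_mirnas", "mirna_ids"]
    )
    table = table.sort_values(
        by=["chromosome", "cytoband", "class_label"],
        key=lambda col: col.map(_chrom_key) if col.name == "chromosome" else col,
    ).reset_index(drop=True)
    return table


@dataclass(frozen=True)
class Hotspot:
    """A cytoband carrying more than the threshold of same-class miRNAs."""

    cytoband: str
    chromosome: str
    class_label: str
    mirna_ids: tuple
    n_members: int
    band_total: int  # distinct classified miRNAs on the band
    band_proportion: float  # n_members / band_total
    genome_class_total: int  # distinct miRNAs of the class, genome-wide
    genome_total: int  # distinct classified miRNAs, genome-wide
    genome_proportion: float


def find_hotspots(
    band_table: pd.DataFrame,
    cluster_threshold: int = DEFAULT_CLUSTER_THRESHOLD,
) -> list[Hotspot]:
    """Scan a band composition table for same-class clusters.

    A (band, class) cell qualifies when its distinct-miRNA count is
    *strictly greater* than *cluster_threshold* ("more than five" → ≥ 6 at
    the default).  Each hot spot carries the within-band class proportion
    and, for contrast, the genome-wide proportion of that class among
    distinct classified miRNAs.  Output order (band, class) is deterministic
    and independent of input row order.
    """
    real = band_table[band_table["cytoband"] != UNPLACED]
    genome_members: dict[str, set] = {}
    all_members: set = set()
    for _, row in band_table.iterrows():
        genome_members.setdefault(row["class_label"], set()).update(row["mirna_ids"])
        all_members.update(row["mirna_ids"])
    genome_total = len(all_members)

    band_totals = {
        band: len(set().union(*grp["mirna_ids"]))
        for band, grp in real.groupby("cytoband")
    }
    spots = []
    for _, row in real.iterrows():
        if row["n_mirnas"] <= cluster_threshold:
            continue
        band_total = band_totals[row["cytoband"]]
        g_class = len(genome_members[row["class_label"]])
        spots.append(
            Hotspot(
                cytoband=row["cytoband"],
                chromosome=row["chromosome"],
                class_label=row["class_label"],
                mirna_ids=row["mirna_ids"],
                n_members=int(row["n_mirnas"]),
                band_total=band_total,
                band_proportion=row["n_mirnas"] / band_total,
                genome_class_total=g_class,
                genome_total=genome_total,
                genome_proportion=g_class / genome_total if genome_total else 0.0,
            )
        )
    spots.sort(key=lambda h: (_chrom_key(h.chromosome), h.cytoband, h.class_label))
    return spots


def hotspot_enrichment(hotspot: Hotspot) -> float:
    """Right-tail hypergeometric p for a hot spot's same-class concentration.

    Probability of drawing at least ``n_members`` miRNAs of the class when
    ``band_total`` miRNAs are sampled without replacement from a genome of
    ``genome_total`` containing ``genome_class_total`` of the class.
    """
    if not (hotspot.n_members <= hotspot.band_total <= hotspot.genome_total
            and hotspot.genome_class_total <= hotspot.genome_total):
        raise ValueError("inconsistent hot-spot totals")
    return float(
        stats.hypergeom.sf(
            hotspot.n_members - 1,
            hotspot.genome_total,
            hotspot.genome_class_total,
            hotspot.band_total,
        )
    )


def hotspots_to_frame(spots: list[Hotspot]) -> pd.DataFrame:
    """Flatten hot spots to a table (one row per band/class) for output."""
    return pd.DataFrame(
        [
            {
                "cytoband": h.cytoband,
                "chromosome": h.chromosome,
                "class_label": h.class_label,
                "n_members": h.n_members,
                "band_total": h.band_total,
                "band_percent": 100.0 * h.band_proportion,
                "genome_class_total": h.genome_class_total,
                "genome_total": h.genome_total,
                "genome_percent": 100.0 * h.genome_proportion,
                "hypergeom_p": hotspot_enrichment(h),
                "mirna_ids": ";".join(h.mirna_ids),
            }
            for h in spots
        ],
        columns=[
            "cytoband", "chromosome", "class_label", "n_members", "band_total",
            "band_percent", "genome_class_total", "genome_total",
            "genome_percent", "hypergeom_p", "mirna_ids",
        ],
    )
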