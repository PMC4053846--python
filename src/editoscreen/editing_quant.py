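"""Strand-aware editing-level quantification from pileup columns.

The editing level at a site is ``G / (A + G)`` counted on the edited strand:
for a plus-strand site the reference-strand A and G counts are used
directly; for a minus-strand site the plus-strand T and C counts are the
edited-strand A and G.  Sites with fewer than three quality-passing reads
carry no usable signal and are classified ``no_data``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import PileupColumn, SiteRecord

__all__ = [
    "EditingMeasurement",
    "SiteSampleMatrix",
    "LevelSummary",
    "measure_site",
    "classify_state",
    "quantify_sites",
    "call_candidates",
    "build_matrix",
    "summarize_levels",
    "matrix_correlation",
]

logger = logging.getLogger(__name__)

NO_DATA = "no_data"
EDITED = "edited"
COVERED_UNEDITED = "covered_unedited"

DEFAULT_MIN_TOTAL = 3
DEFAULT_MIN_EDITED_READS = 2
DEFAULT_MIN_LEVEL = 0.01


@dataclass
class EditingMeasurement:
    """Base counts at one site in one sample, on the edited strand."""

    site: SiteRecord
    sample: str
    a_reads: int
    g_reads: int
    other_reads: int
    state: str = NO_DATA

    @property
    def total(self) -> int:
        return self.a_reads + self.g_reads + self.other_reads

    @property
    def level(self) -> float | None:
        """G / (A + G), or None when no A/G reads were seen."""
        ag = self.a_reads + self.g_reads
        if ag == 0:
            return None
        return self.g_reads / ag


def classify_state(
    m: EditingMeasurement,
    min_total: int = DEFAULT_MIN_TOTAL,
    min_edited_reads: int = DEFAULT_MIN_EDITED_READS,
    min_level: float = DEFAULT_MIN_LEVEL,
) -> str:
    """Coverage-state classification of one measurement.

    ``no_data`` below ``min_total`` reads; ``edited`` with at least
    ``min_edited_reads`` G reads at a level of at least ``min_level``;
    otherwise ``covered_unedited``.
    """
    if m.total < min_total:
        return NO_DATA
    lvl = m.level
    if m.g_reads >= min_edited_reads and lvl is not None and lvl >= min_level:
        return EDITED
    return COVERED_UNEDITED


def measure_site(
    col: PileupColumn,
    site: SiteRecord,
    sample: str = "sample",
    min_total: int = DEFAULT_MIN_TOTAL,
    min_edited_reads: int = DEFAULT_MIN_EDITED_READS,
    min_level: float = DEFAULT_MIN_LEVEL,
) -> EditingMeasurement:
    """Fold a reference-strand pileup column onto the edited strand.

    Raises on coordinate mismatch between the column and the site.
    """
    if (col.chrom, col.pos1) != (site.chrom, site.pos1):
        raise ValueError(
            f"pileup column {col.chrom}:{col.pos1} does not match site "
            f"{site.chrom}:{site.pos1}"
        )
    c = col.filtered_counts
    if site.strand == "+":
        a, g = c["A"], c["G"]
        other = c["C"] + c["T"]
    else:
        a, g = c["T"], c["C"]
        other = c["A"] + c["G"]
    m = EditingMeasurement(site=site, sample=sample, a_reads=a, g_reads=g,
                           other_reads=other)
    m.state = classify_state(m, min_total, min_edited_reads, min_level)
    return m


def quantify_sites(
    cols: Iterable[PileupColumn],
    sites: Sequence[SiteRecord],
    sample: str = "sample",
    **state_kwargs,
) -> list[EditingMeasurement]:
    """Measure every site found in a pileup stream; sites absent from the
    stream get a zero-count ``no_data`` measurement."""
    by_key = {(s.chrom, s.pos1): s for s in sites}
    out: dict[tuple[str, int], EditingMeasurement] = {}
    for col in cols:
        site = by_key.get((col.chrom, col.pos1))
        if site is None:
            continue
        out[(col.chrom, col.pos1)] = measure_site(
            col, site, sample, **state_kwargs
        )
    measurements = []
    for s in sites:
        m = out.get((s.chrom, s.pos1))
        if m is None:
            m = EditingMeasurement(site=s, sample=sample, a_reads=0,
                                   g_reads=0, other_reads=0, state=NO_DATA)
        measurements.append(m)
    return measurements


def call_candidates(
    cols: Iterable[PileupColumn],
    species: str = "sample",
    edited_reads_gt: int = 5,
    level_gt: float = 0.01,
    minus_strand: bool = False,
) -> Iterator[tuple[SiteRecord, EditingMeasurement]]:
    """De-novo candidate calling over a pileup stream.

    A plus-strand reference-A column is called when its G-read count exceeds
    ``edited_reads_gt`` and its level exceeds ``level_gt`` (both strictly).
    With ``minus_strand`` enabled, reference-T columns are additionally
    scanned for T→C (edited-strand A→G) signals.
    """
    for col in cols:
        configs = []
        if col.ref_base == "A":
            configs.append("+")
        if minus_strand and col.ref_base == "T":
            configs.append("-")
        for strand in configs:
            site = SiteRecord(species=species, chrom=col.chrom,
                              pos1=col.pos1, strand=strand)
            m = measure_site(col, site, sample=species)
            lvl = m.level
            if m.g_reads > edited_reads_gt and lvl is not None \
                    and lvl > level_gt:
                yield site, m


# ---------------------------------------------------------------------------
# site × sample matrices and summaries
# ---------------------------------------------------------------------------


class SiteSampleMatrix:
    """Rectangular site × sample grid of measurements.

    Rows follow genomic order (chrom, pos1, strand); columns follow first
    appearance in the input.  Missing cells are zero-count ``no_data``.
    """

    def __init__(self, sites: list[SiteRecord], samples: list[str],
                 cells: dict[tuple[tuple, str], EditingMeasurement]):
        self.sites = sites
        self.samples = samples
        self.cells = cells

    def get(self, site: SiteRecord, sample: str) -> EditingMeasurement:
        return self.cells[(site.key, sample)]

    def levels(self) -> pd.DataFrame:
        """Editing levels (NaN where undefined), sites × samples."""
        data = {
            sample: [
                np.nan if (lv := self.cells[(s.key, sample)].level) is None
                else lv
                for s in self.sites
            ]
            for sample in self.samples
        }
        index = [f"{s.chrom}:{s.pos1}:{s.strand}" for s in self.sites]
        return pd.DataFrame(data, index=index)

    def states(self) -> pd.DataFrame:
        data = {
            sample: [self.cells[(s.key, sample)].state for s in self.sites]
            for sample in self.samples
        }
        index = [f"{s.chrom}:{s.pos1}:{s.strand}" for s in self.sites]
        return pd.DataFrame(data, index=index)

    def coverage(self) -> pd.DataFrame:
        data = {
            sample: [self.cells[(s.key, sample)].total for s in self.sites]
            for sample in self.samples
        }
        index = [f"{s.chrom}:{s.pos1}:{s.strand}" for s in self.sites]
        return pd.DataFrame(data, index=index)


def build_matrix(measurements: Iterable[EditingMeasurement]) -> SiteSampleMatrix:
    """Assemble measurements into a rectangular matrix.

    Duplicate (site, sample) pairs are an error; (site, sample) holes are
    filled with zero-count ``no_data`` cells.
    """
    cells: dict[tuple[tuple, str], EditingMeasurement] = {}
    site_by_key: dict[tuple, SiteRecord] = {}
    samples: list[str] = []
    for m in measurements:
        key = (m.site.key, m.sample)
        if key in cells:
            raise ValueError(f"duplicate measurement for {key}")
        cells[key] = m
        site_by_key.setdefault(m.site.key, m.site)
        if m.sample not in samples:
            samples.append(m.sample)
    sites = sorted(site_by_key.values(),
                   key=lambda s: (s.chrom, s.pos1, s.strand))
    for s in sites:
        for sample in samples:
            cells.setdefault(
                (s.key, sample),
                EditingMeasurement(site=s, sample=sample, a_reads=0,
                                   g_reads=0, other_reads=0, state=NO_DATA),
            )
    return SiteSampleMatrix(sites, samples, cells)


@dataclass
class LevelSummary:
    """Per-site and per-group editing-level statistics."""

    per_site: pd.DataFrame  # index site key string; mean, sd, n_defined, expression
    group_means: dict[str, float]
    group_mean_sd: dict[str, float]
    expression_sample: str


def summarize_levels(
    matrix: SiteSampleMatrix,
    group_labels: dict[tuple, str] | None = None,
) -> LevelSummary:
    """Per-site mean/SD of editing levels across samples, plus group means.

    The SD is the sample standard deviation (ddof=1) over samples where the
    level is defined; sites with no defined level are excluded with a log
    entry.  The per-site expression proxy is the read count in the single
    deepest sample (maximal summed coverage across sites), mirroring the
    use of the highest-depth strain for expression.
    """
    levels = matrix.levels()
    coverage = matrix.coverage()
    if coverage.empty:
        raise ValueError("empty matrix")
    expression_sample = coverage.sum(axis=0).idxmax()
    rows = []
    labels = []
    for s in matrix.sites:
        idx = f"{s.chrom}:{s.pos1}:{s.strand}"
        vals = levels.loc[idx].dropna()
        if vals.empty:
            logger.info("site %s has no defined editing level; excluded", idx)
            continue
        rows.append(
            {
                "site": idx,
                "mean_level": float(vals.mean()),
                "sd_level": float(vals.std(ddof=1)) if len(vals) > 1
                else 0.0,
                "n_defined": int(len(vals)),
                "expression": int(coverage.loc[idx, expression_sample]),
            }
        )
        labels.append(
            group_labels.get(s.key, "all") if group_labels else "all"
        )
    per_site = pd.DataFrame(rows).set_index("site")
    per_site["group"] = labels
    group_means = (
        per_site.groupby("group")["mean_level"].mean().to_dict()
    )
    group_mean_sd = per_site.groupby("group")["sd_level"].mean().to_dict()
    return LevelSummary(
        per_site=per_site,
        group_means=group_means,
        group_mean_sd=group_mean_sd,
        expression_sample=expression_sample,
    )


def matrix_correlation(m1: SiteSampleMatrix, m2: SiteSampleMatrix) -> float:
    """Pearson correlation of per-site mean levels between two matrices,
    restricted to sites with a defined level in both."""
    s1 = m1.levels().mean(axis=1, skipna=True)
    s2 = m2.levels().mean(axis=1, skipna=True)
    joined = pd.concat([s1, s2], axis=1, join="inner").dropna()
    if len(joined) < 2:
        raise ValueError("fewer than two sites defined in both matrices")
    return float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
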