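"""Downstream conservation statistics for edited-site catalogs.

Covers: greedy site-accumulation curves across strains, neighbor-preference
motif matrices around the edited adenosine, genomic-region and recoding
classification, the G-reversion asymmetry between two species, and a
sequence-level scan for candidate exon-complementary sequences (ECS) — the
genomic region that base-pairs with the edited exon to form the dsRNA
structure ADAR requires.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .alignment import ScoringScheme, smith_waterman
from .conservation_screen import GenomicWindow, align_windows, extract_window
from .io_formats import GenomeAssembly, SiteRecord, reverse_complement

__all__ = [
    "AccumulationCurve",
    "MotifMatrix",
    "RegionReport",
    "ReversionReport",
    "ReversionAnalysis",
    "EcsHit",
    "accumulation_curve",
    "motif_matrix",
    "classify_regions",
    "parse_aa_change",
    "fisher_exact_2x2",
    "reversion_analysis",
    "find_ecs",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# accumulation curves
# ---------------------------------------------------------------------------


@dataclass
class AccumulationCurve:
    """Cumulative distinct-site counts under greedy minimal-addition order."""

    ordered_samples: list[str]
    cumulative_counts: list[int]
    total: int

    @property
    def fraction_at_k(self) -> list[float]:
        return [c / self.total for c in self.cumulative_counts]


def accumulation_curve(site_sets: dict[str, set]) -> AccumulationCurve:
    """Greedy accumulation: start from the smallest sample, then repeatedly
    add the sample contributing the fewest new sites.  Ties break
    lexicographically by sample name."""
    if not site_sets:
        raise ValueError("no samples given")
    remaining = dict(site_sets)
    order: list[str] = []
    cumulative: list[int] = []
    covered: set = set()
    first = min(remaining, key=lambda s: (len(remaining[s]), s))
    order.append(first)
    covered |= remaining.pop(first)
    cumulative.append(len(covered))
    while remaining:
        nxt = min(remaining, key=lambda s: (len(remaining[s] - covered), s))
        order.append(nxt)
        covered |= remaining.pop(nxt)
        cumulative.append(len(covered))
    return AccumulationCurve(order, cumulative, len(covered))


# ---------------------------------------------------------------------------
# motif matrix
# ---------------------------------------------------------------------------


@dataclass
class MotifMatrix:
    """Per-offset base frequencies around the edited base.

    ``frequencies`` is indexed by offset (−halfwidth..+halfwidth) with
    columns A, C, G, T; each row sums to 1.  Offset 0 is degenerate at A
    for editing-site input.  The layout is directly consumable by logo
    renderers expecting a position × base probability matrix.
    """

    frequencies: pd.DataFrame
    n_windows: int

    def information_content(self) -> pd.Series:
        """Per-offset information content 2 + Σ p·log2 p (bits)."""
        p = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return pd.Series(2.0 + plogp.sum(axis=1),
                         index=self.frequencies.index)


def motif_matrix(windows: list[GenomicWindow], halfwidth: int = 10) -> MotifMatrix:
    """Empirical base frequencies at offsets ±halfwidth around the center."""
    if not windows:
        raise ValueError("no windows given")
    offsets = range(-halfwidth, halfwidth + 1)
    counts = {off: Counter() for off in offsets}
    for w in windows:
        if w.center_index - halfwidth < 0 or \
                w.center_index + halfwidth >= len(w.seq):
            raise ValueError("window too short for requested halfwidth")
        for off in offsets:
            counts[off][w.seq[w.center_index + off]] += 1
    rows = []
    for off in offsets:
        n = sum(counts[off][b] for b in "ACGT")
        rows.append([counts[off][b] / n if n else 0.0 for b in "ACGT"])
    freq = pd.DataFrame(rows, index=list(offsets), columns=list("ACGT"))
    freq.index.name = "offset"
    return MotifMatrix(frequencies=freq, n_windows=len(windows))


# ---------------------------------------------------------------------------
# genomic-region / recoding classification
# ---------------------------------------------------------------------------

_AA_CHANGE = re.compile(r"p\.([A-Za-z*]+?)(\d+)([A-Za-z*]+)$")
_STOP_TOKENS = {"stop", "*", "X", "Ter"}


def parse_aa_change(substitution: str | None) -> tuple[str, str] | None:
    """Extract (ref_aa, alt_aa) from an annotation like
    ``NM_000826:c.A1820G:p.Q607R``; None when absent or unparseable."""
    if not substitution:
        return None
    token = substitution.split(":")[-1]
    m = _AA_CHANGE.match(token)
    if not m:
        return None
    return m.group(1), m.group(3)


def _is_nonsynonymous(change: tuple[str, str]) -> bool:
    ref, alt = change
    if alt in _STOP_TOKENS or ref in _STOP_TOKENS:
        return ref != alt
    return ref != alt


@dataclass
class RegionReport:
    """Counts of sites per genomic region class plus recoding statistics.

    ``cds_rows`` counts every CDS-labeled site; ``annotated_cds`` only those
    with a parseable amino-acid annotation (the synonymy denominator).
    Both are exposed because catalogs may carry CDS rows without an
    annotated substitution.
    """

    total: int
    region_counts: dict[str, int]
    cds_rows: int
    annotated_cds: int
    nonsynonymous: int
    synonymous: int
    unannotated_cds: int
    intronic: int
    intronic_in_recoding_genes: int
    per_gene: dict[str, dict[str, int]]

    @property
    def nonsynonymous_fraction(self) -> float:
        return self.nonsynonymous / self.annotated_cds \
            if self.annotated_cds else float("nan")


def classify_regions(sites: list[SiteRecord]) -> RegionReport:
    """Region and recoding classification of an annotated site list.

    A coding site is non-synonymous iff the reference and alternate
    amino-acid symbols of its substitution annotation differ (stop gain
    counts as non-synonymous).  An intronic site is "in a recoding gene"
    when its gene also carries at least one CDS site in the same list.
    """
    region_counts: Counter = Counter()
    per_gene: dict[str, Counter] = {}
    nonsyn = syn = unannot_cds = 0
    genes_with_cds: set[str] = set()
    for s in sites:
        region = s.region or "unannotated"
        region_counts[region] += 1
        if s.gene:
            per_gene.setdefault(s.gene, Counter())[region] += 1
        if region == "CDS":
            if s.gene:
                genes_with_cds.add(s.gene)
            change = parse_aa_change(s.substitution)
            if change is None:
                unannot_cds += 1
                logger.info("CDS site %s:%s lacks a substitution annotation",
                            s.chrom, s.pos1)
            elif _is_nonsynonymous(change):
                nonsyn += 1
            else:
                syn += 1
    intronic_sites = [s for s in sites if s.region == "intron"]
    intronic_in_recoding = sum(
        1 for s in intronic_sites if s.gene and s.gene in genes_with_cds
    )
    cds_rows = region_counts.get("CDS", 0)
    return RegionReport(
        total=len(sites),
        region_counts=dict(region_counts),
        cds_rows=cds_rows,
        annotated_cds=cds_rows - unannot_cds,
        nonsynonymous=nonsyn,
        synonymous=syn,
        unannotated_cds=unannot_cds,
        intronic=len(intronic_sites),
        intronic_in_recoding_genes=intronic_in_recoding,
        per_gene={g: dict(c) for g, c in per_gene.items()},
    )


# ---------------------------------------------------------------------------
# exact Fisher test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table by integer hypergeometric
    enumeration.

    Sums the probabilities of all tables (with the observed margins) whose
    point probability does not exceed the observed one; the comparison is
    done on exact integer numerators over the common denominator, so tie
    handling is exact rather than float-epsilon based.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    kept = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += num_k
        if num_k <= num_obs:
            kept += num_k
    return float(Fraction(kept, total))


# ---------------------------------------------------------------------------
# G-reversion asymmetry
# ---------------------------------------------------------------------------


@dataclass
class ReversionReport:
    """Counterpart-base distribution for one conversion direction.

    ``fraction_g`` uses all matched counterparts as denominator;
    ``fraction_g_of_ag`` restricts the denominator to A/G counterparts
    (the two readings of "sites with matching position" — both reported).
    """

    direction: str
    n_sites: int
    matched_sites: int
    unmatched_sites: int
    counterpart_base_counts: dict[str, int]
    control_matched: int = 0
    control_base_counts: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_g(self) -> float:
        return self.counterpart_base_counts.get("G", 0) / self.matched_sites \
            if self.matched_sites else float("nan")

    @property
    def fraction_g_of_ag(self) -> float:
        ag = (self.counterpart_base_counts.get("A", 0)
              + self.counterpart_base_counts.get("G", 0))
        return self.counterpart_base_counts.get("G", 0) / ag \
            if ag else float("nan")

    @property
    def control_fraction_g(self) -> float:
        return self.control_base_counts.get("G", 0) / self.control_matched \
            if self.control_matched else float("nan")


@dataclass
class ReversionAnalysis:
    """Both directions plus the 2×2 G vs non-G contingency comparison."""

    forward: ReversionReport
    backward: ReversionReport
    contingency: list[list[int]]
    odds_ratio: float
    fisher_p: float

    @property
    def fold_change(self) -> float:
        return self.forward.fraction_g / self.backward.fraction_g


def _counterpart_base(
    site: SiteRecord,
    own_genome: GenomeAssembly,
    other_genome: GenomeAssembly,
    flank: int,
    min_identical: int,
    scoring: ScoringScheme,
    edited_keys: set[tuple[str, int, str]],
    control_offset_max: int,
) -> tuple[str | None, str | None]:
    """(counterpart base, control counterpart base) on the edited strand,
    None where the window does not align or has no paired column."""
    try:
        qw = extract_window(own_genome, site, flank, require_center_a=True)
        sw_site = SiteRecord(species=other_genome.name, chrom=site.chrom,
                             pos1=site.pos1, strand=site.strand)
        sw = extract_window(other_genome, sw_site, flank,
                            require_center_a=False)
    except (IndexError, KeyError, ValueError) as exc:
        logger.warning("reversion: skipping %s:%s: %s",
                       site.chrom, site.pos1, exc)
        return None, None
    aln = align_windows(qw, sw, scoring)
    if aln.identical < min_identical or aln.center_partner_index is None:
        return None, None
    counterpart = sw.seq[aln.center_partner_index]

    # control: nearest non-edited A within +-control_offset_max nt on the
    # edited strand, upstream first on ties
    control = None
    found = False
    for off in range(1, control_offset_max + 1):
        for signed in (-off, off):  # upstream first on ties
            idx = qw.center_index + signed
            if not (0 <= idx < len(qw.seq)) or qw.seq[idx] != "A":
                continue
            if site.strand == "+":
                pos1 = site.pos1 + signed
            else:
                pos1 = site.pos1 - signed
            if (site.chrom, pos1, site.strand) in edited_keys:
                continue
            full = align_windows(qw, sw, scoring, keep_alignment=True)
            pairs = full.alignment.pairs if full.alignment else {}
            partner = pairs.get(idx)
            if partner is not None:
                control = sw.seq[partner]
            found = True
            break
        if found:
            break
    return counterpart, control


def _direction_report(
    direction: str,
    sites: list[SiteRecord],
    own_genome: GenomeAssembly,
    other_genome: GenomeAssembly,
    flank: int,
    min_identical: int,
    scoring: ScoringScheme,
    control_offset_max: int,
) -> ReversionReport:
    edited_keys = {s.key for s in sites}
    counts: Counter = Counter()
    ctrl_counts: Counter = Counter()
    matched = unmatched = ctrl_matched = 0
    for site in sites:
        base, ctrl = _counterpart_base(
            site, own_genome, other_genome, flank, min_identical, scoring,
            edited_keys, control_offset_max,
        )
        if base is None:
            unmatched += 1
            continue
        matched += 1
        counts[base] += 1
        if ctrl is not None:
            ctrl_matched += 1
            ctrl_counts[ctrl] += 1
    return ReversionReport(
        direction=direction,
        n_sites=len(sites),
        matched_sites=matched,
        unmatched_sites=unmatched,
        counterpart_base_counts=dict(counts),
        control_matched=ctrl_matched,
        control_base_counts=dict(ctrl_counts),
    )


def reversion_analysis(
    query_sites: list[SiteRecord],
    subject_sites: list[SiteRecord],
    query_genome: GenomeAssembly,
    subject_genome: GenomeAssembly,
    flank: int = 40,
    min_identical: int = 70,
    scoring: ScoringScheme = ScoringScheme(),
    control_offset_max: int = 20,
) -> ReversionAnalysis:
    """G-reversion asymmetry between two species.

    For every editing site the window at the orthologous locus of the other
    genome is aligned to the site's own window; when the alignment reaches
    ``min_identical`` identical columns, the base paired with the edited
    position is its counterpart (any base — requiring an A↔A center here
    would exclude exactly the reverted sites being counted).  The control
    repeats the lookup for the nearest non-edited A near each site.
    The two directions are compared in a 2×2 G vs non-G table with a sample
    odds ratio and a two-sided exact Fisher p.
    """
    fwd = _direction_report(
        f"{query_genome.name}->{subject_genome.name}", query_sites,
        query_genome, subject_genome, flank, min_identical, scoring,
        control_offset_max,
    )
    bwd = _direction_report(
        f"{subject_genome.name}->{query_genome.name}", subject_sites,
        subject_genome, query_genome, flank, min_identical, scoring,
        control_offset_max,
    )
    a = fwd.counterpart_base_counts.get("G", 0)
    b = fwd.matched_sites - a
    c = bwd.counterpart_base_counts.get("G", 0)
    d = bwd.matched_sites - c
    contingency = [[a, b], [c, d]]
    odds = (a * d) / (b * c) if b * c else float("inf") if a * d else \
        float("nan")
    p = fisher_exact_2x2(contingency)
    return ReversionAnalysis(
        forward=fwd, backward=bwd, contingency=contingency,
        odds_ratio=odds, fisher_p=p,
    )


# ---------------------------------------------------------------------------
# ECS (exon complementary sequence) scan
# ---------------------------------------------------------------------------


@dataclass
class EcsHit:
    """A candidate ECS: a reverse-complement match of the site's window
    elsewhere in the locus (labelled candidate — no structure is folded)."""

    site: SiteRecord
    start0: int  # plus-strand, half-open
    end0: int
    orientation: str
    identical: int
    aligned_length: int
    score: int


def find_ecs(
    site: SiteRecord,
    search_seq: str,
    window: GenomicWindow,
    min_identical: int = 70,
    scoring: ScoringScheme = ScoringScheme(),
    max_hits: int = 25,
    window_start0: int | None = None,
) -> list[EcsHit]:
    """Scan a locus for reverse-complement matches of a site's window.

    The window is locally aligned against the reverse complement of
    ``search_seq``; every non-self hit with at least ``min_identical``
    identical columns is reported (best first).  Found intervals are masked
    with N and the scan repeats, so multiple candidate ECS are returned.
    ``window_start0`` locates the window's own occurrence inside
    ``search_seq`` (found by exact search when omitted) so self-hits can be
    excluded.
    """
    if len(search_seq) < len(window.seq):
        raise ValueError("search sequence shorter than the window")
    search_seq = search_seq.upper()
    if window_start0 is None:
        plus_repr = window.seq if site.strand == "+" \
            else reverse_complement(window.seq)
        idx = search_seq.find(plus_repr)
        window_start0 = idx if idx >= 0 else None
    self_iv = (
        (window_start0, window_start0 + len(window.seq))
        if window_start0 is not None else None
    )
    L = len(search_seq)
    rc = list(reverse_complement(search_seq))
    hits: list[EcsHit] = []
    while len(hits) < max_hits:
        aln = smith_waterman(window.seq, "".join(rc), scoring)
        if aln.identical < min_identical:
            break
        # map the RC-space interval back to plus-strand coordinates
        start0 = L - aln.subject_end
        end0 = L - aln.subject_start
        for k in range(aln.subject_start, aln.subject_end):
            rc[k] = "N"
        if self_iv is not None and start0 < self_iv[1] and end0 > self_iv[0]:
            continue  # overlaps the site's own window
        hits.append(
            EcsHit(
                site=site, start0=start0, end0=end0, orientation="revcomp",
                identical=aln.identical, aligned_length=aln.aligned_length,
                score=aln.score,
            )
        )
    hits.sort(key=lambda h: (-h.identical, h.start0))
    return hits
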