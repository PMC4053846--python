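"""Cross-species conservation screen for edited adenosines.

The screen takes each candidate site, extracts the 81-nt genomic window on
the edited strand (40 nt of flank on either side of the edited base), aligns
every query window against every subject-species window with an exact local
aligner, and keeps pairs whose alignment has at least ``min_identical``
identical columns *and* pairs the two edited bases in one identically
matching column (A opposite A).  A SNP control run through the same
machinery calibrates the expected number of chance hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .alignment import LocalAlignment, ScoringScheme, encode_seq, smith_waterman
from .io_formats import GenomeAssembly, SiteRecord

__all__ = [
    "GenomicWindow",
    "WindowAlignment",
    "ScreenResult",
    "SignalNoiseReport",
    "extract_window",
    "extract_windows",
    "align_windows",
    "evaluate_hit",
    "run_screen",
    "control_signal_to_noise",
]

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 40
DEFAULT_MIN_IDENTICAL = 70


@dataclass(frozen=True)
class GenomicWindow:
    """The window around a site, on the edited strand.

    ``seq`` has length ``2 * flank + 1``; the edited base sits at
    ``center_index == flank``.  For editing sites the center base is A
    (validated at extraction); SNP-control windows carry any center base.
    """

    site: SiteRecord
    seq: str
    center_index: int


@dataclass
class WindowAlignment:
    """Alignment statistics between two windows.

    ``centers_paired`` is true iff the two center positions occupy the same
    alignment column; ``center_match`` additionally requires that column to
    be an identical match.  ``center_partner_index`` / ``center_partner_base``
    give the subject position (index into the subject window) paired with
    the query center, when any.
    """

    query_site: SiteRecord
    subject_site: SiteRecord
    score: int
    aligned_length: int
    identical: int
    gaps: int
    centers_paired: bool
    center_match: bool
    center_partner_index: int | None = None
    center_partner_base: str | None = None
    alignment: LocalAlignment | None = field(default=None, repr=False)


def extract_window(
    genome: GenomeAssembly,
    site: SiteRecord,
    flank: int = DEFAULT_FLANK,
    require_center_a: bool = True,
) -> GenomicWindow:
    """Extract the edited-strand window around ``site``.

    The plus-strand slice ``[pos0 - flank, pos0 + flank + 1)`` is taken and
    reverse-complemented for minus-strand sites, so the returned sequence
    always reads 5'→3' on the edited strand with the edited base centered.

    Raises ``IndexError`` for sites closer than ``flank`` to a contig end
    and ``ValueError`` when an editing site's center base is not A.
    """
    start0 = site.pos0 - flank
    end0 = site.pos0 + flank + 1
    seq = genome.fetch(site.chrom, start0, end0, site.strand)
    if require_center_a and seq[flank] != "A":
        raise ValueError(
            f"center base of editing site {site.chrom}:{site.pos1}"
            f"({site.strand}) is {seq[flank]!r}, expected 'A'"
        )
    return GenomicWindow(site=site, seq=seq, center_index=flank)


def extract_windows(
    genome: GenomeAssembly,
    sites: list[SiteRecord],
    flank: int = DEFAULT_FLANK,
    require_center_a: bool = True,
) -> list[GenomicWindow]:
    """Batch extraction; out-of-range or non-A-center sites are skipped
    with a logged warning rather than raising."""
    windows = []
    skipped = 0
    for site in sites:
        try:
            windows.append(
                extract_window(genome, site, flank, require_center_a)
            )
        except (IndexError, ValueError, KeyError) as exc:
            skipped += 1
            logger.warning("skipping site %s:%s(%s): %s",
                           site.chrom, site.pos1, site.strand, exc)
    if skipped:
        logger.info("extract_windows: skipped %d of %d sites",
                    skipped, len(sites))
    return windows


def align_windows(
    q: GenomicWindow, s: GenomicWindow,
    scoring: ScoringScheme = ScoringScheme(),
    keep_alignment: bool = False,
) -> WindowAlignment:
    """Optimal local alignment between two windows, with center bookkeeping."""
    aln = smith_waterman(q.seq, s.seq, scoring)
    partner = aln.pairs.get(q.center_index)
    centers_paired = partner == s.center_index and partner is not None
    center_match = bool(
        centers_paired and q.seq[q.center_index] == s.seq[s.center_index]
    )
    return WindowAlignment(
        query_site=q.site,
        subject_site=s.site,
        score=aln.score,
        aligned_length=aln.aligned_length,
        identical=aln.identical,
        gaps=aln.gaps,
        centers_paired=centers_paired,
        center_match=center_match,
        center_partner_index=partner,
        center_partner_base=s.seq[partner] if partner is not None else None,
        alignment=aln if keep_alignment else None,
    )


def evaluate_hit(
    aln: WindowAlignment, min_identical: int = DEFAULT_MIN_IDENTICAL
) -> bool:
    """Conservation criterion: >= ``min_identical`` identical columns and the
    two edited positions aligned in one identically matching column."""
    return (
        aln.identical >= min_identical
        and aln.centers_paired
        and aln.center_match
    )


@dataclass
class ScreenResult:
    """Outcome of an all-vs-all window screen."""

    conserved_pairs: list[WindowAlignment]
    conserved_query_sites: list[SiteRecord]
    n_query: int
    n_subject: int
    flank: int
    min_identical: int
    scoring: ScoringScheme

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_query_sites)


def run_screen(
    query_sites: list[SiteRecord],
    subject_sites: list[SiteRecord],
    query_genome: GenomeAssembly,
    subject_genome: GenomeAssembly,
    flank: int = DEFAULT_FLANK,
    min_identical: int = DEFAULT_MIN_IDENTICAL,
    scoring: ScoringScheme = ScoringScheme(),
    require_center_a: bool = True,
) -> ScreenResult:
    """All-vs-all window screen between two species.

    A query site with at least one passing subject hit counts once in
    ``conserved_query_sites`` (no reciprocal-best requirement); all passing
    pairs are retained, sorted by descending identical-column count.
    """
    if not query_sites or not subject_sites:
        raise ValueError("both site lists must be non-empty")
    q_windows = extract_windows(query_genome, query_sites, flank,
                                require_center_a)
    s_windows = extract_windows(subject_genome, subject_sites, flank,
                                require_center_a)
    if not q_windows or not s_windows:
        raise ValueError("no alignable windows after filtering")
    # pre-encode subject windows once; alignment is the hot loop
    s_encoded = [encode_seq(w.seq) for w in s_windows]
    pairs: list[WindowAlignment] = []
    conserved: list[SiteRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for qw in q_windows:
        q_enc = encode_seq(qw.seq)
        for sw, s_enc in zip(s_windows, s_encoded):
            aln = smith_waterman(q_enc, s_enc, scoring)
            if aln.identical < min_identical:
                continue
            wa = _window_alignment_from(qw, sw, aln)
            if evaluate_hit(wa, min_identical):
                pairs.append(wa)
                if qw.site.key not in seen:
                    seen.add(qw.site.key)
                    conserved.append(qw.site)
    pairs.sort(key=lambda a: (-a.identical,
                              a.query_site.key, a.subject_site.key))
    logger.info("screen: %d/%d query sites conserved (%d pairs)",
                len(conserved), len(q_windows), len(pairs))
    return ScreenResult(
        conserved_pairs=pairs,
        conserved_query_sites=conserved,
        n_query=len(q_windows),
        n_subject=len(s_windows),
        flank=flank,
        min_identical=min_identical,
        scoring=scoring,
    )


def _window_alignment_from(
    qw: GenomicWindow, sw: GenomicWindow, aln: LocalAlignment
) -> WindowAlignment:
    partner = aln.pairs.get(qw.center_index)
    centers_paired = partner is not None and partner == sw.center_index
    center_match = bool(
        centers_paired and qw.seq[qw.center_index] == sw.seq[sw.center_index]
    )
    return WindowAlignment(
        query_site=qw.site,
        subject_site=sw.site,
        score=aln.score,
        aligned_length=aln.aligned_length,
        identical=aln.identical,
        gaps=aln.gaps,
        centers_paired=centers_paired,
        center_match=center_match,
        center_partner_index=partner,
        center_partner_base=sw.seq[partner] if partner is not None else None,
    )


@dataclass
class SignalNoiseReport:
    """Signal-to-noise calibration of the screen against a SNP control.

    ``control_normalized`` rescales the raw control hit count to the editing
    dataset sizes; ``ratio`` is infinite when no control hit was found.
    """

    editing_hits: int
    control_raw_hits: int
    n_edit_query: int
    n_edit_subject: int
    n_control_query: int
    n_control_subject: int
    control_normalized: float
    ratio: float
    ratio_is_infinite: bool


def control_signal_to_noise(
    screen: ScreenResult,
    control_query_snps: list[SiteRecord],
    control_subject_snps: list[SiteRecord],
    query_genome: GenomeAssembly,
    subject_genome: GenomeAssembly,
    sizes: tuple[int, int, int, int] | None = None,
) -> SignalNoiseReport:
    """Run the identical screen on SNP windows and compute signal-to-noise.

    SNP windows use the same flank, scoring and hit criterion, with the
    center-base-must-be-A extraction check disabled (the center column must
    still be an exact match between the two SNP positions).

    ``sizes`` optionally overrides the four dataset sizes
    (n_edit_query, n_edit_subject, n_control_query, n_control_subject) used
    in the normalization — e.g. full database sizes when the screen itself
    ran on a subset.
    """
    if not control_query_snps or not control_subject_snps:
        raise ValueError("control SNP lists must be non-empty")
    control = run_screen(
        control_query_snps,
        control_subject_snps,
        query_genome,
        subject_genome,
        flank=screen.flank,
        min_identical=screen.min_identical,
        scoring=screen.scoring,
        require_center_a=False,
    )
    if sizes is not None:
        n_eq, n_es, n_cq, n_cs = sizes
    else:
        n_eq, n_es = screen.n_query, screen.n_subject
        n_cq, n_cs = control.n_query, control.n_subject
    control_normalized = control.n_conserved * (n_eq / n_cq) * (n_es / n_cs)
    editing_hits = screen.n_conserved
    if control_normalized == 0:
        ratio = math.inf if editing_hits else 0.0
        infinite = bool(editing_hits)
    else:
        ratio = editing_hits / control_normalized
        infinite = False
    return SignalNoiseReport(
        editing_hits=editing_hits,
        control_raw_hits=control.n_conserved,
        n_edit_query=n_eq,
        n_edit_subject=n_es,
        n_control_query=n_cq,
        n_control_subject=n_cs,
        control_normalized=control_normalized,
        ratio=ratio,
        ratio_is_infinite=infinite,
    )
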