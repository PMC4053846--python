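"""Seeded generators for two diverged "species" genomes with planted
editing structure, plus strain panels and multi-strain pileups.

The generator emulates the structure the conservation screen assumes:
orthologous loci diverged i.i.d. at a background rate, editing-site windows
held at a lower divergence with the edited adenosine preserved in both
species, lineage-specific sites whose counterpart base can be forced to G
(reversion structure), SNP controls placed away from editing sites, and
multi-strain read pileups with binomial editing, sequencing error, and a
quality-filter-exercising share of low-quality bases.

Identical configurations (including the seed) yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .conservation_screen import (
    GenomicWindow,
    align_windows,
    evaluate_hit,
    extract_window,
)
from .io_formats import GenomeAssembly, SiteRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_ortholog_pair",
    "simulate_pileups",
    "simulate_strain_panel",
    "simulate_motif_windows",
]

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Divergences are per-base substitution probabilities; editing levels are
    Beta-distributed per site and strain — conserved sites around 0.5
    (echoing the ~51% mean editing of the conserved set), lineage-specific
    sites around 0.1 with a wide spread.  ``reversion_fraction_*`` is the
    share of lineage-specific sites whose counterpart base in the other
    genome is hardwired to G.
    """

    seed: int = 0
    query_name: str = "speciesA"
    subject_name: str = "speciesB"
    n_chrom: int = 2
    chrom_length: int = 60_000
    flank: int = 40
    min_identical: int = 70
    background_divergence: float = 0.05
    conserved_window_divergence: float = 0.02
    n_conserved_sites: int = 10
    n_query_only_sites: int = 100
    n_subject_only_sites: int = 50
    n_snps_per_species: int = 100
    n_shared_snps: int = 2
    reversion_fraction_query: float = 0.26
    reversion_fraction_subject: float = 0.18
    n_strains: int = 15
    conserved_presence: float = 0.97
    noncons_presence: float = 0.5
    coverage_lambda: float = 30.0
    conserved_level_beta: tuple[float, float] = (12.0, 12.0)   # mean .5, sd ~.1
    noncons_level_beta: tuple[float, float] = (0.125, 1.125)   # mean .1, sd ~.2
    sequencing_error: float = 0.001
    low_quality_fraction: float = 0.1
    motif_g_upstream: float = 0.05
    motif_g_downstream: float = 0.45

    def __post_init__(self) -> None:
        for name in (
            "background_divergence", "conserved_window_divergence",
            "reversion_fraction_query", "reversion_fraction_subject",
            "conserved_presence", "noncons_presence", "sequencing_error",
            "low_quality_fraction", "motif_g_upstream", "motif_g_downstream",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        window = 2 * self.flank + 1
        # expected identical columns must clear the threshold with margin
        if window * (1 - self.conserved_window_divergence) < \
                self.min_identical + 2:
            raise ValueError(
                "conserved_window_divergence too high: expected identity "
                f"{window * (1 - self.conserved_window_divergence):.1f} < "
                f"{self.min_identical} + 2 margin"
            )

    @property
    def site_spacing(self) -> int:
        # windows must not overlap and SNPs must sit >100 nt from sites
        return max(2 * self.flank + 10, 101)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("conserved_level_beta", "noncons_level_beta"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("conserved_level_beta", "noncons_level_beta"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth for everything the generator planted."""

    conserved_pairs: list[tuple[SiteRecord, SiteRecord]]
    query_only: list[SiteRecord]
    subject_only: list[SiteRecord]
    query_snps: list[SiteRecord]
    subject_snps: list[SiteRecord]
    shared_snp_pairs: list[tuple[SiteRecord, SiteRecord]]
    counterpart_query_to_subject: dict[tuple, str]
    counterpart_subject_to_query: dict[tuple, str]
    strains: list[str] = field(default_factory=list)
    true_levels: dict[tuple, float] = field(default_factory=dict)

    @property
    def query_sites(self) -> list[SiteRecord]:
        return [q for q, _ in self.conserved_pairs] + self.query_only

    @property
    def subject_sites(self) -> list[SiteRecord]:
        return [s for _, s in self.conserved_pairs] + self.subject_only

    @property
    def conserved_query_keys(self) -> set[tuple]:
        return {q.key for q, _ in self.conserved_pairs}

    def to_json(self, path: str | Path) -> None:
        def site(s: SiteRecord) -> dict:
            return {"species": s.species, "chrom": s.chrom, "pos1": s.pos1,
                    "strand": s.strand}

        data = {
            "conserved_pairs": [[site(q), site(s)]
                                for q, s in self.conserved_pairs],
            "query_only": [site(s) for s in self.query_only],
            "subject_only": [site(s) for s in self.subject_only],
            "query_snps": [site(s) for s in self.query_snps],
            "subject_snps": [site(s) for s in self.subject_snps],
            "counterpart_query_to_subject": {
                f"{k[0]}:{k[1]}:{k[2]}": v
                for k, v in sorted(self.counterpart_query_to_subject.items())
            },
            "counterpart_subject_to_query": {
                f"{k[0]}:{k[1]}:{k[2]}": v
                for k, v in sorted(self.counterpart_subject_to_query.items())
            },
            "strains": self.strains,
            "true_levels": {
                f"{k[0][0]}:{k[0][1]}:{k[0][2]}|{k[1]}": round(v, 6)
                for k, v in sorted(self.true_levels.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _complement_code(code: int) -> int:
    return 3 - code


def _set_edited_strand_base(arr: np.ndarray, pos0: int, strand: str,
                            base_code: int) -> None:
    arr[pos0] = base_code if strand == "+" else _complement_code(base_code)


def _get_edited_strand_base(arr: np.ndarray, pos0: int, strand: str) -> str:
    code = int(arr[pos0])
    if strand == "-":
        code = _complement_code(code)
    return _BASES[code]


def _draw_neighbor(rng: np.random.Generator, p_g: float) -> int:
    """Edited-strand neighbor base: G with probability p_g, else uniform
    over A, C, T."""
    if rng.random() < p_g:
        return 2  # G
    return int(rng.choice(np.array([0, 1, 3])))


def _mutate(arr: np.ndarray, rates: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    mask = rng.random(arr.shape[0]) < rates
    n_mut = int(mask.sum())
    if n_mut:
        shift = rng.integers(1, 4, size=n_mut)
        out[mask] = (out[mask] + shift) % 4
    return out


def _codes_to_str(arr: np.ndarray) -> str:
    return bytes(_DECODE[arr]).decode("ascii")


def simulate_ortholog_pair(
    cfg: SimulationConfig,
) -> tuple[GenomeAssembly, GenomeAssembly, SyntheticTruth]:
    """Generate a diverged genome pair with planted editing structure.

    The subject genome is the query genome mutated i.i.d. at the background
    rate, except inside conserved-site windows (mutated at the lower
    conserved rate, edited base preserved in both).  Lineage-specific sites
    keep an A at their own center; their counterpart center in the other
    genome is hardwired to G for the configured reversion fraction and
    preserved as A otherwise, so the planted counterpart distribution is
    exact.  A post-generation self-check verifies every conserved pair
    passes the screen criterion and aborts otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.site_spacing
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    query_arrs = {
        c: rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
        for c in chroms
    }
    # candidate loci: one per spacing-grid slot, window-safe from both ends
    slots: list[tuple[str, int]] = []
    for c in chroms:
        pos0 = cfg.flank
        while pos0 + cfg.flank + 1 <= cfg.chrom_length:
            slots.append((c, pos0))
            pos0 += spacing
    needed = (cfg.n_conserved_sites + cfg.n_query_only_sites
              + cfg.n_subject_only_sites + 2 * cfg.n_snps_per_species
              + cfg.n_shared_snps)
    if needed > len(slots):
        raise ValueError(
            f"{needed} loci requested but only {len(slots)} fit; increase "
            "chrom_length or n_chrom"
        )
    order = rng.permutation(len(slots))
    it = iter(order)

    def take(n: int) -> list[tuple[str, int]]:
        return [slots[next(it)] for _ in range(n)]

    def strands(n: int) -> list[str]:
        return ["+" if rng.random() < 0.5 else "-" for _ in range(n)]

    cons_loci, cons_strands = take(cfg.n_conserved_sites), \
        strands(cfg.n_conserved_sites)
    qonly_loci, qonly_strands = take(cfg.n_query_only_sites), \
        strands(cfg.n_query_only_sites)
    sonly_loci, sonly_strands = take(cfg.n_subject_only_sites), \
        strands(cfg.n_subject_only_sites)
    qsnp_loci = take(cfg.n_snps_per_species)
    ssnp_loci = take(cfg.n_snps_per_species)
    shared_snp_loci = take(cfg.n_shared_snps)

    # plant edited-strand A centers; conserved sites get the ADAR-like
    # neighbor bias (G-depleted 5' neighbor, G-enriched 3' neighbor)
    for (c, p0), strand in zip(cons_loci, cons_strands):
        up = _draw_neighbor(rng, cfg.motif_g_upstream)
        down = _draw_neighbor(rng, cfg.motif_g_downstream)
        _set_edited_strand_base(query_arrs[c], p0, strand, 0)
        if strand == "+":
            query_arrs[c][p0 - 1] = up
            query_arrs[c][p0 + 1] = down
        else:
            query_arrs[c][p0 + 1] = _complement_code(up)
            query_arrs[c][p0 - 1] = _complement_code(down)
    for (c, p0), strand in zip(qonly_loci, qonly_strands):
        _set_edited_strand_base(query_arrs[c], p0, strand, 0)
    for (c, p0), strand in zip(sonly_loci, sonly_strands):
        _set_edited_strand_base(query_arrs[c], p0, strand, 0)

    # divergence rates: background everywhere, reduced in conserved windows
    rates = {
        c: np.full(cfg.chrom_length, cfg.background_divergence)
        for c in chroms
    }
    for c, p0 in cons_loci:
        rates[c][p0 - cfg.flank: p0 + cfg.flank + 1] = \
            cfg.conserved_window_divergence
    subject_arrs = {c: _mutate(query_arrs[c], rates[c], rng) for c in chroms}

    counterpart_q2s: dict[tuple, str] = {}
    counterpart_s2q: dict[tuple, str] = {}
    conserved_pairs: list[tuple[SiteRecord, SiteRecord]] = []
    for (c, p0), strand in zip(cons_loci, cons_strands):
        subject_arrs[c][p0] = query_arrs[c][p0]  # preserve edited base
        q = SiteRecord(species=cfg.query_name, chrom=c, pos1=p0 + 1,
                       strand=strand, source="sim_conserved")
        s = SiteRecord(species=cfg.subject_name, chrom=c, pos1=p0 + 1,
                       strand=strand, source="sim_conserved")
        conserved_pairs.append((q, s))
        counterpart_q2s[q.key] = "A"
        counterpart_s2q[s.key] = "A"

    query_only: list[SiteRecord] = []
    for (c, p0), strand in zip(qonly_loci, qonly_strands):
        reverted = rng.random() < cfg.reversion_fraction_query
        _set_edited_strand_base(subject_arrs[c], p0, strand,
                                2 if reverted else 0)
        site = SiteRecord(species=cfg.query_name, chrom=c, pos1=p0 + 1,
                          strand=strand, source="sim_query_only")
        query_only.append(site)
        counterpart_q2s[site.key] = "G" if reverted else "A"

    subject_only: list[SiteRecord] = []
    for (c, p0), strand in zip(sonly_loci, sonly_strands):
        _set_edited_strand_base(subject_arrs[c], p0, strand, 0)
        reverted = rng.random() < cfg.reversion_fraction_subject
        _set_edited_strand_base(query_arrs[c], p0, strand,
                                2 if reverted else 0)
        site = SiteRecord(species=cfg.subject_name, chrom=c, pos1=p0 + 1,
                          strand=strand, source="sim_subject_only")
        subject_only.append(site)
        counterpart_s2q[site.key] = "G" if reverted else "A"

    def snp_records(loci, species):
        return [
            SiteRecord(species=species, chrom=c, pos1=p0 + 1, strand="+",
                       source="sim_snp")
            for c, p0 in loci
        ]

    query_snps = snp_records(qsnp_loci + shared_snp_loci, cfg.query_name)
    subject_snps = snp_records(ssnp_loci + shared_snp_loci, cfg.subject_name)
    shared_pairs = list(zip(snp_records(shared_snp_loci, cfg.query_name),
                            snp_records(shared_snp_loci, cfg.subject_name)))

    query_genome = GenomeAssembly(
        cfg.query_name, {c: _codes_to_str(query_arrs[c]) for c in chroms}
    )
    subject_genome = GenomeAssembly(
        cfg.subject_name, {c: _codes_to_str(subject_arrs[c]) for c in chroms}
    )

    strains = [f"strain{i + 1:02d}" for i in range(cfg.n_strains)]
    true_levels: dict[tuple, float] = {}
    a_c, b_c = cfg.conserved_level_beta
    a_n, b_n = cfg.noncons_level_beta
    for q, _ in conserved_pairs:
        for strain in strains:
            true_levels[(q.key, strain)] = float(rng.beta(a_c, b_c))
    for site in query_only:
        for strain in strains:
            true_levels[(site.key, strain)] = float(rng.beta(a_n, b_n))

    truth = SyntheticTruth(
        conserved_pairs=conserved_pairs,
        query_only=query_only,
        subject_only=subject_only,
        query_snps=query_snps,
        subject_snps=subject_snps,
        shared_snp_pairs=shared_pairs,
        counterpart_query_to_subject=counterpart_q2s,
        counterpart_subject_to_query=counterpart_s2q,
        strains=strains,
        true_levels=true_levels,
    )

    # self-check: every planted conserved pair must pass the screen criterion
    for q, s in conserved_pairs:
        qw = extract_window(query_genome, q, cfg.flank)
        sw = extract_window(subject_genome, s, cfg.flank)
        aln = align_windows(qw, sw)
        if not evaluate_hit(aln, cfg.min_identical):
            raise RuntimeError(
                f"planted conserved pair {q.chrom}:{q.pos1} fails the "
                f"screen criterion (identical={aln.identical}); the "
                "conserved divergence leaves no margin"
            )
    return query_genome, subject_genome, truth


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def simulate_pileups(
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    query_genome: GenomeAssembly,
    outdir: str | Path | None = None,
) -> dict[str, list[str] | Path]:
    """Per-strain mpileup text for every query-species editing site.

    Depth is Poisson; edited reads are Binomial(depth, true level); each
    read base is mis-read uniformly at the sequencing error rate; a
    configured fraction of base qualities falls below Phred 30 so the
    quality filter is exercised.  Zero-depth sites emit no line.
    Returns strain → list of lines, or strain → written file path when
    ``outdir`` is given.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    sites = sorted(truth.query_sites, key=lambda s: (s.chrom, s.pos1))
    out: dict[str, list[str] | Path] = {}
    for strain in truth.strains:
        lines: list[str] = []
        for site in sites:
            level = truth.true_levels[(site.key, strain)]
            depth = int(rng.poisson(cfg.coverage_lambda))
            if depth == 0:
                continue
            g = int(rng.binomial(depth, level))
            # edited-strand reads
            reads = np.array([2] * g + [0] * (depth - g), dtype=np.int64)
            err = rng.random(depth) < cfg.sequencing_error
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                reads[err] = (reads[err] + shift) % 4
            if site.strand == "-":
                reads = 3 - reads  # fold to the reference strand
            ref = query_genome.fetch(site.chrom, site.pos0, site.pos0 + 1)
            base_chars = []
            for code in reads:
                base = _BASES[int(code)]
                reverse_read = rng.random() < 0.5
                if base == ref:
                    base_chars.append("," if reverse_read else ".")
                else:
                    base_chars.append(base.lower() if reverse_read else base)
            quals = []
            for _ in range(depth):
                if rng.random() < cfg.low_quality_fraction:
                    quals.append(chr(int(rng.integers(2, 30)) + 33))
                else:
                    quals.append(chr(int(rng.integers(30, 41)) + 33))
            lines.append(
                "\t".join([site.chrom, str(site.pos1), ref, str(depth),
                           "".join(base_chars), "".join(quals)])
            )
        if outdir is not None:
            path = Path(outdir) / f"{strain}.mpileup"
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
            out[strain] = path
        else:
            out[strain] = lines
    return out


# ---------------------------------------------------------------------------
# strain presence panel
# ---------------------------------------------------------------------------


def simulate_strain_panel(
    cfg: SimulationConfig,
    conserved_sites: list | None = None,
    other_sites: list | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, set], dict[str, list]]:
    """Per-strain site-presence sets for accumulation-curve analysis.

    Conserved sites appear in each strain with ``conserved_presence`` and
    are topped up so every conserved site is present in at least 94% of
    strains; other sites appear independently with ``noncons_presence``.
    Site identifiers default to opaque labels when no site lists are given.
    """
    if cfg.n_strains < 2:
        raise ValueError("need at least 2 strains")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2_000_003)
    if conserved_sites is None:
        conserved_sites = [f"cons_{i}" for i in range(cfg.n_conserved_sites)]
    if other_sites is None:
        other_sites = [f"other_{i}" for i in range(cfg.n_query_only_sites)]
    strains = [f"strain{i + 1:02d}" for i in range(cfg.n_strains)]
    panel: dict[str, set] = {s: set() for s in strains}
    min_present = int(np.ceil(0.94 * cfg.n_strains))
    for site in conserved_sites:
        present = [s for s in strains
                   if rng.random() < cfg.conserved_presence]
        if len(present) < min_present:
            absent = [s for s in strains if s not in present]
            extra = rng.choice(len(absent), size=min_present - len(present),
                               replace=False)
            present += [absent[int(i)] for i in np.atleast_1d(extra)]
        for s in present:
            panel[s].add(site)
    for site in other_sites:
        for s in strains:
            if rng.random() < cfg.noncons_presence:
                panel[s].add(site)
    return panel, {"conserved": list(conserved_sites),
                   "other": list(other_sites)}


# ---------------------------------------------------------------------------
# standalone motif windows
# ---------------------------------------------------------------------------


def simulate_motif_windows(
    n: int,
    p_up_g: float,
    p_down_g: float,
    flank: int = 40,
    seed: int = 0,
) -> list[GenomicWindow]:
    """Random edited-strand windows with a biased neighbor composition:
    center A, 5' neighbor G with ``p_up_g``, 3' neighbor G with
    ``p_down_g``, everything else uniform."""
    rng = np.random.default_rng(seed)
    windows = []
    length = 2 * flank + 1
    for i in range(n):
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        codes[flank] = 0
        codes[flank - 1] = _draw_neighbor(rng, p_up_g)
        codes[flank + 1] = _draw_neighbor(rng, p_down_g)
        site = SiteRecord(species="sim", chrom="simchr", pos1=flank + 1 + i,
                          strand="+")
        windows.append(GenomicWindow(site=site, seq=_codes_to_str(codes),
                                     center_index=flank))
    return windows
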