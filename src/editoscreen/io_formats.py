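"""Readers and writers for the pipeline's on-disk formats.

Conventions
-----------
* Internal coordinates are 0-based half-open; every user-facing site table
  carries 1-based positions (``pos``), matching both published editing-site
  tables and the BED interchange after conversion.
* Site identity is the triple ``(chrom, pos1, strand)``.  Species is a record
  label and site lists are never mixed across species.
* mpileup read-strand case is folded: a :class:`PileupColumn` holds
  reference-strand base counts.  The site strand is applied downstream, in
  :mod:`editoscreen.editing_quant`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeAssembly",
    "SiteRecord",
    "PileupColumn",
    "load_genome",
    "write_genome",
    "read_site_table",
    "write_site_table",
    "merge_site_datasets",
    "read_mpileup",
    "reverse_complement",
    "write_tsv",
    "read_tsv",
    "write_json",
]

SITE_TABLE_COLUMNS = [
    "species",
    "chrom",
    "pos",
    "strand",
    "gene",
    "region",
    "substitution",
    "source",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiteRecord:
    """One candidate editing site or SNP.

    ``pos1`` is 1-based, as printed in published site tables.  ``region`` is
    one of {CDS, intron, 3UTR, 5UTR, microRNA, intergenic} when annotated.
    ``substitution`` carries a transcript annotation such as
    ``NM_000826:c.A1820G:p.Q607R``; only the ``p.`` token is interpreted
    (by :func:`editoscreen.evolutionary_stats.classify_regions`).
    """

    species: str
    chrom: str
    pos1: int
    strand: str
    gene: str | None = None
    region: str | None = None
    substitution: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.pos1 < 1:
            raise ValueError(f"pos1 must be >= 1, got {self.pos1}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity: (chrom, pos1, strand)."""
        return (self.chrom, self.pos1, self.strand)

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos1 - 1


class GenomeAssembly:
    """A named set of chromosome sequences with strand-aware fetch."""

    def __init__(self, name: str, sequences: Mapping[str, str]):
        self.name = name
        self.sequences: dict[str, str] = {}
        for chrom, seq in sequences.items():
            if chrom in self.sequences:
                raise ValueError(f"duplicate chromosome name {chrom!r}")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            seq = seq.upper()
            if not set(seq) <= _VALID_BASES:
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            self.sequences[chrom] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start0: int, end0: int, strand: str = "+") -> str:
        """Half-open 0-based slice; reverse-complemented when strand is '-'."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r} in genome {self.name!r}")
        seq = self.sequences[chrom]
        if not (0 <= start0 <= end0 <= len(seq)):
            raise IndexError(
                f"slice [{start0}, {end0}) out of range for {chrom} "
                f"(length {len(seq)})"
            )
        sub = seq[start0:end0]
        if strand == "-":
            return reverse_complement(sub)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return sub


def load_genome(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Load a (multi-)FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; IUPAC ambiguity codes outside {A,C,G,T,N}
    are mapped to N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(name or path.stem, sequences)


def write_genome(genome: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    """Write a genome as wrapped FASTA (deterministic chromosome order)."""
    with open(path, "w") as fh:
        for chrom in genome.sequences:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------


def _none_if_blank(v: str) -> str | None:
    v = v.strip()
    return v if v else None


def read_site_table(
    path: str | Path, dialect: str = "table1_tsv", species: str | None = None
) -> list[SiteRecord]:
    """Read a site table into :class:`SiteRecord` s (1-based positions).

    dialect ``table1_tsv``: header ``species chrom pos strand gene region
    substitution source``; positions 1-based.  dialect ``bed6``: headerless
    6-column BED, 0-based half-open; start ``s`` maps to ``pos1 = s + 1``
    (``species`` must then be supplied by the caller).
    """
    path = Path(path)
    records: list[SiteRecord] = []
    if dialect == "table1_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != SITE_TABLE_COLUMNS:
                raise ValueError(
                    f"bad site-table header in {path}: {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != len(SITE_TABLE_COLUMNS):
                    raise ValueError(f"{path}:{lineno}: expected 8 columns")
                sp, chrom, pos, strand, gene, region, subst, source = parts
                records.append(
                    SiteRecord(
                        species=sp,
                        chrom=chrom,
                        pos1=int(pos),
                        strand=strand,
                        gene=_none_if_blank(gene),
                        region=_none_if_blank(region),
                        substitution=_none_if_blank(subst),
                        source=_none_if_blank(source),
                    )
                )
    elif dialect == "bed6":
        if species is None:
            raise ValueError("bed6 dialect requires an explicit species label")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, start, end, bname, _score, strand = parts[:6]
                start_i, end_i = int(start), int(end)
                if start_i < 0 or end_i <= start_i:
                    raise ValueError(
                        f"{path}:{lineno}: invalid BED interval [{start}, {end})"
                    )
                records.append(
                    SiteRecord(
                        species=species,
                        chrom=chrom,
                        pos1=start_i + 1,
                        strand=strand,
                        gene=_none_if_blank(bname) if bname != "." else None,
                    )
                )
    else:
        raise ValueError(f"unknown site-table dialect {dialect!r}")
    return records


def write_site_table(
    records: Iterable[SiteRecord], path: str | Path, dialect: str = "table1_tsv"
) -> None:
    """Write site records; table1_tsv round-trips losslessly."""
    records = list(records)
    if dialect == "table1_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.species,
                            r.chrom,
                            str(r.pos1),
                            r.strand,
                            r.gene or "",
                            r.region or "",
                            r.substitution or "",
                            r.source or "",
                        ]
                    )
                    + "\n"
                )
    elif dialect == "bed6":
        with open(path, "w") as fh:
            for r in records:
                fh.write(
                    "\t".join(
                        [r.chrom, str(r.pos1 - 1), str(r.pos1), r.gene or ".",
                         "0", r.strand]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown site-table dialect {dialect!r}")


def merge_site_datasets(tables: Iterable[Iterable[SiteRecord]]) -> list[SiteRecord]:
    """Merge several site lists of one species into a unique, sorted list.

    Uniqueness is by (chrom, pos1, strand); source labels of duplicates are
    concatenated with commas in input order.  Output is stably sorted by
    (chrom, pos1, strand).
    """
    merged: dict[tuple[str, int, str], SiteRecord] = {}
    species_seen: set[str] = set()
    for table in tables:
        for rec in table:
            species_seen.add(rec.species)
            if len(species_seen) > 1:
                raise ValueError(
                    f"mixed species in merge: {sorted(species_seen)}"
                )
            if rec.key in merged:
                prev = merged[rec.key]
                sources = [s for s in (prev.source, rec.source) if s]
                merged[rec.key] = replace(
                    prev,
                    source=",".join(sources) if sources else None,
                    gene=prev.gene or rec.gene,
                    region=prev.region or rec.region,
                    substitution=prev.substitution or rec.substitution,
                )
            else:
                merged[rec.key] = rec
    return sorted(merged.values(), key=lambda r: (r.chrom, r.pos1, r.strand))


# ---------------------------------------------------------------------------
# samtools mpileup text
# ---------------------------------------------------------------------------


@dataclass
class PileupColumn:
    """Quality-filtered base counts at one reference position.

    ``filtered_counts`` holds reference-strand base counts (read-strand case
    folded).  Bases below the Phred cutoff never contribute.  ``depth`` is
    the depth declared in column 4 of the mpileup line.
    """

    chrom: str
    pos1: int
    ref_base: str
    depth: int
    filtered_counts: dict[str, int] = field(
        default_factory=lambda: {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}
    )

    @property
    def total_filtered(self) -> int:
        return sum(self.filtered_counts.values())


def _parse_pileup_bases(bases: str, ref: str) -> list[str]:
    """Expand an mpileup base string into one reference-strand base per call.

    Handles ``^`` (read start; consumes the following mapping-quality char),
    ``$`` (read end), ``+n…``/``-n…`` indel blocks, ``.``/``,`` (reference
    match on forward/reverse read), ``>``/``<`` (reference skips, ignored)
    and ``*`` (deletion placeholder, counted as N).
    """
    out: list[str] = []
    ref = ref.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise ValueError("dangling '^' in mpileup base string")
            i += 2  # skip caret and mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"malformed indel length at {bases[i:i+5]!r}")
            ilen = int(bases[i + 1 : j])
            i = j + ilen
            if i > n:
                raise ValueError("indel block runs past end of base string")
            continue
        if c in "><":
            out.append("<")  # reference skip: placeholder, no quality pairing?
            i += 1
            continue
        if c == ".":
            out.append(ref)
        elif c == ",":
            out.append(ref)
        elif c == "*":
            out.append("N")
        else:
            base = c.upper()
            if base not in "ACGTN":
                raise ValueError(f"unexpected pileup character {c!r}")
            out.append(base)
        i += 1
    return out


def read_mpileup(
    path: str | Path, min_phred: int = 30
) -> Iterator[PileupColumn]:
    """Stream 6-column samtools-mpileup text as :class:`PileupColumn` s.

    Base calls with Phred+33 quality below ``min_phred`` are dropped.
    Reference skips (``>``/``<``) consume a quality character but are never
    counted; ``*`` deletions count as N (excluded from A/G arithmetic
    downstream).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 mpileup columns")
            chrom, pos, ref, depth, bases, quals = parts[:6]
            calls = _parse_pileup_bases(bases, ref)
            if len(calls) != len(quals):
                raise ValueError(
                    f"{path}:{lineno}: {len(calls)} base calls vs "
                    f"{len(quals)} quality characters"
                )
            col = PileupColumn(
                chrom=chrom, pos1=int(pos), ref_base=ref.upper(),
                depth=int(depth),
            )
            for base, qc in zip(calls, quals):
                if base == "<":
                    continue
                if ord(qc) - 33 < min_phred:
                    continue
                col.filtered_counts[base] += 1
            yield col


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, float_precision: int = 6) -> None:
    """Write a result table as TSV with deterministic column order and
    fixed-precision floats (reproducible diffs)."""
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_precision}f")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_json(obj, path: str | Path, float_precision: int = 6) -> None:
    """Serialize a JSON result with sorted keys and fixed float precision."""
    with open(path, "w") as fh:
        json.dump(_round_floats(obj, float_precision), fh, indent=2,
                  sort_keys=True, allow_nan=True)
        fh.write("\n")
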