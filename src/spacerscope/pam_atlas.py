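"""Genome-wide protospacer/PAM enumeration and spacer-library design.

A type II-A Cas9 acquires 30-nt spacers from phage DNA fragments whose 3'
flank carries a protospacer-adjacent motif (PAM) — canonically NGG, but a
"slipped" class of spacers targets protospacers followed by N-A-G-G, where
the canonical GG dinucleotide sits one base further from the protospacer.
This module enumerates every protospacer window on both strands of a genome
whose downstream flank matches a degenerate motif, classifies the 4-nt PAM,
derives the one-base-shifted canonical counterpart of each NAGG site, and
designs the fixed-length cloning oligos for a pooled spacer library.

Coordinates are 0-based, half-open, on the forward strand (BED convention),
with an explicit strand flag. For a minus-strand site the interval [start,
end) still addresses forward-strand bases; ``spacer_seq`` and ``pam4`` are
reported on the protospacer strand (i.e. reverse-complemented), and the PAM
lies 5' of the interval in forward coordinates. On circular genomes windows
may wrap the origin, in which case ``end`` exceeds the genome length and is
to be read modulo the length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "ProtospacerSite",
    "LibraryOligo",
    "OligoScaffold",
    "ConfigurationError",
    "PreconditionError",
    "classify_pam",
    "scan_pam_sites",
    "count_motif_sites",
    "shifted_counterpart",
    "design_library",
    "load_genome",
    "write_sites",
    "read_sites",
    "write_library",
]

PAM_LEN = 4
DEFAULT_SPACER_LEN = 30

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigurationError(ValueError):
    """Raised for invalid motifs, scaffolds or parameter combinations."""


class PreconditionError(ValueError):
    """Raised when an operation's input contract is violated."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence; the coordinate frame for all sites.

    ``allow_n`` enables a masking policy: windows containing non-ACGT bases
    are skipped during scanning (and counted), rather than rejected up front.
    """

    name: str
    sequence: str
    circular: bool = False
    allow_n: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGT")
        if bad and not (self.allow_n and bad <= {"N"}):
            raise ConfigurationError(
                f"genome {self.name!r} contains non-ACGT characters {sorted(bad)}; "
                "set allow_n=True to mask N-containing windows"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand slice; wraps the origin on circular genomes."""
        n = len(self.sequence)
        length = end - start
        if length > n:
            raise ValueError("window longer than genome")
        start %= n
        if start + length <= n:
            return self.sequence[start:start + length]
        if not self.circular:
            raise ValueError("window runs off the end of a linear genome")
        return self.sequence[start:] + self.sequence[: start + length - n]


@dataclass(frozen=True)
class ProtospacerSite:
    """One protospacer window with its downstream 4-nt PAM.

    ``start``/``end`` are forward-strand, 0-based half-open coordinates of
    the protospacer; ``spacer_seq`` and ``pam4`` are given on the protospacer
    strand, the PAM immediately 3' of the protospacer on that strand.
    """

    start: int
    end: int
    strand: str
    spacer_seq: str
    pam4: str
    pam_class: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.pam4) != PAM_LEN:
            raise ValueError("pam4 must be 4 nt")

    @property
    def spacer_len(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OligoScaffold:
    """Fixed flanking segments of a library oligo.

    The designed oligo is
    ``up_primer + left_arm + spacer + right_arm + down_primer``; the arms
    carry repeat homology plus the type-IIS (BsaI) recognition sites used for
    Golden Gate assembly, the primers are universal amplification sites.
    Segment sequences are configuration, not constants.
    """

    up_primer: str
    left_arm: str
    right_arm: str
    down_primer: str
    total_len: int = 85

    @property
    def flank_len(self) -> int:
        return len(self.up_primer) + len(self.left_arm) + len(self.right_arm) + len(self.down_primer)


@dataclass(frozen=True)
class LibraryOligo:
    spacer_seq: str
    full_oligo: str
    parts: tuple[str, ...]
    multiplicity: int = 1
    name: str | None = None


# ---------------------------------------------------------------------------
# PAM classification
# ---------------------------------------------------------------------------

def classify_pam(pam4: str) -> str:
    """Classify a 4-nt PAM as NGG, NAGG, NNGG_other or other.

    Precedence: a canonical GG at positions 2-3 (0-based 1:3) wins (so
    "AGGG" is NGG), then N-A-G-G, then any other NNGG, then everything else.
    """
    if len(pam4) != PAM_LEN:
        raise PreconditionError(f"pam4 must be 4 nt, got {pam4!r}")
    pam4 = pam4.upper()
    if not set(pam4) <= set("ACGT"):
        raise PreconditionError(f"pam4 must be over ACGT, got {pam4!r}")
    if pam4[1:3] == "GG":
        return "NGG"
    if pam4[1] == "A" and pam4[2:4] == "GG":
        return "NAGG"
    if pam4[2:4] == "GG":
        return "NNGG_other"
    return "other"


def _motif_regex(motif: str) -> re.Pattern[str]:
    if not motif:
        raise ConfigurationError("empty motif")
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ConfigurationError(f"non-IUPAC motif character {ch!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


_ACGT = set("ACGT")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _strand_starts(seq: str, motif_re: re.Pattern[str], spacer_len: int,
                   motif_len: int, circular: bool, flank_len: int) -> Iterable[int]:
    """Protospacer start positions (strand-local) with a motif match 3' of the
    window. ``flank_len`` is the number of downstream bases that must exist
    (max of motif length and PAM length, so pam4 is always populated)."""
    n = len(seq)
    if circular:
        ext = seq + seq[: spacer_len + flank_len - 1] if n else seq
    else:
        ext = seq
    for m in motif_re.finditer(ext):
        p = m.start()
        i = p - spacer_len
        if i < 0:
            continue
        if circular:
            if i >= n:
                continue
        elif i + spacer_len + flank_len > n:
            continue
        yield i


def scan_pam_sites(
    genome: Genome,
    motif: str,
    spacer_len: int = DEFAULT_SPACER_LEN,
    strands: Sequence[str] = ("+", "-"),
    report: dict | None = None,
) -> list[ProtospacerSite]:
    """Enumerate all protospacer sites whose downstream flank matches *motif*.

    Returns sites sorted by (start, strand), each (start, strand) at most
    once. On linear genomes, windows whose protospacer or 4-nt PAM would run
    off an end are excluded; on circular genomes windows wrap. Windows
    containing non-ACGT bases are skipped and counted in
    ``report["skipped_ambiguous"]``.
    """
    motif_re = _motif_regex(motif)
    motif_len = len(motif)
    flank_len = max(motif_len, PAM_LEN)
    if spacer_len < 1:
        raise ConfigurationError("spacer_len must be positive")
    skipped = 0
    n = len(genome)
    sites: dict[tuple[int, str], ProtospacerSite] = {}
    if n < spacer_len + motif_len:
        logger.warning(
            "genome %s (length %d) shorter than spacer_len + motif length (%d); no sites",
            genome.name, n, spacer_len + motif_len,
        )
        if report is not None:
            report["skipped_ambiguous"] = 0
        return []

    for strand in strands:
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        ext = seq + seq[: spacer_len + flank_len - 1] if genome.circular else seq
        for i in _strand_starts(seq, motif_re, spacer_len, motif_len,
                                genome.circular, flank_len):
            window = ext[i : i + spacer_len + flank_len]
            if not set(window) <= _ACGT:
                skipped += 1
                continue
            spacer = window[:spacer_len]
            pam4 = window[spacer_len : spacer_len + PAM_LEN]
            if strand == "+":
                start = i
            else:
                start = (n - (i + spacer_len)) % n
            key = (start, strand)
            if key in sites:
                continue
            sites[key] = ProtospacerSite(
                start=start,
                end=start + spacer_len,
                strand=strand,
                spacer_seq=spacer,
                pam4=pam4,
                pam_class=classify_pam(pam4),
            )
    if report is not None:
        report["skipped_ambiguous"] = skipped
    return sorted(sites.values(), key=lambda s: (s.start, s.strand))


def count_motif_sites(genome: Genome, motif: str) -> int:
    """Count occurrences of a degenerate motif on both strands.

    Motif occurrences only (no protospacer window requirement): on a circular
    genome every NGG therefore has an upstream base, so count("NGG") equals
    count("NNGG") exactly.
    """
    motif_re = _motif_regex(motif)
    motif_len = len(motif)
    n = len(genome)
    if n < motif_len:
        logger.warning("genome %s shorter than motif; count is 0", genome.name)
        return 0
    total = 0
    for strand in ("+", "-"):
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        ext = seq + seq[: motif_len - 1] if genome.circular else seq
        for m in motif_re.finditer(ext):
            if m.start() < n:
                total += 1
    return total


# ---------------------------------------------------------------------------
# Shifted canonical counterparts
# ---------------------------------------------------------------------------

def shifted_counterpart(site: ProtospacerSite, genome: Genome) -> ProtospacerSite | None:
    """Shift an NAGG site's protospacer window one base toward its PAM.

    The former N of the N-A-G-G PAM becomes the protospacer's 3'-terminal
    base, leaving a canonical PAM beginning AGG. On the + strand the forward
    interval advances by one; on the - strand it retreats by one (the shift
    is always in the 5'->3' direction of the protospacer strand). Returns
    None (with a warning) if the shifted window runs off a linear genome end.
    The counterpart inherits the site's name suffixed with "*".
    """
    if site.pam_class != "NAGG":
        raise PreconditionError(
            f"shifted_counterpart requires an NAGG site, got {site.pam_class}"
        )
    n = len(genome)
    spacer_len = site.spacer_len
    if site.strand == "+":
        new_start, new_end = site.start + 1, site.end + 1
        pam_end_fwd = new_end + PAM_LEN
        if not genome.circular and pam_end_fwd > n:
            logger.warning("shifted counterpart of site at %d runs off genome end; rejected", site.start)
            return None
        spacer = genome.fetch(new_start, new_end)
        pam4 = genome.fetch(new_end, pam_end_fwd)
    else:
        new_start, new_end = site.start - 1, site.end - 1
        if not genome.circular and new_start - PAM_LEN < 0:
            logger.warning("shifted counterpart of site at %d runs off genome start; rejected", site.start)
            return None
        spacer = revcomp(genome.fetch(new_start, new_end))
        pam_start = new_start - PAM_LEN
        pam4 = revcomp(genome.fetch(pam_start, pam_start + PAM_LEN))
    new_start %= n
    return ProtospacerSite(
        start=new_start,
        end=new_start + spacer_len,
        strand=site.strand,
        spacer_seq=spacer,
        pam4=pam4,
        pam_class=classify_pam(pam4),
        name=(site.name + "*") if site.name else None,
    )


# ---------------------------------------------------------------------------
# Library design
# ---------------------------------------------------------------------------

def design_library(sites: Sequence[ProtospacerSite], scaffold: OligoScaffold) -> list[LibraryOligo]:
    """One fixed-length cloning oligo per unique spacer sequence.

    Duplicate spacer sequences collapse into a single oligo with a recorded
    multiplicity. Raises if the scaffold segments plus the spacer length do
    not add up to the configured total oligo length.
    """
    if not sites:
        return []
    spacer_len = sites[0].spacer_len
    if scaffold.flank_len + spacer_len != scaffold.total_len:
        raise ConfigurationError(
            f"scaffold flanks ({scaffold.flank_len} nt) + spacer ({spacer_len} nt) "
            f"!= configured oligo length {scaffold.total_len}"
        )
    seen: dict[str, LibraryOligo] = {}
    for idx, site in enumerate(sites):
        sp = site.spacer_seq
        if sp in seen:
            seen[sp] = replace(seen[sp], multiplicity=seen[sp].multiplicity + 1)
            continue
        parts = (scaffold.up_primer, scaffold.left_arm, sp, scaffold.right_arm, scaffold.down_primer)
        seen[sp] = LibraryOligo(
            spacer_seq=sp,
            full_oligo="".join(parts),
            parts=parts,
            multiplicity=1,
            name=site.name or f"oligo{len(seen) + 1:04d}",
        )
    return list(seen.values())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_genome(path: str, contig: str | None = None, circular: bool = False,
                allow_n: bool = False) -> Genome:
    """Load a genome from FASTA; first record unless *contig* is given."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ConfigurationError(f"no FASTA records in {path}")
    if contig is not None:
        matches = [r for r in records if r.id == contig]
        if not matches:
            raise ConfigurationError(f"contig {contig!r} not found in {path}")
        rec = matches[0]
    else:
        rec = records[0]
    return Genome(name=rec.id, sequence=str(rec.seq), circular=circular, allow_n=allow_n)


def write_sites(sites: Sequence[ProtospacerSite], genome_name: str,
                bed_path: str, tsv_path: str | None = None) -> None:
    """Write sites as BED6 plus an optional TSV sidecar with pam4/pam_class."""
    with open(bed_path, "w") as bed:
        for s in sites:
            name = s.name or s.spacer_seq
            bed.write(f"{genome_name}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\n")
    if tsv_path:
        with open(tsv_path, "w") as tsv:
            tsv.write("name\tstart\tend\tstrand\tspacer_seq\tpam4\tpam_class\n")
            for s in sites:
                name = s.name or s.spacer_seq
                tsv.write(f"{name}\t{s.start}\t{s.end}\t{s.strand}\t{s.spacer_seq}\t{s.pam4}\t{s.pam_class}\n")


def read_sites(tsv_path: str) -> list[ProtospacerSite]:
    sites = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(ProtospacerSite(
                start=int(f[idx["start"]]), end=int(f[idx["end"]]),
                strand=f[idx["strand"]], spacer_seq=f[idx["spacer_seq"]],
                pam4=f[idx["pam4"]], pam_class=f[idx["pam_class"]],
                name=f[idx["name"]],
            ))
    return sites


def write_library(oligos: Sequence[LibraryOligo], fasta_path: str, tsv_path: str) -> None:
    with open(fasta_path, "w") as fa:
        for o in oligos:
            fa.write(f">{o.name}\n{o.full_oligo}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("name\tspacer_seq\tfull_oligo\tmultiplicity\n")
        for o in oligos:
            tsv.write(f"{o.name}\t{o.spacer_seq}\t{o.full_oligo}\t{o.multiplicity}\n")
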