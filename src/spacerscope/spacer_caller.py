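"""Spacer extraction from CRISPR-array amplicon reads and per-sample tables.

Amplicons of an expanded CRISPR array look like repeat-spacer-repeat(-spacer-
repeat...). Spacers are recovered by anchoring on the repeat: all
non-overlapping repeat occurrences (up to a configurable number of
mismatches) are located, the read is orientation-normalised so the repeats
run in their forward sense, and the inter-repeat segments of plausible
spacer length are emitted leader-proximal first. Spacers are then mapped
back to the genome by exact full-length matching on both strands, annotated
with their downstream PAM, and tabulated as read counts and frequencies.

Acquisition-order convention: new spacers are integrated at the leader, so
the leader-proximal spacer in a read is the most recently acquired; in a
double-acquisition event the *first*-acquired spacer is the leader-distal
one. ``LEADER_PROXIMAL_IS_NEWEST`` records this convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pam_atlas import (
    PAM_LEN,
    Genome,
    PreconditionError,
    ProtospacerSite,
    classify_pam,
    revcomp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArrayRead",
    "AcquisitionEvent",
    "SpacerTable",
    "ExtractParams",
    "LEADER_PROXIMAL_IS_NEWEST",
    "extract_spacers",
    "extract_from_fastq",
    "map_spacer",
    "tabulate",
    "classify_pam",
    "read_fastq",
    "write_events",
    "read_events",
]

#: Leader-proximal spacer in an array = most recently acquired.
LEADER_PROXIMAL_IS_NEWEST = True


@dataclass(frozen=True)
class ArrayRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class AcquisitionEvent:
    """Spacers recovered from one array read, leader-proximal first.

    ``status`` is "ok", "too_few_repeats" (fewer than two repeat matches) or
    "chimeric" (repeat matches in both orientations; spacers discarded).
    ``n_new`` excludes any configured pre-existing (engineered) spacers.
    """

    read_id: str
    spacers: tuple[str, ...]
    n_new: int
    status: str = "ok"


@dataclass
class ExtractParams:
    max_mismatches: int = 2
    min_len: int = 28
    max_len: int = 32
    denylist: frozenset[str] = field(default_factory=frozenset)


@dataclass
class SpacerTable:
    """Per-sample spacer counts, frequencies and mapping annotations.

    ``df`` columns: spacer_seq, read_count, frequency, n_matches, start, end,
    strand, pam4, pam_class, ambiguous. Frequencies are over mapped spacer
    occurrences by default (unmapped spacers tallied in ``unmapped``);
    ``matches`` holds the full match list per spacer for ambiguous cases.
    """

    sample_id: str
    df: pd.DataFrame
    unmapped: dict[str, int]
    matches: dict[str, list[ProtospacerSite]]
    qc: dict

    def __post_init__(self) -> None:
        if len(self.df):
            if (self.df["read_count"] < 1).any():
                raise ValueError("retained rows must have read_count >= 1")
            total = float(self.df["frequency"].sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")

    def write(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repeat-anchored extraction
# ---------------------------------------------------------------------------

def _repeat_hits(seq: str, repeat: str, max_mm: int) -> list[int]:
    """Start positions of non-overlapping repeat matches (leftmost-greedy)."""
    n, r = len(seq), len(repeat)
    if n < r:
        return []
    if max_mm == 0:
        # exact: plain string search
        starts, pos = [], seq.find(repeat)
        while pos != -1:
            starts.append(pos)
            pos = seq.find(repeat, pos + r)
        return starts
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rep = np.frombuffer(repeat.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, r)
    mm = (windows != rep).sum(axis=1)
    candidates = np.flatnonzero(mm <= max_mm)
    starts: list[int] = []
    prev_end = -1
    for c in candidates:
        if c >= prev_end:
            starts.append(int(c))
            prev_end = c + r
    return starts


def extract_spacers(read: ArrayRead, repeat: str,
                    params: ExtractParams | None = None) -> AcquisitionEvent:
    """Extract inter-repeat spacers from one read.

    The read is reverse-complemented first if the repeat matches only in the
    reverse orientation; repeats found in both orientations mark the read
    chimeric and its spacers are discarded. Reads with fewer than two repeat
    matches yield an event with zero spacers.
    """
    if len(repeat) < 12:
        raise PreconditionError("repeat must be at least 12 nt")
    params = params or ExtractParams()
    repeat = repeat.upper()
    seq = read.sequence.upper()
    fwd = _repeat_hits(seq, repeat, params.max_mismatches)
    rev = _repeat_hits(revcomp(seq), repeat, params.max_mismatches)
    if fwd and rev:
        return AcquisitionEvent(read.read_id, (), 0, status="chimeric")
    if rev:
        seq, hits = revcomp(seq), rev
    else:
        hits = fwd
    if len(hits) < 2:
        return AcquisitionEvent(read.read_id, (), 0, status="too_few_repeats")
    r = len(repeat)
    segments = []
    for a, b in zip(hits, hits[1:]):
        seg = seq[a + r : b]
        if params.min_len <= len(seg) <= params.max_len:
            segments.append(seg)
    spacers = tuple(s for s in segments if s not in params.denylist)
    return AcquisitionEvent(read.read_id, spacers, n_new=len(spacers))


def read_fastq(path: str):
    """Iterate ArrayReads from a FASTQ file (gzip transparently handled)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ArrayRead(rec.id, str(rec.seq))


def extract_from_fastq(path: str, repeat: str,
                       params: ExtractParams | None = None) -> tuple[list[AcquisitionEvent], dict]:
    """Run extraction over a FASTQ file; returns (events, QC counters)."""
    events, qc = [], {"reads_in": 0, "with_spacers": 0, "chimeric": 0, "too_few_repeats": 0}
    for read in read_fastq(path):
        qc["reads_in"] += 1
        ev = extract_spacers(read, repeat, params)
        if ev.status != "ok":
            qc[ev.status] += 1
        elif ev.n_new:
            qc["with_spacers"] += 1
        events.append(ev)
    return events, qc


# ---------------------------------------------------------------------------
# Mapping and tabulation
# ---------------------------------------------------------------------------

def _approx_starts(search: str, query: str, max_mm: int) -> list[int]:
    """Window start positions with Hamming distance <= max_mm."""
    arr = np.frombuffer(search.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    if arr.size < q.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, q.size)
    return np.flatnonzero((windows != q).sum(axis=1) <= max_mm).tolist()


def map_spacer(spacer_seq: str, genome: Genome,
               max_mismatches: int = 0) -> list[ProtospacerSite]:
    """Full-length matches of a spacer on both genome strands.

    Exact matching by default; ``max_mismatches`` enables sequencing-error
    rescue (substitutions only). Each match is annotated with the 4 nt
    immediately 3' of the protospacer on its strand; matches on a linear
    genome without room for a full PAM are dropped. More than one match
    marks the spacer ambiguous downstream. The reported ``spacer_seq`` is
    always the genomic sequence at the matched window.
    """
    spacer_seq = spacer_seq.upper()
    if not spacer_seq or not set(spacer_seq) <= set("ACGT"):
        raise PreconditionError("spacer must be a non-empty ACGT string")
    n = len(genome)
    L = len(spacer_seq)
    if L > n:
        return []
    sites: list[ProtospacerSite] = []
    search = genome.sequence + (genome.sequence[: L - 1] if genome.circular else "")
    for strand in ("+", "-"):
        query = spacer_seq if strand == "+" else revcomp(spacer_seq)
        if max_mismatches > 0:
            starts = iter(_approx_starts(search, query, max_mismatches))
            pos = next(starts, -1)
        else:
            starts = None
            pos = search.find(query)
        while pos != -1:
            start = pos  # forward coordinate of 5'-most base of the match
            if strand == "+":
                pam_start, pam_end = start + L, start + L + PAM_LEN
                ok = genome.circular or pam_end <= n
                pam4 = genome.fetch(pam_start, pam_end) if ok else None
            else:
                pam_start = start - PAM_LEN
                ok = genome.circular or pam_start >= 0
                pam4 = revcomp(genome.fetch(pam_start, pam_start + PAM_LEN)) if ok else None
            if pam4 is not None:
                window = search[pos:pos + L]
                sites.append(ProtospacerSite(
                    start=start, end=start + L, strand=strand,
                    spacer_seq=window if strand == "+" else revcomp(window),
                    pam4=pam4,
                    pam_class=classify_pam(pam4),
                ))
            pos = next(starts, -1) if starts is not None else search.find(query, pos + 1)
    return sorted(sites, key=lambda s: (s.start, s.strand))


def tabulate(events: list[AcquisitionEvent], genome: Genome,
             sample_id: str = "sample",
             include_unmapped: bool = False,
             mapping_mismatches: int = 0) -> SpacerTable:
    """Tabulate spacer occurrences from one sample's events.

    Every mapped spacer occurrence counts (a double-acquisition read
    contributes two); unmapped spacers are tallied separately and excluded
    from the frequency denominator unless ``include_unmapped`` is set (then
    they appear as rows with empty mapping annotations).
    ``mapping_mismatches`` > 0 enables substitution-tolerant rescue mapping.
    """
    counts: dict[str, int] = {}
    for ev in events:
        if ev.status != "ok":
            continue
        for sp in ev.spacers:
            counts[sp] = counts.get(sp, 0) + 1
    matches = {sp: map_spacer(sp, genome, max_mismatches=mapping_mismatches)
               for sp in counts}
    unmapped = {sp: c for sp, c in counts.items() if not matches[sp]}
    rows = []
    for sp, c in counts.items():
        m = matches[sp]
        if not m and not include_unmapped:
            continue
        first = m[0] if m else None
        rows.append({
            "spacer_seq": sp,
            "read_count": c,
            "n_matches": len(m),
            "start": first.start if first else pd.NA,
            "end": first.end if first else pd.NA,
            "strand": first.strand if first else "",
            "pam4": first.pam4 if first else "",
            "pam_class": first.pam_class if first else "unmapped",
            "ambiguous": len(m) > 1,
        })
    qc = {
        "events_ok": sum(ev.status == "ok" for ev in events),
        "spacer_occurrences": sum(counts.values()),
        "unique_spacers": len(counts),
        "unmapped_spacers": len(unmapped),
        "unmapped_occurrences": sum(unmapped.values()),
    }
    if not rows:
        logger.warning("sample %s: no spacers to tabulate", sample_id)
        df = pd.DataFrame(columns=[
            "spacer_seq", "read_count", "frequency", "n_matches", "start",
            "end", "strand", "pam4", "pam_class", "ambiguous"])
        return SpacerTable(sample_id, df, unmapped, matches, qc)
    df = pd.DataFrame(rows)
    df["frequency"] = df["read_count"] / df["read_count"].sum()
    df = df[["spacer_seq", "read_count", "frequency", "n_matches", "start",
             "end", "strand", "pam4", "pam_class", "ambiguous"]]
    df = df.sort_values("read_count", ascending=False, kind="stable").reset_index(drop=True)
    return SpacerTable(sample_id, df, unmapped, matches, qc)


def write_events(events: list[AcquisitionEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tn_new\tspacers\n")
        for ev in events:
            fh.write(f"{ev.read_id}\t{ev.status}\t{ev.n_new}\t{','.join(ev.spacers)}\n")


def read_events(path: str) -> list[AcquisitionEvent]:
    events = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, status, n_new, spacers = line.rstrip("\n").split("\t")
            events.append(AcquisitionEvent(
                rid, tuple(s for s in spacers.split(",") if s), int(n_new), status))
    return events
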