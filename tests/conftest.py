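"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything from first principles
(per-window character checks, no regex, no shared helpers) so they stay
independent of the implementation they validate.
"""

from __future__ import annotations

import numpy as np
import pytest

from spacerscope.pam_atlas import Genome

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _window(seq: str, start: int, length: int, circular: bool) -> str | None:
    n = len(seq)
    if circular:
        return "".join(seq[(start + k) % n] for k in range(length))
    if start < 0 or start + length > n:
        return None
    return seq[start:start + length]


def oracle_scan(genome: Genome, motif: str, spacer_len: int):
    """Quadratic-time window check of every (start, strand) position.

    Returns {(start, strand): (spacer, pam4)} in the same coordinate
    convention as the implementation: forward-strand start of the
    protospacer's 5'-most base (for '-' sites, of the interval).
    """
    seq = genome.sequence
    n = len(seq)
    flank = max(len(motif), 4)
    out = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else oracle_revcomp(seq)
        for i in range(n):
            win = _window(s, i, spacer_len + flank, genome.circular)
            if win is None or "N" in win:
                continue
            pam_region = win[spacer_len:spacer_len + len(motif)]
            if all(b in IUPAC_SETS[m] for b, m in zip(pam_region, motif)):
                start = i if strand == "+" else (n - (i + spacer_len)) % n
                out[(start, strand)] = (win[:spacer_len], win[spacer_len:spacer_len + 4])
    return out


def oracle_motif_count(genome: Genome, motif: str) -> int:
    seq = genome.sequence
    n = len(seq)
    total = 0
    for strand_seq in (seq, oracle_revcomp(seq)):
        for i in range(n):
            win = _window(strand_seq, i, len(motif), genome.circular)
            if win is None:
                continue
            if all(b in IUPAC_SETS[m] for b, m in zip(win, motif)):
                total += 1
    return total


def oracle_map(spacer: str, genome: Genome):
    """Every full-length exact occurrence on both strands, by window test."""
    seq = genome.sequence
    n = len(seq)
    L = len(spacer)
    hits = []
    for start in range(n):
        win = _window(seq, start, L, genome.circular)
        if win is None:
            continue
        if win == spacer:
            hits.append((start, "+"))
        if win == oracle_revcomp(spacer):
            hits.append((start, "-"))
    return sorted(hits)


def random_genome(rng: np.random.Generator, length: int, circular: bool = False,
                  gc: float = 0.5) -> Genome:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return Genome("rand", seq, circular=circular)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(11)
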