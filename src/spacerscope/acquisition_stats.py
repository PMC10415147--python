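"""Enrichment, paired fitness, and PAM nucleotide-preference statistics.

A pooled spacer-plasmid library is sequenced before and after phage
challenge; a spacer's enrichment ratio is its read frequency in the infected
culture divided by its frequency in the uninfected culture, so protective
spacers enrich (ratio > 1) and ineffective ones deplete. When a
non-canonical NAGG spacer is paired with its one-base-shifted canonical AGG
counterpart in the same competition, the NAGG spacer's fitness is

    fitness = ER_NAGG / (ER_NAGG + ER_AGG)

which is 0.5 for equal performance, scale-invariant, and satisfies
fitness(a, b) + fitness(b, a) = 1. A frequency-based variant (infected-
sample frequencies instead of enrichment ratios) is available behind a flag.

Nucleotide-preference analysis asks whether the enrichment ratios of spacers
grouped by the first PAM base (AAGG/CAGG/GAGG/TAGG), by the 3'-terminal
("seed-last") protospacer base, or by the seed-last+PAM-N dinucleotide,
differ from the rest; a group is called preferred (or disfavored) only if
its mean differs from every other group's (max of pairwise two-sided Welch
p-values, Holm-adjusted); complement-pool and permutation variants are
provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spacer_caller import SpacerTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "PairResult",
    "PreferenceResult",
    "enrichment",
    "pair_fitness",
    "pair_fitness_table",
    "fitness_partition",
    "complete_cases",
    "acquisition_by_pam_class",
    "nucleotide_preference",
]


@dataclass
class EnrichmentResult:
    """Per-spacer enrichment ratios plus the spacers that could not be scored.

    ``df`` columns: spacer_seq, freq_infected, freq_uninfected,
    enrichment_ratio, and the mapping annotations (start, strand, pam4,
    pam_class, ambiguous) carried over from the infected table.
    """

    df: pd.DataFrame
    dropped: list[str]

    def summary(self) -> dict:
        er = self.df["enrichment_ratio"]
        return {"n": int(len(er)), "mean": float(er.mean()),
                "std": float(er.std(ddof=1)) if len(er) > 1 else float("nan")}


@dataclass(frozen=True)
class PairResult:
    pair_id: str
    nagg_spacer: str
    agg_spacer: str
    er_nagg: float
    er_agg: float
    fitness: float


@dataclass
class PreferenceResult:
    """Group means vs the overall mean with per-group adjusted p-values.

    ``table`` columns: group, n, mean_er, delta (group mean - overall mean),
    p_value, p_adj, significant, skipped.
    """

    grouping: str
    overall_mean: float
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["start", "end", "strand", "pam4", "pam_class", "ambiguous"]


def enrichment(table_infected: SpacerTable, table_uninfected: SpacerTable) -> EnrichmentResult:
    """Enrichment ratio per spacer present (count >= 1) in both samples.

    Spacers seen in only one sample are returned in ``dropped`` rather than
    being given a ratio (no pseudocounts by default).
    """
    inf = table_infected.df.set_index("spacer_seq")
    uninf = table_uninfected.df.set_index("spacer_seq")
    shared = inf.index.intersection(uninf.index)
    dropped = sorted(inf.index.symmetric_difference(uninf.index))
    if len(shared) == 0:
        logger.warning("no spacers shared between %s and %s",
                       table_infected.sample_id, table_uninfected.sample_id)
        return EnrichmentResult(pd.DataFrame(columns=[
            "spacer_seq", "freq_infected", "freq_uninfected",
            "enrichment_ratio", *_ANNOT_COLS]), dropped)
    df = pd.DataFrame({
        "spacer_seq": shared,
        "freq_infected": inf.loc[shared, "frequency"].to_numpy(),
        "freq_uninfected": uninf.loc[shared, "frequency"].to_numpy(),
    })
    df["enrichment_ratio"] = df["freq_infected"] / df["freq_uninfected"]
    for col in _ANNOT_COLS:
        df[col] = inf.loc[shared, col].to_numpy()
    df = df.sort_values("spacer_seq", kind="stable").reset_index(drop=True)
    return EnrichmentResult(df, dropped)


# ---------------------------------------------------------------------------
# Paired fitness
# ---------------------------------------------------------------------------

def pair_fitness(er_nagg: float, er_agg: float) -> float:
    """Fitness of the NAGG member of a pair: er_nagg / (er_nagg + er_agg)."""
    if er_nagg <= 0 or er_agg <= 0:
        raise ValueError("enrichment ratios must be positive")
    return er_nagg / (er_nagg + er_agg)


def pair_fitness_table(result: EnrichmentResult, manifest: pd.DataFrame,
                       variant: str = "enrichment") -> list[PairResult]:
    """Fitness for each (NAGG spacer, shifted AGG counterpart) pair.

    *manifest* needs columns pair_id, nagg_spacer, agg_spacer. Pairs whose
    members lack ratios (absent or non-positive) are dropped and logged.
    ``variant="frequency"`` scores fitness from infected-sample frequencies
    instead of enrichment ratios.
    """
    if variant not in ("enrichment", "frequency"):
        raise ValueError(f"unknown fitness variant {variant!r}")
    col = "enrichment_ratio" if variant == "enrichment" else "freq_infected"
    values = result.df.set_index("spacer_seq")[col]
    out: list[PairResult] = []
    n_dropped = 0
    for row in manifest.itertuples(index=False):
        v_n = values.get(row.nagg_spacer)
        v_a = values.get(row.agg_spacer)
        if v_n is None or v_a is None or v_n <= 0 or v_a <= 0:
            n_dropped += 1
            continue
        # fitness formula is shared between variants; keep ER fields on the
        # scale actually used so downstream summaries are self-consistent
        out.append(PairResult(str(row.pair_id), row.nagg_spacer, row.agg_spacer,
                              float(v_n), float(v_a), pair_fitness(v_n, v_a)))
    if n_dropped:
        logger.info("pair_fitness_table: dropped %d pairs lacking positive values", n_dropped)
    return out


def fitness_partition(results: list[PairResult], hi: float = 0.5,
                      lo: float = 0.1) -> dict[str, float]:
    """Fractions of pairs with fitness strictly > hi, in [lo, hi], and < lo."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if not results:
        raise ValueError("empty pair list")
    f = np.array([r.fitness for r in results])
    n = len(f)
    return {
        "frac_above_hi": float((f > hi).sum() / n),
        "frac_mid": float(((f >= lo) & (f <= hi)).sum() / n),
        "frac_below_lo": float((f < lo).sum() / n),
    }


# ---------------------------------------------------------------------------
# Completeness and per-class acquisition
# ---------------------------------------------------------------------------

def complete_cases(tables: list[SpacerTable]) -> set[str]:
    """Spacers observed (count >= 1) in every one of >= 2 tables."""
    if len(tables) < 2:
        raise ValueError("complete_cases needs at least two tables")
    sets = [set(t.df["spacer_seq"]) for t in tables]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def acquisition_by_pam_class(table: SpacerTable,
                             site_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Aggregate a spacer table by PAM class.

    Returns one row per class with the number of distinct spacers, total
    reads, total/mean/std of per-spacer frequencies, and — when
    ``site_counts`` (available sites per class, e.g. from an exhaustive
    atlas scan) is supplied — reads per available site, the basis for
    acquisition-rate comparisons between canonical and non-canonical PAMs.
    """
    df = table.df
    rows = []
    for cls, grp in df.groupby("pam_class", sort=True):
        row = {
            "pam_class": cls,
            "n_spacers": int(len(grp)),
            "total_reads": int(grp["read_count"].sum()),
            "total_frequency": float(grp["frequency"].sum()),
            "mean_frequency": float(grp["frequency"].mean()),
            "std_frequency": float(grp["frequency"].std(ddof=1)) if len(grp) > 1 else float("nan"),
        }
        if site_counts is not None:
            n_sites = site_counts.get(cls, 0)
            row["n_sites"] = n_sites
            row["reads_per_site"] = row["total_reads"] / n_sites if n_sites else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def class_rate_log10_ratio(summary: pd.DataFrame, num_class: str, den_class: str) -> float:
    """log10 of per-site acquisition-rate ratio between two PAM classes."""
    s = summary.set_index("pam_class")
    return float(np.log10(s.loc[num_class, "reads_per_site"] / s.loc[den_class, "reads_per_site"]))


# ---------------------------------------------------------------------------
# Nucleotide preference
# ---------------------------------------------------------------------------

def _group_labels(df: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "pam_first_nt":
        return df["pam4"].str[0]
    if grouping == "seed_last_nt":
        return df["spacer_seq"].str[-1]
    if grouping == "seed_pam_dinucleotide":
        return df["spacer_seq"].str[-1] + df["pam4"].str[0]
    raise ValueError(f"unknown grouping {grouping!r}")


def nucleotide_preference(df: pd.DataFrame, grouping: str = "pam_first_nt",
                          method: str = "welch", n_perm: int = 10_000,
                          alpha: float = 0.05,
                          rng: np.random.Generator | None = None) -> PreferenceResult:
    """Compare per-group mean enrichment ratios to the overall mean.

    *df* needs columns enrichment_ratio, pam4 and spacer_seq. The default
    ``method="welch"`` flags a group only if its mean differs from *every*
    other group (intersection-union test: the group's p-value is the maximum
    of its pairwise two-sided Welch p-values), which keeps a single strongly
    deviant group from dragging the remaining groups to significance through
    a contaminated complement. ``method="complement"`` is the plain Welch
    test of each group against the pool of all other spacers;
    ``method="permutation"`` is a label-permutation test of the
    group-vs-complement mean difference. p-values are Holm-adjusted across
    groups. Groups with fewer than two members are flagged skipped, not
    tested.
    """
    labels = _group_labels(df, grouping)
    er = df["enrichment_ratio"].to_numpy(dtype=float)
    overall = float(er.mean())
    rng = rng or np.random.default_rng()
    groups = sorted(labels.unique())
    values = {g: er[(labels == g).to_numpy()] for g in groups}

    def _welch(x: np.ndarray, y: np.ndarray) -> float:
        if x.var() == 0 and y.var() == 0:
            # degenerate: no within-group spread, t undefined
            return 1.0 if x.mean() == y.mean() else 0.0
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)

    rows = []
    for g in groups:
        x = values[g]
        y = er[(labels != g).to_numpy()]
        row = {"group": g, "n": int(len(x)), "mean_er": float(x.mean()),
               "delta": float(x.mean() - overall), "skipped": False}
        if len(x) < 2 or len(y) < 2:
            row.update({"p_value": np.nan, "skipped": True})
        elif method == "welch":
            others = [values[h] for h in groups if h != g and len(values[h]) >= 2]
            if not others:
                row.update({"p_value": np.nan, "skipped": True})
            else:
                row["p_value"] = max(_welch(x, z) for z in others)
        elif method == "complement":
            row["p_value"] = _welch(x, y)
        elif method == "permutation":
            obs = abs(x.mean() - y.mean())
            k = len(x)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(er)
                count += abs(perm[:k].mean() - perm[k:].mean()) >= obs
            row["p_value"] = float((count + 1) / (n_perm + 1))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = ~table["skipped"]
    table["p_adj"] = np.nan
    if tested.any():
        table.loc[tested, "p_adj"] = multipletests(
            table.loc[tested, "p_value"], method="holm")[1]
    table["significant"] = table["p_adj"] < alpha
    return PreferenceResult(grouping, overall, table)
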