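"""End-to-end orchestration: atlas -> spacer calling -> stats -> priming.

One JSON run config drives all stages; outputs are plain TSV/JSON files in
a run directory, each run stamped with the tool version and a hash of the
config so results are traceable to their exact inputs. Stages hand data to
each other through files, so any stage's output can be inspected or re-used
independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd

from . import __version__
from .acquisition_stats import (
    acquisition_by_pam_class,
    enrichment,
    fitness_partition,
    nucleotide_preference,
    pair_fitness_table,
)
from .pam_atlas import (
    ConfigurationError,
    scan_pam_sites,
    shifted_counterpart,
    load_genome,
    write_sites,
)
from .priming import find_primed_pairs, histogram, priming_significance
from .spacer_caller import ExtractParams, extract_from_fastq, tabulate, write_events

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed after configuration validation."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    genome: str
    outdir: str
    samples: dict[str, str] = dataclasses.field(default_factory=dict)
    repeat_file: str | None = None
    repeat_seq: str | None = None
    circular: bool = False
    contig: str | None = None
    contrast: list[str] | None = None  # [infected, uninfected]
    pair_manifest: str | None = None
    denylist: str | None = None
    atlas: dict = dataclasses.field(default_factory=lambda: {"motif": "NAGG", "spacer_len": 30})
    extract: dict = dataclasses.field(default_factory=dict)
    priming: dict = dataclasses.field(default_factory=lambda: {"sample": None, "first_pam": "NAGG", "bin_width": 1000})
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in [self.genome, self.repeat_file, self.pair_manifest,
                               self.denylist, *self.samples.values()]
                   if p is not None and not os.path.exists(p)]
        if missing:
            raise ConfigurationError(f"missing input paths: {missing}")
        if self.samples and not (self.repeat_file or self.repeat_seq):
            raise ConfigurationError("samples given but no repeat sequence configured")
        if self.contrast is not None:
            if len(self.contrast) != 2 or any(s not in self.samples for s in self.contrast):
                raise ConfigurationError("contrast must name two configured samples [infected, uninfected]")

    def repeat(self) -> str | None:
        if self.repeat_seq:
            return self.repeat_seq.strip().upper()
        if self.repeat_file:
            return Path(self.repeat_file).read_text().strip().upper()
        return None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    stage = "atlas"
    try:
        genome = load_genome(config.genome, contig=config.contig, circular=config.circular)
        scan_report: dict = {}
        sites = scan_pam_sites(genome, config.atlas.get("motif", "NAGG"),
                               spacer_len=config.atlas.get("spacer_len", 30),
                               report=scan_report)
        for i, s in enumerate(sites):
            sites[i] = dataclasses.replace(s, name=f"spc{i + 1:04d}")
        write_sites(sites, genome.name, str(outdir / "sites.bed"), str(outdir / "sites.tsv"))
        report["stages"]["atlas"] = {"n_sites": len(sites), **scan_report}
        if config.atlas.get("motif", "NAGG").upper() == "NAGG":
            shifted = [shifted_counterpart(s, genome) for s in sites]
            shifted = [s for s in shifted if s is not None]
            write_sites(shifted, genome.name, str(outdir / "sites_shifted.bed"),
                        str(outdir / "sites_shifted.tsv"))
            report["stages"]["atlas"]["n_shifted"] = len(shifted)

        stage = "call"
        tables = {}
        all_events = {}
        if config.samples:
            repeat = config.repeat()
            deny = frozenset()
            if config.denylist:
                deny = frozenset(l.strip().upper() for l in Path(config.denylist).read_text().splitlines() if l.strip())
            params = ExtractParams(denylist=deny, **config.extract)
            for sid, fq in config.samples.items():
                events, qc = extract_from_fastq(fq, repeat, params)
                table = tabulate(events, genome, sample_id=sid)
                table.write(str(outdir / f"{sid}.table.tsv"))
                write_events(events, str(outdir / f"{sid}.events.tsv"))
                with open(outdir / f"{sid}.qc.json", "w") as fh:
                    json.dump({**qc, **table.qc}, fh, indent=2)
                tables[sid] = table
                all_events[sid] = events
                by_class = acquisition_by_pam_class(table)
                by_class.to_csv(outdir / f"{sid}.by_class.tsv", sep="\t", index=False)
            report["stages"]["call"] = {
                sid: {"reads_in": None, **t.qc} for sid, t in tables.items()
            }

        stage = "stats"
        if config.contrast:
            inf_id, uninf_id = config.contrast
            enr = enrichment(tables[inf_id], tables[uninf_id])
            enr.df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            stats_report = {"enrichment": enr.summary(), "n_dropped": len(enr.dropped)}
            if config.pair_manifest:
                manifest = pd.read_csv(config.pair_manifest, sep="\t")
                pairs = pair_fitness_table(enr, manifest)
                pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
                    outdir / "pair_fitness.tsv", sep="\t", index=False)
                if pairs:
                    stats_report["fitness_partition"] = fitness_partition(pairs)
                    stats_report["mean_fitness"] = float(
                        pd.Series([p.fitness for p in pairs]).mean())
            prefs = {}
            if len(enr.df) and (enr.df["pam4"].str.len() == 4).all():
                for grouping in ("pam_first_nt", "seed_last_nt", "seed_pam_dinucleotide"):
                    res = nucleotide_preference(enr.df, grouping)
                    prefs[grouping] = {
                        "overall_mean": res.overall_mean,
                        "groups": res.table.to_dict(orient="records"),
                    }
                with open(outdir / "preference.json", "w") as fh:
                    json.dump(prefs, fh, indent=2, default=str)
            report["stages"]["stats"] = stats_report

        stage = "priming"
        prime_sample = config.priming.get("sample")
        if prime_sample:
            events = all_events[prime_sample]
            counters: dict = {}
            pairs = find_primed_pairs(events, genome,
                                      first_class_filter=config.priming.get("first_pam", "NAGG"),
                                      counters=counters)
            prime_report = dict(counters)
            prime_report["n_pairs"] = len(pairs)
            if pairs:
                bw = int(config.priming.get("bin_width", 1000))
                hist = histogram(pairs, bw)
                with open(outdir / "priming_histogram.tsv", "w") as fh:
                    fh.write("bin\tcount\n")
                    for b, c in hist.bins.items():
                        fh.write(f"{b}\t{c}\n")
                pd.DataFrame([
                    {"event_id": p.event_id, "first_start": p.first_site.start,
                     "first_strand": p.first_site.strand,
                     "second_start": p.second_site.start,
                     "second_strand": p.second_site.strand,
                     "distance_bp": p.distance_bp} for p in pairs
                ]).to_csv(outdir / "priming_pairs.tsv", sep="\t", index=False)
                prime_report.update(priming_significance(pairs, len(genome), bw))
            report["stages"]["priming"] = prime_report
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001 - named-stage failure contract
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
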