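# spacerscope

Analysis toolkit for spacer-acquisition studies of type II-A CRISPR-Cas
systems, built around the question of how bacteria handle *non-canonical*
protospacer-adjacent motifs (PAMs). *S. pyogenes* Cas9 canonically requires
an NGG immediately 3′ of the 30-nt protospacer, but a class of "slipped"
spacers targets protospacers followed by N-A-G-G — the GG dinucleotide one
base further out. Such NAGG spacers can defend well, yet are acquired orders
of magnitude less often than canonical ones, and they behave like primed
spacers: when a read carries two newly acquired spacers and the first
targets an NAGG site, the second target clusters within ~1 kb.

spacerscope implements the complete computational side of such a study:

- **`pam_atlas`** — enumerate every protospacer/PAM site matching a
  degenerate IUPAC motif on both strands of a genome (linear or circular),
  classify 4-nt PAMs (`NGG` / `NAGG` / `NNGG_other` / `other`), derive the
  one-base-shifted canonical AGG counterpart of each NAGG site
  (`spc11 → spc11*`), and design fixed-length (default 85 nt) Golden-Gate
  library oligos. Coordinates are BED-style: 0-based, half-open, forward
  strand, with a strand flag.
- **`spacer_caller`** — extract newly acquired spacers from
  repeat-spacer-repeat amplicon reads (mismatch-tolerant repeat anchoring,
  orientation normalization, chimera filtering), map them back to the
  genome by exact full-length match on both strands, and tabulate
  per-sample read counts and frequencies.
- **`acquisition_stats`** — enrichment ratios
  (freq<sub>infected</sub>/freq<sub>uninfected</sub>), paired NAGG-vs-AGG
  fitness *f* = ER<sub>NAGG</sub>/(ER<sub>NAGG</sub>+ER<sub>AGG</sub>),
  fitness partitions (> 0.5 / 0.1–0.5 / < 0.1), complete-case filtering
  across samples, per-PAM-class acquisition rates, and PAM/seed
  nucleotide-preference tests.
- **`priming`** — double-acquisition pairing, signed first-to-second target
  distances, 1-kb histograms, and a one-sided binomial test of locality
  against the uniform (no-priming) null.
- **`synthetic_data`** — a fully seeded generator for phage-like genomes,
  PAM-class-weighted acquisition events with a locality kernel, multinomial
  selection experiments with planted per-spacer protection, and amplicon
  FASTQ reads with substitution errors; ground truth is retained so every
  stage is testable without any external download.
- **`pipeline`** / `spacerscope` CLI — one JSON config drives
  atlas → call → stats → priming with versioned, hashed, plain-file outputs.

## Worked example

A complete simulated experiment — genome, acquisition, sequencing, calling,
statistics — in a few lines:

```python
from spacerscope import scan_pam_sites, shifted_counterpart
from spacerscope.synthetic_data import SimConfig, gen_genome, sim_acquisition, emit_fastq
from spacerscope.spacer_caller import ArrayRead, extract_spacers, tabulate
from spacerscope.acquisition_stats import acquisition_by_pam_class, class_rate_log10_ratio
from spacerscope.priming import find_primed_pairs, priming_significance

cfg = SimConfig(seed=1)                     # 30 kb genome, GC 0.33, NGG:NNGG = 1:10^-2.5
rng = cfg.rng()
genome = gen_genome(cfg.genome_length, cfg.gc_content, rng)

sites = scan_pam_sites(genome, "NAGG", spacer_len=30)
print("NAGG sites:", len(sites))            # NAGG sites: 570

events, truth = sim_acquisition(genome, cfg, 20_000, rng)
reads = emit_fastq(events, cfg.repeat_seq, 0.0, rng)
called = [extract_spacers(ArrayRead(r, s), cfg.repeat_seq) for r, s in reads]
table = tabulate(called, genome, sample_id="demo")

site_counts = {}
for s in truth.sites:
    site_counts[s.pam_class] = site_counts.get(s.pam_class, 0) + 1
summary = acquisition_by_pam_class(table, site_counts)
print("log10 bias NAGG vs NGG:",
      round(class_rate_log10_ratio(summary, "NAGG", "NGG"), 2))

pairs = find_primed_pairs(called, genome, first_class_filter=None, dedupe=False)
sig = priming_significance(pairs, len(genome), bin_width=1000)
print("double acquisitions:", sig["n_pairs"],
      "| within 1 kb:", round(sig["frac_within_bin"], 3))
```

Output:

```
NAGG sites: 570
log10 bias NAGG vs NGG: -2.52
double acquisitions: 1990 | within 1 kb: 0.882
```

The genome carries 570 NAGG protospacer sites; re-calling 20,000 simulated
reads recovers the planted 10^−2.5 per-site acquisition bias of NAGG
against NGG sites (−2.52), and 88% of second spacers in double-acquisition
reads fall within 1 kb of the first target, as expected under the
exponential priming kernel (500 bp scale) the events were drawn with.

The same analysis runs from the shell:

```bash
spacerscope atlas scan --genome phage.fa --motif NAGG --spacer-len 30 --out sites.bed
spacerscope call --fastq s1.fq.gz --repeat repeat.txt --genome phage.fa --out s1.tsv
spacerscope stats enrich --infected i.tsv --uninfected u.tsv --out enrichment.tsv
spacerscope priming --events s1.events.tsv --genome phage.fa --first-pam NAGG --out priming.json
spacerscope run --config run.json        # the whole pipeline from one config
```

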