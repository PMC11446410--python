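# hcrkit

Probe design for third-generation hybridization chain reaction (HCR v3)
RNA imaging, plus the companion statistics for comparing two
spot-detection methods run on the same sample.

HCR v3 detects single mRNA molecules with **split-initiator probe
pairs**: two DNA oligos bind adjacent 25-nt sites on the target, each
carrying one 18-nt half of a 36-nt initiator behind a short flexible
connector. Only when both probes are bound is the full initiator
presented, triggering polymerization of fluorophore-labelled hairpins —
a single non-specifically bound probe stays dark. Because the signal is
amplified, as few as five probe pairs per transcript give a quantifiable
image, which makes the method attractive for medium-throughput screens.
That puts the burden on probe design; `hcrkit` implements that pipeline:

1. **Tiling** — every window of `2·arm_len + gap_len` nt (default
   25 + 2 + 25 = 52) along the target, one per start position. Exon
   junctions are masked with `N` (two accepted FASTA conventions: one
   record with `N` between exons, or one record per exon), and any
   window touching a mask is rejected, so no probe spans a splice
   junction.
2. **Thermodynamic filtering** — each arm is scored as an independent
   DNA:DNA duplex with the unified nearest-neighbor model
   (SantaLucia 1998 parameters, entropic monovalent-salt correction,
   −0.6 °C per % formamide applied last) under the hybridization buffer
   defaults (5×SSC → 0.75 M Na⁺, 30 % formamide, 10 nM probe). Arms must
   fall in the Tm window [40, 60] °C and GC window [0.35, 0.65], with no
   homopolymer run over 4 nt.
3. **Off-target screening** — candidate windows sharing a contiguous
   exact match > 16 nt with any non-target transcript are rejected,
   via a deterministic k-mer seed-and-extend screen over a transcriptome
   FASTA (or optionally NCBI `blastn -task blastn-short` against a
   pre-built database).
4. **Selection** — a maximum-cardinality non-overlapping set (greedy
   earliest-end, provably optimal) or, on request, a fixed number of
   windows maximizing the minimum inter-probe spacing. Fewer than five
   final pairs raises the `FEWER_THAN_MIN_PAIRS` warning.
5. **Assembly & output** — each window becomes a probe pair
   (`half_up + conn + revcomp(arm2)`, `revcomp(arm1) + conn + half_dn`,
   45-nt oligos by default) for one of the five B1–B5 initiators; every
   pair is verified by simulated hybridization (`validate_pair`), and the
   results are written as an order sheet (CSV/XLSX with 96-well layout),
   a probe map (positions + per-arm Tm), JSON, and a run manifest.

The colocalization module quantifies agreement between two detection
methods (e.g. HCR vs smFISH): the directional fractions of spots of one
set whose nearest neighbor in the other set lies within a radius
(default 750 nm, strict `<`), computed exactly via KD-trees.

All stages are exercisable on synthetic fixtures (multi-exon targets,
decoy transcriptomes with planted off-targets, paired spot fields with a
known shared fraction) generated deterministically from a seed.

## Worked example

`python examples/design_probes.py` designs probes for a synthetic 2-kb,
3-exon transcript against a decoy transcriptome with one planted
off-target:

```
target: synthgene, 2002 nt, 3 exons
candidate windows tiled: 1951
windows passing all filters: 1418
non-overlapping pairs selected: 34
warnings: none

pair  window(1-based)  Tm arm1  Tm arm2   oligo P1 (5'->3')
   1       1-52       52.01    50.90   GAGGAGGGCAGCAAACGGAAACATACCAGCACTGCTACACTCATG
   2      55-106      48.30    52.31   GAGGAGGGCAGCAAACGGAAGACAGCCGCTGGTGTCGGTATATAT
...
```

1951 windows tile the 2002-nt target (L − 52 + 1); 104 junction-spanning
windows and all thermodynamic/off-target failures are removed; 34
non-overlapping pairs remain (well above the recommended minimum of
five). Each P1 oligo starts with the B1 initiator's first half
(`GAGGAGGGCAGCAAACGG`) + `AA` connector, followed by the reverse
complement of the window's 3′ arm; Tm values are per-arm melting
temperatures under the hybridization buffer.

`python examples/colocalization.py` recovers a planted spot-field
overlap:

```
spots: 380 (hcr), 345 (smfish)
% hcr spots with a smfish spot within 750 nm:  68.4  (planted: 68.4)
% smfish spots with an hcr spot within 750 nm: 75.7  (planted: 75.4)
```

The same operations are available from the shell:

```bash
hcrkit design --target gene.fa --transcriptome txome.fa --initiator B2 --out run/
hcrkit coloc --a spots_hcr.csv --b spots_smfish.csv --radius 750
hcrkit simulate target --seed 1 --out fixtures/
hcrkit validate --sheet run/order_sheet.csv --target gene.fa --result-json run/design_result.json
```

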