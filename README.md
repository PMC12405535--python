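# sensorscreen

Analysis toolkit for pooled screens of barcoded, memory-circuit-coupled
bacterial biosensors. It covers the full desk side of such a screen:

1. **`tcs_miner`** — mine "grouped" two-component systems (an HK–RR gene pair
   within 200 bp on the same strand, head-to-head with a divergently
   transcribed neighbour) from a genome FASTA + GFF3 + HK/RR role table;
   extract the sensor region (shared intergenic promoter through the far end
   of the pair) and flag SapI/BsaI Golden Gate compatibility.
2. **`barcode_caller`** — call reference barcodes from short-read amplicon
   data: dereplicate, filter to the expected 106 bp, greedily cluster at 95%
   global-alignment identity, and aggregate counts onto each cluster's
   highest-count sequence.
3. **`assigner`** — link barcodes to sensors with long reads that span the
   sensor–barcode junction: adapter trimming (5 mismatches, ≥10 bp match),
   \>400 bp length filter, semi-global placement on sensor references,
   tail-to-barcode matching, and dual-criterion assignment (a sensor must win
   both the read count and the sensor-normalised read fraction, with ≥5
   reads; disagreements are discarded).
4. **`for_quant`** — per-barcode odds ratios normalised to positive-control
   barcodes, fractional odds ratios (FOR) rescaled between negative (~0) and
   positive (~1) control anchors, sensor-level aggregation (median of
   barcode FORs, or pooled counts), and the FOR > 0.01 activation call.
5. **`qc`** — the three sample gates (positive-control outgrowth fit with
   r² > 0.6 and slope in (0.5, 2); barcode abundance > 1/5000 of the
   −spectinomycin reads; positive/negative geometric-mean OR fold change
   \> 30), the 100-read positive-barcode exclusion, and recovery fractions.
6. **`ranker`** — rank sensors OFF at gavage (FOR < 0.25) by mean faecal FOR
   minus gavage FOR, or by treatment-vs-control mean FOR difference.
7. **`synthetic`** — seeded simulators with full ground truth: library
   generation (mutually <80%-identical barcodes, log-normal abundances),
   bacteriostatic ±spectinomycin outgrowth (expected OR = f + (1−f)/G, so
   expected FOR equals the true ON-fraction f), multinomial read sampling,
   short/long read error models, colonisation bottlenecks, and annotated
   genomes with planted grouped TCSs for the miner.

## CLI

One entry point with a subcommand per stage:

```sh
sensorscreen simulate --seed 4 --config sim.yaml --out sim/
sensorscreen mine-tcs --fasta G.fa --gff G.gff3 --roles roles.tsv --out mined
sensorscreen call-barcodes --reads R.fastq --length 106 --identity 0.95 --out called
sensorscreen link --long-reads L.fastq --sensors S.fa --barcodes called.fasta --out map.tsv
sensorscreen quantify --counts counts.tsv --map map.tsv --norm norm.yaml --mode median --out for
sensorscreen qc --counts counts.tsv --map map.tsv --norm norm.yaml --out qc.tsv
sensorscreen rank --for for.sensors.tsv --design design.tsv --mode in_vivo --out ranks.tsv
```

`simulate` writes FASTQ reads, truth tables, count tables and a
normalisation YAML that the downstream subcommands consume directly. The
count table format is long TSV (`barcode_id, sample_id, culture∈{plus,minus},
reads`); the design table maps `sample_id` to a condition label (one sample
labelled `gavage`).

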