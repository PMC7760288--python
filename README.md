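# rohscan

SNP-array population-genetics toolkit: runs-of-homozygosity (ROH) detection,
genomic inbreeding (F_ROH) statistics, LD-based effective-population-size
(Ne) trajectories, and overlap of ROHs with candidate selection regions —
plus synthetic-data generators (ROH implants and a forward Wright–Fisher
simulator with pedigree truth) so the whole pipeline is testable end to end
without external data.

## Components

| module | purpose |
|---|---|
| `rohscan.genotype_io` | PLINK PED/MAP (text) and BED/BIM/FAM (binary) reading, PED/MAP writing, multi-population merging, marker QC (missingness, MAF, exact Hardy–Weinberg test) and greedy windowed LD pruning |
| `rohscan.roh_detection` | PLINK-style sliding-window ROH calling (20-SNP windows, ≤1 het, ≤1 missing, support threshold 0.05, min 4 Mb / 20 SNPs / 1 SNP per 100 kb, max 1 Mb gap) and 4–8 / 8–16 / >16 Mb size classes |
| `rohscan.inbreeding_stats` | per-individual F_ROH (total, cumulative by length threshold, per chromosome), per-population × class summaries (counts, frequencies, mean/SD/CV/95% CI), tabular and plot-ready reports |
| `rohscan.ne_estimation` | composite r² between dosage vectors, distance-binned adjusted LD, and the N_T(t) = (4·f(c))⁻¹(E[r²_adj]⁻¹ − α) trajectory with t = 1/(2c) |
| `rohscan.region_overlap` | BED I/O, ROH-vs-region overlap statistics, per-region F_ROH, per-SNP ROH incidence |
| `rohscan.synthetic_data` | seeded ROH-implant datasets with exact truth, forward Wright–Fisher simulation under an arbitrary N(t) trajectory with recorded pedigree inbreeding, and random candidate-region generation |
| `rohscan.cli` | `rohscan` executable chaining the stages |

## CLI

```sh
# simulate a declining population and genotype it (PED/MAP + truth + BED)
rohscan simulate --mode wf --out-prefix sim --seed 1 \
    --n-samples 40 --n-chrom 29 --snps-per-chrom 1000

# full pipeline: qc -> roh -> froh -> ne -> overlap
rohscan all --ped sim.ped --map sim.map --regions sim.regions.bed --out-dir out/

# or stage by stage
rohscan qc  --ped sim.ped --map sim.map --out-prefix out/qc
rohscan roh --ped out/qc.ped --map out/qc.map --out out/roh.tsv \
    --homozyg-window-snp 20 --min-length-kb 4000
rohscan froh --roh out/roh.tsv --map out/qc.map --out-dir out/froh
rohscan ne  --ped out/qc.ped --map out/qc.map --out out/ne.tsv --alpha 2.2
rohscan overlap --roh out/roh.tsv --regions sim.regions.bed --out out/overlap.tsv
```

All thresholds default to the standard 50K-chip parameterisation and can be
overridden by flags or a plain-text `key = value` file via `--config`.
Outputs are tab-separated; logs go to standard error.

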