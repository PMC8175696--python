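# wgtkit

Tools for three genome analyses that together characterise the evolutionary
history and breeding system of a Solanaceae genome such as wolfberry
(*Lycium barbarum*):

1. **Ks-based polyploidy detection and dating.** The synonymous distance
   *K*<sub>S</sub> between two coding sequences acts as a molecular clock, so the
   *K*<sub>S</sub> age distribution of a genome's duplicate pairs (the *paranome*, or
   the syntenic *anchor pairs*) shows a peak for every burst of duplication.
   `wgtkit` estimates *K*<sub>S</sub>/*K*<sub>a</sub> per pair with the Nei–Gojobori (1986)
   counting method and Jukes–Cantor correction, detects density modes by
   Gaussian KDE on log *K*<sub>S</sub>, orders a whole-genome duplication (WGD/WGT)
   peak among speciation peaks taken from one-to-one ortholog distributions
   (reciprocal best hits), and converts the peak into an absolute age via a
   per-lineage substitution rate λ = *K*<sub>S</sub>/time, T = *K*<sub>S,WGD</sub>/λ.
2. **Heterozygosity hotspot scanning.** Heterozygous sites from a filtered
   diploid VCF (2 ≤ DP ≤ 20, QUAL ≥ 20) are counted in 200-kb windows;
   windows with >1000 sites (>0.5% heterozygosity) are hotspots. Genes in
   hotspots are tested for term enrichment (Fisher exact +
   Benjamini–Hochberg).
3. **S-RNase / self-incompatibility classification.** Within the RNase-T2
   family, S-RNase candidates lack amino-acid pattern 4
   `[CG]P[QLRSTIK][DGIKNPSTVY][ADEIMNPSTV][DGKNQST]` and have an
   isoelectric point in [8, 10] (computed by charge bisection with
   Bjellqvist pKa values). An S-RNase gene with F-box genes in its
   flanking region marks an S-locus candidate.

A synthetic-data module generates every input class with known ground
truth (lognormal *K*<sub>S</sub> mixtures, codon pairs evolved to a target
divergence, VCFs with planted hotspot intervals, protein sets with planted
motifs), so the whole pipeline is testable at desk scale.

## Worked example

```python
from wgtkit import build_distribution, detect_peaks, gen_cds_pair

pairs = [gen_cds_pair(0.65, 0.0, 400, seed)[:2] for seed in range(300)]
dist = build_distribution(pairs, kind="anchors")
peaks = detect_peaks(dist, search_range=(0.4, 1.0))
print(f"mode: {peaks.primary.ks_mode:.4f}")
```

Running `python examples/01_anchor_peak_recovery.py` prints:

```
pairs simulated        : 300 (400 codons each)
saturated pairs dropped: 0
mean per-pair Ks       : 0.6413
detected density mode  : 0.6192
```

The detected mode recovers the planted divergence of 0.65 to within the
stochastic scatter of a 300-pair sample — this is the age signature a real
WGD leaves in an anchor-pair distribution. The other examples
(`examples/02` – `05`) walk through rate-calibrated dating (per-species λ
and a WGD age range of 64.83–75.54 Mya, mean 69.00, on the bundled
synthetic dating table), the hotspot scan (one planted 10× interval
recovered exactly), S-RNase classification and RBH ortholog selection.

A thin CLI mirrors the library:

```bash
wgtkit simulate vcf --chrom-lengths chr1:1000000 --background-rate 0.001 \
    --hotspot chr1:400000:600000:0.01 --seed 7 --out het.vcf
wgtkit hotspots scan --vcf het.vcf --out-bed hotspots.bed
wgtkit wgd date --wgd-ks 0.65 --events events.tsv
wgtkit run --config run.cfg     # full pipeline with a manifest
```

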