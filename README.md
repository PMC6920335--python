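# growthgwas

Time-resolved genotype–phenotype analysis of early plant growth.

High-throughput phenotyping platforms image every plant of a mapping panel
every day, turning "biomass" from a single end-point number into a daily
trajectory. `growthgwas` implements the full analysis chain needed to exploit
that: from replicated raw phenotype time series and SNP/CNV marker calls of a
diploid (here: allotetraploid canola, *Brassica napus*, AACC) panel to
per-day genotype BLUEs, relative growth rates, marker–trait association scans
per day, *dynamic* (stage-specific) QTL calls, and LD-based candidate gene
intervals. A synthetic-data generator with a known QTL architecture makes
every stage testable end to end.

It is written for quantitative geneticists and breeders analysing
image-derived growth traits (biovolume, projected leaf area, plant height,
colour uniformity) measured daily over an early vegetative phase, plus
end-point biomass.

## The models

**Per-day BLUEs.** For each trait and day, genotype values are adjusted
genotype means from a linear mixed model with genotype fixed and design
factors random (REML variance components):

    Y = G + E + GxE + C + CxE + e            (image traits)
    Y = G + E + P + GxE + C + CxE + PxE + e  (end-point biomass)

with experiment E, check-line identity C, pot position P and residual e.
Broad-sense heritability uses the all-random refit:

    H² = σ²_G / (σ²_G + σ²_e / n₀)

where n₀ is the number of experiments (image traits) or plant replicates
(end-point biomass).

**Growth rates.** Between two imaging time points t₁, t₂ (minute precision):

    RGR = (ln W₂ − ln W₁) / (t₂ − t₁),    ACR = (W₂ − W₁) / (t₂ − t₁).

**Association scans.** An iterative pseudo-QTN scan per trait × time label:
each marker is tested by least squares with the first 4 genotype PCs (and the
current pseudo-QTN dosages) as covariates; markers below a 1e-5 threshold are
promoted to pseudo-QTNs, deduplicated per genomic bin with the bin size
chosen by the restricted likelihood of a kinship model built from the
candidates; iterate to convergence (≤ 100 loops). P-values are
Benjamini–Hochberg adjusted within each scan; adjusted P ≤ 0.1 is
significant. Variance explained per significant marker is the sequential
(type-I) sum of squares of a joint model with markers entered in decreasing
P order: PVE% = SS_marker / (Σ SS + SS_resid) × 100.

**Dynamic QTL.** A marker is a dynamic QTL if significant at ≥ 3 consecutive
measured days (≥ 2 consecutive intervals for rates); adjacency follows the
measured-day list, so days 13 and 15 are adjacent when day 14 was never
measured. Allele-effect trajectories (covariate-adjusted single-marker
estimates per day) are scanned for sign reversals.

**Candidate intervals.** Pairwise LD is the squared dosage correlation r²;
decay per subgenome is fitted with the Hill–Weir drift–recombination
expectation E[r²](C = ρ·d, n). The interval around a significant marker is
its LD block (contiguous markers with r² ≥ 0.6 to the focal marker) extended
to the nearest flanking unrelated markers, or a ±100 kb window when no block
exists; genes overlapping the interval are the candidates.

## Worked example

```python
import growthgwas as gg
from growthgwas import assocscan as asc, phenostats as ps

cfg = gg.SimConfig(
    n_genotypes=200, n_snp=800, n_cnv=80, n_experiments=3, seed=7,
    qtl=[gg.QtlSpec("biovolume", (9, 13), variance_fraction=0.15)],
)
panel, obs, truth = gg.simulate_study(cfg)

filt, log = gg.filter_markers(panel)            # MAF/missing/het rules
imputed, zero_var = gg.impute_for_scan(filt)    # missing -> heterozygous
pcs = gg.compute_pcs(imputed, k=10)

obs_clean, _ = ps.filter_outliers(obs)          # median +/- 3 SD per stratum
blues = ps.fit_blues(obs_clean, ps.EQ1, trait="biovolume", day=11)
h2 = ps.estimate_h2(obs_clean, ps.EQ1, trait="biovolume", day=11)
print(f"H2(biovolume, 11 DAS) = {h2.h2:.3f}")

y = blues.blues[~blues.blues.index.str.startswith("CHK")]
rec = asc.scan_with_fdr(y, filt, pcs, asc.ScanParams(),
                        trait="biovolume", time_label=11)
print(rec.nsmallest(3, "p_value")[["marker_id", "effect",
                                   "p_value", "p_value_fdr", "pve_pct"]])
```

prints (the planted marker tops the scan on the day inside its active
window and explains ~14% of the BLUE variance):

```
H2(biovolume, 11 DAS) = 0.837
        marker_id chromosome  position      effect  p_value  p_value_fdr   pve_pct
sim-C08-p33822801        C08  33822801  343.183804 0.000002     0.001639 14.482261
sim-A02-p23971301        A02  23971301 -206.189986 0.001161     0.355529       NaN
sim-A06-p22514201        A06  22514201  203.235898 0.001212     0.355529       NaN
```

The full chain (simulate → QC → BLUEs → rates → scans → dynamics →
candidates) runs from the command line:

```bash
growthgwas all --config run.yaml --seed 1 --out results/
```

Two small published association tables ship with the package
(`growthgwas.examples`): the 22 end-point biomass marker–trait associations
(13 fresh weight, 9 dry weight) and the five candidate regions around
temporally dynamic markers; they drive the worked-example checks of the
cross-trait sharing logic and the interval arithmetic.

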