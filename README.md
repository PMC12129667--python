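# divescan

Two-stage detection of adaptive genetic variation in closely related human
populations: a genome-wide **selection scan** for excess allele-frequency
change in a focal population, followed by **covariate-adjusted association**
of the scan's top candidates with a quantitative phenotype. The design
mirrors studies of diving and altitude adaptation in small, phenotypically
distinctive populations (e.g. the Haenyeo breath-hold divers of Jeju
Island): because association testing is restricted to a handful of
selection candidates, the multiple-testing burden shrinks from genome-wide
to a Bonferroni correction over ~10 SNPs.

The package is aimed at population geneticists who want the full pipeline —
QC, population-structure statistics, the scan, peak selection, association —
as reusable, tested library code, together with a synthetic-data generator
that reproduces the statistical structure of such a study so every stage can
be validated without access to restricted cohort data.

## The model

Populations `i = 1..K` descend from a shared ancestor by drift. For each SNP,
outgroup-rooted frequency contrasts `y_i = p_i − p_outgroup` are modelled as

    y ~ N(0, s·C),      s = p̄(1 − p̄),

where `p̄` is the across-population mean frequency and `C` is the genome-wide
contrast covariance estimated as `mean(y yᵀ / s)`. The per-SNP test
multiplies the focal population's diagonal entry of `C` by a scalar `γ ≥ 1`
estimated by maximum likelihood, giving a boundary-constrained
likelihood-ratio statistic

    LLR = 2 (ℓ(γ̂) − ℓ(1)) ≥ 0,

with `LLR = 0` exactly when the boundary `γ = 1` is optimal. Because the
null distribution is a mixture of a point mass at zero and a χ²₁-like
component, genomic control uses 99th percentiles instead of medians:
`λ = P99(observed) / P99(χ²₁)` on the retained (upper) half of the
statistics, and calibrated p-values are `1` at `LLR = 0`, else
`½·S_χ²₁(LLR/λ)`.

Candidate signals are the 99th-percentile outliers that have another
outlier within ±100 kb, are local maxima in that window, survive
single-linkage collapsing of wide (megabase-scale) peaks, and rank in the
top 10 by LLR. Each candidate's representative SNP is then tested by OLS:

    phenotype ~ intercept + dosage + age + height + weight
                + dive_duration (+ age²) + 10 genotype PCs,

with significance declared at the Bonferroni threshold `α/m` (0.005 for
`α = 0.05`, `m = 10`).

Supporting statistics: Weir–Cockerham F_ST (ratio of averages), windowed
nucleotide diversity π with `Ne = π/(4μ)` (default `μ = 1.25e-8`), exact
one-sided heterozygote-excess site filtering, MAF filtering, allele-flip
(fixed-difference) detection between merged panels, and IBS-based K0
relatedness pruning.

## Worked example

Simulate a 20,000-SNP three-population panel (focal `JEJ`, sister `KOR`,
outgroup `CHS`; focal–sister F_ST ≈ 0.004) with one swept locus whose focal
frequency is displaced from 0.07 to 0.33, then run the full two-stage
pipeline:

```python
from divescan import *
from divescan.peaks import run_peak_pipeline

params = SimulationParams(n_snps=20_000, sweeps=(SweepSpec(center_index=10_000),), seed=1)
panel = simulate_panel(params)
gm = sample_genotypes(panel, seed=2)

print("FST(JEJ,KOR) = %.5f" % wc_fst(gm, ("JEJ", "KOR")).fst)
scan = scan_genome(gm, focal="JEJ", outgroup="CHS")
cal, scan_cal = calibrate_llrs(scan)
print("zero-LLR fraction = %.3f, lambda = %.3f" % (cal.fraction_zero, cal.lambda_))

cand = run_peak_pipeline(scan_cal, n=10)
pheno_ids = [s for s in gm.sample_ids if s.startswith("JEJ")] + \
    [s for s in gm.sample_ids if s.startswith("KOR")][:28]          # n = 85
sub = gm.select_samples(pheno_ids)
pheno = simulate_phenotype(sub, PhenotypeParams(causal_snp="snp10000",
                                                beta_per_allele=-10.0,
                                                noise_sd=8.0, seed=3))
report = run_two_stage(gm, pheno, cand, alpha=0.05)
print(report.as_frame().head(3).to_string(index=False))
```

Output:

```
FST(JEJ,KOR) = 0.00419
zero-LLR fraction = 0.680, lambda = 0.702
      id      beta       se         t        p  n  significant
snp10000 -8.736896 1.628858 -5.363818 0.000001 85         True
snp16256  2.739919 1.763081  1.554052 0.124747 85        False
snp19143  2.771883 1.654288  1.675575 0.098348 85        False
```

The swept SNP tops the candidate list (LLR = 35.1 against a null whose
largest values are ~11), and the association stage recovers its protective
per-allele effect (true β = −10, estimated −8.7 ± 1.6) at
p = 1×10⁻⁶ ≤ 0.005, while the other candidates stay null. The zero-LLR
fraction of 0.68 is the exact finite-sample null mass of the boundary test,
`P(χ²₁ ≤ 1) = 0.683` (see `docs/methods.md` for why this exceeds the
asymptotic 50%).

The same pipeline is scriptable from the shell:

```bash
divescan simulate --n-snps 20000 --seed 1 --out-prefix sim
divescan scan --vcf sim.vcf --pops sim.pops.tsv --focal JEJ --outgroup CHS --out scan.tsv
divescan calibrate --scan scan.tsv --out scan_cal.tsv
divescan peaks --scan scan_cal.tsv --top 10 --out-prefix peaks
divescan assoc --vcf sim.vcf --pops sim.pops.tsv --pheno sim.pheno.tsv \
    --candidates peaks.candidates.tsv --out-prefix assoc
```

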