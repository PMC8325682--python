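# qpcrkit

A toolkit for designing and validating homolog-discriminating qPCR assays,
and for choosing reference genes that are actually stable under the
conditions of an experiment.

Plant genomes are full of nearly identical gene copies, so primers designed
by naive tools often amplify several homologs at once. `qpcrkit` implements
a stepwise protocol that addresses this end to end:

1. **Homologs & SNPs** — rank a gene's homologs by global-alignment
   identity and call the single-nucleotide differences against the most
   similar copy (`seq_homology`). A digital pre-screen selects candidate
   reference genes from an expression matrix (min ≥ 200 TPM, mean
   < 2000 TPM, CV < 0.35).
2. **Primer design** — enumerate primers whose 3′ terminal base sits on a
   discriminating SNP (extension then fails on the non-target copy), under
   length 20–23 nt, GC 45–55%, no >4-nt homopolymer, and assemble forward ×
   reverse pairs into 85–125 bp amplicons containing at least one more
   interior SNP (`primer_design`).
3. **Standard-curve optimization** — pick annealing temperature and primer
   concentration by lowest Ct, fit Ct against log₁₀ input over a serial
   dilution, and compute the amplification efficiency from the slope *A*:

       E(%) = (10^(−1/A) − 1) × 100

   An assay passes at R² ≥ 0.99 and E = 100 ± 5%; up to two points may be
   trimmed from either end of the dilution series to find the best passing
   consecutive subrange (`curve_optimization`).
4. **Quantification** — 2^−ΔΔCt relative expression with multi-reference
   geometric-mean normalization, and the efficiency-calibrated (Pfaffl)
   ratio using per-gene amplification bases (`quantification`).
5. **Stability** — rank candidate reference genes by CV%, Delta-Ct,
   BestKeeper, NormFinder, and geNorm M; aggregate the per-method ranks by
   geometric mean; decide how many reference genes suffice from the geNorm
   pairwise variation V (threshold 0.15) (`stability`).

A `synthetic_data` module generates Ct tables with planted stability
structure and gene families with planted SNPs, so the whole pipeline runs
without any external data.

## Worked example

```python
import qpcrkit as qk

# a 600-nt gene family with 6 planted SNPs
records, truth = qk.simulate_gene_family(qk.FamilySimSpec(length=600, n_snps=6, seed=11))
homologs = qk.rank_homologs(records[0], records[1:])
print(round(homologs.best()[1], 3))          # 0.99  (identity to nearest copy)

pairs = qk.design_assay(records[0], homologs)
for p in pairs:
    print(p.label, p.forward.seq, p.amplicon_len)
# F2/R1 ACGCCACAATCCGTCCGTGAAT 190
# F1/R1 TACGCCACAATCCGTCCGTGAAT 191
# F2/R2 ACGCCACAATCCGTCCGTGAAT 191
# F1/R2 TACGCCACAATCCGTCCGTGAAT 192

# a noise-free doubling dilution series fits to exactly 100% efficiency
series = qk.DilutionSeries()                 # 50 ng/ul, 1:10 ... 1:160
points = [(x, 27.0 + i) for i, x in enumerate(series.log_inputs)]
fit = qk.fit_standard_curve(points)
print(round(fit.A, 4), round(fit.efficiency_pct, 1), fit.passes)
# -3.3219 100.0 True
```

The identity is the fraction of matching alignment columns; each primer's
final base sits on a planted SNP, and the amplicon length is measured on
the plus strand including both primers (these four pairs use the relaxed
upper bound, since this family's SNP spacing admits no 85–125 bp
amplicon). A slope of −3.3219 cycles per log₁₀ input means the template
exactly doubles each cycle.

The same pipeline is available from a shell:

```bash
qpcrkit simulate family --spec family.yaml --out family.fasta --truth truth.csv
qpcrkit design --gene gene.fasta --homologs homologs.fasta --out pairs.csv
qpcrkit optimize --ct ct.csv --out fits.csv
qpcrkit stability --ct ct.csv --groups --out report.csv
qpcrkit quantify --ct ct.csv --target H33 --refs BI1,TCTPH --calibrator root --out folds.csv
```

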