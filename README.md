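# pedimmune

Immuno-transcriptomic analysis of bulk RNA-seq tumor cohorts, built for the
kind of study that profiles pediatric solid tumors (osteosarcoma, Ewing
sarcoma, neuroblastoma, ...) alongside a normal-tissue panel and asks four
questions of the same count matrices:

1. **How infiltrated is each tumor?** Single-sample GSEA (ssGSEA) scores
   every sample against immune cell-type signatures on TMM-normalized FPKM,
   summarized as the percentage of tumors per type with a positive
   enrichment score and as per-type median scores.
2. **Does infiltration predict survival?** An optimized Kaplan-Meier
   stratification scans every admissible cutoff of a continuous score,
   keeps the cutoff maximizing the two-group log-rank statistic, and
   corrects the cutoff-optimization bias with a permutation test.
3. **Are T cells clonally expanded, and are clonotypes shared?** TCR-beta
   CDR3 clonotype tables are normalized (counts per million, intra-sample
   fraction); a clone is called expanded iff its cpm strictly exceeds the
   pooled cohort 99th percentile **and** its intra-tumoral fraction
   strictly exceeds 1%; distinct CDR3s are partitioned into private,
   reference-shared, and multi-tumor-private (public) categories against
   healthy-donor databases.
4. **Which genes are tumor-specific antigen candidates?** A
   negative-binomial exact test compares each cancer type against the
   normal panel (testis and ovary excluded), and a candidate must satisfy
   all four criteria: p <= 1e-5, log2 fold change >= 4 (>= 16-fold),
   median FPKM < 1 in vital organs (heart, brain), and median FPKM >= 5
   in the tumor.

A checkpoint-vs-CD8 association module (Spearman rho > 0.3 and BH-adjusted
p < 0.05, both strict) and a synthetic-cohort generator with exported
ground truth complete the pipeline, so every stage is verifiable without
restricted patient data.

## The statistics, briefly

**ssGSEA.** For sample *j* and gene set *S* with |S| = m out of G genes,
genes are sorted by expression (descending, stable ties); with ranks
r = G..1 down the list and weight exponent α (default 0.75),

    ES = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i) = Σ_{g∈S, pos≤i} r_g^α / Σ_{g∈S} r_g^α,
    P_out(i) = #{g∉S, pos≤i} / (G − m).

**TMM.** Factor for sample *j* vs reference *r*: the precision-weighted
mean of per-gene log-ratios M_g = log2((x_gj/N_j)/(x_gr/N_r)) after
discarding the extreme 30% tails of M and 5% tails of abundance A, then
rescaled to geometric mean one. FPKM uses the TMM-effective library size:
fpkm = x·10^9/(L·N·f).

**Optimized KM.** Over admissible cutoffs c (both groups >= max(5,
ceil(0.10·n))), the log-rank χ² = U²/V is maximized;
permutation_p = (1 + #{b : max_c χ²_b ≥ max_c χ²_obs}) / (B+1) with the
score vector shuffled against fixed (time, event) pairs.

**NB exact test.** Counts are rescaled to a common library size; under
H0 the group sums are NB with a shared success parameter, so conditioning
on the total gives a closed-form split distribution; the two-sided p sums
the probabilities of all splits no more likely than the observed one.

## Worked example

```python
import pedimmune as pi

cfg = pi.SimulationConfig(seed=11)          # 3 tumor types x 20, 8-tissue normal panel
cm, truth = pi.simulate_expression(cfg)     # NB counts + latent immune factors
nm = pi.fpkm(cm, pi.tmm_factors(cm))        # TMM -> FPKM
sigs = pi.simulate.immune_signature_collection(truth, seed=11)
scores = pi.ssgsea_scores(nm, sigs)
print(pi.positive_fraction(scores, cm.sample_groups).loc[["OS", "EWS", "NBL", "heart"]].round(1))

surv = pi.simulate_survival(truth.immune_factors, cfg)
mean_score = scores.to_frame().loc[list(truth.immune_factors)].mean(axis=1)
res = pi.kmopt(mean_score, surv, pi.KmcutConfig(n_permutations=1000, seed=11))
print(f"kmopt: cutoff={res.cutoff:.1f} chi2={res.chi_square:.2f} "
      f"nominal_p={res.nominal_p:.2e} permutation_p={res.permutation_p:.4f} "
      f"({res.n_cutoffs_scanned} cutoffs scanned)")
```

prints

```
       immune_sig_1  immune_sig_2  immune_sig_3  immune_sig_4
OS             65.0          95.0          80.0          85.0
EWS            65.0         100.0          80.0          85.0
NBL            75.0          90.0          75.0          85.0
heart         100.0         100.0         100.0         100.0

kmopt: cutoff=353.8 chi2=24.00 nominal_p=9.64e-07 permutation_p=0.0020 (49 cutoffs scanned)
```

Most samples — including normals — score positive on immune signatures
(the signatures' genes are expressed everywhere; the *latent infiltration
factor* drives the variation among tumors), and the optimized KM split of
the simulated cohort finds the planted protective effect of infiltration:
the nominal p at the optimum (1e-6) is optimistic, while the permutation
p (0.002) is the honest, scan-corrected significance.

The same stages are available as a CLI:

```bash
pedimmune simulate --out cohort/ --seed 11
pedimmune normalize --counts cohort/counts.tsv --annotation cohort/ann.tsv --out cohort/fpkm.tsv
pedimmune score --expr cohort/fpkm.tsv --gmt cohort/signatures.gmt --out cohort/scores.tsv
pedimmune kmcut --scores cohort/scores.tsv --survival cohort/surv.tsv --permutations 1000 --seed 3 --out cohort/kmcut.tsv
pedimmune tcr --clones cohort/clones --meta cohort/tcr_meta.tsv --refs cohort/healthy_db.txt --out cohort/tcr
pedimmune antigens --counts cohort/counts.tsv --annotation cohort/ann.tsv \
    --gmt cohort/categories.gmt --cancer-type OS \
    --normal-labels heart,brain,testis,ovary,lung,liver,kidney,muscle --out cohort/antigens.tsv
```

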