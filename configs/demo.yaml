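# Bundled end-to-end demonstration run on a synthetic admixed cohort.
# All values are the package defaults, written out for visibility.
seed: 1
out_dir: stratgen_demo

# synthetic cohort scale
n_genes: 150
n_variants: 3000
F: 0.1
n_per_pop: 500
n_admixed: 500
base_n: 5000
nuclei_mean: 40.0
h2: 0.25

# planted architecture
n_eqtl_genes: 10
sexde_n: 25
n_pheno_variants: 25
pheno_beta_sd: 0.2
n_coloc_genes: 3

# analysis thresholds
cis_window: 500000
maf_threshold: 0.10
eqtl_fdr: 0.10
gwas_p: 5.0e-8
pph4_threshold: 0.5
de_fdr: 0.10
n_perm: 1000
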