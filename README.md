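# otuherit

Twin-heritability benchmarking of OTU clustering methods for 16S rRNA gene
microbiome studies.

## The problem

Reads from a 16S amplicon experiment must be collapsed into operational
taxonomic units (OTUs) before analysis, and many clustering strategies exist
(closed/open reference, de novo greedy algorithms, de-replication,
entropy-based methods). They produce different tables from the same reads,
and there is no ground truth for which units best represent the biological
taxa interacting with the host. When the samples come from a twin cohort,
heritability offers a biological yardstick: units that better capture real
host-interacting taxa should show more of their abundance variance explained
by host genetics. `otuherit` implements that benchmark end to end, for
anyone comparing OTU tables built from the same twin-study samples.

## The model

For each OTU, counts are preprocessed the way twin-microbiome heritability
analyses do it: a pseudo-count of 1, conversion to within-sample relative
abundances, restriction to OTUs present (count > 0, before pseudo-counts) in
at least 50% of samples, a Box–Cox power transform with the exponent λ chosen
to maximize the profile log-likelihood of the linear model

    y(λ) ~ gender + age + sequencing run + sequencing depth
           + collection method + technician,       y(λ) = (y^λ − 1)/λ

and finally the standardized OLS residuals of the transformed abundance.

Each residual trait is fitted with the classical twin ACE variance
decomposition by maximum likelihood. Twins in a pair are bivariate normal
with common mean μ, per-twin variance a² + c² + e², and within-pair
covariance a² + c² for monozygotic (MZ) pairs and ½a² + c² for dizygotic
(DZ) pairs — shared environment (C) is assumed equal across zygosities, and
DZ twins share half their segregating genetic material. Standardized
proportions A = a²/(a²+c²+e²), C, E are reported; A is the narrow-sense
heritability. 95% confidence intervals come from the profile likelihood
(χ²₁ cutoff 3.841).

On top of the per-OTU estimates the package provides: pairwise Mann–Whitney
U comparisons of A/C/E distributions between methods with Benjamini–Hochberg
FDR correction; a "heritable unit" filter (A above the pooled mean and CI
lower bound ≥ 1%); taxonomic collapse from genus to phylum with a
taxon + method linear model for heritability; rarefaction alpha diversity
(Shannon, Simpson, Chao1, observed OTUs; 10,000 reads × 25 rarefactions) with
cross-method Kendall τ-b rank concordance; and a synthetic twin-microbiome
generator with known per-OTU A/C/E structure plus split/merge perturbations
that emulate alternative clusterings of the same reads.

## Worked example

Simulate a small twin dataset, derive a noisy "alternative clustering" of
the same reads, and benchmark the two tables:

```sh
otuherit simulate --n-mz 60 --n-dz 50 --n-otus 12 --library-size 20000 \
    --seed 4 --out-dir demo
python - <<'PY'
from otuherit import read_otu_table, perturb_clustering, write_otu_table
t = read_otu_table("demo/table.tsv", method_label="vsearch_97")
write_otu_table(perturb_clustering(t, "split", k=2, noise=0.5, seed=9),
                "demo/table_split.tsv")
PY
cat > demo/config.yaml <<'YAML'
tables:
  vsearch_97: demo/table.tsv
  dereplicated: demo/table_split.tsv
metadata: demo/metadata.tsv
rarefaction_depth: 10000
rarefaction_reps: 25
seed: 4
output_dir: demo_out
YAML
otuherit benchmark --config demo/config.yaml
```

which prints

```
vsearch_97	mean A = 0.1588
dereplicated	mean A = 0.0860
manifest: demo_out/manifest.json
```

The intact table produces more heritable units (mean Â = 0.16) than the
variant whose reads were noisily reassigned between units (0.09) — the
benchmark's core contrast. `demo_out/` holds per-OTU heritability TSVs with
profile CIs, the pairwise Mann–Whitney comparison tables with q-values
(`compare_A.tsv` etc.), per-sample rarefied diversity, Kendall τ
concordance matrices, and a manifest recording the seed, config hash and
every file written. At this demonstration size (110 pairs) individual CIs
are wide and the two-method contrast is not significant (q = 0.14); the
study-scale analyses below use 875 pairs.

The same stages are available as library functions (`prepare_traits`,
`fit_ace`, `profile_ci`, `compare_profiles`, `alpha_diversity`, ...) and as
per-stage subcommands (`otuherit preprocess|heritability|compare|collapse|
diversity|concordance`).

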