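# circenet

Inference and prioritization of circRNA miRNA-sponge activity from a
competing-endogenous-RNA (ceRNA) network.

## The problem

Circular RNAs are stable, brain-enriched non-coding RNAs that can act as
miRNA sponges: by soaking up shared miRNAs they de-repress the miRNAs'
mRNA targets. To find disease-relevant sponge circRNAs from public
expression data, one needs a chain of analyses:

1. **Differential expression.** Per dataset (e.g. per brain region), a
   moderated two-group t-statistic shrinks each feature's pooled variance
   s²_g toward an empirical-Bayes prior (d₀, s₀²):

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g = (x̄₁ − x̄₂) / √(s̃²_g (1/n₁ + 1/n₂)) ~ t(d₀ + d_g),

   with (d₀, s₀²) fit by method of moments on log s²_g. Evidence is
   combined across datasets by a signed-z Stouffer rule,
   z_meta = Σ wᵢ zᵢ / √(Σ wᵢ²) with wᵢ = √nᵢ, followed by
   Benjamini–Hochberg adjustment. Consistent DE genes (CDEGs, FDR < 0.01)
   and DE miRNAs (DEmiRs, FDR < 0.05) result.
2. **ceRNA network construction.** From miRNA→circRNA and miRNA→mRNA
   interaction tables, every circRNA–mRNA pair sharing ≥ 5 miRNAs is a
   candidate competing pair; each (circRNA, miRNA, mRNA) combination with
   the miRNA in the shared set is one unit of miRNA-mediated ceRNA
   crosstalk. Only interactions participating in ≥ 1 crosstalk are kept,
   yielding a tripartite competitive network.
3. **Disease subnetwork and risk ranking.** Crosstalks containing a CDEG
   or a DEmiR form the disease subnetwork; crosstalks additionally
   containing a curated known disease gene or miRNA are *risk*
   crosstalks. circRNAs are ranked by risk-crosstalk frequency.
4. **Topology and function.** The degree distribution is checked for the
   scale-free property (power-law MLE exponent, log-log R²), and the
   risk-crosstalk mRNAs are tested for gene-set over-representation
   (hypergeometric upper tail, BH FDR < 0.05).

A seeded synthetic-data generator produces every input with the
statistical structure the methods assume — scaled-inverse-chi-square
variance heterogeneity, shared DE membership across datasets, planted
crosstalk triples, a planted top-risk circRNA and a planted enriched gene
set — so the whole chain is testable end to end against known truth.

## Worked example

The numbered scripts under `analysis/` run the study step by step into
`results/run/` (equivalently: `circenet run-all --seed 1 --out-dir results/run`):

```
$ python analysis/01_simulate_inputs.py --seed 1
simulated study written to results/run/inputs
  datasets: 6 gene + 1 miRNA
  planted DE features: 150
  planted crosstalk triples: 288
  planted risk circRNA: circ_0001

$ python analysis/02_differential_expression.py
CDEGs at FDR<0.01: 150
DEmiRs at FDR<0.05: 20

$ python analysis/03_build_cerna_network.py
competitive network (min shared miRNAs = 5):
  n_circ: 12
  n_mirna: 152
  n_mrna: 48
  n_edges: 572
  n_triples: 297

$ python analysis/04_disease_risk_ranking.py
disease subnetwork: 212 nodes, 572 edges, 297 triples
risk crosstalks: 98
top 5 circRNAs by risk-crosstalk count:
           risk_triple_count  rank  total_triple_count  coverage
circ_id
circ_0001                 24     1                  24  1.000000
circ_0045                  9     2                  25  0.360000
...
planted risk circRNA circ_0001 recovered at rank 1

$ python analysis/05_network_topology.py
power-law exponent alpha (MLE, xmin=1.0): 1.690
log-log regression slope -1.215, R^2 0.448 over 212 nodes

$ python analysis/06_enrichment.py
terms enriched at FDR<0.05: ['T051']
...
manifest written; top circRNA: circ_0001
```

Reading the output: all 150 planted DE genes are recovered as CDEGs; the
network stage keeps exactly the circRNA–mRNA pairs that share ≥ 5 miRNAs;
the planted risk circRNA `circ_0001` tops the risk ranking with full
known-list coverage (24/24 of its crosstalks are risk crosstalks); and
the planted gene set `T051` is the only term called enriched.

The same machinery is available as a library
(`circenet.pipeline.analyze_study`) and as a CLI with one subcommand per
stage (`circenet simulate / de / build-net / extract / prioritize /
stats / enrich / run-all`).

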