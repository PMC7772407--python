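# lncrules

Interpretable classification of entities described by gene sets (e.g.
lncRNAs via their co-expressed genes) under strong class imbalance:

1. **Enrichment encoding** — each entity becomes a vector of
   −log10 hypergeometric upper-tail probabilities against every annotation
   term (GO-like and KEGG-like named gene sets), computed in log space so
   genome-scale universes neither overflow nor underflow.
2. **mRMR ranking** — features are discretized at mean ± 1 sd into three
   codes and greedily ranked by mutual information with the label minus
   mean redundancy to the already-selected features (MID criterion), on the
   original imbalanced data.
3. **SMOTE** — the minority class is grown to parity by interpolating
   between minority samples and their k = 5 nearest minority neighbors
   (used only while evaluating/fitting classifiers, never for ranking).
4. **IFS with CART** — nested prefixes of the ranked list are evaluated by
   pooled stratified 10-fold cross-validation of a Gini decision tree; the
   subset with maximal MCC is the optimum, and the smallest subset within
   `tradeoff_delta` of it is the trade-off choice.
5. **Decision rules** — the final tree (refit on all samples) is exported
   as root-to-leaf IF/THEN rules that partition the feature space, split
   into "identifying" (positive) and "excluding" (negative) groups.

A synthetic-data module generates annotation databases, co-expressed gene
sets and labels with a *planted* signal (a few discriminative terms whose
genes positives preferentially sample), so the whole pipeline is testable
offline at configurable imbalance up to ~1:260.

## CLI

All stages are exposed through one entry point:

```sh
# generate a synthetic fixture (GMT + pairs TSV + labels TSV)
lncrules simulate --seed 1 --outdir fixture/

# encode entities as enrichment-score vectors
lncrules encode --gmt fixture/annotations.gmt --pairs fixture/coexpression.tsv \
    --labels fixture/labels.tsv --universe infer --out features.tsv

# mRMR-rank the features
lncrules rank --features features.tsv --labels fixture/labels.tsv --out ranked.tsv

# incremental feature selection (writes the IFS curve TSV)
lncrules ifs --features features.tsv --labels fixture/labels.tsv \
    --ranked ranked.tsv --step 10 --smote train_only --out curve.tsv

# final decision rules from the top-k features
lncrules rules --features features.tsv --labels fixture/labels.tsv \
    --ranked ranked.tsv --top-k 20 --smote on --out rules_out/

# or everything at once (ranked list, IFS curve + plot, metrics, rules, manifest)
lncrules run --gmt fixture/annotations.gmt --pairs fixture/coexpression.tsv \
    --labels fixture/labels.tsv --outdir run_out/
```

`simulate --config cfg.yaml` accepts YAML overrides for any
`SyntheticConfig` field (`n_positive`, `n_negative`, `signal_fraction`,
`term_size_range`, ...).

## Library

```python
from lncrules.synthetic_data import SyntheticConfig, generate_dataset
from lncrules.enrichment import GeneUniverse, encode_profiles
from lncrules.feature_ranking import mrmr_rank
from lncrules.ifs_pipeline import run_ifs, select_tradeoff, train_final_rule_model

db, truth, profiles, labels = generate_dataset(SyntheticConfig(seed=1))
universe = GeneUniverse.from_iterable(
    set().union(*(p.gene_set for p in profiles)) | set(db.all_genes())
)
matrix = encode_profiles(universe, db, profiles, labels=labels)
ranked = mrmr_rank(matrix)
curve = run_ifs(matrix, ranked, step=10)
model, rules, report = train_final_rule_model(
    matrix, ranked, select_tradeoff(curve)
)
print(report)
```

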