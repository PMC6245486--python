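# phipred

Predict whether a phage–bacterium pair interacts, from genomic information
alone. The pipeline builds a labelled pair corpus, extracts two kinds of
fixed-length features from the cross-proteome protein–protein interaction
(PPI) grid, and trains grid-searched, cross-validated classifiers.

## Pipeline

1. **Corpus** (`phipred.corpus`) — positive pairs are balanced across
   bacterial families by replication (each family is replicated
   `round(target / n)` times toward a ~300-record target; families holding
   the dominant host species are exempt). Putative negatives are pairs that
   are absent from the positives and species-mismatched with the phage's
   known host, drawn per species to match positive counts. A stratified
   train/test split keeps all replicates of a pair in the same split.
2. **DDI features** (`phipred.features_ddi`) — each PPI is scored as the
   sum of domain–domain interaction (DDI) table scores over its domain
   pairs; the variable-length per-pair score vector is reduced to a
   fixed-length histogram. 18 histogram variants (fixed bin count
   5/10/15/30/50 or fixed bin size, normalized or absolute frequencies)
   plus the chemical dataset form the standard 19-config grid.
3. **Chemical features** (`phipred.features_chem`) — 27 features per
   protein (21 amino-acid frequencies including an unknown bucket, C/H/N/O/S
   atom fractions, molecular weight), 54 per PPI, and 108 per pair via the
   mean and population standard deviation across the PPI grid.
4. **Modeling** (`phipred.modeling`) — k-NN, random forests, RBF-SVMs and
   single-hidden-layer neural networks, grid-searched with 10-fold
   stratified cross-validation (per-fold standardization on training-fold
   statistics only); an exploration phase over all datasets, a refinement
   phase extending the network's hidden-layer sweep, and a final held-out
   evaluation where the 10 fold-models predict the test set. An optional
   group-aware folding mode keeps replicates inside one fold, avoiding the
   inflated scores memorizing methods otherwise obtain on oversampled data.
5. **Synthetic data** (`phipred.synthetic_data`) — generates proteomes,
   domain annotations, a DDI table and a skewed family structure with a
   tunable planted receptor/RBP signal, so the whole pipeline is testable
   end to end without any downloads.

## CLI

```sh
# generate a synthetic input bundle
phipred synth generate --seed 1 --out bundle/

# build the oversampled, balanced, split corpus
phipred corpus build --pairs bundle/pairs.tsv --target 300 \
    --test-fraction 0.1 --seed 1 --out corpus/

# featurize (DDI histogram and chemical variants)
phipred features ddi --corpus corpus/ --proteomes bundle/proteomes \
    --domains bundle/domain_hits.tsv --ddi bundle/ddi.tsv \
    --config NBN50 --out nbn50
phipred features chem --corpus corpus/ --proteomes bundle/proteomes --out ch

# model: exploration, refinement, held-out evaluation
phipred model explore --train nbn50_train.csv,ch_train.csv --seed 1 --out reports/
phipred model refine  --train nbn50_train.csv,ch_train.csv --seed 1 --out refine/
phipred model test --train ch_train.csv --test ch_test.csv \
    --method ann --params n_neurons=9,epochs=50,momentum=0.1 --out final/
```

Domain hits are accepted either as a 2-column TSV
(`protein_id`, `domain_accession`) or as HMMER per-domain tabular output
(`--dialect hmmer_domtbl`). A recipe for producing the latter:
`hmmscan --domtblout hits.domtbl Pfam-A.hmm proteins.fasta`.

## Notes on interpretation

* The SVM grid's second hyperparameter (spanning 1e-4..1e4) is read as the
  RBF kernel width (gamma); the network uses one hidden layer of logistic
  units trained by SGD with momentum at learning rate 1e-4; the forest's
  "L-size" is the minimum leaf size.
* Fixed-bin-count histograms span each pair's own [0, max score] range;
  fixed-bin-size histograms use a global upper bound (by default the
  training split's maximum PPI score, recorded in the dataset manifest)
  plus an overflow bin.
* Domain multiplicity counts in PPI scores by default
  (`--unique-domains` disables it); zero scores are included in histograms
  by default.
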