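# phageprom

Two-layer convolutional classification of promoters in bacteriophage
genomic sequence.

Annotating a newly sequenced phage genome requires locating its promoters —
short, poorly conserved regulatory elements that come in two flavours:
promoters read by the *host* bacterial RNA polymerase (sigma70-style −35/−10
boxes) and promoters read by a *phage*-encoded RNA polymerase (longer,
well-conserved elements such as the T7 class). `phageprom` addresses both
questions with a cascade of two binary 1-D CNNs over fixed 99-bp inputs:

1. **layer 1** — is the query a promoter at all? (gate at p ≥ 0.5)
2. **layer 2** — for predicted promoters only: phage or host?

Each layer is a small convolutional network over a zero-padded 99×4 one-hot
encoding: two [Conv1D(16, kernel 5, ReLU) → MaxPool(4, stride 2) →
Dropout 0.5] blocks, Flatten, Dense(64, ReLU), Dropout 0.5, Dense(1,
sigmoid), with L2 = 10⁻⁴ kernel and bias penalties, trained with Adam on
binary cross-entropy at batch size 20 for 85 epochs.

Two ingredients matter beyond the network. First, **hard negatives**:
non-promoters are built from the promoters themselves by cutting each
positive into 8 blocks and re-placing 5 of them at random (no selected block
stays put) while 3 keep their exact positions — every negative conserves
35–40% of its source promoter, so the classes cannot be separated by
composition alone. Second, a **feature-encoding/model selection grid**: ten
DNA encodings (one-hot, NCP, kmer, PseEIIP, PseDNC, PseKNC, PCPseDNC,
PCPseTNC, DACC, Moran autocorrelation) crossed with ten classical ML
baselines plus the CNN under stratified 5-fold cross-validation
(Acc / Sn / Sp / MCC, ROC/AUROC).

The package is aimed at bioinformaticians working on phage genome annotation
and at anyone who needs a clean, fully seeded reference implementation of
pseudo-nucleotide-composition descriptors and block-shuffle hard negatives.
A synthetic benchmark generator emulating a phiSITE-style promoter set makes
every stage testable offline; see `docs/methods.md` for the model,
parameters and limitations.

## Worked example

```python
import phageprom as pp

recipe = pp.SyntheticRecipe(seed=7)          # defaults: 500/class, 99 bp
layer1 = pp.generate_layer1_set(recipe)      # 500 promoters + 500 hard negatives
layer2 = pp.generate_layer2_set(recipe)      # 500 phage + 500 host promoters
cascade = pp.train_cascade(layer1, layer2, pp.CNNConfig(seed=7))

queries = pp.generate_threeway_set(pp.SyntheticRecipe(n_per_class=10, seed=99),
                                   n_each=2)
for res in pp.predict_cascade(cascade, queries):
    p2 = "-" if res.p_phage is None else f"{res.p_phage:.3f}"
    print(f"{res.id:16s} p_promoter={res.p_promoter:.3f} "
          f"p_phage={p2:5s} call={res.call}")
```

prints (about two minutes on one CPU):

```
ev_phage_00000   p_promoter=0.936 p_phage=1.000 call=phage_promoter
ev_host_00000    p_promoter=0.983 p_phage=0.000 call=host_promoter
ev_phage_00001   p_promoter=0.944 p_phage=1.000 call=phage_promoter
ev_host_00001    p_promoter=0.979 p_phage=0.000 call=host_promoter
ev_src_00000_neg p_promoter=0.230 p_phage=-     call=non_promoter
ev_src_00001_neg p_promoter=0.031 p_phage=-     call=non_promoter
```

Reading the output: `p_promoter` is the layer-1 probability; sequences below
the 0.5 gate are called non-promoters and never reach layer 2 (`p_phage`
absent). For gated sequences `p_phage` is the probability of the *phage*
class (host = 1 − p_phage). Here all four true promoters pass the gate and
are typed correctly, while the two block-shuffled hard negatives — which
still share ≥ 3 of 8 blocks with real promoters — are rejected at layer 1.

The same pipeline is scriptable from the shell:

```sh
phageprom synth --layer 1 --n 500 --seed 7 --out l1.fasta --labels l1.tsv
phageprom train --layer 1 --in l1.fasta --labels l1.tsv --out l1.ppm --seed 7
phageprom crossval --in l1.fasta --labels l1.tsv --out cv.json --seed 7
phageprom make-negatives --in pos.fasta --out neg.fasta --seed 7 --report frac.tsv
phageprom benchmark --in l1.fasta --labels l1.tsv \
    --encodings onehot,kmer,psednc --models logistic_regression,svm,cnn \
    --folds 5 --seed 7 --out grid.csv
```

Exit codes: 0 success, 1 usage error, 2 data error. Every artifact embeds
the effective configuration and seed.

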