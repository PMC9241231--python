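# deeppn

RNA-binding proteins (RBPs) recognise short sequence elements in their
target transcripts, and CLIP-seq experiments map those binding sites
genome-wide at considerable cost.  `deeppn` is a sequence-only classifier
for this problem: given a fixed 101-nt RNA window it predicts whether the
window contains an RBP binding site, using nothing but the one-hot encoded
sequence.

The model is a **parallel two-branch network**.  A convolutional branch
scans the sequence with learned sliding-window filters (two layers, 16 and
32 filters, LeakyReLU, no pooling), the way classic motif scanners do.  A
spectral graph-convolution branch (ChebNet) treats the window as a path
graph over its positions and filters node features with Chebyshev
polynomials of the rescaled normalized Laplacian:

    L  = I − D^(−1/2) A D^(−1/2),       L̃ = 2L/λ_max − I
    g_θ(L̃) x = Σ_{k=0}^{K−1} θ_k T_k(L̃) x,   T_k = 2 L̃ T_{k−1} − T_{k−2}

with T₀ = I and T₁ = L̃, so no eigendecomposition is ever needed.  The two
flattened branch outputs are fused by concatenation,

    H = concat( g_ChebNet(X), g_CNN(X) ),

and three fully connected layers (dropout on the first two, a single
logistic unit) turn H into a binding probability.  Training minimises the
binary cross-entropy ζ = −Σᵢ yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ) with mini-batch
Adam (batch 16, learning rate 10⁻³), an 8:2 train/test split, and early
stopping with patience 2 on a held-out monitoring split.  Ablation modes
(`chebnet_only`, `cnn_only`) drop one branch while keeping everything else
identical.

Because real CLIP datasets are large downloads, the package ships a
**planted-motif simulator** that emulates their structure with known
ground truth: positives are background sequence with one PWM-sampled motif
instance at a random offset, negatives are dinucleotide (Euler-path)
shuffles that preserve local composition, so the only learnable signal is
the motif itself.  The whole network — both branches, backpropagation,
Adam, dropout, early stopping — is implemented directly in numpy, and the
analytic gradients are verified against finite differences in the test
suite.

## Worked example

```python
from deeppn import DeepPNClassifier, ModelConfig, TrainConfig, split_dataset
from deeppn.synthetic import default_bench_config, generate_dataset

data, truth = generate_dataset(default_bench_config(seed=1))   # 1000+1000 sequences
train_data, test_data = split_dataset(data, ratio=0.8, seed=1) # 1600 / 400
clf = DeepPNClassifier(ModelConfig(), TrainConfig(seed=1))
history = clf.fit(train_data)
report = clf.evaluate(test_data)
print(f"stopped after epoch {history.stopped_epoch} (best epoch {history.best_epoch})")
print(f"test AUC {report.auc:.4f}, accuracy {report.accuracy:.4f}")
```

prints

```
stopped after epoch 23 (best epoch 21)
test AUC 0.8654, accuracy 0.7925
```

i.e. on the benchmark the trained model ranks a random true binding window
above a random shuffled control about 87% of the time, from sequence
alone.  The monitored accuracy, per-epoch training loss and the restored
best epoch are all in `history`.

The same pipeline is available from the shell:

```bash
deeppn simulate --out-prefix bench --seed 1
deeppn train    --pos bench.positives.fa --neg bench.negatives.fa --out-dir run --seed 1
deeppn evaluate --pos bench.positives.fa --neg bench.negatives.fa \
                --checkpoint run/checkpoint.npz --out report.json
deeppn predict  --fasta bench.positives.fa --checkpoint run/checkpoint.npz --out preds.tsv
```

Every run writes its resolved configuration and seed to `run.log`, and
repeated runs with the same seed are bit-identical.

## Repository layout

- `src/deeppn/seq_encoding.py` — sequences, one-hot / k-gram / k-mer encodings, FASTA IO
- `src/deeppn/seq_graph.py` — position graph, rescaled Laplacian, Chebyshev basis
- `src/deeppn/chebnet_branch.py` — spectral branch (embedding + two Chebyshev layers)
- `src/deeppn/cnn_branch.py` — convolutional branch (two sliding-window layers)
- `src/deeppn/model.py` — fusion, dense head, loss, Adam, early stopping, evaluation
- `src/deeppn/synthetic.py` — planted-motif benchmark generator
- `src/deeppn/cli.py` — configuration and command-line pipeline
- `docs/methods.md` — the model, its assumptions and design choices in detail
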