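# sparseppi

Sequence-based prediction of protein–protein interactions (PPIs), combining a
**global encoding** (GE) descriptor of amino-acid sequences with a **weighted
sparse representation classifier** (WSRC).

Most proteins act in pairs, but experimental interaction screens are slow,
expensive and noisy, and structure- or domain-based predictors fail when those
annotations are missing. `sparseppi` is for computational biologists who want a
PPI predictor that needs nothing but the two primary sequences: it turns each
protein into a fixed-length physicochemical descriptor and classifies a
candidate pair by how well it can be reconstructed from known interacting
versus non-interacting pairs.

## The method

**Global encoding.** The 20 amino acids are reduced to six physicochemical
classes — aliphatic C1 = {A,V,L,I,M,C}, aromatic C2 = {F,W,Y}, polar
C3 = {S,T,N,Q}, positive C4 = {K,R,H}, negative C5 = {D,E}, special
conformations C6 = {G,P}. Splitting the six classes 3-vs-3 (keeping C1 on the
positive side) gives ten *transformation modes*; each mode maps a protein
sequence P = p₁…pₙ to a binary *characteristic sequence* Sᵢ, with bit j = 1
iff class(pⱼ) is in the mode's positive triple. Each Sᵢ is cut into L nested
prefixes, SubSₖ = first ⌊k·n/L⌋ bits, and each prefix is summarized by three
numbers: the **composition** pair (f₀, f₁) — the fractions of 0s and 1s — and
the **transition** count — the number of adjacent bit switches. A protein is
therefore a 10·L·3 vector (150 at the default L = 5) and a protein pair is the
300-entry concatenation. A 400-dimensional 2-mer (dimer-frequency) baseline
encoder is included for comparison.

**WSRC.** Training pairs form the columns of a dictionary X with labels
1 (interacting) / 0 (non-interacting). A test vector y is reconstructed by the
weighted stable ℓ1 program

    min ‖W α‖₁   subject to   ‖y − X α‖₂ ≤ ε,

where W is diagonal with Gaussian locality weights built from
d_G(y, xᵢ) = exp(−‖y − xᵢ‖²/2σ²), σ = 1.5, ε = 5·10⁻⁵ by default. The pair is
assigned to the class c minimizing the residual r_c = ‖y − X δ_c(α)‖, where
δ_c keeps only class-c coefficients; the margin r₀ − r₁ serves as a continuous
score for ROC analysis. See `docs/methods.md` for the solver and the exact
weighting convention used for prediction.

Evaluation utilities provide accuracy, sensitivity, precision, Matthews
correlation, rank-statistic AUC, stratified k-fold cross-validation, an
L-sweep experiment, and a train-on-one-dataset / test-on-another protocol.
A synthetic-data module generates labelled pair datasets with a planted,
GE-detectable composition signal, so the full pipeline is testable without
any database download.

## Worked example

Simulate a benchmark with a moderate planted signal and cross-validate the
full pipeline:

```sh
sparseppi simulate --out demo --signal-strength 0.4 --seed 7
sparseppi crossval --fasta demo/proteins.fasta --pairs demo/pairs.tsv \
    --out demo/cv -k 5 --seed 42
```

```
wrote 400 proteins to demo/proteins.fasta
wrote 200 pairs to demo/pairs.tsv
fold     accuracy  sensitivity    precision          mcc          auc
   1       0.9500       0.9000       1.0000       0.9045       0.9975
   2       0.9000       0.8500       0.9444       0.8040       0.9625
   3       0.8500       0.8000       0.8889       0.7035       0.9625
   4       0.9000       0.9000       0.9000       0.8000       0.9875
   5       0.9250       0.9000       0.9474       0.8511       0.9800
 avg 0.9050±0.0332 0.8700±0.0400 0.9361±0.0395 0.8126±0.0664 0.9780±0.0138
```

Each fold row reports the held-out metrics of one of the five splits; the
last row is their mean ± standard deviation. At signal strength 0.4 the
interaction-prone proteins are tilted toward aliphatic/basic residues and the
classifier recovers the planted labels at ~90 % accuracy with AUC ≈ 0.98;
at `--signal-strength 0` accuracy sits at chance, and at 0.5 it approaches 1.
The same objects are available from Python:

```python
from sparseppi import GlobalEncoder, WSRC, generate_pair_dataset, GeneratorConfig

proteins, pairs = generate_pair_dataset(GeneratorConfig(signal_strength=0.4, seed=7))
X, y = GlobalEncoder(L=5).encode_pairs(pairs, proteins)
model = WSRC(sigma=1.5, epsilon=5e-5).fit(X[:160], y[:160])
print(model.predict(X[160:]))
```

Encoding one 100-residue protein gives a 150-vector whose first triple, e.g.
`[0.35, 0.65, 8.0]`, is (f₀, f₁, transition) of the first prefix under the
first mode.

Other subcommands: `encode` (write feature matrices), `train`/`predict`
(persisted models), `lsweep` (repeat CV across L ∈ {4,5,6,8,12,16};
dimensions 120…480), and `cross-species` (train once, evaluate independent
test sets).

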