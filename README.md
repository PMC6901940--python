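# bcpflow

Analysis toolkit for human **B-cell precursor (BCP) maturation** in bone
marrow, combining 10-colour flow-cytometry gating with IGH repertoire
analysis of sorted pre-B subsets. It is aimed at immunologists studying
normal B-cell development and its blockades in primary immunodeficiencies
(e.g. RAG or BTK deficiency).

The package covers four linked analyses plus a fully synthetic data
generator with ground truth, so every step is testable without patient
material:

1. **Stage gating.** Events (CD20, smIgM, CD38, TdT, cyCD79a, IgD, cyIgM,
   CD19, CD34, CD10) are arcsinh-transformed (`arcsinh(x/150)`) and gated by
   the BCR-associated marker hierarchy: cyCD79a⁻ → non-B; cyCD79a⁺ CD19⁻
   TdT⁺ → pro-B; CD19⁺ smIgM⁻ cells split on cytoplasmic Igμ into pre-BI
   (cyIgμ⁻) and pre-BII (cyIgμ⁺); smIgM⁺ cells are immature (IgD⁻) or mature
   (IgD⁺). Within pre-BI/pre-BII, CD34/TdT define the +/+ ("pp"), −/−
   ("nn") and intermediate subsets. Composition is reported over the
   precursor compartment (mature B cells excluded, since they may derive
   from peripheral blood).

2. **Pooled-control PCA reference ("APS" view).** Gated BCP events from ≥2
   healthy controls are pooled, standardized, and reduced to PC1–PC2. Each
   reference population receives a Gaussian **2SD contour**: the ellipse at
   Mahalanobis distance k = 2,

       (x − μ_p)ᵀ Σ_p⁻¹ (x − μ_p) ≤ k²,

   in PC space. Test samples are projected with the *model's*
   standardization, and the fraction of BCP events outside **both** the
   pre-BI and pre-BII contours quantifies asynchronous/transitioning cells.
   Composition outside the controls' min–max intervals plus the 2%-rules
   (pre-BII + immature < 2% → `complete_block_preBI`; pre-BII ≥ 2% but
   immature < 2% → `partial_block_preBII`) yield a maturation blockade call.

3. **IGH repertoire productivity.** Rearranged sequences are assigned the
   best germline V and J by ungapped semi-global alignment (match +1,
   mismatch −1) against a built-in mini germline database; the conserved
   V 2nd-CYS and J-TRP codons are mapped through the alignment. The CDR3 is
   the substring strictly between the anchors; a rearrangement is
   **in-frame** when the J-TRP codon start is ≡ 0 (mod 3) from V codon 1 and
   **productive** when additionally stop-free through the anchor. Reads
   collapse to clones on (V gene, J gene, CDR3 nucleotides); statistics
   (in-frame fraction, in-frame:unproductive ratio, CDR3 length, counts of
   positive residues R/K/H) are computed per clone, never per read.

4. **Synthetic data.** `simulate_bm_sample` draws donors as bounded latent
   "cell-state" continua per stage (pseudotime × size factors on a disk,
   CD34/TdT descending through S-ramps, 2% transitioning cells between the
   pre-BI and pre-BII centroids, bounded multiplicative donor gain);
   `simulate_compartment_repertoire` assembles V(D)J junctions
   (trimmed V + N1 + trimmed D + N2 + trimmed J) with class-conditional
   rejection sampling so each sorted compartment hits its configured
   in-frame clone fraction: pre-BI+/+ 0.10, pre-BI−/− 0.75, pre-BII−/− 0.80,
   pre-BII+/+ 0.75.

## Worked example

```python
from bcpflow import (simulate_bm_sample, gate_sample, build_reference,
                     deviation_report, outside_fraction)

controls = []
for i in range(5):
    events, _ = simulate_bm_sample("healthy", 50_000, donor_id=f"ctrl{i}", seed=100 + i)
    controls.append(gate_sample(events))
model = build_reference(controls, k=2.0)

events, _ = simulate_bm_sample("healthy", 50_000, donor_id="sixth", seed=999)
transformed, gates = gate_sample(events)
report = deviation_report(transformed, gates, model, sample_id="sixth")
print(f"outside both pre-B 2SD contours: {100 * report.outside_preB_fraction:.2f}% of BCP")
print("blockade call:", report.blockade)
```

prints

```
outside both pre-B 2SD contours: 2.16% of BCP
blockade call: none
```

— a healthy donor leaves only a small percentage of BCP events (the
asynchronously transitioning cells) outside the pre-BI/pre-BII contours and
triggers no blockade. Running the same comparison on a simulated
RAG-deficient marrow yields `complete_block_preBI` (no cyIgμ⁺ stages at
all), and a BTK-deficient marrow yields `partial_block_preBII` (a small
pre-BII fraction, no immature output).

The same pipeline is available from the shell:

```bash
bcpflow simulate-bm --profile healthy --n-cells 50000 --donor-id c0 --seed 100 --out-dir sim/
bcpflow gate --events sim/c0.events.csv --out-dir gated/
bcpflow build-ref --events sim/c0.events.csv --events sim/c1.events.csv ... --out model.json
bcpflow compare --events sim/sixth.events.csv --model model.json --out-dir cmp/
bcpflow simulate-rep --compartment preBII_nn --n-clones 20000 --seed 3 --out-dir rep/
bcpflow repertoire --fasta preBII_nn=rep/preBII_nn.fasta --out-dir stats/
bcpflow report --deviation cmp/sixth.deviation.json --stats stats/stats.json
```

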