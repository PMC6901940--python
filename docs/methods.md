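# Methods

## Scope and model overview

bcpflow models the B-cell precursor (BCP) compartment of human bone marrow
as six stages — non-B contaminants, pro-B, pre-BI, pre-BII, immature and
mature B cells — defined by BCR-associated markers, and treats maturation
within and between the pre-B stages as an asynchronous continuum rather
than a sequence of discrete jumps. Three analyses sit on top of that
picture: deterministic stage gating, a pooled-control principal-component
reference with per-population 2SD contours, and clone-level IGH repertoire
productivity statistics for the four sortable pre-B subsets
(pre-BI+/+, pre-BI−/−, pre-BII−/−, pre-BII+/+, by CD34/TdT).

## Synthetic bone-marrow samples

### Why a latent-continuum intensity model

Each stage is generated as the image of a bounded two-dimensional latent
variable, not as a multivariate Gaussian. Every cell draws a
(pseudotime, size) pair uniformly from the unit disk. Pseudotime moves the
cell through its stage: CD20 rises and CD10/CD38 fall with stage-specific
signed amplitudes, and within pre-BI and pre-BII the CD34 and TdT levels
descend from the positive to the negative plateau through a steep
smoothstep ramp placed at a profile-specific point of pseudotime. The
CD34/TdT subdivisions (+/+, intermediate, −/−) are therefore *regions of
pseudotime*; their proportions follow from the ramp positions. The size
factor modulates all channels weakly with one shared loading pattern.
Independent Gaussian measurement noise (SD 0.07 on the arcsinh scale) is
added per channel, and raw intensities are recovered by inverting the
gating transform (`sinh(v) · 150`).

The choice is substantive, not cosmetic. A population that is truly
bivariate Gaussian in the reference PC plane has exactly 1 − e⁻² ≈ 86.5% of
its mass inside its own Mahalanobis-2 ellipse, so with pre-B cells making
up half or more of the BCP compartment a Gaussian generator forces ≥7% of
BCP events outside both pre-B contours — an order of magnitude more than
the 1–3% observed in healthy marrow. Real stage populations behave like
compact heterogeneous clouds: tight bounded biological variation inside a
wide fitted ellipse. Bounded latent factors with a radially bounded joint
reproduce exactly that: every linear projection of a population is bounded,
so the fitted 2SD ellipse covers essentially all of it, and the events
outside the contours are dominated by genuinely asynchronous cells.

### Stage mixture and transitioning cells

The healthy profile uses 20% non-B contaminants; of the B lineage, 10% is
mature; the precursor compartment splits pro-B 5%, pre-BI 30%, pre-BII 40%,
immature 25%. Transitioning cells — 2% of BCP by default — are drawn
uniformly along the segment between the pre-BI and pre-BII latent-averaged
centroids (pseudotime parameter 0.15–0.85), carrying intermediate cyIgμ
with stage-inappropriate accompanying markers. The RAG-deficient profile
has zero weight on every cyIgμ⁺ stage (pre-BII, immature, mature) and loses
CD34 early in pseudotime while TdT persists; the BTK-deficient profile
keeps a small (6% of BCP) pre-BII fraction and no immature/mature output.
Both patient profiles carry exaggerated CD20/CD10 kinetics in the arrested
pre-BI stage, so patient cells exceed healthy donors in out-of-contour
fraction, as observed clinically.

### Donor effect

Donor-to-donor variation is modelled as a bounded multiplicative
staining/instrument gain — a raw-scale scaling that appears as a constant
offset on the arcsinh scale for bright channels and almost none for
negative channels — with log-gain `0.3 · 0.25 · triangular(−1, 0, 1)`
(≈ up to 0.3 within-population SDs on bright channels), plus an independent
per-channel Gaussian residual of 3% of the within-population SD. Modelling
the donor effect as independent per-channel offsets instead makes single
donors swing the out-of-contour fraction severalfold, which contradicts the
tight healthy range the reference method relies on; instrument-standardized
acquisition makes the correlated, bounded form the realistic one.

Calibration note: the heterogeneity geometry (ramp windows, drift
amplitudes, noise and donor-gain scales) was fixed once so that a healthy
sixth donor leaves 1–3% of BCP events outside both pre-B 2SD contours —
the generator's defining study condition — and was then frozen. Across
three independently built references and twelve test donors the measured
range is 1.9–3.9% (mean 2.5%).

### IGH rearrangement simulation

A sequence is assembled as trimmed-V + N1 + trimmed-D + N2 + trimmed-J from
a built-in mini germline database (6 V, 4 D, 5 J synthetic but IMGT-like
segments with explicit 2nd-CYS/J-TRP anchor offsets). Deletion counts at
the four junction ends are truncated-geometric (mean 2.5 nt; 1.0 nt for the
pre-BI−/− compartment, which consequently has the longest CDR3s); deletions
are capped at the erodible tails so anchors always survive. N-insert
lengths are Poisson (mean 5 nt each, a proxy for TdT activity); insert
content is uniform ACGT. The productivity class is drawn first (in-frame
with the compartment's configured probability — 0.10 / 0.75 / 0.80 / 0.75
for pre-BI+/+, pre-BI−/−, pre-BII−/−, pre-BII+/+), then junctions are
rejection-sampled (cap 10,000 attempts) until the class *recomputed from
the assembled sequence* matches, so the realized clone-level in-frame
fraction equals the target in expectation while frame and stop status are
always genuine sequence properties. Truth labels are written to sidecar
tables only, never into FASTA headers or the event CSV.

What the generator does **not** emulate: somatic hypermutation, light-chain
loci, sequencing error beyond optional duplicates, spectral spillover,
doublets/debris, and the long-tailed instrument artefacts of real
cytometry. Passing tests therefore demonstrate the internal consistency and
calibration of the analysis pipeline, not its robustness to every artefact
of clinical data.

## Gating

Intensities are transformed channel-wise with `arcsinh(x / cofactor)`
(cofactor 150 for all channels — a single-parameter, order-preserving
alternative to logicle). Positivity cutoffs are explicit objects: either
configured, or estimated per channel as the deepest density valley between
the two largest modes of a Gaussian KDE evaluated on a 512-point grid. Two
numerical details matter: the valley is placed at the *midpoint of the
near-minimal basin* (points within 10% of the dip depth), because the raw
argmin wanders on wide flat valleys; and a channel is declared unimodal
(falling back to the configured cutoff, default 2.6) when the dip is
shallower than 10% below the smaller peak. The fallback is what gates
cyIgμ in RAG-deficient samples, where no positive mode exists.

Stage assignment follows the hierarchy listed in the README; surface IgM
takes precedence over cyIgμ, mirroring the sequential dot-plot strategy.
cyCD79a⁺ CD19⁻ TdT⁻ events fit no stage definition and are assigned non-B
while being tallied as `unclassified_b_lineage` QC events, keeping the
stage partition exhaustive. Composition percentages are computed over
pro-B + pre-BI + pre-BII + immature only.

## Reference model

PCA (two components, full SVD) is fitted on the pooled, per-marker
standardized, transformed BCP events of all controls (non-B and mature
excluded); all ten panel markers enter by default. Sign conventions: PC1
is oriented so the immature population mean is positive; PC2 so its
largest-magnitude loading is positive. Each reference population's PC-space
mean and covariance define the contour at Mahalanobis distance k (default
2); covariances are symmetrized and required positive-definite, and each
population must contribute ≥50 pooled events. Composition reference
intervals are per-control min–max.

The out-of-contour statistic counts gated pre-BI/pre-BII events whose
Mahalanobis distance exceeds k for *both* pre-B populations, divided by all
BCP events — the numerator convention is fixed this way because the
measurement targets cells that are pre-B by cyIgμ status yet fit neither
pre-B phenotype. Blockade thresholds (2% of BCP) are package-defined
constants chosen to separate the qualitative patterns (complete arrest
before cyIgμ; partial arrest at pre-BII) with a wide margin.

Projection of a test sample always uses the model's standardization
parameters, so deviations appear as displacement rather than being
re-normalized away. Models serialize to schema-versioned JSON and
round-trip bit-exactly.

## Repertoire analysis

The V/J assigner performs ungapped semi-global alignment: each germline V
slides with its 3' end over the query prefix (5' overhang allowed, V start
at most 12 nt into the query), each germline J slides over the query with
right overhang allowed; score = matches − mismatches, minimum overlap 12,
ties broken by database order. Ungapped alignment is exact for unmutated
rearrangements (no internal indels exist by construction of V(D)J joining)
and keeps anchor mapping trivial: query anchor positions are germline
anchor offsets plus the placement shift. Queries shorter than 60 nt, or
with best V/J score below 20, are "unassigned" and excluded from statistics
but counted in QC.

CDR3 is exclusive of both anchor codons; anchors whose mapped codon content
is not TGT/TGC (V) or TGG (J) mark the record "junction-unresolved". Frame
status is mod-3 arithmetic from the V frame origin to the J-TRP codon
start; the stop scan translates codon-by-codon from the frame origin
through the anchor codon. Productive ("in_frame") requires in-frame and
stop-free; unproductive records are split into out-of-frame and
stop-containing classes. Clones collapse on the (V gene, J gene, CDR3
nucleotide) triple with first-seen representatives, and every statistic —
in-frame fraction, in-frame:unproductive ratio, CDR3 amino-acid length
(in-frame clones only), and the 0/1/2/≥3 positive-charge classes counting
arginine, lysine and histidine — is clone-level. Histidine is counted as
positive and anchors are excluded from the CDR3 by convention; both choices
are uniform across compartments, so between-compartment comparisons are
unaffected by either.

## Problem sizes and numerical choices

Repertoire checks use 20,000 clones per compartment (binomial SE ≈ 0.3
percentage points at p = 0.8); the reference is built from five 50,000-cell
controls and tested on a sixth. Gaussian-contour containment is verified on
10,000 synthetic bivariate-normal draws against 1 − e⁻² within three
standard errors. KDE threshold estimation thins inputs to ≤20,000 events
deterministically. Random number use flows through
`numpy.random.SeedSequence` spawning, so every entry point is reproducible
from a single integer seed.

## Known limitations

* Manual-gate equivalence with expert analysis cannot be claimed — only
  internal consistency against generator truth; the numeric cutoffs and
  transform of commercial analysis software are not public.
* The 2SD contour is one defensible operationalization ("Mahalanobis ≤ 2
  per-population ellipse in PC1–PC2"); contour algorithms in commercial
  tools are proprietary and may differ in coverage.
* The germline database is synthetic; V/J calls are only meaningful
  relative to it, and D segments are not called at all (no statistic here
  needs them).
* Repertoire alignment is not mutation-tolerant beyond simple mismatches;
  somatically hypermutated sequences would need a different assigner.
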