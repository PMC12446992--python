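# cublink

Codon-usage-bias (CUB) analysis linking a plant host and a plant-growth-
promoting bacterium: per-gene CUB indices, host-adaptation indices, a
cross-species RSCU correlation screen, and an expression-response stage.

## The scientific problem

Plant-associated bacteria such as *Bacillus amyloliquefaciens* can improve
their host's tolerance of abiotic stress (e.g. the high-calcium soils of
karst regions for *Arabidopsis thaliana*). One proposed molecular axis of
such partnerships is codon usage: host genes whose synonymous-codon
preferences resemble the bacterium's may sit preferentially in the
pathways the interaction modulates. Testing that idea takes four
computational stages, all implemented here for anyone analysing a CDS pair
plus expression data:

1. **CUB indices** per gene — GC/GC1/GC2/GC3, RSCU, ENC (effective number
   of codons), SCUO (codon usage orderliness), PR2 parity coordinates, and
   the expected ENC–GC3 curve.
2. **Host adaptation** — CAI (codon adaptation index) and RCDI (relative
   codon deoptimization index) of each bacterial gene against the plant
   reference, and the organism-level similarity index
   SiD = (1 − cosine similarity)/2.
3. **Similarity screen** — Pearson correlation of each plant gene's RSCU
   vector with the bacterium's organism-level RSCU profile; genes with
   r ≥ 0.5 and p < 0.05 are called "similar-CUB" (no multiple-testing
   correction, per the conventional screen; BH optional).
4. **Expression response** — intersect the up/down calls of two DE methods
   ("common genes"), cluster group-level expression responses into integer
   model profiles with an exact 24-permutation null (the *rescue* profile
   (0, 0, +k, 0) marks genes up under calcium stress and restored by the
   bacterium), and compute 2^-ddCt fold changes from qPCR Ct tables.

A first-class synthetic-data generator fabricates both CDS collections
(with a planted similar-CUB subset at tunable mixing weight λ),
negative-binomial count matrices with planted profile genes, DEG tables
with exact planted overlaps, and Ct tables — so every stage is validated
against known ground truth. `docs/methods.md` gives the formulas,
defaults, and known statistical caveats.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with known
truth (each prints what it found and writes tables under `results/`):

```bash
python analysis/01_simulate_data.py      # synthetic study dataset + truth
python analysis/02_codon_usage_indices.py
python analysis/03_host_adaptation.py
python analysis/04_similarity_screen.py
python analysis/05_expression_response.py
python analysis/06_full_pipeline.py      # orchestrated rerun + checksums
```

Actual output of stages 3–5:

```
partner CAI vs query reference: mean 0.6648, range 0.6091 - 0.7358
partner RCDI vs query reference: mean 1.5162, range 1.2641 - 1.9604
SiD (RSCU basis) = 0.0672; SiD (frequency basis) = 0.0590 (0 = identical usage direction, 0.5 = orthogonal)

screened 2000 query genes against the partner RSCU profile
  selected (r >= 0.5, p < 0.05): 168
  recovery of the 200 planted similar genes (lambda = 0.9): sensitivity 0.840, specificity 1.000

merged DEG calls: 25 common up, 25 common down, 5 direction conflicts excluded
count matrix subset to 168 screen-selected genes (of 2000 total)
profile clustering of the selected genes: 1 of 50 model profiles significant after Bonferroni
  rescue profile 6 pattern (0, 0, 1, 0): 59 genes assigned (expected 16.1 under the exact permutation null), adjusted p = 1.03e-17
  recovery of the 85 planted rescue genes present in the subset: 0.694
2^-ddCt mean fold changes vs Control:
group   CaCl2  CaCl2+LZ04  Control   LZ04
BGLU40  3.932       1.556    1.001  0.968
HNL     2.568       1.885    1.004  1.000
```

Reading this: the screen recovers 84% of the genes planted with
codon usage mixed toward the bacterium (λ = 0.9) with no false positives;
among the selected genes, the only significant expression profile is the
rescue pattern — up under calcium, restored when the bacterium is present —
with 59 genes against 16.1 expected under the exact permutation null; and
the Ct table's planted fold changes (4.0 and 1.5 for BGLU40; 2.5 and 2.0
for HNL) are recovered by 2^-ddCt within simulation noise.

The same stages are available as a CLI (`cublink simulate|indices|adapt|
screen|expression|run`) and as one orchestrated call:

```bash
cublink run --config my_study.yaml   # YAML config; writes a manifest with
                                     # sha256 checksums of every output
```

To analyse real organisms, point `query_fasta`/`partner_fasta` at CDS
FASTA downloads and supply your own count matrix, DEG tables, and Ct
table; every threshold (r_min, p_max, alpha, lfc_min, c, m, min_codons) is
a config field.

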