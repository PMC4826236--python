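# chromatex

Quantitative nuclear image analysis for fluorescence microscopy: chromatin
texture from grey-level co-occurrence matrices, DNA-damage focus counting,
and compartment-based immunofluorescence scoring of tissue-microarray
cores — together with a synthetic-scene generator that provides full ground
truth for every analysis.

## The scientific problem

Chromatin reorganises when cells are injured: after DNA-damaging treatment
(platinum drugs, ionising radiation) nuclei that stained smoothly become
clumped and heterogeneous as heterochromatin forms. This change is visible
to a pathologist but needs numbers to be compared across treatments,
time points and models. `chromatex` provides the measurement pipeline:

* **Chromatin texture.** Inside each DAPI-segmented nucleus the package
  builds a grey-level co-occurrence matrix (GLCM) — the joint probability
  p(i, j) that two pixels at offset (d, θ) carry quantized grey levels
  i and j — and summarises it with five Haralick statistics:

  | feature | formula | reads as |
  |---|---|---|
  | ASM | Σᵢⱼ p(i,j)² | uniformity / smoothness |
  | contrast | Σᵢⱼ (i−j)² p(i,j) | local intensity variation |
  | correlation | Σᵢⱼ (i−μₓ)(j−μᵧ) p(i,j) / (σₓσᵧ) | grey-level linear dependency |
  | IDM | Σᵢⱼ p(i,j) / (1+(i−j)²) | local homogeneity |
  | entropy | −Σᵢⱼ p(i,j) log₂ p(i,j) | pattern disorder (bits) |

  Features are averaged per sample, compared between groups
  (exact two-tailed Mann-Whitney U for small samples), expressed as
  percent change of treated over control, and interpreted as directional
  calls on three chromatin patterns (homogeneity, heterogeneity, contrast).
  Chromatin condensation shows up as ASM/correlation/IDM ↓ with
  entropy/contrast ↑.

* **Focus counting.** γH2AX-like punctate foci are detected with
  multi-scale Laplacian-of-Gaussian blob detection restricted to the
  nuclear mask; a cell is focus-positive when its count exceeds a
  background cut-point (default: more than 5 foci per cell).

* **Compartment scoring.** For tissue-microarray cores, the epithelium is
  defined by the cytokeratin channel and split into nuclear (DAPI) and
  cytoplasmic compartments; a target channel is scored as mean intensity
  per compartment (arbitrary units), and cores with less than 5% epithelium
  are excluded as non-representative.

No imaging data ships with the package; the `synth` module generates
scenes for all three tasks with exact ground truth (nucleus masks, focus
coordinates, compartment labels), which is what the test suite and the
examples run on.

## Worked example

```bash
python examples/chromatin_texture_signature.py
```

simulates five control and five treated coverslips, segments nuclei,
profiles texture and compares the arms. Output (seed 1):

```
percent change, treated over control:
  asm             -67.4 %
  contrast       +373.0 %
  correlation     -18.0 %
  idm             -25.8 %
  entropy         +41.2 %

two-tailed Mann-Whitney per feature (per-sample means, n=5 vs 5):
  asm          U= 25.0  p=0.0079  (mann_whitney_exact)
  contrast     U=  0.0  p=0.0079  (mann_whitney_exact)
  correlation  U= 25.0  p=0.0079  (mann_whitney_exact)
  idm          U= 25.0  p=0.0079  (mann_whitney_exact)
  entropy      U=  0.0  p=0.0079  (mann_whitney_exact)

chromatin pattern call: homogeneity decreased, heterogeneity increased, contrast increased
```

The treated arm's clumped nuclei lose uniformity (ASM, IDM down), lose
pixel-to-pixel correlation, and gain disorder and contrast — the texture
signature of chromatin condensation. With five samples per arm the
smallest exact two-tailed p is 0.0079 (complete separation).

Other examples: `foci_counting.py` (exact recovery of planted foci and the
\>5 cut-point), `tma_compartment_scoring.py` (compartment scores and the
<5% epithelium exclusion), `exact_mann_whitney.py` (exact vs asymptotic
rank tests). An end-to-end YAML-configured run:

```bash
chromatex run examples/demo_config.yaml
```

writes per-nucleus CSVs, per-sample means, group comparisons and a run
manifest under `runs/demo/`.

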