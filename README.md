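# segmix

Quantitative image analysis for cell-sorting assays and early epithelial
morphometry in zebrafish, with a fully ground-truthed synthetic data
generator.

When dissociated blastoderm cells from two differently labeled populations
(red/green dextran) are co-plated 1:1 and allowed to re-aggregate, the way
the two populations arrange inside each cluster reports on their relative
adhesiveness: equally adhesive cells intermix, differentially adhesive
cells sort into compartments or engulf one another. `segmix` implements the
complete measurement chain for such experiments — aggregate segmentation,
per-cluster segregation statistics, population comparisons — plus the
morphometry of the embryo's outer epithelial layer (EVL): cell shape,
junction arity and rosettes, and mitotic fraction. Because the raw
microscopy of such studies is rarely deposited, the package ships a seeded
generator of synthetic two-channel aggregate fields and EVL mosaics with
machine-readable ground truth, so every stage of the chain is benchmarked
against known answers.

## The statistics

Each segmented aggregate's red and green intensity matrices
$l_c[r,x]$ are normalized to unit mass $w_c$. With per-channel centroids
$\mu_c$, combined centroid $\mu = (\mu_{red}+\mu_{green})/2$ and gyration
radii

$$g_c = \sqrt{\textstyle\sum_x w_c(x)\,\lVert x-\mu\rVert^2},$$

the package computes

* **Scattering** $S$ — either the raw ratio $S = g_{red}/g_{green}$ or the
  bounded symmetric form $S = 2g_{red}/(g_{red}+g_{green}) \in [0,2]$
  (default). $S \approx 1$ for intermixed populations; asymmetric
  segregation (e.g. a compact core engulfed by the other population) drives
  it toward 0 or 2. A cluster is *intermixed* when $0.9 < S < 1.1$.
* **Dipole moment** $P = \lVert\mu_{red}-\mu_{green}\rVert \,/\,
  (8R_{eq}/3\pi)$ with $R_{eq} = \sqrt{A/\pi}$. The normalization is the
  centroid separation of two half-disks, so an ideally bisected disk scores
  $P = 1$, while full mixing and concentric engulfment both score
  $P \approx 0$.

Segmentation follows the standard recipe for low-magnification two-channel
fields: maximum z-projection, local contrast normalization, Gaussian blur
($\sigma = 1$ px), Li minimum-cross-entropy threshold, connected components,
removal of objects smaller than 1000 px. EVL images are binarized,
despeckled (3×3 median), split by a distance-transform watershed and
measured (area, Crofton perimeter, circularity $4\pi A/P^2$ clamped at 1);
junction points are boundary loci where ≥ 3 cells meet within a small
window, with junctions of ≥ 5 cells flagged as rosettes. Tabular statistics
cover epiboly staging (normalization to the 4.33 h dome reference, two-way
genotype × stage ANOVA with Bonferroni post-hoc contrasts) and qPCR
relative quantification (ΔΔCT, housekeeping-normalized, calibrator-anchored,
RQ $=2^{-\Delta\Delta C_T}$).

## Worked example

Simulate a field of six engulfed-configuration aggregates at intermediate
mixing, segment it, and compute segregation statistics:

```sh
cat > agg.yaml <<'YAML'
n_clusters: 6
mode: engulfed
mixing_m: 0.5
YAML
segmix simulate aggregates --config agg.yaml --seed 7 --out sim
segmix segment --in sim --out seg
segmix segregation --rois seg --images sim --group wt-like --out stats
```

which prints

```
wrote 1 field(s) to sim
segmented 1 field(s) into seg
6 clusters, intermixed fraction 0.167
```

and writes `stats/clusters.csv` beginning

```
field,roi_id,S_ratio,S_bounded,P,area_px
field_000,0,0.7679991835287077,0.8687777581388655,0.06101774696805823,4871
field_000,1,0.8100867797576795,0.8950805992474323,0.22698994378953158,5126
field_000,2,0.7532612186056885,0.8592686709910035,0.09304144991886532,3885
```

Read: the clusters sit below the intermixed window ($S_{bounded} \approx
0.86{-}0.90 < 0.9$, reflecting the compact red core) while $P$ stays near 0
(concentric populations share a centroid) — exactly the engulfment
signature, distinct from both mixing ($S \approx 1$) and bisection
($P \approx 1$). Only 1 of 6 clusters falls in the intermixed window.

The same CLI exposes `simulate evl|epiboly|qpcr`, `evl-morpho`, `epiboly`,
`qpcr` and `report`; every command writes a `provenance.json` (config echo,
seed, version) beside its outputs. The library API (`segmix.segstats`,
`segmix.evlmorph`, `segmix.studystats`, `segmix.synthgen`) offers the same
operations programmatically.

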