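# cellpattern

Quantitative analysis of how cultured cells organize on a substrate, from
the positions of their fluorescently labelled nuclei. Given a nuclei image
(or a centroid list), the package computes:

* the **radially averaged two-point autocorrelation** S2(r) of the binary
  nuclei mask — the probability that two pixels a distance r apart are
  both foreground, FFT-accelerated with finite-size correction and
  normalized so S2(0) = 1 and S2 → 0 for uncorrelated images. Its shape
  reads out the spatial organization: on an undulating curve the first
  minimum is the typical object (cell or agglomeration) size and the
  first peak the typical object spacing, while on a flattened curve the
  bend from steep decline to a near-constant regime (the *correlation
  length*) estimates the average agglomeration size;
* the **number of cell clusters** and their properties, via K-means on
  nuclei coordinates with three mutually checking selectors — the elbow
  of the total within-cluster variation totW(k) = Σₖ Σ_{xᵢ∈Cₖ} ‖xᵢ−μₖ‖²,
  the gap statistic Gap(k) = E[log totW_uniform(k)] − log totW(k) against
  B = 50 uniform reference sets with the one-standard-error rule
  K = min{k : Gap(k) ≥ Gap(k+1) − s(k+1)}, s(k) = √(1+1/B)·sd(k), and the
  silhouette coefficient SilCoef(i) = (x(i)−y(i))/max(x(i),y(i)) with a
  0.35 mean-width quality threshold — plus per-cluster cell counts,
  covariance-ellipse areas and in-cluster densities in cells/mm².

It is aimed at biomaterials and neural-interface work, where glia-like
cells spreading evenly and neuron-like cells forming dense agglomerations
must be distinguished and the agglomeration sizes and densities compared
across substrate materials. Synthetic generators (homogeneous Poisson,
Thomas-process clusters, planted blobs) make the whole pipeline testable
without microscopy data.

## Worked example

The frozen fixture `CLUST-A` plants four Gaussian blobs of 200 nuclei
each (sd = 60 µm) on a 2000×2000 µm field, centres 1200 µm apart:

```python
from cellpattern import CellClusterModel, SpatialCorrelationModel, rasterize
from cellpattern.synthetic import clust_a

pattern = clust_a()
res = CellClusterModel(pattern).fit(kmax=8, seed=1)
print(res.summary())
```

```
Cell cluster-number inference
======================================================
n cells                 800
selected K                4
gap candidate K           4
mean silhouette       0.908
quality                  ok
------------------------------------------------------
cluster  n_cells   area_mm2   dens/mm2    sil
      0      200     0.0680     2943.1   0.91
      1      200     0.0655     3053.4   0.91
      2      200     0.0613     3264.2   0.91
      3      200     0.0751     2663.7   0.90
```

The gap statistic proposes four clusters, the mean silhouette width 0.908
is far above the 0.35 quality threshold (`quality: ok`), and each planted
blob is recovered with its 200 cells; the 95%-coverage ellipse of each
cluster covers ≈ 0.06–0.08 mm², giving in-cluster densities of ≈ 2700–
3300 cells/mm². The same pattern rasterized as 6 µm nucleus disks yields
the autocorrelation branch:

```python
img = rasterize(pattern, nucleus_radius=6.0)
corr = SpatialCorrelationModel(img).fit(max_radius=300.0)
print(corr.summary())
```

```
Radially averaged two-point autocorrelation
===============================================
fill fraction p            0.0183
max radius (um)             300.0
correlation length (um)      16.0
first minimum (um)           none
first peak (um)              none
undulating                  False
```

S2 starts at exactly 1, and the curve bends at 16 µm — the isolated-disk
(single-nucleus) scale, since these sparse synthetic disks do not merge
into contiguous patches. `res.plot_clusters()`, `res.plot_gap()` and
`corr.plot()` draw the standard diagnostic figures.

The same stages are available from the shell:

```sh
cellpattern simulate --fixture CLUST-A --out pattern.csv
cellpattern cluster --in pattern.csv --kmax 8 --b 50 --seed 1 --out out/
cellpattern run --in pattern.csv --pixel-size 2 --seed 1 --out out/
```

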