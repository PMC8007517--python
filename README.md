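# ionclust

Spatially aware clustering of ion images from mass spectrometry imaging
(MSI) data. Each ion image (the 2-D intensity map of one m/z bin) is turned
into a fixed-length **neural ion image** vector by splitting it into
overlapping square patches at a target physical size (~1–2 mm), embedding
every patch, and max-pooling the patch embeddings. The vectors (or the raw
pixel vectors) are clustered with UMAP→DBSCAN or k-means, and the result is
scored with the **relative isotope ratio** (RIR): the fraction of isotope
pairs (+1.003 Da companions with Pearson-correlated images) that land in the
same cluster, divided by the expectation under size-preserving random
relabelings, estimated by bootstrap. A segment-wise top-N ranking benchmark
against expert similarity scores is also included.

## Layout

| module | role |
|---|---|
| `ionclust.msi_io` | imzML/ibd read + write (continuous and processed), ion-image materialization, assignments CSV, HDF5 vectors bundle |
| `ionclust.preprocess` | TIC normalization, running-median baseline, upper winsorization, unit scaling |
| `ionclust.patching` | patch-grid planning (40–50% overlap, integer upsampling), bilinear upsampling, patch extraction |
| `ionclust.embedding` | embedder contract, 101-dim reference embedder, max-pool aggregation |
| `ionclust.xception` | NumPy forward pass of the Xception trunk (random init, 2048-dim, 71 px minimum input) |
| `ionclust.clustering` | UMAP→DBSCAN and k-means, meaningful-cluster count, mean cluster images |
| `ionclust.evaluation` | isotope-pair detection, isotope fraction, bootstrap null, RIR, cosine similarity, ranking benchmark |
| `ionclust.synthetic` | seeded MSI generator with known spatial patterns, isotope companions, and noise channels |
| `ionclust.pipeline` / `ionclust.cli` | the four end-to-end pipelines and the `ionclust` command |

The backbone adapter instantiates the Xception architecture with seeded
random weights (no download, fully deterministic); it reproduces the
published embedding geometry and can be swapped for a pretrained Keras model
behind the same `Embedder` contract. The reference embedder is the default
everywhere else.

## CLI

```bash
# synthetic dataset (imzML + ground-truth CSV)
ionclust simulate --out runs/sim --seed 7

# one of: regular-ud, neural-ud, regular-kmeans, neural-kmeans
ionclust run --input runs/sim/synthetic.imzML --pipeline neural-kmeans \
    --out runs/nk --k 4 --seed 0

# individual stages
ionclust embed --input runs/sim/synthetic.imzML --out runs/vec.h5 --embedder reference
ionclust cluster --vectors runs/vec.h5 --method kmeans --k 4 --out runs/assign.csv
ionclust evaluate --input runs/sim/synthetic.imzML --assignments runs/assign.csv \
    --out runs/rir.csv
ionclust benchmark-ranking --scores scores.csv --similarities sims.csv \
    --cutoffs 0.5,1.0,2.0 --out runs/segments.csv
```

A run directory contains `assignments.csv`, `rir.csv`, `manifest.json`
(config, per-stage seeds, artifact list), `mean_cluster_*.png`,
`mean_spectrum.png`, plus `vectors.h5` (neural pipelines) and
`embedding3d.csv` (UMAP pipelines).

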