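"""End-to-end pipeline runner binding the modules into four named pipelines:
regular/neural x UMAP-DBSCAN/k-means, plus the report artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import (ClusteringResult, NOISE_LABEL, cluster_dbscan,
                         cluster_kmeans, count_meaningful_clusters,
                         mean_cluster_image, reduce_umap)
from .embedding import embed_ion_image, get_embedder
from .errors import ParameterError, StageError
from .evaluation import IsotopeCriteria, evaluate_rir
from .msi_io import (MSIDataset, ion_images, read_imzml, write_assignments,
                     write_vectors)
from .patching import plan_patch_grid
from .preprocess import standardize_image, tic_normalize_dataset

PIPELINES = ("regular-ud", "neural-ud", "regular-kmeans", "neural-kmeans")


@dataclass
class PipelineConfig:
    input: str
    pipeline: str
    outdir: str
    seed: int = 0
    # preprocessing
    tic_enabled: bool = True
    winsor_quantile: float = 0.95
    # patching / embedding
    target_mm: float = 1.5
    min_side: int | None = None
    overlap_target: float = 0.5
    embedder: str = "reference"
    # clustering
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 5
    kmeans_k: int = 10
    # evaluation
    mass_shift: float = 1.003
    rir_delta: float = 0.01
    rir_min_corr: float = 0.85
    rir_B: int = 1000
    bin_tol: float = 0.01

    def __post_init__(self):
        if self.pipeline not in PIPELINES:
            raise ParameterError(f"pipeline must be one of {PIPELINES}")


def _stage_seeds(master: int) -> dict[str, int]:
    """Fan one master seed out to independent per-stage streams."""
    children = np.random.SeedSequence(master).spawn(3)
    names = ("umap", "kmeans", "bootstrap")
    return {name: int(child.generate_state(1)[0]) for name, child in zip(names, children)}


def run_pipeline(config: PipelineConfig, dataset: MSIDataset | None = None) -> Path:
    """Run one full pipeline; returns the run directory.

    ``dataset`` may be passed directly (bypassing ``config.input``) for
    programmatic use.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stage_seeds": seeds, "artifacts": [], "warnings": []}
    neural = config.pipeline.startswith("neural")
    use_umap = config.pipeline.endswith("-ud")

    def _artifact(path: Path) -> Path:
        manifest["artifacts"].append(path.name)
        return path

    try:
        if dataset is None:
            dataset = read_imzml(config.input, bin_tol=config.bin_tol)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    try:
        if config.tic_enabled:
            dataset, n_zero = tic_normalize_dataset(dataset)
            if n_zero:
                manifest["warnings"].append(f"{n_zero} zero-TIC spectra")
        raw_images = ion_images(dataset)
        images = [standardize_image(img, config.winsor_quantile) for img in raw_images]
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc

    try:
        if neural:
            embedder = get_embedder(config.embedder, seed=config.seed)
            min_side = config.min_side if config.min_side is not None else embedder.min_side
            grid = plan_patch_grid(images[0].shape, dataset.pixel_size_um,
                                   target_mm=config.target_mm, min_side=min_side,
                                   overlap_target=config.overlap_target)
            neural_images = [embed_ion_image(img, grid, embedder) for img in images]
            vectors = np.stack([ni.vector for ni in neural_images])
            _artifact(write_vectors(vectors, dataset.mz_axis,
                                    [ni.provenance for ni in neural_images],
                                    outdir / "vectors.h5"))
        else:
            vectors = np.stack([img.pixels.ravel() for img in images])
    except Exception as exc:
        raise StageError("embed", str(exc)) from exc

    embedding3d = None
    try:
        if use_umap:
            embedding3d = reduce_umap(vectors, n_neighbors=config.umap_n_neighbors,
                                      min_dist=config.umap_min_dist, seed=seeds["umap"])
            labels = cluster_dbscan(embedding3d, eps=config.dbscan_eps,
                                    min_samples=config.dbscan_min_samples)
            method = "umap_dbscan"
        else:
            labels = cluster_kmeans(vectors, k=config.kmeans_k, seed=seeds["kmeans"])
            method = "kmeans"
        result = ClusteringResult(labels=labels, method=method,
                                  params={"pipeline": config.pipeline},
                                  embedding3d=embedding3d)
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc

    try:
        _artifact(write_assignments(result.labels, dataset.mz_axis,
                                    outdir / "assignments.csv"))
        if embedding3d is not None:
            import pandas as pd

            df = pd.DataFrame({"mz": dataset.mz_axis, "u1": embedding3d[:, 0],
                               "u2": embedding3d[:, 1], "u3": embedding3d[:, 2],
                               "cluster": result.labels})
            df.to_csv(_artifact(outdir / "embedding3d.csv"), index=False)

        criteria = IsotopeCriteria(mass_shift=config.mass_shift,
                                   delta=config.rir_delta,
                                   min_corr=config.rir_min_corr)
        try:
            rir = evaluate_rir(dataset.mz_axis, raw_images, result.labels,
                               criteria=criteria, B=config.rir_B,
                               seed=seeds["bootstrap"])
            import pandas as pd

            pd.DataFrame([vars(rir)]).to_csv(_artifact(outdir / "rir.csv"), index=False)
            manifest["rir"] = vars(rir)
        except Exception as exc:  # noqa: BLE001 - RIR is optional when no pairs exist
            manifest["warnings"].append(f"RIR not computed: {exc}")
        manifest["n_meaningful_clusters"] = count_meaningful_clusters(result)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    try:
        _write_reports(dataset, raw_images, result, outdir, _artifact,
                       config.winsor_quantile)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _write_reports(dataset, images, result, outdir, register, winsor_q):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cid in sorted(set(result.labels.tolist()) - {NOISE_LABEL}):
        mean_img = mean_cluster_image(images, result.labels, cid, winsor_q)
        path = outdir / f"mean_cluster_{cid}.png"
        plt.imsave(path, mean_img.pixels, cmap="viridis")
        register(path)
    register(report_mean_spectrum(dataset, result.labels,
                                  outdir / "mean_spectrum.png"))


def report_mean_spectrum(dataset: MSIDataset, labels, path) -> Path:
    """Mean spectrum with per-cluster colored stems; noise label in gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    means = dataset.intensities.mean(axis=0)
    uniq = sorted(set(labels.tolist()) - {NOISE_LABEL})
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(10, 4))
    for lab in uniq + [NOISE_LABEL]:
        sel = labels == lab
        if not sel.any():
            continue
        color = "0.6" if lab == NOISE_LABEL else cmap(uniq.index(lab) % 20)
        name = "noise" if lab == NOISE_LABEL else f"cluster {lab}"
        ax.vlines(dataset.mz_axis[sel], 0, means[sel], color=color, label=name)
    ax.set_xlabel("m/z (Da)")
    ax.set_ylabel("mean intensity")
    if len(uniq) <= 10:
        ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
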