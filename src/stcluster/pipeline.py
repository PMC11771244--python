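"""End-to-end convenience wrapper: preprocess -> graphs -> train -> cluster."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import Labeling, fit_gmm_eee, louvain_cluster
from .dataset import SpatialDataset
from .graph import SpatialGraph, build_ctsag, build_sag, tune_radius
from .preprocess import PreprocessConfig, preprocess
from .trainer import TrainConfig, TrainResult, train

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: SpatialDataset          # preprocessed
    sag: SpatialGraph
    ctsag: SpatialGraph
    train_result: TrainResult
    labeling: Labeling

    @property
    def embeddings(self) -> np.ndarray:
        return self.train_result.embeddings

    @property
    def labels(self) -> np.ndarray:
        return self.labeling.labels


def run_pipeline(dataset: SpatialDataset,
                 config: TrainConfig | None = None,
                 preprocess_config: PreprocessConfig | None = None,
                 radius: float | None = None,
                 ctsag_k: int = 35, ctsag_theta: float = 0.96) -> PipelineResult:
    """Run the full workflow on a raw dataset.

    When config.n_clusters is set, domains come from the tied-covariance
    Gaussian mixture with that K; otherwise Louvain on the embeddings.
    """
    config = config or TrainConfig()
    pp = preprocess(dataset, preprocess_config or PreprocessConfig())
    if radius is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            radius = tune_radius(pp.coords)
    sag = build_sag(pp.coords, radius)
    k = min(ctsag_k, pp.n_spots - 1)
    ctsag = build_ctsag(pp.coords, pp.dense(), k=k, theta=ctsag_theta,
                        seed=config.seed)
    result = train(pp, sag, ctsag, config)
    if config.n_clusters is not None:
        labeling = fit_gmm_eee(result.embeddings, config.n_clusters,
                               seed=config.seed)
    else:
        labeling = louvain_cluster(result.embeddings, seed=config.seed)
    return PipelineResult(dataset=pp, sag=sag, ctsag=ctsag,
                          train_result=result, labeling=labeling)
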