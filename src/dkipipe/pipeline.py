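"""End-to-end pipeline: simulate/fit -> scalar maps -> features -> classify.

Mirrors the study workflow: each subject's diffusion-weighted volume is
fitted voxelwise inside the shared ROI, tensor components (and derived
FA/MD/MK maps) become per-subject feature vectors after cohort-wide
zero-pruning, and the biomarkers are compared by elastic-net selection
plus SVM classification on a held-out stratified split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import ElasticNetConfig, run_experiment
from .cohort import CohortDesign, generate_cohort
from .features import extract_subject_matrix, flatten_features, prune_zero_rows_columns
from .fit import FitOptions, fit_volume
from .maps import scalar_maps_volume

__all__ = ["fit_cohort", "cohort_feature_sets", "run_cohort_experiment"]


def fit_cohort(bundle: dict, options: FitOptions = FitOptions()) -> list[dict[str, np.ndarray]]:
    """Fit every subject of a cohort bundle; returns per-subject map dicts."""
    return [
        fit_volume(s["volume"], s["mask"], bundle["scheme"], options)
        for s in bundle["subjects"]
    ]


def cohort_feature_sets(
    maps_list: list[dict[str, np.ndarray]],
    mask: np.ndarray,
    biomarkers: tuple[str, ...] = ("DT", "KT", "FA", "MD", "MK", "FA+MK"),
    mk_directions: int = 256,
) -> dict[str, np.ndarray]:
    """Build subjects x features arrays for each requested biomarker.

    Tensor biomarkers (DT, KT) are the flattened components x voxels
    matrices after cohort-wide zero-pruning; scalar biomarkers are the
    per-voxel map values on the pruned voxel support; FA+MK concatenates
    the two scalar vectors.
    """
    scalars_needed = {"FA", "MD", "MK"} & (
        set(biomarkers) | ({"FA", "MK"} if "FA+MK" in biomarkers else set())
    )
    scalar_vols = (
        [scalar_maps_volume(m, mask, n_directions=mk_directions) for m in maps_list]
        if scalars_needed
        else None
    )

    out: dict[str, np.ndarray] = {}
    cache: dict[str, np.ndarray] = {}

    def scalar_features(name: str) -> np.ndarray:
        if name not in cache:
            cohort = [
                extract_subject_matrix(np.nan_to_num(v[name]), mask, "scalar")
                for v in scalar_vols
            ]
            pruned, _ = prune_zero_rows_columns(cohort)
            cache[name] = np.stack([flatten_features(m) for m in pruned])
        return cache[name]

    for name in biomarkers:
        if name in ("DT", "KT"):
            cohort = [extract_subject_matrix(m, mask, name) for m in maps_list]
            pruned, _ = prune_zero_rows_columns(cohort)
            out[name] = np.stack([flatten_features(m) for m in pruned])
        elif name in ("FA", "MD", "MK"):
            out[name] = scalar_features(name)
        elif name == "FA+MK":
            out[name] = np.hstack([scalar_features("FA"), scalar_features("MK")])
        else:
            raise ValueError(f"unknown biomarker {name!r}")
    return out


def run_cohort_experiment(
    design: CohortDesign,
    biomarkers: tuple[str, ...] = ("DT", "KT", "FA", "MD", "MK", "FA+MK"),
    selection: str = "L1+L2",
    test_size: float = 0.25,
    seed: int | None = None,
    cv_folds: int = 5,
    enet: ElasticNetConfig | None = None,
    fit_options: FitOptions = FitOptions(),
) -> pd.DataFrame:
    """Simulate a cohort from the design and evaluate each biomarker."""
    bundle = generate_cohort(design)
    maps_list = fit_cohort(bundle, fit_options)
    features = cohort_feature_sets(maps_list, bundle["mask"], biomarkers)
    labels = (bundle["labels"]["group"] == "patient").astype(int).to_numpy()
    return run_experiment(
        features,
        labels,
        selection=selection,
        test_size=test_size,
        seed=design.seed if seed is None else seed,
        cv_folds=cv_folds,
        enet=enet,
    )
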