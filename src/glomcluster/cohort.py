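"""Cohort-level orchestration: extract features for many cells, run the
clustering on a parameter sheet, and glue the stages together.

These helpers operate on in-memory cell records (``morphology``,
``context``, ``sweeps``) such as those produced by
:mod:`glomcluster.synthetic_data`, or on a feature table read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_pipeline import (
    ClusterLabels,
    GapCurve,
    PreprocessSpec,
    StabilityReport,
    gap_statistic,
    jaccard_stability,
    preprocess,
    select_k,
    ward_cluster,
)
from .ephys_features import average_spike_shape, compute_ephys_features, fit_ahp_ica
from .io_formats import (
    MORPHOLOGICAL_PARAMETERS,
    PHYSIOLOGICAL_PARAMETERS,
    FeatureTable,
    read_parameter_sheet,
)
from .morphometry import compute_morpho_features

__all__ = [
    "extract_cohort_features",
    "cluster_features",
    "ClusteringResult",
    "analyze_parameter_sheet",
]


def extract_cohort_features(cells: list[dict], ica_seed: int = 0) -> FeatureTable:
    """Morphological + physiological features for a list of cell records.

    The ICA AHP factors are fitted across the whole cohort's average spike
    shapes (they are population-level factors), then every cell is scored
    against them.
    """
    shapes = []
    for c in cells:
        shapes.append(average_spike_shape(c["sweeps"]).ahp_segment())
    shapes = np.asarray(shapes)
    ica = fit_ahp_ica(shapes, sampling_rate=cells[0]["sweeps"].sampling_rate,
                      seed=ica_seed)
    rows = {}
    for c in cells:
        morpho = compute_morpho_features(c["morphology"], c["context"])
        ephys = compute_ephys_features(c["sweeps"], ica)
        rows[c["cell_id"]] = morpho.as_dict() | ephys.as_dict()
    df = pd.DataFrame(rows).T
    df.index.name = "cell_id"
    return FeatureTable(data=df)


@dataclass
class ClusteringResult:
    labels: ClusterLabels
    gap_curve: GapCurve
    k: int
    stability: StabilityReport | None = None


def cluster_features(table: FeatureTable | pd.DataFrame,
                     columns: tuple[str, ...] = MORPHOLOGICAL_PARAMETERS,
                     asinh: bool = True,
                     k: int | None = None,
                     k_max: int = 10,
                     B: int = 100,
                     f: float = 2.0,
                     seed: int = 0,
                     method: str = "ward.D2",
                     stability_boot: int = 0) -> ClusteringResult:
    """Preprocess → Ward → gap-statistic k selection (→ optional stability).

    ``asinh`` applies the inverse-hyperbolic-sine transform to the selected
    columns before scaling (the default for the skewed morphological
    parameters; physiological parameters are typically clustered with
    ``asinh=False``).  If ``k`` is given the gap curve is still computed but
    the cut uses the requested k.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    sub = df.loc[:, list(columns)]
    spec = PreprocessSpec(asinh_columns=frozenset(columns) if asinh else frozenset())
    X = preprocess(sub, spec)
    curve = gap_statistic(X, k_max=k_max, B=B, seed=seed, f=f, method=method)
    chosen = k if k is not None else select_k(curve)
    labels = ward_cluster(X, chosen, cell_ids=[str(i) for i in sub.index], method=method)
    stability = None
    if stability_boot > 0:
        stability = jaccard_stability(X, labels, n_boot=stability_boot, seed=seed)
    return ClusteringResult(labels=labels, gap_curve=curve, k=chosen, stability=stability)


def analyze_parameter_sheet(path, columns: tuple[str, ...] = MORPHOLOGICAL_PARAMETERS,
                            asinh: bool = True, k_max: int = 10, B: int = 100,
                            seed: int = 0, method: str = "ward.D2",
                            stability_boot: int = 500,
                            extra_aliases: dict[str, str] | None = None) -> ClusteringResult:
    """Full clustering of a per-cell parameter sheet on disk.

    Reads the sheet (alias-mapped to canonical parameter names), clusters the
    requested columns, selects k by the gap statistic and assesses bootstrap
    stability.  Intended for deposited measurement sheets; the synthetic
    cohorts go through :func:`extract_cohort_features` instead.
    """
    table = read_parameter_sheet(path, extra_aliases=extra_aliases, require=columns)
    return cluster_features(table, columns=columns, asinh=asinh, k_max=k_max,
                            B=B, seed=seed, method=method,
                            stability_boot=stability_boot)
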