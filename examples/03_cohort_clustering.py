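"""The full unsupervised pipeline on a synthetic 95-cell cohort.

Generates the default seven-archetype cohort, extracts all 18 parameters,
selects the number of morphological clusters with the gap statistic
(f·SE rule, f = 2), checks bootstrap stability, and compares the
morphological with the physiological partition.
"""

import numpy as np

from glomcluster import CohortSpec, compare_clusterings, jaccard_stability
from glomcluster.cluster_pipeline import PreprocessSpec, preprocess
from glomcluster.cohort import cluster_features, extract_cohort_features
from glomcluster.io_formats import MORPHOLOGICAL_PARAMETERS, PHYSIOLOGICAL_PARAMETERS
from glomcluster.synthetic_data import generate_cohort_objects
from sklearn.metrics import adjusted_rand_score

cells, truth = generate_cohort_objects(CohortSpec(), seed=0)
table = extract_cohort_features(cells)
print(f"cohort: {len(cells)} cells, {table.data.shape[1]} extracted parameters")

morpho = cluster_features(table, columns=MORPHOLOGICAL_PARAMETERS, k_max=10, B=100, seed=0)
print(f"gap statistic selects k = {morpho.k} morphological clusters")
print("cluster sizes:", morpho.labels.sizes())
ari_truth = adjusted_rand_score(truth.cells["cluster"], morpho.labels.labels)
print(f"agreement with generating classes: ARI = {ari_truth:.2f}")

X = preprocess(table.data.loc[:, list(MORPHOLOGICAL_PARAMETERS)],
               PreprocessSpec(asinh_columns=frozenset(MORPHOLOGICAL_PARAMETERS)))
stab = jaccard_stability(X, morpho.labels, n_boot=100, seed=0)
print("bootstrap Jaccard stability:",
      {c: round(v, 2) for c, v in stab.jaccard.items()})

physio = cluster_features(table, columns=PHYSIOLOGICAL_PARAMETERS,
                          asinh=False, k=7, B=50, seed=0)
rep = compare_clusterings(morpho.labels, physio.labels)
print(f"morphological vs physiological partition: ARI = {rep.ari:.2f}")

# A Jaccard index near 1 means a cluster reappears almost unchanged in
# bootstrap resamples; the cross-modality ARI quantifies how far physiology
# alone predicts the morphological class.
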