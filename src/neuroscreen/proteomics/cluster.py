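"""Z-score hierarchical clustering of protein profiles.

Rows (proteins) are standardised to mean 0 / SD 1 across samples, then
clustered by agglomerative average linkage on Euclidean distances — the
standard heatmap preparation for LFQ data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage


@dataclass
class ClusterResult:
    """Dendrogram of the clustered (z-scored) matrix."""

    row_order: np.ndarray           # leaf order, indices into the input rows
    linkage_matrix: np.ndarray      # scipy linkage encoding (merges + heights)
    zscored: pd.DataFrame

    @property
    def ordered_index(self) -> pd.Index:
        return self.zscored.index[self.row_order]


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0, SD 1 (population SD).

    Constant rows have zero variance and are mapped to all-zeros.
    """
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    z = np.divide(arr - mean, sd, out=np.zeros_like(arr), where=sd > 0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def zscore_cluster(values: pd.DataFrame, complete_missing: bool = True) -> ClusterResult:
    """Cluster protein rows by average-linkage Euclidean distance on z-scores.

    ``values`` is a proteins x samples matrix of log2 intensities.  Missing
    entries are completed with the row mean when ``complete_missing`` is
    set (a z-score of 0 after standardisation); otherwise they raise.
    """
    if len(values) < 2:
        raise ValueError("clustering needs at least two proteins")
    if values.isna().any().any():
        if not complete_missing:
            raise ValueError("matrix contains missing values; enable complete_missing or pre-filter")
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
        if values.isna().any().any():
            raise ValueError("rows with no observed values cannot be clustered")
    z = zscore_rows(values)
    lm = linkage(z.to_numpy(), method="average", metric="euclidean")
    return ClusterResult(row_order=leaves_list(lm), linkage_matrix=lm, zscored=z)
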