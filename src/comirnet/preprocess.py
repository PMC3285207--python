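"""Per-dataset normalization and assembly of one expression matrix per species.

The preparation mirrors common microarray practice for cross-platform
integration: each dataset is quantile-normalized on its own, probe-level rows
are collapsed to mature miRNA IDs, and the datasets of one species are then
restricted to the miRNAs every platform measured and concatenated sample-wise.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the same empirical distribution.

    The reference distribution is the vector of per-rank row means over the
    sorted columns; each value is replaced by the reference quantile of its
    within-column rank.  Ties receive the mean of the tied reference
    quantiles (average ranks, linearly interpolated), which keeps the
    operation deterministic and idempotent.

    Raises
    ------
    DataError
        If the matrix contains missing values (impute or drop first) or is
        empty.
    """
    if m.n_features < 1 or m.n_samples < 1:
        raise DataError("quantile normalization needs >=1 feature and >=1 sample")
    if m.has_missing():
        raise DataError(
            "matrix contains missing values; impute or drop them before "
            "quantile normalization"
        )
    x = m.values.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    # average ranks, computed per column; np.interp at half-ranks yields the
    # mean of the two adjacent reference quantiles
    from scipy.stats import rankdata

    ranks = rankdata(x, method="average", axis=0)
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def map_probes(
    m: ExpressionMatrix, probe_map: Mapping[str, Iterable[str]]
) -> ExpressionMatrix:
    """Collapse probe-level rows to mature miRNA rows.

    Probes mapping to several miRNAs are ambiguous and removed; probes
    mapping to none are dropped.  When several probes measure one miRNA the
    per-sample median is used.

    Raises
    ------
    DataError
        If no probe survives ("no mappable probes").
    """
    assign: dict[str, str] = {}
    for probe in m.feature_ids:
        targets = list(probe_map.get(probe, ()))
        if len(targets) == 1:
            assign[probe] = targets[0]
    if not assign:
        raise DataError("no mappable probes: every probe maps to 0 or >1 miRNAs")
    kept = m.values.loc[list(assign)]
    collapsed = kept.groupby([assign[p] for p in kept.index]).median()
    collapsed.index.name = m.values.index.name
    return m.with_values(collapsed)


def intersect_datasets(datasets: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate same-species datasets over their common features.

    Every dataset is expected to be normalized (and probe-collapsed) already;
    features are the intersection across all datasets, samples the
    concatenation.  Sample IDs are prefixed with the dataset ID whenever they
    would otherwise collide.
    """
    if not datasets:
        raise DataError("need at least one dataset")
    species = {d.species for d in datasets}
    if len(species) > 1:
        raise DataError(f"datasets mix species: {sorted(species)}")
    common = [f for f in datasets[0].feature_ids if all(f in d.values.index for d in datasets[1:])]
    if not common:
        counts = {d.dataset_id or i: d.n_features for i, d in enumerate(datasets)}
        raise DataError(f"empty feature intersection; per-dataset feature counts: {counts}")
    blocks = []
    seen: set[str] = set()
    for d in datasets:
        block = d.values.loc[common]
        if seen.intersection(block.columns):
            block = block.rename(columns=lambda c: f"{d.dataset_id}:{c}")
        seen.update(block.columns)
        blocks.append(block)
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(
        merged, species=datasets[0].species, dataset_id="+".join(d.dataset_id for d in datasets)
    )
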