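"""Category-level exclusion and overlap-distance KNN imputation.

Missing behavioral features are handled in two steps.  First, participants
with missing features in more than two of the five feature categories
(personality, location, call, Facebook, person-to-person) are removed.
Second, remaining gaps are filled by a k-nearest-neighbor scheme (k = 7)
whose distance is the mean absolute difference over the overlapping observed
features of two participants:

    d_uv = (1/|L_uv|) * sum_{i in L_uv} |x_i(u) - x_i(v)|,   L_uv = F_u ∩ F_v.

Each missing cell is imputed with the average of the neighbors' non-missing
values for that feature; a single observing neighbor's value is copied
directly.  Features are z-standardized before distance computation so
heterogeneous scales contribute comparably; ties at the k-th neighbor are
broken by ascending participant id, which makes the result independent of
row order.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("personality", "location", "call", "Facebook", "person-to-person")


def default_category_map(columns) -> dict[str, str]:
    """Assign each feature column to one of the five feature categories by
    naming convention (trait names -> personality; channel prefixes map the
    call/text channels to 'call' and the two facebook channels to 'Facebook')."""
    from .cohort_data import TRAIT_COLUMNS

    out = {}
    for col in columns:
        if col in TRAIT_COLUMNS:
            out[col] = "personality"
        elif col.startswith(("location_", "n_unique_loc")):
            out[col] = "location"
        elif col.startswith(("call_", "text_")) or col == "n_texts":
            out[col] = "call"
        elif col.startswith("facebook_"):
            out[col] = "Facebook"
        elif col.startswith("proximity_"):
            out[col] = "person-to-person"
        else:
            raise ValueError(f"cannot assign feature {col!r} to a category")
    return out


def category_filter(
    table: pd.DataFrame, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Remove participants with missing features in more than two of the five
    categories.  A category counts as missing when *all* of its features are
    missing for the participant (categories with no features in the table
    count as missing for everyone)."""
    if category_map is None:
        category_map = default_category_map(table.columns)
    missing_cats = pd.Series(0, index=table.index)
    for cat in CATEGORIES:
        cols = [c for c in table.columns if category_map.get(c) == cat]
        if not cols:
            missing_cats += 1
            continue
        missing_cats += table[cols].isna().all(axis=1).astype(int)
    return table.loc[missing_cats <= 2].copy()


def overlap_distance(u, v) -> float:
    """Mean absolute difference over the overlap of observed features.

    Returns +inf for an empty overlap (incomparable participants).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    both = ~np.isnan(u) & ~np.isnan(v)
    if not both.any():
        return float("inf")
    return float(np.mean(np.abs(u[both] - v[both])))


def _pairwise_overlap_distances(x: np.ndarray) -> np.ndarray:
    """All-pairs overlap distance matrix; inf where overlap is empty,
    diagonal inf (a participant is not its own neighbor)."""
    n = x.shape[0]
    mask = ~np.isnan(x)
    xz = np.where(mask, x, 0.0)
    dist = np.empty((n, n))
    for i in range(n):
        both = mask[i] & mask
        diff = np.abs(xz[i] - xz) * both
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.where(cnt > 0, diff.sum(axis=1) / cnt, np.inf)
    np.fill_diagonal(dist, np.inf)
    return dist


def knn_impute(
    table: pd.DataFrame,
    k: int = 7,
    standardize: bool = True,
    return_log: bool = False,
):
    """Fill every missing cell from the k nearest comparable neighbors.

    Neighbors are ranked by overlap distance on (optionally z-standardized)
    features, ties broken by ascending participant id; the same k neighbors
    serve all of a participant's missing features.  A feature observed by no
    neighbor falls back to the cohort mean of that feature (logged).
    Observed cells are never altered.
    """
    order = np.argsort(table.index.astype(str))
    sorted_table = table.iloc[order]
    x = sorted_table.to_numpy(dtype=float)
    n, p = x.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(x, axis=0)
        col_sd = np.nanstd(x, axis=0, ddof=1)
    if standardize:
        col_sd = np.where((col_sd == 0) | np.isnan(col_sd), 1.0, col_sd)
        xs = (x - col_mean) / col_sd
    else:
        xs = x
    dist = _pairwise_overlap_distances(xs)

    filled = x.copy()
    log: list[dict] = []
    ids = sorted_table.index.to_list()
    for i in range(n):
        miss = np.where(np.isnan(x[i]))[0]
        if len(miss) == 0:
            continue
        finite = np.where(np.isfinite(dist[i]))[0]
        if len(finite) == 0:
            raise ValueError(f"participant {ids[i]!r} has no comparable neighbor")
        nb = finite[np.lexsort((finite, dist[i, finite]))][:k]
        for j in miss:
            vals = x[nb, j]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                value, source = float(col_mean[j]), "cohort_mean"
                logger.warning(
                    "no neighbor observes %s for %s; cohort mean used",
                    sorted_table.columns[j], ids[i],
                )
            else:
                value = float(vals.mean())
                source = f"{len(vals)}_neighbors"
            filled[i, j] = value
            log.append(
                {"id": ids[i], "feature": sorted_table.columns[j],
                 "value": value, "source": source}
            )
    out = pd.DataFrame(filled, index=sorted_table.index, columns=sorted_table.columns)
    out = out.loc[table.index]  # restore caller's row order
    if return_log:
        return out, log
    return out
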