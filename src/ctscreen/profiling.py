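"""Landmark expression-profile analysis: quantile normalization, replicate-
averaged log2 fold change versus matched vehicle, and two-group marker
selection.

Marker selection scores each gene with the signal-to-noise ratio

    score = (mean_A - mean_B) / (sd_A + sd_B),

with each group SD floored at max(0.2 * |group mean|, 1e-8) so near-constant
genes cannot blow up the ratio; a Welch-t-like statistic is available as an
alternative.  Ranks run 1..n_genes in descending score order, with ties
broken by mean difference and then by gene label.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

SD_FLOOR_FRACTION = 0.2
SD_FLOOR_ABS = 1e-8


class ProfilingError(ValueError):
    """Invalid input to a profiling operation."""


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common quantile distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values, so after normalization all columns share one
    sorted value vector.  Idempotent; labels preserved.  Ties are resolved
    by stable sort order (first occurrence gets the smaller quantile).
    """
    if matrix.shape[1] < 2:
        raise ProfilingError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_values = np.take_along_axis(values, order, axis=0)
    reference = sorted_values.mean(axis=1)
    out = np.empty_like(values)
    np.put_along_axis(out, order, reference[:, None], axis=0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"treatment", "is_vehicle"}
    if not required.issubset(design.columns):
        raise ProfilingError(f"design missing columns {sorted(required - set(design.columns))}")
    d = design.copy()
    if "timepoint" not in d.columns:
        d["timepoint"] = ""
    if "dose" not in d.columns:
        d["dose"] = np.nan
    return d


def lfc(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-condition mean log2 fold change versus matched vehicle.

    For each (treatment, dose, timepoint) stratum with ``is_vehicle=False``,
    LFC = mean over replicates of log2(value) minus the mean log2 of the
    vehicle samples at the same timepoint.  Requires strictly positive
    values; a condition without a matched vehicle stratum is an error, and
    vehicle-vs-itself LFC is 0 by construction.
    """
    if (matrix.to_numpy() <= 0).any():
        raise ProfilingError("LFC needs strictly positive expression values")
    design = _check_design(design)
    unknown = set(design.index) - set(matrix.columns)
    if unknown:
        raise ProfilingError(f"design samples absent from matrix: {sorted(unknown)}")
    log2 = np.log2(matrix)
    vehicle_mean: dict[object, pd.Series] = {}
    for timepoint, sub in design[design["is_vehicle"]].groupby("timepoint"):
        vehicle_mean[timepoint] = log2[list(sub.index)].mean(axis=1)
    out: dict[str, pd.Series] = {}
    treated = design[~design["is_vehicle"]]
    for (treatment, dose, timepoint), sub in treated.groupby(
        ["treatment", "dose", "timepoint"], dropna=False
    ):
        if timepoint not in vehicle_mean:
            raise ProfilingError(
                f"condition {treatment!r} at timepoint {timepoint!r} has no matched vehicle"
            )
        label = str(treatment)
        if pd.notna(dose):
            label += f"_{dose:g}uM"
        if timepoint != "":
            label += f"_{timepoint}"
        out[label] = log2[list(sub.index)].mean(axis=1) - vehicle_mean[timepoint]
    if not out:
        raise ProfilingError("design contains no non-vehicle condition")
    result = pd.DataFrame(out)
    result.index.name = matrix.index.name
    return result


def _group_stats(values: pd.DataFrame, samples: Sequence[str]) -> tuple[pd.Series, pd.Series]:
    samples = list(samples)
    missing = set(samples) - set(values.columns)
    if missing:
        raise ProfilingError(f"group samples absent from matrix: {sorted(missing)}")
    if len(samples) < 2:
        raise ProfilingError("each group needs >= 2 samples for dispersion terms")
    sub = values[samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    floor = np.maximum(SD_FLOOR_FRACTION * mean.abs(), SD_FLOOR_ABS)
    return mean, np.maximum(sd, floor)


def marker_selection(
    values: pd.DataFrame,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    statistic: str = "snr",
) -> pd.DataFrame:
    """Rank genes by between-group difference in response.

    ``values`` may be an LFC matrix or (log) expression matrix; columns are
    samples.  Returns a frame indexed by gene with ``score``, ``mean_a``,
    ``mean_b`` and ``rank`` (1 = strongest positive A-over-B difference),
    sorted by rank.  Swapping the groups negates every score and reverses
    the ranking.
    """
    if statistic not in ("snr", "ttest"):
        raise ProfilingError(f"unknown marker statistic {statistic!r}")
    if set(group_a_samples) & set(group_b_samples):
        raise ProfilingError("groups overlap")
    mean_a, sd_a = _group_stats(values, group_a_samples)
    mean_b, sd_b = _group_stats(values, group_b_samples)
    diff = mean_a - mean_b
    if statistic == "snr":
        score = diff / (sd_a + sd_b)
    else:
        na, nb = len(group_a_samples), len(group_b_samples)
        score = diff / np.sqrt(sd_a**2 / na + sd_b**2 / nb)
    out = pd.DataFrame({"score": score, "mean_a": mean_a, "mean_b": mean_b, "diff": diff})
    gene_col = values.index.name or "gene"
    order = out.rename_axis(gene_col).reset_index().sort_values(
        ["score", "diff", gene_col],
        ascending=[False, False, True],
        kind="stable",
    )
    order["rank"] = np.arange(1, len(order) + 1)
    order = order.set_index(gene_col)
    return order[["score", "mean_a", "mean_b", "diff", "rank"]]


def top_markers(scores: pd.DataFrame, n_each_tail: int) -> list[str]:
    """The ``n`` highest- and ``n`` lowest-scoring genes, in rank order."""
    if n_each_tail < 0:
        raise ProfilingError("n_each_tail must be >= 0")
    if 2 * n_each_tail > len(scores):
        raise ProfilingError(
            f"n_each_tail {n_each_tail} exceeds half of {len(scores)} genes"
        )
    if n_each_tail == 0:
        return []
    ordered = scores.sort_values("rank").index.tolist()
    return ordered[:n_each_tail] + ordered[-n_each_tail:]


def marker_permutation_pvalues(
    values: pd.DataFrame,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    statistic: str = "snr",
) -> pd.Series:
    """Two-sided sample-label permutation p-values for the marker scores."""
    observed = marker_selection(values, group_a_samples, group_b_samples, statistic)["score"]
    pool = list(group_a_samples) + list(group_b_samples)
    na = len(group_a_samples)
    rng = np.random.default_rng(seed)
    exceed = pd.Series(0, index=observed.index, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permutation(pool)
        score = marker_selection(values, perm[:na], perm[na:], statistic)["score"]
        exceed += (score.abs().loc[observed.index] >= observed.abs()).astype(float)
    return (exceed + 1.0) / (n_permutations + 1.0)
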