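"""Proteome matrix quality control, replicate merging, imputation, RINT.

The QC chain mirrors a DIA proteomics GWAS workflow: drop samples with a low
number of protein identifications (below 80% of the cohort median), drop
features with missingness over 80%, merge duplicate runs of the same
specimen (cross-fill missing values, then average) gated on replicate
Pearson correlation > 0.8, impute remaining missing cells with half the
per-feature minimum, and rank-inverse-normalize each feature before GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProteomeMatrix:
    """Samples x features abundance table; NaN marks missing.

    ``log`` records each QC step applied (name plus removal counts), giving a
    provenance trail for the final analysis matrix.
    """

    values: pd.DataFrame
    log: list = field(default_factory=list)

    @property
    def samples(self):
        return list(self.values.index)

    @property
    def features(self):
        return list(self.values.columns)

    def _logged(self, values: pd.DataFrame, entry: dict) -> "ProteomeMatrix":
        return ProteomeMatrix(values, self.log + [entry])


def filter_low_id_samples(matrix: ProteomeMatrix, fraction: float = 0.8) -> ProteomeMatrix:
    """Remove samples whose identification count is below ``fraction`` of the median.

    The cutoff is strict: a sample is dropped iff its non-missing feature
    count < fraction * median(counts). A single sample defines the median and
    is always kept.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix has no samples")
    counts = matrix.values.notna().sum(axis=1)
    cut = fraction * counts.median()
    keep = counts >= cut
    if not keep.any():
        raise ValueError(
            f"all samples fall below {fraction:.0%} of median identifications ({cut:.1f})"
        )
    removed = list(matrix.values.index[~keep])
    return matrix._logged(
        matrix.values.loc[keep],
        {"step": "filter_low_id_samples", "cutoff": float(cut), "removed": removed},
    )


def filter_high_missing_features(matrix: ProteomeMatrix, max_missing: float = 0.8) -> ProteomeMatrix:
    """Remove features with missing fraction strictly over ``max_missing``."""
    if matrix.values.size == 0:
        raise ValueError("matrix is empty")
    miss = matrix.values.isna().mean(axis=0)
    keep = miss <= max_missing
    removed = list(matrix.values.columns[~keep])
    return matrix._logged(
        matrix.values.loc[:, keep],
        {"step": "filter_high_missing_features", "max_missing": max_missing, "removed": removed},
    )


def merge_replicates(
    run_matrix: pd.DataFrame,
    replicate_map: dict,
    min_r: float = 0.8,
    min_shared: int = 3,
) -> ProteomeMatrix:
    """Collapse run-level rows to one row per specimen.

    For a replicate pair, Pearson r is computed on jointly observed features;
    if r > ``min_r`` the two runs fill each other's missing cells and are
    averaged. Pairs with r <= ``min_r``, or with fewer than ``min_shared``
    jointly observed features (r undefined or degenerate), are excluded and
    logged. Singleton runs pass through unchanged.
    """
    rows, excluded = {}, []
    for sample, runs in replicate_map.items():
        if len(runs) not in (1, 2):
            raise ValueError(f"{sample}: replicate map entries must list 1 or 2 runs")
        if len(runs) == 1:
            rows[sample] = run_matrix.loc[runs[0]]
            continue
        a, b = run_matrix.loc[runs[0]], run_matrix.loc[runs[1]]
        both = a.notna() & b.notna()
        if both.sum() < min_shared:
            excluded.append({"sample": sample, "reason": "too_few_shared", "n_shared": int(both.sum())})
            continue
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(a[both], b[both])[0, 1]
        if not np.isfinite(r) or r <= min_r:
            excluded.append({"sample": sample, "reason": "low_correlation", "r": None if not np.isfinite(r) else float(r)})
            continue
        # cross-fill then average == elementwise mean over available runs
        rows[sample] = pd.concat([a, b], axis=1).mean(axis=1, skipna=True)
    order = [s for s in replicate_map if s in rows]
    merged = pd.DataFrame(
        [rows[s].to_numpy() for s in order] if order else None,
        index=order, columns=run_matrix.columns, dtype=float,
    )
    return ProteomeMatrix(
        merged, [{"step": "merge_replicates", "min_r": min_r, "excluded": excluded}]
    )


def impute_half_min(matrix: ProteomeMatrix) -> ProteomeMatrix:
    """Replace every missing cell of a feature by half its minimum observed value."""
    vals = matrix.values.copy()
    mins = vals.min(axis=0, skipna=True)
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])
        raise ValueError(f"features with no observed values: {bad}")
    n_missing = int(vals.isna().to_numpy().sum())
    vals = vals.fillna(mins / 2.0)
    return matrix._logged(vals, {"step": "impute_half_min", "n_imputed": n_missing})


def rint(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps value with (average, for ties) rank r among n to
    ``Phi^-1((r - c) / (n - 2c + 1))``. Invariant to strictly monotone
    transforms of the input; output is symmetric around 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rint expects a 1-D array")
    if x.size < 2:
        raise ValueError("rint needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("rint requires finite values")
    if np.all(x == x[0]):
        raise ValueError("all values identical: rank transform degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (x.size - 2 * c + 1))


def rint_matrix(matrix: ProteomeMatrix) -> ProteomeMatrix:
    """Apply :func:`rint` to every feature column (requires a complete matrix)."""
    if matrix.values.isna().any().any():
        raise ValueError("rint_matrix requires imputation first (missing cells present)")
    out = matrix.values.apply(lambda col: rint(col.to_numpy()), axis=0)
    return matrix._logged(out, {"step": "rint"})


def run_qc(
    run_matrix: pd.DataFrame,
    replicate_map: dict,
    sample_fraction: float = 0.8,
    feature_max_missing: float = 0.8,
    min_r: float = 0.8,
) -> ProteomeMatrix:
    """Full QC chain: merge replicates, sample filter, feature filter, imputation, RINT."""
    m = merge_replicates(run_matrix, replicate_map, min_r=min_r)
    m = filter_low_id_samples(m, fraction=sample_fraction)
    m = filter_high_missing_features(m, max_missing=feature_max_missing)
    m = impute_half_min(m)
    return rint_matrix(m)
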