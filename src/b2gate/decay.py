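"""Transcript-stability statistics under transcription inhibition.

With Pol II elongation frozen by DRB, the change in transcript abundance
between reader-knockdown and control embryos reflects decay alone: targets
of a decay-promoting reader are stabilized (positive log2 fold change).
This module provides median-of-ratios library normalization, pseudocounted
log2 fold changes, stratification of genes by m6A mark and reader binding,
and ECDF comparison of the strata with the two-sample Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation, GenomicInterval

PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (DESeq-style).

    For features positive in every sample, factor_j = median_i of
    count_ij / geometric_mean_i(counts).  Raises when no feature is positive
    everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with all-positive counts; cannot estimate size factors")
    sub = mat[positive]
    gm = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / gm[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def log2_fold_change(
    counts: pd.DataFrame,
    numerator_samples: Sequence[str],
    denominator_samples: Sequence[str],
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-feature log2((mean normalized num + 0.5) / (mean normalized den + 0.5))."""
    num = [s for s in numerator_samples if s in counts.columns]
    den = [s for s in denominator_samples if s in counts.columns]
    if not num or not den:
        raise ValueError("both contrast groups must have at least one sample")
    norm = normalize_counts(counts, factors)
    m_num = norm[num].mean(axis=1)
    m_den = norm[den].mean(axis=1)
    lfc = np.log2(m_num + PSEUDOCOUNT) - np.log2(m_den + PSEUDOCOUNT)
    lfc.name = "log2fc"
    return lfc


def stratify_features(
    ann: GenomeAnnotation,
    m6a_peaks: Sequence[GenomicInterval],
    lace_targets: Set[str],
) -> pd.DataFrame:
    """Label genes by m6A mark and reader-binding status.

    A gene is ``m6a_modified`` when at least one m6A peak overlaps its
    exonic span (intronic peaks do not count); ``df_target`` follows set
    membership.  Target ids absent from the annotation trigger a warning and
    are ignored.
    """
    known = {g.gene_id for g in ann.genes}
    unknown = set(lace_targets) - known
    if unknown:
        warnings.warn(f"{len(unknown)} target gene ids not in annotation; ignored")
    rows = []
    for g in ann.genes:
        modified = False
        for peak in m6a_peaks:
            if any(peak.overlaps(e) for e in g.exons):
                modified = True
                break
        rows.append(
            {
                "gene_id": g.gene_id,
                "m6a_modified": modified,
                "df_target": g.gene_id in lace_targets,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def ks_compare(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample KS test (asymptotic p); requires n >= 5 per group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs at least 5 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ecdf_table(values: Sequence[float]) -> pd.DataFrame:
    """Sorted values with cumulative fractions, for plotting ECDFs."""
    v = np.sort(np.asarray(values, dtype=float))
    frac = np.arange(1, len(v) + 1) / len(v)
    return pd.DataFrame({"value": v, "cum_frac": frac})


@dataclass
class StabilityResult:
    """KS comparison of one stratification of per-gene fold changes."""

    comparison: str  # e.g. "m6a_modified_vs_unmodified"
    n_a: int
    n_b: int
    median_shift: float  # median(group_a) - median(group_b)
    ks_d: float
    ks_p: float


def stability_report(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    ann: GenomeAnnotation,
    m6a_peaks: Sequence[GenomicInterval],
    lace_targets: Set[str],
    kd_condition: str = "kd_drb",
    ctrl_condition: str = "control_drb",
) -> Tuple[pd.DataFrame, List[StabilityResult], Dict[str, pd.DataFrame]]:
    """Normalized fold changes per gene, strata labels, KS tests and ECDFs.

    ``samples`` is indexed by sample id with a ``condition`` column; the
    contrast is knockdown vs control, both under DRB.  Returns the per-gene
    table, the KS summaries, and per-stratum ECDF tables.
    """
    for cond in (kd_condition, ctrl_condition):
        if not (samples.condition == cond).any():
            raise ValueError(f"no samples with condition {cond!r}")
    kd = list(samples.index[samples.condition == kd_condition])
    ctrl = list(samples.index[samples.condition == ctrl_condition])
    lfc = log2_fold_change(counts, kd, ctrl)
    labels = stratify_features(ann, m6a_peaks, lace_targets)
    genes = labels.index.intersection(lfc.index)
    table = labels.loc[genes].copy()
    table["log2fc"] = lfc.loc[genes]

    results: List[StabilityResult] = []
    ecdfs: Dict[str, pd.DataFrame] = {}
    comparisons = [
        ("m6a_modified_vs_unmodified", table.m6a_modified),
        ("target_vs_nontarget", table.df_target),
    ]
    for name, mask in comparisons:
        a = table.loc[mask, "log2fc"].to_numpy()
        b = table.loc[~mask, "log2fc"].to_numpy()
        if len(a) < 5 or len(b) < 5:
            continue
        d, p = ks_compare(a, b)
        results.append(
            StabilityResult(
                comparison=name,
                n_a=len(a),
                n_b=len(b),
                median_shift=float(np.median(a) - np.median(b)),
                ks_d=d,
                ks_p=p,
            )
        )
        pos, neg = name.split("_vs_")
        ecdfs[pos] = ecdf_table(a)
        ecdfs[neg] = ecdf_table(b)
    return table, results, ecdfs
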