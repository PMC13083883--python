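"""Developmental stage-pattern classification of gene expression.

Genes profiled across the nine preimplantation stages (MII oocyte through
blastocyst) are averaged per stage, z-scored, clustered hierarchically on
Pearson-correlation distance, and each module is assigned to one of 13
stage-related classes (maternal programs, minor/major zygotic genome
activation, 2-cell transient, mid-/late-preimplantation activation, and
related decay/constitutive patterns) by correlation against shipped
template z-vectors.  The exact 13 template shapes are a declared convention
of this package: the class names follow common MZT usage, the vectors are
unit-peak/step interpretations over the nine stages.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .decay import normalize_counts

logger = logging.getLogger(__name__)

STAGES = ("MII", "Zygote", "E2C", "M2C", "L2C", "4C", "8C", "MO", "BL")

N_CLASSES = 13

# Raw template shapes over the 9 stages; z-normalized on access.  Chosen so
# that all pairwise correlations stay below the module-merge threshold.
_TEMPLATE_SHAPES: Dict[str, List[float]] = {
    "maternal": [1, 0.9, 0.6, 0.35, 0.15, 0.05, 0.02, 0, 0],
    "maternal_early_decay": [1, 0.2, 0, 0, 0, 0, 0, 0, 0],
    "minor_zga": [0.05, 0.7, 1, 0.6, 0.25, 0.1, 0.05, 0, 0],
    "major_zga": [0, 0, 0.1, 0.5, 1, 0.7, 0.45, 0.3, 0.2],
    "two_cell_transient": [0, 0, 0.6, 1, 0.6, 0.05, 0, 0, 0],
    "mga": [0, 0, 0, 0.05, 0.3, 1, 0.95, 0.4, 0.15],
    "lga_morula": [0, 0, 0, 0, 0.05, 0.25, 0.55, 1, 0.55],
    "lga_blastocyst": [0, 0, 0, 0, 0, 0.05, 0.2, 0.5, 1],
    "biphasic": [1, 0.55, 0.15, 0.02, 0, 0.1, 0.35, 0.7, 1],
    "mid_decay": [0.8, 0.95, 1, 1, 0.95, 0.6, 0.25, 0.05, 0],
    "late_decay": [0.6, 0.7, 0.8, 0.9, 1, 1, 0.95, 0.4, 0.05],
    "constitutive": [0.5, 0.62, 0.52, 0.64, 0.54, 0.66, 0.56, 0.68, 0.58],
    "others": [1, 0.2, 0.9, 0.3, 1, 0.2, 0.9, 0.3, 1],
}

FALLBACK_CLASS = "others"
MIN_TEMPLATE_CORR = 0.5


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    return df.sub(mean, axis=0).div(sd, axis=0)


def default_templates() -> pd.DataFrame:
    """The 13 shipped class templates as z-scored vectors (class x stage)."""
    raw = pd.DataFrame(_TEMPLATE_SHAPES, index=STAGES).T
    return zscore_rows(raw)


def build_profiles(
    counts: pd.DataFrame, sample_stages: Mapping[str, str], normalize: bool = True
) -> pd.DataFrame:
    """Per-gene z-scored stage-mean expression profiles.

    Counts are median-of-ratios normalized, averaged within each stage
    (every stage must have at least one sample) and z-scored per gene.
    Constant genes cannot be z-scored and are dropped with a log message.
    """
    stage_of = pd.Series({s: sample_stages[s] for s in counts.columns})
    for stage in STAGES:
        if not (stage_of == stage).any():
            raise ValueError(f"no samples for stage {stage}")
    norm = normalize_counts(counts) if normalize else counts.astype(float)
    means = pd.DataFrame(
        {stage: norm.loc[:, stage_of.index[stage_of == stage]].mean(axis=1) for stage in STAGES}
    )
    sd = means.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.info("excluding %d constant gene(s) from stage profiles", int(constant.sum()))
        means = means.loc[~constant]
    return zscore_rows(means)


def _eigenpattern(profiles: pd.DataFrame, members: Sequence[str]) -> np.ndarray:
    v = profiles.loc[list(members)].mean(axis=0).to_numpy()
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def cluster_profiles(
    profiles: pd.DataFrame,
    cut_height: float = 0.2,
    merge_corr: float = 0.8,
) -> Dict[int, List[str]]:
    """Average-linkage clustering on 1 - Pearson correlation distance.

    The tree is cut at ``cut_height``; modules whose eigenpatterns (mean
    z-profiles) correlate above ``merge_corr`` are then merged iteratively,
    always joining the currently most-correlated pair, until stable.  Module
    ids are renumbered deterministically by first gene in the input order.
    """
    if len(profiles) < 2:
        return {1: list(profiles.index)}
    X = profiles.to_numpy(float)
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # exact symmetry for squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    modules: Dict[int, List[str]] = {}
    for gene, lab in zip(profiles.index, labels):
        modules.setdefault(int(lab), []).append(gene)

    # Iteratively merge the currently most-correlated eigenpattern pair.
    gene_pos = {g: i for i, g in enumerate(profiles.index)}
    keys = sorted(modules)
    sums = np.array([X[[gene_pos[g] for g in modules[k]]].sum(axis=0) for k in keys])
    while len(keys) > 1:
        eig = sums - sums.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(eig, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        eig_n = eig / safe[:, None]
        R = eig_n @ eig_n.T
        R[norms == 0, :] = -np.inf
        R[:, norms == 0] = -np.inf
        np.fill_diagonal(R, -np.inf)
        i, j = np.unravel_index(int(R.argmax()), R.shape)
        if R[i, j] <= merge_corr:
            break
        a, b = keys[i], keys[j]
        modules[a] = modules[a] + modules[b]
        del modules[b]
        sums[i] = sums[i] + sums[j]
        sums = np.delete(sums, j, axis=0)
        keys = keys[:j] + keys[j + 1 :]

    order = {k: min(profiles.index.get_loc(g) for g in v) for k, v in modules.items()}
    renumbered = {}
    for new_id, k in enumerate(sorted(modules, key=lambda k: order[k]), start=1):
        renumbered[new_id] = sorted(modules[k], key=profiles.index.get_loc)
    return renumbered


def assign_classes(
    modules: Dict[int, List[str]],
    profiles: pd.DataFrame,
    templates: pd.DataFrame | None = None,
    allow_custom: bool = False,
) -> pd.Series:
    """Assign each module (hence each gene) to its best-correlated class.

    Modules with maximal template correlation below ``MIN_TEMPLATE_CORR``
    fall back to ``others``.  Exactly 13 templates are required unless
    ``allow_custom``.
    """
    if templates is None:
        templates = default_templates()
    if len(templates) != N_CLASSES and not allow_custom:
        raise ValueError(f"expected {N_CLASSES} templates, got {len(templates)}")
    T = templates.to_numpy(float)
    out = {}
    for mod_id in sorted(modules):
        eig = _eigenpattern(profiles, modules[mod_id])
        if eig.std() == 0:
            cls = FALLBACK_CLASS
        else:
            r = np.array([float(np.corrcoef(eig, t)[0, 1]) for t in T])
            cls = templates.index[int(r.argmax())] if r.max() >= MIN_TEMPLATE_CORR else FALLBACK_CLASS
        for gene in modules[mod_id]:
            out[gene] = cls
    return pd.Series(out, name="stage_class").loc[profiles.index.intersection(out.keys())]


def classify_profiles(
    profiles: pd.DataFrame,
    templates: pd.DataFrame | None = None,
    cut_height: float = 0.2,
    merge_corr: float = 0.8,
) -> pd.Series:
    """Cluster profiles into modules and assign stage classes in one call."""
    modules = cluster_profiles(profiles, cut_height=cut_height, merge_corr=merge_corr)
    return assign_classes(modules, profiles, templates)


def overlap_enrichment(
    gene_set: Set[str],
    class_map: pd.Series,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fisher's exact enrichment of a gene set in each stage class.

    One-sided (enrichment) 2x2 Fisher test per class against the profiled
    universe, BH-adjusted across classes.
    """
    if universe is None:
        universe = list(class_map.index)
    universe = list(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    uset = set(universe)
    gset = set(gene_set) & uset
    rows = []
    for cls in sorted(class_map.unique()):
        members = set(class_map.index[class_map == cls]) & uset
        a = len(gset & members)
        b = len(gset - members)
        c = len(members - gset)
        d = N - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"stage_class": cls, "overlap": a, "set_size": len(gset),
             "class_size": len(members), "odds_ratio": odds, "p": p}
        )
    df = pd.DataFrame(rows).set_index("stage_class")
    df["q"] = multipletests(df.p.to_numpy(), method="fdr_bh")[1]
    return df
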