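"""Transposable-element subfamily quantification and binding enrichment.

Multi-mapping reads are handled by fractional 1/k weighting (k = number of
genomic hits per read), a deliberate simplification of EM redistribution:
each read contributes total weight exactly 1, split across the subfamilies
it overlaps.  Binding enrichment per subfamily is the log2 ratio of the
observed fraction of reader tags over an expected fraction from either the
genomic subfamily footprint or a matched input tag set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decay import PSEUDOCOUNT, size_factors
from .genome import GenomeAnnotation
from .lace import TagSet


def _subfamily_trees(ann: GenomeAnnotation) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for te in ann.tes:
        iv = te.interval
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, te.subfamily)
    return trees


def _hit_subfamilies(trees, contig: str, pos: int) -> List[str]:
    tree = trees.get(contig)
    if tree is None:
        return []
    return sorted({hit.data for hit in tree.at(pos)})


def count_te_reads(tags: TagSet, ann: GenomeAnnotation) -> pd.Series:
    """Fractional subfamily counts from tags with multi-hit multiplicity.

    Each tag row may carry a column ``k`` (genomic hits of the read,
    default 1) and contributes weight 1/k, split evenly across the distinct
    subfamilies overlapping its position.  Unassigned weight (reads outside
    TEs) is returned under ``__not_te__`` so total weight is conserved.
    """
    df = tags.tags
    k = df["k"].to_numpy(float) if "k" in df.columns else np.ones(len(df))
    if (k < 1).any():
        raise ValueError("multiplicity k must be >= 1")
    trees = _subfamily_trees(ann)
    weights: Dict[str, float] = {s: 0.0 for s in ann.subfamilies}
    unassigned = 0.0
    for (contig, pos), w in zip(zip(df.contig, df.pos), 1.0 / k):
        subs = _hit_subfamilies(trees, contig, int(pos))
        if not subs:
            unassigned += w
            continue
        share = w / len(subs)
        for s in subs:
            weights[s] += share
    out = pd.Series(weights, name=tags.sample_id).sort_index()
    out.loc["__not_te__"] = unassigned
    return out


@dataclass
class TEEnrichment:
    subfamily: str
    observed_fraction: float
    expected_fraction: float
    score: float  # log2(observed / expected)


def te_enrichment(
    binding_tags: TagSet,
    ann: GenomeAnnotation,
    background: "TagSet | str" = "genomic",
) -> List[TEEnrichment]:
    """Per-subfamily enrichment of reader tags over a background.

    ``background="genomic"`` uses the genomic footprint (subfamily bp over
    total bp); a :class:`TagSet` background uses its tag fractions.  Zero
    fractions are guarded with pseudofraction 1/(2 * total tags).
    """
    n = binding_tags.library_size
    if n == 0:
        raise ValueError("binding tag set is empty")
    trees = _subfamily_trees(ann)
    obs_counts: Dict[str, float] = {s: 0.0 for s in ann.subfamilies}
    for contig, pos in zip(binding_tags.tags.contig, binding_tags.tags.pos):
        subs = _hit_subfamilies(trees, contig, int(pos))
        if subs:
            share = 1.0 / len(subs)
            for s in subs:
                obs_counts[s] += share

    if isinstance(background, TagSet):
        m = background.library_size
        if m == 0:
            raise ValueError("background tag set is empty")
        exp_counts: Dict[str, float] = {s: 0.0 for s in ann.subfamilies}
        for contig, pos in zip(background.tags.contig, background.tags.pos):
            subs = _hit_subfamilies(trees, contig, int(pos))
            if subs:
                share = 1.0 / len(subs)
                for s in subs:
                    exp_counts[s] += share
        expected = {s: exp_counts[s] / m for s in exp_counts}
        pf_exp = 1.0 / (2 * m)
    else:
        total_bp = sum(ann.contig_lengths.values())
        if total_bp == 0:
            raise ValueError("empty genomic background")
        bp: Dict[str, int] = {s: 0 for s in ann.subfamilies}
        for te in ann.tes:
            bp[te.subfamily] += te.interval.length
        expected = {s: bp[s] / total_bp for s in bp}
        pf_exp = 1.0 / (2 * total_bp)

    pf_obs = 1.0 / (2 * n)
    out = []
    for s in sorted(obs_counts):
        obs = obs_counts[s] / n
        exp = expected[s]
        score = float(np.log2(max(obs, pf_obs) / max(exp, pf_exp)))
        out.append(TEEnrichment(s, obs, exp, score))
    return out


def te_differential(
    te_counts: pd.DataFrame,
    conditions: pd.Series,
    kd_condition: str = "kd",
    ctrl_condition: str = "control",
    size_factor_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simplified differential TE expression: Welch t on log2 normalized counts.

    Median-of-ratios normalization is shared with the gene-level decay
    analysis; pass the full gene+TE matrix as ``size_factor_counts`` so that
    library factors are not distorted when several subfamilies change.  Fold
    changes use pseudocount 0.5 and p values are BH-adjusted across
    subfamilies.  This is a documented stand-in for a full
    negative-binomial model.
    """
    kd = [s for s in te_counts.columns if conditions.get(s) == kd_condition]
    ctrl = [s for s in te_counts.columns if conditions.get(s) == ctrl_condition]
    if len(kd) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per condition")
    basis = te_counts if size_factor_counts is None else size_factor_counts[te_counts.columns]
    factors = size_factors(basis)
    norm = te_counts / factors
    log_norm = np.log2(norm + PSEUDOCOUNT)
    lfc = np.log2(norm[kd].mean(axis=1) + PSEUDOCOUNT) - np.log2(
        norm[ctrl].mean(axis=1) + PSEUDOCOUNT
    )
    pvals = []
    for sub in te_counts.index:
        a = log_norm.loc[sub, kd].to_numpy(float)
        b = log_norm.loc[sub, ctrl].to_numpy(float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            pvals.append(1.0)
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        pvals.append(1.0 if np.isnan(p) else float(p))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "q": qvals}, index=te_counts.index
    )
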