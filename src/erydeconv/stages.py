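"""Erythroblast stage-transition concordance and transition-profile clustering.

Reticulocyte transcripts are remnants of erythroblast transcription, so the
direction of a disease DE gene's change can be compared with the direction of
its normal expression change across the ordered maturation transitions
ProE -> EB -> LB -> Poly -> Ortho.  A decreasing concordance proportion across
transitions indicates heightened differentiation early in erythropoiesis that
fades toward the orthochromatic stage; the decrease is tested with the
chi-square trend-in-proportions test.  Genes are additionally clustered on
their transition log-fold-change profiles with average-linkage hierarchical
clustering under correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .containers import StageTransitionTable
from .stats import trend_in_proportions

__all__ = ["ConcordanceSummary", "concordance", "cluster_by_transition_profile"]

#: label for genes with a constant transition profile (undefined correlation)
FLAT_CLUSTER = 0


@dataclass
class ConcordanceSummary:
    """Per-transition concordance proportions and the trend test."""

    table: pd.DataFrame  # index = transition; n_evaluable, n_concordant, proportion
    trend_chi2: float
    trend_p: float


def concordance(de: pd.DataFrame, stages: StageTransitionTable) -> ConcordanceSummary:
    """Directional concordance of DE genes with each stage transition.

    For each transition, evaluable genes are DE genes with a significant
    transition change; a gene is concordant when its DE direction matches the
    transition direction.  The ordered proportions are tested for trend via
    the Cochran–Armitage chi-square with evaluable-n weights and scores 1..4.
    Transitions with zero evaluable genes are flagged (NaN proportion) and
    excluded from the trend with a warning.
    """
    common = de.index.intersection(stages.gene_ids)
    if common.empty:
        raise ValueError("DE gene set and stage table share no genes")
    de_dir = de.loc[common, "direction"].astype(float)
    de_dir = de_dir[de_dir != 0]
    rows = []
    for t in stages.transitions:
        d = stages.direction(t).reindex(de_dir.index)
        evaluable = d != 0
        n_eval = int(evaluable.sum())
        n_conc = int((d[evaluable] == de_dir[evaluable]).sum())
        prop = n_conc / n_eval if n_eval else np.nan
        rows.append((t, n_eval, n_conc, prop))
    table = pd.DataFrame(rows, columns=["transition", "n_evaluable", "n_concordant",
                                        "proportion"]).set_index("transition")
    usable = table["n_evaluable"] > 0
    if not usable.all():
        warnings.warn("transitions with zero evaluable genes excluded from trend test")
    if usable.sum() >= 2:
        scores = 1.0 + np.flatnonzero(usable.to_numpy())
        chi2, p = trend_in_proportions(table.loc[usable, "n_concordant"].to_numpy(),
                                       table.loc[usable, "n_evaluable"].to_numpy(),
                                       scores=scores)
    else:
        chi2, p = np.nan, np.nan
    return ConcordanceSummary(table=table, trend_chi2=chi2, trend_p=p)


def cluster_by_transition_profile(gene_ids, stages: StageTransitionTable,
                                  k: int) -> tuple[pd.Series, pd.DataFrame]:
    """Average-linkage hierarchical clustering on 1 - Pearson r of profiles.

    Genes whose transition log-fold-change profile is constant (zero variance,
    undefined correlation) are assigned to the dedicated flat cluster 0 and
    excluded from the distance computation.  Returns per-gene cluster labels
    (1..k, or 0 for flat) and per-cluster mean profiles.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    effects = stages.effects()
    if effects.shape[1] < 2:
        raise ValueError("each gene needs >= 2 transition effect values")
    genes = [g for g in gene_ids if g in effects.index]
    if not genes:
        raise ValueError("no requested genes in the stage table")
    prof = effects.loc[genes].to_numpy(float)
    if np.isnan(prof).any():
        raise ValueError("missing transition effects; impute or drop genes first")
    var = prof.var(axis=1)
    flat = var == 0
    labels = pd.Series(FLAT_CLUSTER, index=pd.Index(genes), name="cluster", dtype=int)
    active = np.flatnonzero(~flat)
    if active.size:
        if active.size == 1:
            labels.iloc[active] = 1
        else:
            Z = sch.linkage(prof[active], method="average", metric="correlation")
            cut = sch.fcluster(Z, t=min(k, active.size), criterion="maxclust")
            labels.iloc[active] = cut
    profiles = (pd.DataFrame(prof, index=labels.index, columns=effects.columns)
                .groupby(labels).mean())
    return labels, profiles
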