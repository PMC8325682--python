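"""Reference-gene expression-stability ranking.

Five statistics are computed from a genes x samples matrix of
biological-replicate-mean Ct values, each re-implemented from the method's
original description:

* **CV%** — coefficient of variation of each gene's Ct values; the crudest
  screen, sensitive only to overall spread.
* **Delta-Ct** — mean, over all partner genes, of the SD across samples of
  the pairwise Ct difference; a gene co-varying with the panel scores low.
* **BestKeeper** — per-sample geometric mean of all candidate Cts forms the
  BestKeeper index; each gene reports its Ct SD, CV, and Pearson r with
  the index, ranked by SD.
* **NormFinder** — Ct values are sample-centered (per-sample mean across
  genes subtracted); stability combines the within-group SD of the
  residuals with the between-group deviation of their means,
  rho_g = mean_k(|d_gk| + s_gk / sqrt(n_k)); without groups, rho is simply
  the SD of the residuals.
* **geNorm M** — relative quantities Q = base^(minCt - Ct); M_g is the
  mean SD of log2 pairwise quantity ratios; genes are excluded stepwise
  from the worst M, and the pairwise variation V_{n/n+1} between
  normalization factors built from the n and n+1 best genes decides how
  many reference genes suffice (V < 0.15).

Ranks (1 = most stable, average ranks on ties) are aggregated
RefFinder-style as the geometric mean of each gene's per-method ranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curve_optimization import mean_tech_reps

__all__ = [
    "PairwiseVariationSeries",
    "StabilityReport",
    "ct_matrix",
    "cv_ranking",
    "deltact_stability",
    "bestkeeper",
    "normfinder",
    "genorm_m",
    "genorm_v",
    "aggregate_ranking",
    "stability_report",
]

V_THRESHOLD = 0.15


@dataclass
class PairwiseVariationSeries:
    """geNorm V_{n/n+1} series and the implied optimal panel size."""

    genes: tuple[str, ...]  # geNorm ranking, best first
    v: tuple[float, ...]  # V_{n/n+1} for n = 2 .. G-1
    threshold: float = V_THRESHOLD

    @property
    def optimal_n(self) -> int | None:
        """Smallest n with V_{n/n+1} < threshold, or None if all exceed it."""
        for i, value in enumerate(self.v):
            if value < self.threshold:
                return i + 2
        return None


@dataclass
class StabilityReport:
    """Per-gene statistics, per-method ranks, and the aggregate ranking."""

    table: pd.DataFrame  # indexed by gene
    v_series: PairwiseVariationSeries
    genorm_order: tuple[str, ...]

    def final_ranking(self) -> list[str]:
        return list(self.table.sort_values("final_rank").index)


def ct_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long Ct table to genes x observations of bio-rep-mean Ct.

    Technical replicates are collapsed first; each observation column is
    one (sample, biological replicate).
    """
    collapsed = mean_tech_reps(table)
    wide = collapsed.pivot_table(
        index="gene",
        columns=["sample_id", "bio_rep"],
        values="ct",
        aggfunc="mean",
        dropna=False,
    )
    return wide


def observation_groups(table: pd.DataFrame) -> dict[tuple, str]:
    """Map each (sample_id, bio_rep) observation to its group label."""
    collapsed = mean_tech_reps(table)
    sub = collapsed.drop_duplicates(subset=["sample_id", "bio_rep"])
    return {
        (row.sample_id, row.bio_rep): row.group for row in sub.itertuples()
    }


def _rank_ascending(series: pd.Series) -> pd.Series:
    """Rank with average ranks on ties (1 = smallest = most stable)."""
    return pd.Series(
        stats.rankdata(series.values, method="average"), index=series.index
    )


def cv_ranking(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene CV% of Ct across observations (sample SD / mean * 100)."""
    out = {}
    for gene, row in matrix.iterrows():
        vals = row.dropna().astype(float)
        if len(vals) < 2:
            continue
        out[gene] = 100.0 * vals.std(ddof=1) / vals.mean()
    return pd.Series(out, name="cv_pct")


def deltact_stability(matrix: pd.DataFrame) -> pd.Series:
    """Mean pairwise delta-Ct SD per gene.

    For every gene pair the SD over samples of (Ct_g - Ct_h) is computed
    (samples with ND in either gene dropped pairwise); a gene's statistic
    is the mean over its partners.
    """
    genes = list(matrix.index)
    if len(genes) < 2:
        raise ValueError("delta-Ct stability needs >= 2 genes")
    pair_sd = pd.DataFrame(index=genes, columns=genes, dtype=float)
    for g, h in itertools.combinations(genes, 2):
        diff = (matrix.loc[g] - matrix.loc[h]).dropna().astype(float)
        sd = diff.std(ddof=1) if len(diff) >= 2 else np.nan
        pair_sd.loc[g, h] = pair_sd.loc[h, g] = sd
    out = {g: pair_sd.loc[g].drop(g).mean() for g in genes}
    return pd.Series(out, name="deltact_sd")


def bestkeeper(matrix: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper descriptors per gene: Ct SD, Ct CV%, r vs the index.

    The BestKeeper index is the per-observation geometric mean of Ct over
    all genes (observations with any ND dropped from the index).  Genes
    are ranked by SD; a zero-variance gene has an undefined r, reported as
    NaN.
    """
    if matrix.shape[1] < 3:
        raise ValueError("BestKeeper needs >= 3 samples")
    complete = matrix.dropna(axis=1)
    index = np.exp(np.log(complete.astype(float)).mean(axis=0))
    rows = {}
    for gene in matrix.index:
        vals = matrix.loc[gene].dropna().astype(float)
        sd = vals.std(ddof=1)
        cv = 100.0 * sd / vals.mean()
        aligned = complete.loc[gene].astype(float)
        if aligned.std(ddof=1) == 0 or index.std(ddof=1) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(aligned.values, index.values)[0])
        rows[gene] = {"bestkeeper_sd": sd, "bestkeeper_cv": cv, "bestkeeper_r": r}
    return pd.DataFrame.from_dict(rows, orient="index")


def normfinder(
    matrix: pd.DataFrame, groups: dict | None = None
) -> pd.Series:
    """NormFinder-style stability rho per gene (simplified form).

    Cts are sample-centered (the per-observation mean across genes is
    subtracted, removing sample-loading differences).  With groups, each
    gene combines the magnitude of its between-group residual deviation
    with its within-group residual SD scaled by sqrt(n); without groups,
    rho is the residual SD.
    """
    if matrix.shape[0] < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    resid = matrix.astype(float) - matrix.astype(float).mean(axis=0)
    if groups is None:
        return pd.Series(
            {g: resid.loc[g].dropna().std(ddof=1) for g in matrix.index},
            name="normfinder_rho",
        )
    labels = pd.Series(
        [groups[obs] for obs in matrix.columns], index=matrix.columns
    )
    counts = labels.value_counts()
    singleton = counts[counts < 2]
    if not singleton.empty:
        raise ValueError(
            f"NormFinder groups with <2 samples: {sorted(singleton.index)}"
        )
    out = {}
    for gene in matrix.index:
        r = resid.loc[gene].astype(float)
        group_means = r.groupby(labels).mean()
        d = group_means - group_means.mean()
        s = r.groupby(labels).std(ddof=1)
        n = r.groupby(labels).count()
        out[gene] = float((d.abs() + s / np.sqrt(n)).mean())
    return pd.Series(out, name="normfinder_rho")


def _quantities(matrix: pd.DataFrame, efficiencies: dict[str, float] | None):
    """geNorm relative quantities Q_gi = base_g ** (min_i Ct_gi - Ct_gi)."""
    eff = efficiencies or {}
    q = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for gene in matrix.index:
        base = eff.get(gene, 2.0)
        ct = matrix.loc[gene].astype(float)
        q.loc[gene] = base ** (ct.min() - ct)
    return q


def _genorm_m_values(q: pd.DataFrame) -> pd.Series:
    """M_g = mean over partners of SD_i(log2(Q_g / Q_h))."""
    genes = list(q.index)
    log2q = np.log2(q.astype(float))
    m = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            diff = (log2q.loc[g] - log2q.loc[h]).dropna()
            sds.append(diff.std(ddof=1))
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


def genorm_m(
    matrix: pd.DataFrame, efficiencies: dict[str, float] | None = None
) -> tuple[pd.Series, tuple[str, ...]]:
    """geNorm stepwise-exclusion ranking.

    Returns (M value of each gene at its removal step — the final two keep
    their last M —, genes ordered best first).  The worst-M gene is removed
    iteratively; ties removed by gene id descending so the ranking is
    deterministic.  The two surviving genes cannot be separated by M and
    share the top of the order (sorted by id).
    """
    if matrix.shape[0] < 3:
        raise ValueError("geNorm needs >= 3 genes")
    q = _quantities(matrix, efficiencies)
    remaining = q.copy()
    removal_m: dict[str, float] = {}
    removed_order: list[str] = []
    while remaining.shape[0] > 2:
        m = _genorm_m_values(remaining)
        worst = m[m == m.max()].index.max()
        removal_m[worst] = float(m[worst])
        removed_order.append(worst)
        remaining = remaining.drop(index=worst)
    final_m = _genorm_m_values(remaining)
    for gene in sorted(remaining.index):
        removal_m[gene] = float(final_m[gene])
    order = tuple(sorted(remaining.index)) + tuple(reversed(removed_order))
    return pd.Series(removal_m, name="genorm_m"), order


def genorm_v(
    matrix: pd.DataFrame,
    ranking: tuple[str, ...],
    efficiencies: dict[str, float] | None = None,
    threshold: float = V_THRESHOLD,
) -> PairwiseVariationSeries:
    """geNorm pairwise variation V_{n/n+1} for n = 2 .. G-1.

    NF_{n,i} is the geometric mean of the quantities of the n top-ranked
    genes in observation i; V_n is the SD over observations of
    log2(NF_n / NF_{n+1}).
    """
    if len(ranking) < 3:
        raise ValueError("geNorm V needs >= 3 genes")
    q = _quantities(matrix, efficiencies).loc[list(ranking)]
    logq = np.log2(q.astype(float))

    def log_nf(n: int) -> pd.Series:
        return logq.iloc[:n].mean(axis=0)

    v_values = []
    for n in range(2, len(ranking)):
        diff = (log_nf(n) - log_nf(n + 1)).dropna()
        v_values.append(float(diff.std(ddof=1)))
    return PairwiseVariationSeries(
        genes=tuple(ranking), v=tuple(v_values), threshold=threshold
    )


def aggregate_ranking(
    method_ranks: dict[str, pd.Series],
    cv_pct: pd.Series | None = None,
) -> pd.DataFrame:
    """RefFinder-style aggregation: geometric mean of per-method ranks.

    Every method must rank every gene.  The aggregate score orders the
    final ranking ascending; score ties are broken by CV% (when supplied)
    then gene id.
    """
    if len(method_ranks) < 2:
        raise ValueError("need >= 2 methods to aggregate")
    frame = pd.DataFrame(method_ranks)
    if frame.isna().any().any():
        missing = frame[frame.isna().any(axis=1)].index.tolist()
        raise ValueError(f"methods missing ranks for genes: {missing}")
    score = np.exp(np.log(frame.astype(float)).mean(axis=1))
    order_key = pd.DataFrame({"score": score})
    order_key["cv"] = cv_pct if cv_pct is not None else 0.0
    order_key["gene"] = order_key.index
    ordered = order_key.sort_values(["score", "cv", "gene"]).index
    final_rank = pd.Series(
        range(1, len(ordered) + 1), index=ordered, dtype=float
    )
    out = frame.copy()
    out["aggregate_score"] = score
    out["final_rank"] = final_rank
    return out.sort_values("final_rank")


def stability_report(
    table: pd.DataFrame,
    groups: bool | dict | None = None,
    efficiencies: dict[str, float] | None = None,
    v_threshold: float = V_THRESHOLD,
) -> StabilityReport:
    """Run all five methods on a long-format Ct table and aggregate.

    ``groups=True`` takes group labels from the table's ``group`` column
    (used by NormFinder only); a dict maps (sample_id, bio_rep) to label.
    ``efficiencies`` maps gene to amplification base for geNorm.
    """
    matrix = ct_matrix(table)
    if groups is True:
        groups = observation_groups(table)

    cv = cv_ranking(matrix)
    dct = deltact_stability(matrix)
    bk = bestkeeper(matrix)
    nf = normfinder(matrix, groups=groups if isinstance(groups, dict) else None)
    m_values, order = genorm_m(matrix, efficiencies)
    v_series = genorm_v(matrix, order, efficiencies, threshold=v_threshold)

    # geNorm ranks follow the exclusion order (final two tie for rank 1-2)
    genorm_rank = pd.Series(index=matrix.index, dtype=float)
    for pos, gene in enumerate(order, start=1):
        genorm_rank[gene] = float(pos)
    genorm_rank[list(order[:2])] = 1.5

    ranks = {
        "rank_cv": _rank_ascending(cv),
        "rank_deltact": _rank_ascending(dct),
        "rank_bestkeeper": _rank_ascending(bk["bestkeeper_sd"]),
        "rank_normfinder": _rank_ascending(nf),
        "rank_genorm": genorm_rank,
    }
    agg = aggregate_ranking(ranks, cv_pct=cv)

    stats_frame = pd.DataFrame(
        {
            "cv_pct": cv,
            "deltact_sd": dct,
            "bestkeeper_sd": bk["bestkeeper_sd"],
            "bestkeeper_cv": bk["bestkeeper_cv"],
            "bestkeeper_r": bk["bestkeeper_r"],
            "normfinder_rho": nf,
            "genorm_m": m_values,
        }
    )
    full = stats_frame.join(agg).sort_values("final_rank")
    return StabilityReport(table=full, v_series=v_series, genorm_order=order)
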