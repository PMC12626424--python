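"""Cross-line transcriptomic compensation analysis.

Per deletion line, gene expression differences between homozygous
deletion (Del) and wild-type sibling (WT) pools are computed on a
variance-stabilized scale: median-of-ratios size factors followed by
log2(count / size_factor + 1), then an empirical-Bayes batch adjustment
fit on WT samples only.  Host-gene and paralog changes are flagged when
they fall in the top or bottom decile of a line's delta distribution.

To find pathways that respond coordinately across many deletion lines,
gene-level |Del - WT| differences are summed across lines and fed to a
positive preranked GSEA (weighted Kolmogorov-Smirnov running sum, gene
-permutation null, sign-matched NES).  Enriched GO terms (padj < 0.01)
are grouped by complete-linkage hierarchical clustering on Jaccard
distances with the tree cut at 0.9 (clustered terms share >10% of
genes), clusters keep the most significant member as representative,
and the union gene set of each cluster is re-scored per line on the
signed delta ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import bh_adjust

__all__ = [
    "DeltaExpressionSet",
    "GoCluster",
    "correct_degradation",
    "stabilize",
    "batch_adjust",
    "delta_expression",
    "host_paralog_report",
    "joint_ranking",
    "enrichment_score",
    "gsea_preranked",
    "cluster_go_terms",
    "per_line_union_nes",
    "read_gmt",
    "write_gmt",
]


@dataclass
class DeltaExpressionSet:
    """Per-line Del - WT differences on the stabilized scale.

    ``delta`` is genes x lines; ``host_gene`` maps each line to its
    microexon host gene, ``paralogs`` to the host's close paralogs.
    """

    delta: pd.DataFrame
    host_gene: Mapping[str, str] = field(default_factory=dict)
    paralogs: Mapping[str, Sequence[str]] = field(default_factory=dict)


@dataclass
class GoCluster:
    members: list
    representative: str  # most significant member term
    union_genes: frozenset


def correct_degradation(counts: pd.DataFrame,
                        corrected: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Hook for externally degradation-corrected counts.

    Transcript-degradation normalization is performed upstream by
    dedicated tooling; this hook accepts its output (``corrected``)
    and otherwise passes raw counts through unchanged.
    """
    return corrected if corrected is not None else counts


def stabilize(counts: pd.DataFrame, pseudocount: float = 1.0
              ) -> tuple[pd.DataFrame, pd.Series]:
    """Variance-stabilizing normalization of a genes x samples count matrix.

    A robust library size per sample is taken as the median ratio of
    its counts to the geometric mean of the library-size-normalized
    expression profiles (over genes expressed in every sample); the
    size factor is that robust library size per million, and the
    stabilized value is log2(count / size_factor + pseudocount) — a
    log2 robust-CPM.  Building the reference on normalized profiles
    makes the procedure exactly equivariant: scaling one sample's
    counts scales its size factor by the same amount and leaves every
    stabilized value unchanged.  Returns (stabilized matrix, size
    factors).
    """
    c = counts.to_numpy(dtype=float)
    if c.min() < 0:
        raise ValueError("counts must be non-negative")
    totals = c.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene expressed in all samples; cannot form reference")
    logc = np.log(c[all_pos])
    ref = (logc - np.log(totals)).mean(axis=1)  # log geo-mean normalized profile
    robust_lib = np.exp(np.median(logc - ref[:, None], axis=0))
    sf = robust_lib / 1e6
    stab = pd.DataFrame(np.log2(c / sf + pseudocount),
                        index=counts.index, columns=counts.columns)
    return stab, pd.Series(sf, index=counts.columns, name="size_factor")


def batch_adjust(stabilized: pd.DataFrame, batch: pd.Series,
                 wt_mask: pd.Series) -> pd.DataFrame:
    """Remove batch effects estimated on WT samples only.

    Per gene and batch, the WT batch-mean deviation from the WT grand
    mean is computed; the batch's across-gene mean effect is removed in
    full, while the gene-specific deviations around it are shrunk by an
    empirical-Bayes factor (the fraction of their across-gene variance
    in excess of the expected sampling variance).  The fitted effect is
    subtracted from every sample of the batch, so genotype effects
    confined to Del samples are never absorbed.
    """
    batch = batch.reindex(stabilized.columns)
    wt_mask = wt_mask.reindex(stabilized.columns).astype(bool)
    levels = batch.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 batches")
    wt = stabilized.loc[:, wt_mask]
    wt_batch = batch[wt_mask]
    for b in levels:
        if (wt_batch == b).sum() == 0:
            raise ValueError(f"batch {b!r} has no WT sample")
    grand = wt.mean(axis=1)
    adjusted = stabilized.copy()
    # per-gene residual variance of WT within batches (pooled)
    resid_sq, dof = 0.0, 0
    for b in levels:
        cols = wt.loc[:, wt_batch == b]
        if cols.shape[1] > 1:
            resid_sq = resid_sq + ((cols.sub(cols.mean(axis=1), axis=0)) ** 2).sum(axis=1)
            dof += cols.shape[1] - 1
    gene_var = resid_sq / dof if dof > 0 else pd.Series(0.0, index=wt.index)
    for b in levels:
        cols = wt.loc[:, wt_batch == b]
        dev = cols.mean(axis=1) - grand
        mu_b = float(dev.mean())
        resid = dev - mu_b
        sampling = float(np.mean(gene_var)) / max(cols.shape[1], 1)
        tau2 = max(0.0, float(np.var(resid)) - sampling)
        lam = tau2 / (tau2 + sampling) if (tau2 + sampling) > 0 else 0.0
        effect = mu_b + lam * resid
        adjusted.loc[:, (batch == b).to_numpy()] = (
            stabilized.loc[:, (batch == b).to_numpy()].sub(effect, axis=0))
    return adjusted


def delta_expression(adjusted: pd.DataFrame, sample_sheet: pd.DataFrame,
                     host_gene: Mapping[str, str] | None = None,
                     paralogs: Mapping[str, Sequence[str]] | None = None
                     ) -> DeltaExpressionSet:
    """Per line, mean adjusted Del minus mean adjusted WT, per gene.

    ``sample_sheet`` is indexed by sample with columns ``line`` and
    ``genotype`` (WT/Del).
    """
    deltas = {}
    for line, g in sample_sheet.groupby("line"):
        wt_cols = g.index[g["genotype"] == "WT"]
        del_cols = g.index[g["genotype"] == "Del"]
        if len(wt_cols) == 0 or len(del_cols) == 0:
            raise ValueError(f"line {line!r} needs both WT and Del samples")
        deltas[line] = adjusted[del_cols].mean(axis=1) - adjusted[wt_cols].mean(axis=1)
    return DeltaExpressionSet(delta=pd.DataFrame(deltas),
                              host_gene=dict(host_gene or {}),
                              paralogs=dict(paralogs or {}))


def host_paralog_report(deltas: DeltaExpressionSet,
                        decile: float = 10.0) -> pd.DataFrame:
    """Percentile of host-gene and paralog deltas within each line.

    A gene is flagged when its delta sits in the bottom or top decile
    of that line's full delta distribution.
    """
    from scipy.stats import percentileofscore

    rows = []
    for line in deltas.delta.columns:
        dist = deltas.delta[line].dropna()
        targets = []
        host = deltas.host_gene.get(line)
        if host is not None:
            if host not in dist.index:
                raise KeyError(f"host gene {host!r} absent from the delta matrix")
            targets.append((host, "host"))
        for p in deltas.paralogs.get(line, ()):  # absent paralogs are skipped
            if p in dist.index:
                targets.append((p, "paralog"))
        for gene, role in targets:
            pct = float(percentileofscore(dist.to_numpy(), dist[gene], kind="mean"))
            rows.append({"line": line, "gene": gene, "role": role,
                         "delta": float(dist[gene]), "percentile": pct,
                         "flagged": pct <= decile or pct >= 100 - decile})
    return pd.DataFrame(rows)


def joint_ranking(delta: pd.DataFrame) -> pd.Series:
    """Sum of |Del - WT| across lines per gene, ranked descending.

    Requires at least 2 lines; ties break by gene identifier for a
    stable order.
    """
    if delta.shape[1] < 2:
        raise ValueError("joint ranking needs deltas from >= 2 lines")
    score = delta.abs().sum(axis=1)
    return score.sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# Preranked GSEA

def enrichment_score(ranked_scores: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov enrichment score on a ranked list.

    ``ranked_scores`` are the ranking statistics in descending rank
    order; ``hit_mask`` marks set members.  Hits step the running sum
    up by |score|^weight (normalized over hits), misses step it down by
    1/(N - k); the sum is bridge-normalized by (N - k)/N so that at
    weight 0 it is the classic two-sample KS statistic against the
    uniform (a set of the top k genes peaks at ES = 1 - k/N).  Returns
    the signed extreme of the running sum and its position.
    """
    s = np.abs(np.asarray(ranked_scores, dtype=float)) ** weight
    hits = np.asarray(hit_mask, dtype=bool)
    n, k = hits.size, int(hits.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    hit_w = s * hits
    denom = hit_w.sum()
    if denom == 0:  # all member scores zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        denom = float(k)
    steps = hit_w / denom - (~hits) / (n - k)
    running = np.cumsum(steps) * (n - k) / n
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def _rank_genes(scores: pd.Series) -> pd.Series:
    """Descending stable sort; ties broken by gene identifier."""
    df = pd.DataFrame({"score": scores})
    df = df.sort_index(kind="mergesort").sort_values(
        "score", ascending=False, kind="mergesort")
    return df["score"]


def gsea_preranked(scores: pd.Series, gene_sets: Mapping[str, Sequence[str]],
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   positive_only: bool = False, min_size: int = 5,
                   max_size: int = 2000) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    The universe is the ranking itself; sets are intersected with it
    before the size filter.  For each set the running-sum ES is
    computed, the null is built by drawing random member positions
    (equivalent to permuting gene labels), NES = ES / mean |null ES| of
    matching sign, and p comes from the matching-sign null tail
    (add-one corrected).  ``positive_only`` keeps only sets with
    positive ES — the "positive GSEA" used on summed absolute changes.
    p-values are BH-adjusted across the reported sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _rank_genes(scores.astype(float).dropna())
    universe = ranked.index
    arr = ranked.to_numpy()
    n = arr.size
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        members = frozenset(members) & set(universe)
        k = len(members)
        if k < 2:
            raise ValueError(f"gene set {name!r} overlaps the ranking in <2 genes")
        if k == n:
            raise ValueError(f"gene set {name!r} covers the whole ranking")
        if k < min_size or k > max_size:
            continue
        hit = universe.isin(members)
        es, peak = enrichment_score(arr, hit, weight)
        null = np.empty(n_perm)
        for i in range(n_perm):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=k, replace=False)] = True
            null[i] = enrichment_score(arr, m, weight)[0]
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        if same_sign.size == 0:
            nes, p = np.nan, 1.0
        else:
            nes = abs(es) / same_sign.mean() * np.sign(es)
            p = (1 + np.sum(same_sign >= abs(es))) / (1 + same_sign.size)
        leading = (universe[:peak + 1][hit[:peak + 1]] if es >= 0
                   else universe[peak:][hit[peak:]])
        rows.append({"set_name": name, "size": k, "es": es, "nes": float(nes),
                     "p": float(p), "leading_edge": ",".join(leading)})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    if positive_only:
        res = res[res["es"] > 0].reset_index(drop=True)
        if res.empty:
            return res
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return res.sort_values("p", kind="mergesort").reset_index(drop=True)


def cluster_go_terms(results: pd.DataFrame,
                     gene_sets: Mapping[str, Sequence[str]],
                     padj_cut: float = 0.01, cut_height: float = 0.9,
                     keep_p: float = 0.001) -> list[GoCluster]:
    """Group enriched GO terms by gene-overlap similarity.

    Terms with padj < ``padj_cut`` are clustered by complete linkage on
    Jaccard distance (1 - intersection/union) with the tree cut at
    ``cut_height`` — members of a cluster share >10% of genes at the
    default cut.  Clusters survive when at least one member has
    p < ``keep_p``; the representative is the most significant member
    and the union gene set is returned for per-line re-scoring.
    """
    enriched = results[results["padj"] < padj_cut]
    if enriched.empty:
        raise ValueError("no enriched term below the padj cut")
    names = enriched["set_name"].tolist()
    sets = [frozenset(gene_sets[t]) for t in names]
    if len(names) == 1:
        t = names[0]
        keep = float(enriched.iloc[0]["p"]) < keep_p
        return [GoCluster([t], t, sets[0])] if keep else []
    m = len(names)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            dist[i, j] = dist[j, i] = 1.0 - (inter / union if union else 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="complete"),
                      t=cut_height, criterion="distance")
    pvals = enriched.set_index("set_name")["p"]
    clusters = []
    for c in np.unique(labels):
        members = [names[i] for i in np.flatnonzero(labels == c)]
        if min(pvals[t] for t in members) >= keep_p:
            continue
        rep = min(members, key=lambda t: (pvals[t], t))
        union = frozenset().union(*(gene_sets[t] for t in members))
        clusters.append(GoCluster(members=members, representative=rep,
                                  union_genes=union))
    return clusters


def per_line_union_nes(clusters: Sequence[GoCluster], delta: pd.DataFrame,
                       n_perm: int = 1000, seed: int = 0,
                       star_padj: float = 0.01) -> pd.DataFrame:
    """NES of each cluster union set per line, on the signed delta ranking.

    Returns a long frame (line, cluster, nes, p, padj, star); a cluster
    whose union barely intersects a line's universe yields a missing
    row (NaN NES).
    """
    rows = []
    union_sets = {c.representative: c.union_genes for c in clusters}
    for li, line in enumerate(delta.columns):
        scores = delta[line].dropna()
        res = gsea_preranked(scores, union_sets, n_perm=n_perm,
                             seed=seed + li, positive_only=False)
        res = res.set_index("set_name") if not res.empty else res
        for c in clusters:
            if not res.empty and c.representative in res.index:
                r = res.loc[c.representative]
                rows.append({"line": line, "cluster": c.representative,
                             "nes": float(r["nes"]), "p": float(r["p"]),
                             "padj": float(r["padj"]),
                             "star": bool(r["padj"] < star_padj)})
            else:
                rows.append({"line": line, "cluster": c.representative,
                             "nes": np.nan, "p": np.nan, "padj": np.nan,
                             "star": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMT I/O

def read_gmt(path) -> dict[str, list]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
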