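"""Onset timing, cell-type enrichment and over-representation tests.

Onset is scored as the area under a gene's max-scaled pseudotime
trajectory (trapezoidal, bin midpoints mapped to [0, 1]): a gene that is
already on at the root integrates to ~1, a late-switching gene to a small
value, so larger AUC means earlier onset.  Enrichment contrasts a target
cluster (e.g. mature OSNs) against all other cells with a log2 fold
change and a two-sided rank-sum test; over-representation of gene sets
uses the upper-tail hypergeometric with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountForm
from .trajectory import TrajectorySet

LFC_EPS = 1e-9


def trajectory_auc(t: TrajectorySet, form: CountForm = CountForm.LOG_MAX) -> pd.Series:
    """Area under each gene's max-scaled trajectory; in [0, 1].

    Bin midpoints are mapped linearly onto [0, 1] and the trapezoidal rule
    applied, so a constantly-on gene (max-scaled trajectory of all ones)
    scores exactly 1.  Zero-flagged genes are absent from the result.
    """
    if form not in (CountForm.NORM_MAX, CountForm.LOG_MAX):
        raise ValueError("trajectory AUC is defined on max-scaled forms")
    mat = t.forms[form]
    mids = t.midpoints
    x = (mids - mids[0]) / (mids[-1] - mids[0])
    auc = np.trapezoid(mat.to_numpy(), x, axis=1)
    return pd.Series(np.clip(auc, 0.0, 1.0), index=mat.index, name="auc")


def onset_category(
    auc: pd.Series, quantiles: tuple[float, float] = (1 / 3, 2 / 3)
) -> pd.Series:
    """Partition genes into late/mid/early onset classes by AUC terciles.

    ``early`` is the top AUC tercile (earliest activation), ``late`` the
    bottom.  Boundaries are deterministic (values equal to a boundary go
    to the higher class).  With fewer than 3 genes everything is "mid".
    """
    if len(auc) < 3:
        import warnings

        warnings.warn("fewer than 3 genes; all assigned 'mid'", stacklevel=2)
        return pd.Series("mid", index=auc.index, name="onset_class")
    lo, hi = auc.quantile(list(quantiles)).to_numpy()
    cls = np.where(auc >= hi, "early", np.where(auc >= lo, "mid", "late"))
    return pd.Series(cls, index=auc.index, name="onset_class")


def enrichment_scores(
    x,
    genes,
    meta: pd.DataFrame,
    target_cluster: str,
    n_top: int = 100,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Target-cluster enrichment of every gene vs all remaining cells.

    enrich_lfc = log2((mean in target + eps) / (mean in rest + eps)) with
    eps = 1e-9; enrich_p from a two-sided Wilcoxon rank-sum comparison
    (exact for small tie-free samples, normal approximation otherwise).
    The returned top list holds the ``n_top`` genes with the largest lfc
    among those with BH FDR < ``fdr_cut``.
    """
    clusters = meta["cluster"].astype(str).to_numpy()
    in_target = clusters == target_cluster
    if in_target.sum() < 3:
        raise ValueError(
            f"target cluster {target_cluster!r} has {int(in_target.sum())} cells (<3)"
        )
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    a, b = dense[in_target], dense[~in_target]
    lfc = np.log2((a.mean(axis=0) + LFC_EPS) / (b.mean(axis=0) + LFC_EPS))
    pvals = np.ones(dense.shape[1])
    for j in range(dense.shape[1]):
        if np.ptp(dense[:, j]) == 0:
            continue
        pvals[j] = stats.mannwhitneyu(
            a[:, j], b[:, j], alternative="two-sided", method="auto"
        ).pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"enrich_lfc": lfc, "enrich_p": pvals, "enrich_fdr": fdr},
        index=pd.Index(genes, name="gene"),
    )
    table["enrich_rank"] = (
        table["enrich_lfc"].rank(ascending=False, method="first").astype(int)
    )
    signif = table[table["enrich_fdr"] < fdr_cut]
    top = signif.sort_values(
        ["enrich_lfc"], ascending=False, kind="stable"
    ).index[:n_top].tolist()
    return table, top


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene/logfc/pvalue.

    An ``fdr`` column is recomputed by Benjamini-Hochberg if absent.
    """
    de = pd.read_csv(path, sep="\t")
    required = {"gene", "logfc", "pvalue"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    de = de.set_index("gene")
    if "fdr" not in de.columns:
        de["fdr"] = multipletests(de["pvalue"].to_numpy(), method="fdr_bh")[1]
    return de


def correlate_onset_with_de(
    onset: pd.Series | pd.DataFrame, de: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation between onset AUC and external DE logFC.

    Computed over the gene intersection; returns (r, two-sided p, n).
    """
    auc = onset["auc"] if isinstance(onset, pd.DataFrame) else onset
    shared = auc.index.intersection(de.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes (<3)")
    r, p = stats.pearsonr(auc.loc[shared], de.loc[shared, "logfc"])
    return float(r), float(p), int(len(shared))


def ora_test(
    selected: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Gene-set over-representation by upper-tail hypergeometric test.

    With universe size M, set size K (after intersecting the set with the
    universe), selection size n and overlap k, p = P(X >= k) under the
    hypergeometric null; BH correction across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(selected) <= set(universe):
        raise ValueError("selected genes must be a subset of the universe")
    M, n = len(universe), len(selected)
    rows = []
    for name, members in collection.items():
        members = set(members) & set(universe)
        k = len(members & set(selected))
        K = len(members)
        p = stats.hypergeom.sf(k - 1, M, K, n) if K else 1.0
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"])
    out = out.set_index("set")
    out["fdr"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out
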