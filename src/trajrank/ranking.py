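"""Reference-gene coexpression ranking by trajectory RMSE.

For each of the four count forms, every gene's binned trajectory is
compared with a reference gene's trajectory (Rtp1 in the motivating use
case) by root-mean-squared error, genes are ranked per form by ascending
RMSE, and the per-form ranks are integrated so the final candidate list
is not biased toward any single normalization.  The integration rule —
sort by (number of forms in which the gene is in the top k, then mean
rank, then symbol) — is one concrete choice among several defensible
ones, so both sub-orderings are kept as separate columns for re-ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CountForm, MAX_FORMS
from .trajectory import TrajectorySet

RANK_COLUMNS = ["mean_rank", "topk_hits", "final_rank"]


def rmse_to_reference(
    t: TrajectorySet, form: CountForm, reference: str
) -> pd.Series:
    """RMSE of every gene's trajectory against the reference gene's.

    rmse_g = sqrt(mean over bins of (x_gb - x_ref_b)^2); the reference
    itself scores exactly 0.
    """
    mat = t.forms[form]
    if reference not in mat.index:
        if form in MAX_FORMS and reference in t.zero_genes:
            raise ValueError(
                f"reference gene {reference!r} has an all-zero trajectory and "
                f"is excluded from the max-scaled form {form.value}"
            )
        raise KeyError(f"reference gene {reference!r} not in form {form.value}")
    ref = mat.loc[reference].to_numpy()
    diff = mat.to_numpy() - ref
    rmse = np.sqrt((diff**2).mean(axis=1))
    out = pd.Series(rmse, index=mat.index, name=f"rmse_{form.value}")
    out.loc[reference] = 0.0
    return out


def rmse_antiregulated(t: TrajectorySet, form: CountForm, reference: str) -> pd.Series:
    """RMSE against the vertically flipped max-scaled reference trajectory.

    Only meaningful for max-scaled forms, where 1 - x_ref is the mirror
    trajectory; low values indicate anti-regulation with the reference.
    """
    if form not in MAX_FORMS:
        raise ValueError("anti-regulation RMSE is defined on max-scaled forms only")
    mat = t.forms[form]
    ref = 1.0 - mat.loc[reference].to_numpy()
    diff = mat.to_numpy() - ref
    return pd.Series(
        np.sqrt((diff**2).mean(axis=1)), index=mat.index,
        name=f"rmse_anti_{form.value}",
    )


def rank_per_form(rmse: pd.Series, reference: str | None = None) -> pd.Series:
    """1-based ranks by ascending RMSE, ties broken by gene symbol.

    The reference gene (RMSE exactly 0) wins any tie at 0, so it is rank 1
    on any input.
    """
    if len(rmse) < 2:
        raise ValueError("ranking requires at least 2 genes")
    order = sorted(rmse.index, key=lambda g: (rmse[g], g != reference, str(g)))
    return pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="gene"),
        name=rmse.name.replace("rmse", "rank") if rmse.name else "rank",
    ).loc[rmse.index]


def integrate_ranks(
    ranks: dict[CountForm, pd.Series],
    rmses: dict[CountForm, pd.Series] | None = None,
    k: int = 50,
    reference: str | None = None,
    zero_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Combine per-form ranks into one table.

    mean_rank is the arithmetic mean of the available per-form ranks (a
    gene absent from a max-scaled form, i.e. zero-flagged, is averaged
    over the forms it has, and flagged); topk_hits counts forms where the
    gene ranks <= k.  The final ordering is by (descending topk_hits,
    ascending mean_rank, symbol) and excludes flagged genes downstream.
    """
    if set(ranks) != set(CountForm):
        missing = [f.value for f in CountForm if f not in ranks]
        raise ValueError(f"all four count forms required; missing {missing}")
    genes = ranks[CountForm.NORM].index
    table = pd.DataFrame(index=genes.copy())
    table.index.name = "gene"
    for form in CountForm:
        if rmses is not None:
            table[f"rmse_{form.value}"] = rmses[form]
        table[f"rank_{form.value}"] = ranks[form]
    rank_cols = [f"rank_{f.value}" for f in CountForm]
    table["mean_rank"] = table[rank_cols].mean(axis=1, skipna=True)
    table["topk_hits"] = (table[rank_cols] <= k).sum(axis=1).astype(int)
    table["zero_trajectory"] = table[rank_cols].isna().any(axis=1)
    if zero_genes:
        table.loc[table.index.isin(zero_genes), "zero_trajectory"] = True
    table["is_reference"] = table.index == reference
    table["excluded_panneuronal"] = False
    return _assign_final_rank(table)


def _assign_final_rank(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute the final ordering; excluded/zero genes get no rank."""
    eligible = ~(table["excluded_panneuronal"] | table["zero_trajectory"])
    sub = table.loc[eligible]
    order = sorted(
        sub.index, key=lambda g: (-sub.at[g, "topk_hits"], sub.at[g, "mean_rank"], str(g))
    )
    table["final_rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order, dtype="float"
    ).reindex(table.index)
    return table.sort_values(
        ["final_rank"], na_position="last", kind="stable"
    )


def rank_genes(
    t: TrajectorySet,
    reference: str,
    k: int = 50,
    antiregulated: bool = False,
) -> pd.DataFrame:
    """Full RMSE ranking of all genes against a reference gene.

    Convenience wrapper chaining :func:`rmse_to_reference`,
    :func:`rank_per_form` and :func:`integrate_ranks` over the four forms.
    """
    rmses, ranks = {}, {}
    for form in CountForm:
        r = rmse_to_reference(t, form, reference)
        rmses[form] = r
        ranks[form] = rank_per_form(r, reference=reference)
    table = integrate_ranks(
        ranks, rmses, k=k, reference=reference, zero_genes=t.zero_genes
    )
    if antiregulated:
        for form in MAX_FORMS:
            table[f"rmse_anti_{form.value}"] = rmse_antiregulated(t, form, reference)
    return table


def filter_panneuronal(rt: pd.DataFrame, exclusion: set[str]) -> pd.DataFrame:
    """Flag pan-neuronal genes and drop them from the final ordering.

    Flagged rows stay in the table (with their RMSEs untouched) for audit;
    only ``final_rank`` is recomputed over the survivors.
    """
    rt = rt.copy()
    rt["excluded_panneuronal"] = rt.index.isin(list(exclusion))
    return _assign_final_rank(rt)


def top_candidates(rt: pd.DataFrame, n: int = 50) -> pd.Index:
    """The top-n genes of the final ordering, reference excluded."""
    sub = rt[rt["final_rank"].notna() & ~rt["is_reference"]]
    return sub.sort_values("final_rank").index[:n]
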