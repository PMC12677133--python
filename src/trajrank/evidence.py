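"""External-evidence overlays: regulatory-network interaction counts and
differential-expression flags.

The network input is a mutual-information edge list (e.g. ARACNE output:
regulator, target, weight, optional p-value).  Because mutual information
is symmetric, interactions are counted over both edge directions by
default; a directed mode is available.  Evidence is annotation only — it
never reorders or removes ranking candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Transcription factors of the unfolded-protein-response / ER-stress
#: program active during olfactory sensory neuron maturation.
ER_STRESS_TFS = (
    "Atf5", "Atf6", "Ddit3", "Ebf1", "Ebf2", "Ebf3", "Ebf4", "Nfe2l2", "Xbp1",
)


def read_edge_list(
    path,
    regulator_col: str = "regulator",
    target_col: str = "target",
    weight_col: str | None = "weight",
    pvalue_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV edge list into a (regulator, target, weight[, pvalue])
    frame.

    Self-loops are dropped (count logged); duplicate (regulator, target)
    pairs are collapsed keeping the maximum weight.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (regulator_col, target_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found; header is {df.columns.tolist()}"
            )
    out = pd.DataFrame(
        {
            "regulator": df[regulator_col].astype(str),
            "target": df[target_col].astype(str),
        }
    )
    out["weight"] = (
        df[weight_col].astype(float) if weight_col and weight_col in df.columns else 1.0
    )
    if pvalue_col and pvalue_col in df.columns:
        out["pvalue"] = df[pvalue_col].astype(float)
    n_loops = int((out["regulator"] == out["target"]).sum())
    if n_loops:
        logger.info("dropping %d self-loop(s)", n_loops)
        out = out[out["regulator"] != out["target"]]
    before = len(out)
    out = (
        out.sort_values("weight", ascending=False)
        .drop_duplicates(["regulator", "target"], keep="first")
        .reset_index(drop=True)
    )
    if len(out) < before:
        logger.info("collapsed %d duplicate edge(s)", before - len(out))
    logger.info("edge list: %d edges", len(out))
    return out


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def count_tf_interactions(
    edges: pd.DataFrame,
    gene: str,
    tf_list=ER_STRESS_TFS,
    directed: bool = False,
) -> tuple[int, list[str], bool]:
    """Count distinct TFs from ``tf_list`` adjacent to ``gene``.

    Returns (count, sorted matched TF names, absent flag).  With
    ``directed=False`` (default, matching symmetric mutual-information
    networks) both edge directions count; a gene absent from the network
    yields count 0 with the absent flag set rather than an error.
    """
    tf_list = list(tf_list)
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    reg, tgt = edges["regulator"].to_numpy(), edges["target"].to_numpy()
    absent = not (np.any(reg == gene) or np.any(tgt == gene))
    partners = set(tgt[reg == gene])
    if not directed:
        partners |= set(reg[tgt == gene])
    matched = sorted(partners & set(tf_list))
    return len(matched), matched, absent


def overlay_de_table(
    rt: pd.DataFrame,
    de: pd.DataFrame,
    fdr_cut: float = 0.05,
    direction: str = "down",
) -> pd.DataFrame:
    """Annotate a rank table with external differential-expression calls.

    Candidates present in ``de`` with fdr < ``fdr_cut`` and a logfc whose
    sign matches ``direction`` ("down", "up" or "both") get ``de_flag``;
    genes absent from the DE table are marked ``"no data"``.  Only
    annotation columns are added — ordering and membership are untouched.
    """
    if direction not in ("down", "up", "both"):
        raise ValueError("direction must be one of down/up/both")
    rt = rt.copy()
    de = de.reindex(rt.index)
    rt["de_logfc"] = de["logfc"]
    rt["de_fdr"] = de["fdr"]
    sign_ok = {
        "down": de["logfc"] < 0,
        "up": de["logfc"] > 0,
        "both": de["logfc"] != 0,
    }[direction]
    rt["de_flag"] = ((de["fdr"] < fdr_cut) & sign_ok).fillna(False)
    rt["de_status"] = np.where(
        de["logfc"].isna(), "no data", np.where(rt["de_flag"], "flagged", "tested")
    )
    logger.info(
        "DE overlay: %d/%d candidates flagged (%s, fdr<%g)",
        int(rt["de_flag"].sum()), len(rt), direction, fdr_cut,
    )
    return rt
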