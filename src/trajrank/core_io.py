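"""Input/output, quality control and count-form construction.

Counts are held as a sparse cell x gene matrix with explicit barcode and
gene-symbol axes.  Two on-disk dialects are supported: a Matrix Market
triplet directory (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``,
features as rows in the .mtx as is conventional for droplet pipelines)
and a dense TSV with an orientation flag in the header.

The four "count forms" used downstream are depth-normalized counts
(NORM), log1p of those (LOG), and the per-gene max-scaled variants of
each (NORM_MAX, LOG_MAX).  Max scaling is applied to binned trajectories
(one row per gene over pseudotime bins), not to per-cell values, so that
every gene contributes a single trajectory per form.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIXES = ("mt-",)
#: prefixes identifying odorant-receptor genes; ``Or`` alone would swallow
#: unrelated symbols (Orc2, ...) so the modern nomenclature requires a digit.
DEFAULT_OR_PATTERNS = ("Olfr", r"Or\d")
DEFAULT_NOISE_PATTERNS = ("mt-", "Malat")


class CountForm(str, Enum):
    """The four representations of a binned expression trajectory."""

    NORM = "norm"
    LOG = "log"
    NORM_MAX = "norm_max"
    LOG_MAX = "log_max"


#: forms that are per-gene max-scaled
MAX_FORMS = (CountForm.NORM_MAX, CountForm.LOG_MAX)


@dataclass
class CountMatrix:
    """Sparse nonnegative integer cell x gene count matrix with axes.

    Parameters
    ----------
    barcodes : sequence of unique cell identifiers (rows).
    genes : sequence of unique gene symbols (columns).
    counts : anything :func:`scipy.sparse.csr_matrix` accepts; stored CSR.
    """

    barcodes: list[str]
    genes: list[str]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.barcodes = [str(b) for b in self.barcodes]
        self.genes = [str(g) for g in self.genes]
        self.counts = sp.csr_matrix(self.counts)
        n, m = self.counts.shape
        if n != len(self.barcodes) or m != len(self.genes):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        for name, axis in (("barcode", self.barcodes), ("gene", self.genes)):
            dupes = pd.Index(axis)[pd.Index(axis).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} identifiers: {dupes}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, symbol: str) -> int:
        try:
            return self.genes.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not present") from None

    def to_dense_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.genes
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            [b for b, keep in zip(self.barcodes, mask) if keep],
            list(self.genes),
            self.counts[mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            list(self.barcodes),
            [g for g, keep in zip(self.genes, mask) if keep],
            self.counts[:, mask],
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_single_column(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(path: str | Path, dialect: str = "auto") -> CountMatrix:
    """Read a count matrix from disk.

    ``dialect`` is ``"triplet"`` (directory with matrix.mtx, barcodes.tsv,
    features.tsv; features x barcodes orientation), ``"dense-tsv"`` (TSV
    whose header's first field is ``gene`` for genes-as-rows or ``barcode``
    for cells-as-rows) or ``"auto"``.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "triplet" if path.is_dir() else "dense-tsv"
    if dialect in ("triplet", "matrix-market-triplet"):
        mtx_path = path / "matrix.mtx"
        if not mtx_path.exists():
            raise FileNotFoundError(f"missing matrix file: {mtx_path}")
        barcodes = _read_single_column(path / "barcodes.tsv", "barcodes")
        genes = _read_single_column(path / "features.tsv", "features")
        mat = sp.csr_matrix(scipy.io.mmread(mtx_path)).T  # -> cells x genes
        return CountMatrix(barcodes, genes, mat)
    if dialect == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        orient = df.index.name or ""
        if orient.lower() in ("gene", "genes", "symbol"):
            df = df.T  # -> cells x genes
        return CountMatrix(
            df.index.tolist(), df.columns.tolist(), sp.csr_matrix(df.to_numpy())
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_counts(m: CountMatrix, path: str | Path, dialect: str = "triplet") -> None:
    """Write a CountMatrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if dialect in ("triplet", "matrix-market-triplet"):
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts.T))
        pd.Series(m.barcodes).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(m.genes).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        return
    if dialect == "dense-tsv":
        df = m.to_dense_df()
        df.index.name = "barcode"
        df.to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_gene_sets(path: str | Path, uppercase: bool = False) -> dict[str, set[str]]:
    """Read a GMT file into a mapping set-name -> set of gene symbols."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if uppercase:
            genes = [g.upper() for g in genes]
        collection[name] = set(genes)
    return collection


def write_gene_sets(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# QC


def match_genes(genes: Sequence[str], patterns: Iterable[str]) -> np.ndarray:
    """Boolean mask of genes whose symbol starts with any pattern.

    Patterns are prefix-anchored regular expressions, so plain prefixes
    (``"mt-"``) work as-is and ``r"Or\\d"`` matches Or1ad1 but not Orc2.
    """
    compiled = [re.compile(p) for p in patterns]
    return np.array(
        [any(c.match(g) for c in compiled) for g in genes], dtype=bool
    )


def compute_qc(
    m: CountMatrix, mito_patterns: Sequence[str] = DEFAULT_MITO_PREFIXES
) -> pd.DataFrame:
    """Per-cell totals and mitochondrial fraction.

    Returns a DataFrame indexed by barcode with columns ``total_counts``,
    ``mito_frac`` and ``zero_total`` (flag for empty cells, for which
    ``mito_frac`` is defined as 0).
    """
    if not list(mito_patterns):
        raise ValueError("mito_patterns must be non-empty")
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    mito_mask = match_genes(m.genes, mito_patterns)
    mito = np.asarray(m.counts[:, mito_mask].sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    frac = np.divide(mito, totals, out=np.zeros_like(mito), where=~zero)
    return pd.DataFrame(
        {"total_counts": totals, "mito_frac": frac, "zero_total": zero},
        index=pd.Index(m.barcodes, name="barcode"),
    )


def filter_cells(
    m: CountMatrix,
    meta: pd.DataFrame,
    max_mito: float = 0.2,
    min_counts: int = 500,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells with high mitochondrial content or shallow coverage.

    Thresholds default to max_mito=0.2 and min_counts=500 and are logged.
    """
    meta = meta.loc[m.barcodes]
    keep = (meta["mito_frac"].to_numpy() <= max_mito) & (
        meta["total_counts"].to_numpy() >= min_counts
    )
    logger.info(
        "filter_cells: max_mito=%.3g min_counts=%d -> kept %d/%d cells",
        max_mito, min_counts, int(keep.sum()), m.n_cells,
    )
    if not keep.any():
        raise ValueError(
            "all cells removed by QC; review max_mito/min_counts thresholds"
        )
    return m.subset_cells(keep), meta.loc[keep].copy()


def exclude_genes(
    m: CountMatrix,
    patterns: Sequence[str],
    purpose: str = "embedding-only",
    whitelist: Iterable[str] = (),
):
    """Exclude genes matching symbol prefixes/regexes.

    ``purpose="embedding-only"`` returns a boolean *keep* mask leaving the
    matrix intact (for genes excluded from dimensionality reduction only,
    e.g. odorant receptors); ``"global"`` returns a reduced CountMatrix
    (e.g. mitochondrial and Malat noise genes).
    """
    if not list(patterns):
        raise ValueError("patterns must be non-empty")
    hit = match_genes(m.genes, patterns)
    wl = set(whitelist)
    if wl:
        hit &= ~np.isin(m.genes, list(wl))
    if not hit.any():
        warnings.warn(
            f"gene-exclusion patterns {list(patterns)} matched no genes",
            stacklevel=2,
        )
    keep = ~hit
    if purpose == "embedding-only":
        return keep
    if purpose == "global":
        return m.subset_genes(keep)
    raise ValueError(f"unknown purpose {purpose!r}")


# ---------------------------------------------------------------------------
# normalization and count forms


def normalize_depth(m: CountMatrix | sp.spmatrix, target: float = 1e4):
    """Scale each cell to ``target`` total counts (median-free depth
    normalization).  Returns a CSR float matrix of the same shape."""
    if target <= 0:
        raise ValueError("target must be positive")
    if isinstance(m, CountMatrix):
        counts, barcodes = m.counts, m.barcodes
    else:
        counts, barcodes = sp.csr_matrix(m), None
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = (
            [barcodes[i] for i in zero[:5]] if barcodes is not None else zero[:5].tolist()
        )
        raise ValueError(f"zero-total cells present (e.g. {names}); filter first")
    scale = sp.diags(target / totals)
    return sp.csr_matrix(scale @ counts)


def log_transform(x):
    """Elementwise log(1+x); accepts dense or sparse, preserves zeros."""
    if sp.issparse(x):
        if x.nnz and x.data.min() < 0:
            raise ValueError("negative entries")
        out = x.copy()
        out.data = np.log1p(out.data)
        return out
    x = np.asarray(x, dtype=float)
    if x.size and x.min() < 0:
        raise ValueError("negative entries")
    return np.log1p(x)


def select_hvg(
    x, genes: Sequence[str] | None = None, n_top: int = 1000, n_bins: int = 20
) -> np.ndarray:
    """Highly-variable-gene mask by binned normalized dispersion.

    Dispersion is variance/mean of depth-normalized counts; genes are
    grouped into ``n_bins`` mean-expression bins and dispersions z-scored
    within each bin, then the top ``n_top`` genes by normalized dispersion
    are selected.  Genes with zero variance are never selected before a
    varying gene.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if sp.issparse(x):
        mean = np.asarray(x.mean(axis=0)).ravel()
        sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    else:
        x = np.asarray(x, dtype=float)
        mean = x.mean(axis=0)
        sq = (x**2).mean(axis=0)
    n_genes = mean.size
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {n_genes}")
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    score = np.full(n_genes, -np.inf)
    varying = var > 0
    if varying.any():
        # quantile bins on mean expression of varying genes
        order = pd.qcut(
            pd.Series(mean[varying]).rank(method="first"),
            min(n_bins, int(varying.sum())),
            labels=False,
        ).to_numpy()
        d = disp[varying]
        z = np.empty_like(d)
        for b in np.unique(order):
            sel = order == b
            mu, sd = d[sel].mean(), d[sel].std()
            z[sel] = (d[sel] - mu) / (sd if sd > 0 else 1.0)
        score[varying] = z
    # deterministic tie-break on (-score, symbol or index)
    keys = genes if genes is not None else [str(i) for i in range(n_genes)]
    order = sorted(range(n_genes), key=lambda i: (-score[i], str(keys[i])))
    mask = np.zeros(n_genes, dtype=bool)
    mask[order[:n_top]] = True
    return mask


def make_count_forms(
    norm_traj: pd.DataFrame, log_traj: pd.DataFrame
) -> tuple[dict[CountForm, pd.DataFrame], list[str]]:
    """Build the four count-form trajectory matrices.

    Input: gene x bin mean-expression matrices for the NORM and LOG forms
    (shared axes).  NORM_MAX / LOG_MAX divide each gene row by its row
    maximum; all-zero rows are excluded from the max-scaled forms and
    returned as the second element (flagged, not fatal).
    """
    if not norm_traj.index.equals(log_traj.index) or not norm_traj.columns.equals(
        log_traj.columns
    ):
        raise ValueError("NORM and LOG trajectory matrices must share axes")
    rowmax = norm_traj.max(axis=1)
    zero_genes = rowmax.index[rowmax <= 0].tolist()
    nz = ~norm_traj.index.isin(zero_genes)
    forms = {
        CountForm.NORM: norm_traj,
        CountForm.LOG: log_traj,
        CountForm.NORM_MAX: norm_traj.loc[nz].div(rowmax[nz], axis=0),
        CountForm.LOG_MAX: log_traj.loc[nz].div(log_traj.loc[nz].max(axis=1), axis=0),
    }
    return forms, zero_genes
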