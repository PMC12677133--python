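"""Embedding, diffusion pseudotime and trajectory binning.

The ordering of cells along the maturation axis follows the standard
diffusion-pseudotime construction: a kNN graph with an adaptive Gaussian
kernel, anisotropic density normalization (exponent 1), eigendecomposition
of the symmetric conjugate of the row-normalized transition operator, and
pseudotime as Euclidean distance from a root cell in the space of diffusion
components scaled by lambda/(1-lambda), rescaled to [0, 1].

Branch detection is deliberately absent: the target use case is a single
linear maturation lineage (GBC -> INP -> iOSN -> mOSN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import CountForm, CountMatrix, make_count_forms

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """PCA embedding: cell x component coordinates, ordered by decreasing
    explained variance."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]


@dataclass
class DiffusionSpace:
    """Diffusion components after dropping the stationary eigenpair.

    ``eigenvalues`` are sorted decreasing in (0, 1]; ``components`` holds
    the unit-normalized eigenvectors (cells x n_comps) of the transition
    operator's symmetric conjugate, mapped back to right eigenvectors.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    root: int | None = None


@dataclass
class TrajectorySet:
    """Per-gene binned expression trajectories under the four count forms."""

    n_bins: int
    edges: np.ndarray
    occupancy: np.ndarray
    forms: dict[CountForm, pd.DataFrame] = field(repr=False)
    interpolated: np.ndarray = field(default=None, repr=False)
    zero_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.forms[CountForm.NORM].index

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_long_df(self) -> pd.DataFrame:
        mids = self.midpoints
        records = []
        for form, mat in self.forms.items():
            long = mat.stack().rename("value").reset_index()
            long.columns = ["gene", "bin", "value"]
            long["form"] = form.value
            long["pseudotime_midpoint"] = mids[long["bin"].to_numpy()]
            long["interpolated"] = self.interpolated[long["bin"].to_numpy()]
            records.append(long)
        out = pd.concat(records, ignore_index=True)
        return out[["gene", "form", "bin", "pseudotime_midpoint", "value", "interpolated"]]

    @classmethod
    def from_long_df(cls, df: pd.DataFrame) -> "TrajectorySet":
        bins = np.sort(df["bin"].unique())
        n_bins = bins.size
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        interp = np.zeros(n_bins, dtype=bool)
        flags = df.groupby("bin")["interpolated"].any()
        interp[flags.index.to_numpy()] = flags.to_numpy()
        forms = {}
        for form in CountForm:
            sub = df[df["form"] == form.value]
            if sub.empty:
                continue
            forms[form] = sub.pivot(index="gene", columns="bin", values="value")
        zero = []
        if CountForm.NORM in forms and CountForm.NORM_MAX in forms:
            zero = forms[CountForm.NORM].index.difference(
                forms[CountForm.NORM_MAX].index
            ).tolist()
        return cls(n_bins, edges, np.zeros(n_bins, dtype=int), forms, interp, zero)


# ---------------------------------------------------------------------------


def pca_embed(x, n_pcs: int = 40, scale: bool = True) -> Embedding:
    """PCA of the (HVG-masked, log-normalized) expression matrix.

    Genes are centered and, by default, scaled to unit variance before the
    decomposition.  Deterministic (full SVD).
    """
    x = np.asarray(x.toarray() if sp.issparse(x) else x, dtype=float)
    n, g = x.shape
    if n_pcs > min(n, g):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n, g)}")
    if scale:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    p = PCA(n_components=n_pcs, svd_solver="full")
    coords = p.fit_transform(x)
    return Embedding(coords, p.explained_variance_ratio_)


def knn_graph(e: Embedding, k: int = 10) -> sp.csr_matrix:
    """Symmetrized kNN graph with adaptive Gaussian kernel weights.

    Each cell is connected to its k nearest neighbors (Euclidean); the
    graph is symmetrized by union.  The kernel bandwidth for cell i is its
    distance to the ceil(k/2)-th neighbor, and the edge weight is
    exp(-d_ij^2 / (sigma_i * sigma_j)), hence in (0, 1].
    """
    n = e.coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cell count {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(e.coords)
    dist, idx = nn.kneighbors(e.coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist[:, int(np.ceil(k / 2)) - 1]
    sigma = np.where(sigma > 0, sigma, np.finfo(float).tiny ** 0.25)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    g = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    g = g.maximum(g.T)  # union symmetrization
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def diffusion_map(g: sp.spmatrix, n_comps: int = 15) -> DiffusionSpace:
    """Diffusion components of a weighted cell graph.

    The kernel is density-normalized on both sides (anisotropic exponent
    1), the transition operator is row-normalized, and the top eigenpairs
    are obtained from its symmetric conjugate; the stationary eigenvector
    (eigenvalue 1) is dropped.
    """
    g = sp.csr_matrix(g)
    n = g.shape[0]
    n_cc, labels = connected_components(g, directed=False)
    if n_cc > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"graph has {n_cc} connected components (sizes {sizes}); "
            "diffusion pseudotime requires a connected graph"
        )
    q = np.asarray(g.sum(axis=1)).ravel()
    inv_q = sp.diags(1.0 / q)
    k = inv_q @ g @ inv_q  # density normalization, alpha = 1
    d = np.asarray(k.sum(axis=1)).ravel()
    d_isqrt = sp.diags(1.0 / np.sqrt(d))
    s = d_isqrt @ k @ d_isqrt  # symmetric conjugate of D^-1 K
    s = (s + s.T) * 0.5
    ncv = min(n, max(2 * (n_comps + 1) + 1, 20))
    # largest algebraic eigenvalues: the walk operator can carry strong
    # negative spectrum (oscillatory modes) that LM would pick up instead
    evals, evecs = eigsh(
        s, k=min(n_comps + 1, n - 1), which="LA", v0=np.ones(n), ncv=ncv
    )
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the stationary eigenpair (eigenvalue 1)
    evals, evecs = evals[1:], evecs[:, 1:]
    positive = evals > 0
    evals, evecs = evals[positive], evecs[:, positive]
    # map eigenvectors of S back to right eigenvectors of D^-1 K
    evecs = (d_isqrt @ evecs)
    evecs /= np.linalg.norm(evecs, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude entry positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    return DiffusionSpace(evals, evecs)


def select_root(
    x,
    genes,
    meta: pd.DataFrame,
    root_cluster: str = "GBC",
    root_markers: list[str] | None = None,
    dspace: DiffusionSpace | None = None,
) -> int:
    """Pick the root cell for pseudotime.

    Within ``root_cluster``, the cell maximizing mean normalized marker
    expression is chosen (ties broken by lexicographically lowest
    barcode).  Without markers, the cluster cell most extreme on the
    first diffusion component is used instead (requires ``dspace``).
    """
    clusters = meta["cluster"].astype(str)
    in_cluster = (clusters == root_cluster).to_numpy()
    if not in_cluster.any():
        raise ValueError(
            f"root cluster {root_cluster!r} absent; available: "
            f"{sorted(clusters.unique())}"
        )
    cells = np.flatnonzero(in_cluster)
    barcodes = meta.index.to_numpy()
    if root_markers:
        genes = list(genes)
        cols = [genes.index(m) for m in root_markers if m in genes]
        if not cols:
            raise ValueError(f"none of the root markers {root_markers} present")
        xm = x[:, cols]
        score = np.asarray(xm.mean(axis=1)).ravel()[cells]
    else:
        if dspace is None:
            raise ValueError("root selection without markers requires a DiffusionSpace")
        psi1 = dspace.components[:, 0]
        score = np.abs(psi1 - psi1.mean())[cells]
    top = score.max()
    tied = cells[score >= top]
    return int(min(tied, key=lambda i: str(barcodes[i])))


def dpt_coordinates(d: DiffusionSpace) -> np.ndarray:
    """Cells embedded with each diffusion component scaled by
    lambda/(1-lambda); Euclidean distances here are DPT distances."""
    lam = d.eigenvalues
    usable = lam < 1.0
    if not usable.all():
        logger.warning(
            "skipping %d diffusion component(s) with eigenvalue 1",
            int((~usable).sum()),
        )
    lam = lam[usable]
    psi = d.components[:, usable]
    return psi * (lam / (1.0 - lam))


def compute_dpt(d: DiffusionSpace, root: int) -> np.ndarray:
    """Diffusion pseudotime from a root cell, rescaled to [0, 1].

    dpt(cell) is the Euclidean distance from the root in the space of
    diffusion components psi_i scaled by lambda_i / (1 - lambda_i);
    pseudotime(root) = 0 and the maximum is 1.
    """
    coords = dpt_coordinates(d)
    dist = np.linalg.norm(coords - coords[root], axis=1)
    mx = dist.max()
    if mx == 0:
        raise ValueError("degenerate diffusion space: all cells at zero distance")
    return dist / mx


def assign_bins(
    pseudotime: np.ndarray, B: int = 50, min_cells: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign cells to equal-width pseudotime bins over [0, 1].

    Returns (bin index per cell, bin edges, sparse-bin flags).  The last
    bin is right-inclusive; bins holding fewer than ``min_cells`` cells
    are flagged sparse.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if B < 2:
        raise ValueError("B must be >= 2")
    if B > pt.size:
        raise ValueError(f"B={B} exceeds cell count {pt.size}")
    edges = np.linspace(0.0, 1.0, B + 1)
    bins = np.minimum((pt * B).astype(int), B - 1)
    occupancy = np.bincount(bins, minlength=B)
    sparse = occupancy < min_cells
    return bins, edges, sparse


def bin_trajectories(
    norm_x,
    log_x,
    genes,
    bins: np.ndarray,
    B: int,
    edges: np.ndarray | None = None,
    sparse_flags: np.ndarray | None = None,
) -> TrajectorySet:
    """Average expression per gene per pseudotime bin, then build forms.

    Sparse or empty bins are filled by linear interpolation between the
    nearest populated bins (constant extension at the ends) and flagged,
    so every gene trajectory has identical length B.
    """
    if edges is None:
        edges = np.linspace(0.0, 1.0, B + 1)
    occupancy = np.bincount(bins, minlength=B)
    if sparse_flags is None:
        sparse_flags = occupancy < 1
    populated = (occupancy > 0) & ~sparse_flags
    if populated.sum() < 2:
        raise ValueError("fewer than 2 populated bins")

    def _bin_means(x) -> np.ndarray:
        x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
        sums = np.zeros((B, x.shape[1]))
        np.add.at(sums, bins, x)
        with np.errstate(invalid="ignore"):
            means = sums / occupancy[:, None]
        return means  # NaN rows for empty bins

    mids = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for name, x in (("norm", norm_x), ("log", log_x)):
        means = _bin_means(x)
        filled = means.copy()
        if (~populated).any():
            for j in range(means.shape[1]):
                filled[~populated, j] = np.interp(
                    mids[~populated], mids[populated], means[populated, j]
                )
        out[name] = pd.DataFrame(filled.T, index=pd.Index(genes, name="gene"))
    forms, zero_genes = make_count_forms(out["norm"], out["log"])
    return TrajectorySet(
        n_bins=B,
        edges=edges,
        occupancy=occupancy,
        forms=forms,
        interpolated=~populated,
        zero_genes=zero_genes,
    )
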