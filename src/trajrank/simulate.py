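"""Synthetic maturation-lineage scRNA-seq generator with known truth.

Cells carry a latent maturation time t ~ Uniform(0, 1) partitioned into
the four lineage stages (GBC / INP / iOSN / mOSN).  Each gene follows a
smooth mean program mu_g(t) drawn from four template families (sigmoid
switch-on, switch-off, Gaussian pulse, constant); UMI counts are negative
binomial around L_c * mu_g(t_c) with a log-normal library factor L_c and
shared dispersion.  Planted structure, all recorded in the truth table:

* one reference gene plus a block of coregulated genes sharing its
  switch-on template up to small parameter jitter,
* pan-neuronal genes (constant, also neuron-enriched in the companion
  "bulb" dataset from :func:`simulate_bulb`),
* odorant-receptor-like genes expressed mutually exclusively — every
  mature-stage cell expresses exactly one, at high amplitude,
* mitochondrial genes plus a small fraction of damaged cells with
  inflated mitochondrial content,
* a few basal-cell marker genes for root selection.

The generator targets the statistical assumptions the pipeline needs
(smooth programs, overdispersed counts, depth variation), not empirical
realism of any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix

STAGES = ("GBC", "INP", "iOSN", "mOSN")
TEMPLATES = ("sigmoid-on", "sigmoid-off", "pulse", "constant")
#: threshold above which an OR-like gene counts as "expressed"
OR_AMPLITUDE_THRESHOLD = 5


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_cells: int = 3000
    n_genes: int = 2000
    n_coreg: int = 25
    n_panneuronal: int = 30
    n_or: int = 100
    n_mito: int = 10
    n_gbc_markers: int = 5
    stage_boundaries: tuple[float, float, float] = (0.25, 0.5, 0.75)
    dispersion: float = 0.3  # NB: var = m + dispersion * m^2
    libsize_sigma: float = 0.35  # log-normal sd of the library factor
    #: global scale on all gene means; down-sized gene panels keep a
    #: realistic per-cell depth (and sensible default QC thresholds) by
    #: raising this
    mean_scale: float = 1.0
    frac_damaged: float = 0.03
    reference_gene: str = "Rtp1"
    ref_t0: float = 0.35
    ref_slope: float = 12.0
    ref_amplitude: float = 3.0
    coreg_t0_jitter: float = 0.01
    coreg_rel_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.n_cells, self.n_genes)):
            raise ValueError("n_cells and n_genes must be positive")
        b = self.stage_boundaries
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("stage boundaries must be strictly increasing in (0,1)")
        planted = (
            1 + self.n_coreg + self.n_panneuronal + self.n_or + self.n_mito
            + self.n_gbc_markers
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene sets ({planted}) exceed n_genes ({self.n_genes})"
            )


PRESETS = {
    "default": SimConfig(),
    "tiny": SimConfig(
        n_cells=300, n_genes=300, n_coreg=10, n_panneuronal=10, n_or=20,
        n_mito=5, n_gbc_markers=3, mean_scale=6.0,
    ),
    "stress": SimConfig(n_cells=5000, n_genes=3000, frac_damaged=0.1),
}


def _template_mean(t, template, t0, slope, amplitude, baseline, width=0.08):
    t = np.asarray(t, dtype=float)
    if template == "sigmoid-on":
        return baseline + amplitude / (1.0 + np.exp(-slope * (t - t0)))
    if template == "sigmoid-off":
        return baseline + amplitude / (1.0 + np.exp(slope * (t - t0)))
    if template == "pulse":
        return baseline + amplitude * np.exp(-((t - t0) ** 2) / (2 * width**2))
    if template == "constant":
        return np.full_like(t, baseline + amplitude)
    raise ValueError(f"unknown template {template!r}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean m, var m + phi m^2) via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(1.0 / phi, phi * mean[pos])
    return rng.poisson(lam)


def _stage_of(t: np.ndarray, boundaries) -> np.ndarray:
    idx = np.searchsorted(np.asarray(boundaries), t, side="right")
    return np.asarray(STAGES)[idx]


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene names, template assignments and flags for one dataset."""
    names: list[str] = []
    rows: list[dict] = []

    def add(name, template, t0, slope, amplitude, baseline, **flags):
        names.append(name)
        row = dict(
            gene=name, template=template, t0=t0, slope=slope,
            amplitude=amplitude, baseline=baseline,
            is_reference=False, is_coreg=False, is_panneuronal=False,
            is_or=False, is_mito=False, is_gbc_marker=False,
        )
        row.update(flags)
        rows.append(row)

    add(
        cfg.reference_gene, "sigmoid-on", cfg.ref_t0, cfg.ref_slope,
        cfg.ref_amplitude, 0.02, is_reference=True,
    )
    for i in range(cfg.n_coreg):
        add(
            f"Coreg{i + 1:03d}", "sigmoid-on",
            float(cfg.ref_t0 + rng.normal(0, cfg.coreg_t0_jitter)),
            float(cfg.ref_slope * rng.lognormal(0, cfg.coreg_rel_jitter)),
            float(cfg.ref_amplitude * rng.lognormal(0, cfg.coreg_rel_jitter)),
            0.02, is_coreg=True,
        )
    for i in range(cfg.n_panneuronal):
        add(
            f"Pann{i + 1:03d}", "constant", 0.5, 0.0,
            float(rng.lognormal(0.3, 0.5)), 0.0, is_panneuronal=True,
        )
    for i in range(cfg.n_or):
        # OR-like genes have no template-driven mean; they are assigned
        # one-per-mature-cell at sampling time
        add(f"Olfr{i + 1:04d}", "constant", 0.5, 0.0, 0.0, 0.0, is_or=True)
    for i in range(cfg.n_mito):
        add(
            f"mt-Sim{i + 1:02d}", "constant", 0.5, 0.0,
            float(rng.lognormal(1.6, 0.3)), 0.0, is_mito=True,
        )
    for i in range(cfg.n_gbc_markers):
        add(
            f"Gbcm{i + 1:02d}", "sigmoid-off", 0.12, 20.0,
            float(rng.lognormal(1.3, 0.2)), 0.02, is_gbc_marker=True,
        )
    n_background = cfg.n_genes - len(names)
    kinds = rng.choice(
        TEMPLATES, size=n_background, p=(0.25, 0.2, 0.2, 0.35)
    )
    for i, kind in enumerate(kinds):
        add(
            f"Gene{i + 1:04d}", str(kind),
            float(rng.uniform(0.05, 0.95)),
            float(rng.uniform(6.0, 20.0)),
            float(rng.lognormal(0.0, 0.8)),
            float(rng.uniform(0.0, 0.1)),
        )
    return pd.DataFrame(rows).set_index("gene")


def simulate_lineage(
    cfg: SimConfig | None = None,
    shuffle_planted: bool = False,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate one maturation-lineage dataset.

    Returns (counts, cell metadata with true latent time and stage
    labels, truth table).  With ``shuffle_planted=True`` each planted
    coregulated gene is decoupled from the reference by evaluating its
    template on an independently permuted latent-time vector: marginal
    count distributions are preserved but the coordination with the
    reference trajectory is destroyed (negative control).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_truth(cfg, rng)
    t = np.sort(rng.uniform(0.0, 1.0, cfg.n_cells))
    stage = _stage_of(t, cfg.stage_boundaries)
    lib = rng.lognormal(0.0, cfg.libsize_sigma, cfg.n_cells)

    mu = np.empty((cfg.n_cells, cfg.n_genes))
    for j, (gene, row) in enumerate(truth.iterrows()):
        tj = t
        if shuffle_planted and row["is_coreg"]:
            tj = rng.permutation(t)
        mu[:, j] = cfg.mean_scale * _template_mean(
            tj, row["template"], row["t0"], row["slope"],
            row["amplitude"], row["baseline"],
        )

    damaged = np.zeros(cfg.n_cells, dtype=bool)
    n_damaged = int(round(cfg.frac_damaged * cfg.n_cells))
    if n_damaged:
        damaged[rng.choice(cfg.n_cells, n_damaged, replace=False)] = True
    mito_cols = truth["is_mito"].to_numpy()
    mu[np.ix_(damaged, mito_cols)] *= 20.0  # inflated mitochondrial content

    counts = _nb_sample(rng, lib[:, None] * mu, cfg.dispersion)

    # mutually exclusive OR-like expression in mature cells
    or_cols = np.flatnonzero(truth["is_or"].to_numpy())
    chosen_or = np.full(cfg.n_cells, "", dtype=object)
    if or_cols.size:
        mature = np.flatnonzero(stage == "mOSN")
        pick = rng.choice(or_cols, size=mature.size)
        burst = OR_AMPLITUDE_THRESHOLD + _nb_sample(
            rng, lib[mature] * 25.0 * cfg.mean_scale, cfg.dispersion
        )
        counts[mature, pick] = burst
        chosen_or[mature] = truth.index.to_numpy()[pick]

    barcodes = [f"cell{i + 1:05d}" for i in range(cfg.n_cells)]
    meta = pd.DataFrame(
        {
            "cluster": stage,
            "true_time": t,
            "damaged": damaged,
            "chosen_or": chosen_or,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(barcodes, truth.index.tolist(), sp.csr_matrix(counts))
    return cm, meta, truth.reset_index()


def simulate_bulb(
    seed: int = 0,
    n_cells: int = 400,
    n_background: int = 170,
    pan_genes: list[str] | None = None,
    dispersion: float = 0.3,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Companion "olfactory bulb"-style dataset for pan-neuronal calling.

    Half the cells are neurons; the pan-neuronal genes are strongly
    neuron-enriched while background genes are balanced, so target-cluster
    enrichment on this dataset recovers the pan-neuronal list.
    """
    rng = np.random.default_rng(seed)
    if pan_genes is None:
        pan_genes = [f"Pann{i + 1:03d}" for i in range(30)]
    genes = list(pan_genes) + [f"Bulb{i + 1:04d}" for i in range(n_background)]
    neuron = np.arange(n_cells) < n_cells // 2
    mean = np.empty((n_cells, len(genes)))
    mean[:, : len(pan_genes)] = np.where(neuron[:, None], 5.0, 0.2)
    base = rng.lognormal(0.0, 0.6, n_background)
    mean[:, len(pan_genes):] = base[None, :]
    lib = rng.lognormal(0.0, 0.3, n_cells)
    counts = _nb_sample(rng, lib[:, None] * mean, dispersion)
    barcodes = [f"bulb{i + 1:04d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"cluster": np.where(neuron, "neuron", "other")},
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(barcodes, genes, sp.csr_matrix(counts)), meta


def write_fixture(
    cm: CountMatrix,
    meta: pd.DataFrame,
    truth: pd.DataFrame | None,
    out_dir,
    overwrite: bool = False,
) -> Path:
    """Write a simulated dataset as a Matrix Market triplet + TSVs."""
    from .core_io import write_counts

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is non-empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts(cm, out_dir, dialect="triplet")
    meta.to_csv(out_dir / "cell_meta.tsv", sep="\t")
    if truth is not None:
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir


def tiny_config(seed: int = 0) -> SimConfig:
    """The tiny preset with a chosen seed (unit-test scale)."""
    return replace(PRESETS["tiny"], seed=seed)


def default_config(seed: int = 0) -> SimConfig:
    return replace(PRESETS["default"], seed=seed)
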