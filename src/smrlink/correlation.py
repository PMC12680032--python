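"""Gene-expression vs biophysics association pipeline.

Links per-cell buoyant mass and stiffness to Smart-seq2 expression:

1. cell QC — drop cells with fewer than 1000 total reads or more than 20%
   mitochondrial reads (both strict inequalities);
2. log-normalization — counts-per-10k then ln(1+x);
3. model-specific gene exclusion — drop genes expressed (raw count > 0) in
   less than 10% of cells in *any* model, removing sex/immunoglobulin-type
   model idiosyncrasies before cross-model correlation;
4. per-gene Spearman correlation with each biophysical covariate;
5. conversion of the gene-wise rho distribution to z scores and selection
   of genes with z > 2.5;
6. combined ranking by the average z across covariates;
7. empirical per-gene null bounds from random expression/biophysics
   pairings (default 10,000 permutations, 95th percentile).

The z scores standardize rho across genes (mean/sd of the gene-wise rho
distribution) rather than Fisher-transforming each rho: a common 2.5 cutoff
applied to two differently distributed correlates is only meaningful after
cross-gene standardization.  A Fisher-transform variant is available via
``method="fisher"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = [
    "QCConfig",
    "qc_filter_cells",
    "log_normalize",
    "exclude_model_specific_genes",
    "spearman_vs_biophys",
    "rho_to_z",
    "select_top",
    "combined_rank",
    "permutation_ci",
    "correlation_table",
]


@dataclass(frozen=True)
class QCConfig:
    """Cell- and gene-level quality gates.

    ``min_total_reads`` and ``max_mito_fraction`` act per cell (a cell is
    kept when total >= min AND mito fraction <= max); the expressing-
    fraction gate acts per gene and per model.
    """

    min_total_reads: int = 1000
    max_mito_fraction: float = 0.20
    min_expressing_fraction_per_model: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if not 0 <= self.min_expressing_fraction_per_model <= 1:
            raise ValueError("min_expressing_fraction_per_model must be in [0, 1]")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")


def qc_filter_cells(
    matrix: CountMatrix, cfg: QCConfig = QCConfig()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-depth and high-mitochondrial cells.

    A cell is removed when its total read count is *below*
    ``min_total_reads`` or its mitochondrial fraction is *above*
    ``max_mito_fraction`` — a cell at exactly 1000 reads or exactly 20%
    mito is retained.  Returns the filtered matrix and a per-removed-cell
    report with reasons.
    """
    totals = matrix.counts.sum(axis=0)
    mito = matrix.counts[matrix.mito_mask()].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    low = totals < cfg.min_total_reads
    high_mito = mito_frac > cfg.max_mito_fraction
    keep = ~(low | high_mito)
    if not keep.any():
        raise ValueError("QC removed every cell")
    report = pd.DataFrame(
        {
            "cell_id": [c for c, k in zip(matrix.cells, keep) if not k],
            "total_reads": totals[~keep],
            "mito_fraction": mito_frac[~keep],
            "reason": [
                "+".join(
                    r
                    for r, f in (("low_reads", lo), ("high_mito", hm))
                    if f
                )
                for lo, hm in zip(low[~keep], high_mito[~keep])
            ],
        }
    )
    return matrix.subset(cell_mask=keep), report


def log_normalize(matrix: CountMatrix, scale: float = 10_000.0) -> np.ndarray:
    """Counts-per-``scale`` per cell, then ln(1 + x).  Genes x cells float."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-total cells present; run qc_filter_cells first")
    return np.log1p(matrix.counts / totals * scale)


def exclude_model_specific_genes(
    matrix: CountMatrix,
    model_label,
    min_fraction: float = 0.10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep genes expressed in at least ``min_fraction`` of cells in EVERY model.

    "Expressed" means raw count > 0.  A gene at exactly the threshold
    fraction in each model is retained ("less than 10%" excludes).  Returns
    a boolean gene mask and a per-gene report of the minimum expressing
    fraction across models.
    """
    models = np.asarray(model_label)
    if len(models) != len(matrix.cells):
        raise ValueError("model_label must have one entry per cell")
    expressed = matrix.counts > 0
    fractions = []
    for m in pd.unique(models):
        sel = models == m
        if not sel.any():
            raise ValueError(f"model {m!r} has zero cells")
        fractions.append(expressed[:, sel].mean(axis=1))
    min_frac = np.min(fractions, axis=0)
    keep = min_frac >= min_fraction
    report = pd.DataFrame(
        {"gene": matrix.genes, "min_expressing_fraction": min_frac, "retained": keep}
    )
    return keep, report


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return rankdata(x, axis=-1, method="average")


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, r / norm, np.nan)


def spearman_vs_biophys(norm_matrix: np.ndarray, biophys) -> np.ndarray:
    """Per-gene Spearman rho of expression against a per-cell covariate.

    Average-rank tie handling (identical to scipy.stats.spearmanr), fully
    vectorized over genes: rho is the Pearson correlation of the row ranks
    with the covariate ranks.  Constant genes get NaN and are excluded
    downstream.
    """
    norm_matrix = np.asarray(norm_matrix, float)
    biophys = np.asarray(biophys, float)
    if norm_matrix.shape[1] != biophys.size:
        raise ValueError("biophys must have one value per cell")
    if biophys.size < 3:
        raise ValueError("need at least 3 cells for correlation")
    gr = _standardize_rows(_rank_rows(norm_matrix))
    br = _standardize_rows(_rank_rows(biophys))
    if np.all(np.isnan(br)):
        raise ValueError("biophysical covariate is constant; correlation undefined")
    return gr @ br


def rho_to_z(rhos, method: str = "cross_gene") -> np.ndarray:
    """Convert a gene-wise rho vector to z scores.

    ``cross_gene`` (default) standardizes by the mean and sample sd of the
    finite rhos; ``fisher`` applies the variance-stabilizing atanh(rho)
    transform first and then standardizes the transformed values the same
    way (the two differ only in the tails).  NaN rhos stay NaN.
    """
    rhos = np.asarray(rhos, float)
    finite = np.isfinite(rhos)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite correlations")
    vals = np.arctanh(np.clip(rhos, -1 + 1e-12, 1 - 1e-12)) if method == "fisher" else rhos
    mu = vals[finite].mean()
    sd = vals[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread in correlations; z scores undefined")
    z = np.full_like(rhos, np.nan)
    z[finite] = (vals[finite] - mu) / sd
    return z


def select_top(z, genes, threshold: float = 2.5) -> list[str]:
    """Genes with z strictly greater than ``threshold``, by descending z."""
    z = np.asarray(z, float)
    order = np.argsort(-np.where(np.isfinite(z), z, -np.inf), kind="stable")
    return [genes[i] for i in order if np.isfinite(z[i]) and z[i] > threshold]


def combined_rank(z_mass, z_stiffness, genes) -> pd.DataFrame:
    """Rank genes by descending average of the two z scores.

    Ties break lexicographically by gene symbol so the ranking is
    deterministic; the rank column is a permutation of 1..G.
    """
    z_mass = np.asarray(z_mass, float)
    z_stiffness = np.asarray(z_stiffness, float)
    if not (len(z_mass) == len(z_stiffness) == len(genes)):
        raise ValueError("z vectors and gene list must share a common gene set")
    avg = (z_mass + z_stiffness) / 2.0
    df = pd.DataFrame(
        {"gene": list(genes), "z_mass": z_mass, "z_stiffness": z_stiffness, "combined_z": avg}
    )
    df = df.sort_values(["combined_z", "gene"], ascending=[False, True], na_position="last")
    df["rank_combined"] = np.arange(1, len(df) + 1)
    return df.set_index("gene").loc[list(genes)].reset_index()


def permutation_ci(
    norm_matrix: np.ndarray,
    biophys,
    n_iter: int = 10_000,
    percentile: float = 95.0,
    seed: int = 0,
    absolute: bool = False,
) -> np.ndarray:
    """Per-gene null bound on rho from random expression/biophysics pairings.

    Each iteration permutes the biophysical vector over cells and recomputes
    every gene's Spearman rho; the per-gene ``percentile`` of the signed
    null rhos (or of |rho| when ``absolute``) is returned.  Deterministic
    for a fixed seed.
    """
    if n_iter < 100:
        raise ValueError("n_iter < 100 gives unstable percentile bounds")
    norm_matrix = np.asarray(norm_matrix, float)
    biophys = np.asarray(biophys, float)
    gr = _standardize_rows(_rank_rows(norm_matrix))
    br = _standardize_rows(_rank_rows(biophys))
    if np.all(np.isnan(br)):
        raise ValueError("biophysical covariate is constant; permutation null undefined")
    rng = np.random.default_rng(seed)
    n_genes, n_cells = gr.shape
    null = np.empty((n_iter, n_genes))
    for it in range(n_iter):
        null[it] = gr @ br[rng.permutation(n_cells)]
    if absolute:
        null = np.abs(null)
    return np.percentile(null, percentile, axis=0)


def correlation_table(
    matrix: CountMatrix,
    model_label,
    mass,
    stiffness,
    cfg: QCConfig = QCConfig(),
    z_threshold: float = 2.5,
    n_iter: int = 10_000,
    seed: int = 0,
    scale: float = 10_000.0,
    z_method: str = "cross_gene",
) -> pd.DataFrame:
    """End-to-end per-gene association table.

    ``matrix`` must already be cell-QC'd and aligned with ``model_label``,
    ``mass`` and ``stiffness`` (one entry per cell).  Applies the
    model-specific gene exclusion, then computes rho/z/selection/rank and
    permutation bounds for both covariates.
    """
    keep, _ = exclude_model_specific_genes(
        matrix, model_label, cfg.min_expressing_fraction_per_model
    )
    sub = matrix.subset(gene_mask=keep)
    norm = log_normalize(sub, scale=scale)
    rho_m = spearman_vs_biophys(norm, mass)
    rho_s = spearman_vs_biophys(norm, stiffness)
    z_m = rho_to_z(rho_m, method=z_method)
    z_s = rho_to_z(rho_s, method=z_method)
    ci_m = permutation_ci(norm, mass, n_iter=n_iter, seed=seed)
    ci_s = permutation_ci(norm, stiffness, n_iter=n_iter, seed=seed + 1)
    ranked = combined_rank(z_m, z_s, sub.genes)
    table = pd.DataFrame(
        {
            "gene": sub.genes,
            "rho_mass": rho_m,
            "rho_stiffness": rho_s,
            "z_mass": z_m,
            "z_stiffness": z_s,
            "combined_z": ranked["combined_z"].to_numpy(),
            "rank_combined": ranked["rank_combined"].to_numpy(),
            "ci95_mass": ci_m,
            "ci95_stiffness": ci_s,
            "selected_mass": np.isfinite(z_m) & (z_m > z_threshold),
            "selected_stiffness": np.isfinite(z_s) & (z_s > z_threshold),
        }
    )
    return table
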