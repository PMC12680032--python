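"""Repeated-simulation experiments that characterize the pipeline.

These functions run the package's own methods over many synthetic datasets
and measure operating characteristics: type-I error and p-value uniformity
of the bootstrap-t mass-response test, its power under a 20% median mass
reduction, recovery of injected gene-biophysics associations by the z > 2.5
gate, permutation-null coverage, and the mass-stiffness decorrelation of
the generator.  The transport-LP check gives an independent oracle for the
sorted-pairing EMD.

All randomness flows from a single integer seed via ``numpy.random
.SeedSequence`` spawning, so every experiment is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import linprog
from scipy.stats import kstest, linregress

from .correlation import (
    QCConfig,
    exclude_model_specific_genes,
    log_normalize,
    permutation_ci,
    qc_filter_cells,
    rho_to_z,
    select_top,
    spearman_vs_biophys,
)
from .mass_response import bootstrap_t_test, emd_sorted
from .simulate import DrugSimConfig, LinkedSimConfig, simulate_drug_triplet, simulate_linked

__all__ = [
    "wasserstein_lp",
    "emd_oracle_check",
    "rejection_rate",
    "null_pvalue_study",
    "recovery_study",
    "permutation_null_exceedance",
    "mass_stiffness_r2",
]


def wasserstein_lp(x, z) -> float:
    """Exact 1-Wasserstein distance by a transportation linear program.

    Brute-force oracle: minimizes sum_ij c_ij |x_i - z_j| over all couplings
    with uniform marginals.  Independent of the sorted-pairing route; only
    practical for small n.
    """
    x, z = np.asarray(x, float), np.asarray(z, float)
    n, m = x.size, z.size
    cost = np.abs(x[:, None] - z[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row marginals
        row = np.zeros((n, m))
        row[i] = 1
        a_eq.append(row.ravel())
    for j in range(m):  # column marginals
        col = np.zeros((n, m))
        col[:, j] = 1
        a_eq.append(col.ravel())
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd_oracle_check(n_instances: int = 100, max_n: int = 8, seed: int = 0) -> float:
    """Max |emd_sorted/N - LP Wasserstein| over random equal-size instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_n + 1))
        x = np.sort(rng.uniform(1, 100, n))
        z = np.sort(rng.uniform(1, 100, n))
        worst = max(worst, abs(emd_sorted(x, z) / n - wasserstein_lp(x, z)))
    return worst


def _triplet_pvalues(
    cfg: DrugSimConfig,
    n_repeats: int,
    n_boot: int,
    seed: int,
    alpha: float = 0.05,
) -> np.ndarray:
    """p-values of the bootstrap-t test over repeated triplet draws."""
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    pvals = np.empty(n_repeats)
    for i, child in enumerate(children):
        s1, s2 = (int(s) for s in child.generate_state(2) % (2**31))
        z, y, x = simulate_drug_triplet(replace(cfg, seed=s1))
        pvals[i] = bootstrap_t_test(x, y, z, n_boot=n_boot, seed=s2, alpha=alpha).p_value
    return pvals


def rejection_rate(
    cfg: DrugSimConfig,
    n_repeats: int = 200,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of repeated triplet draws the test rejects at ``alpha``."""
    return float((_triplet_pvalues(cfg, n_repeats, n_boot, seed, alpha) < alpha).mean())


def null_pvalue_study(
    n_cells: int = 300,
    n_repeats: int = 1000,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and p-value uniformity under identical lognormal arms.

    The null triplet has reduction 0 and no replicate jitter, so all three
    arms are i.i.d.  Returns the empirical rejection rate at ``alpha`` and
    the Kolmogorov-Smirnov distance of the p-values from U(0, 1).
    """
    cfg = DrugSimConfig(
        n_cells=n_cells, sensitivity="resistant", mass_reduction_fraction=0.0,
        replicate_jitter=0.0,
    )
    pvals = _triplet_pvalues(cfg, n_repeats, n_boot, seed, alpha)
    ks = kstest(pvals, "uniform").statistic
    return {
        "type_i_error": float((pvals < alpha).mean()),
        "ks_distance": float(ks),
        "n_repeats": n_repeats,
    }


def recovery_study(
    n_seeds: int = 20,
    n_genes: int = 2000,
    n_injected: int = 30,
    z_threshold: float = 2.5,
    seed: int = 0,
    qc: QCConfig = QCConfig(),
) -> dict:
    """Sensitivity / false positives of z > threshold selection on synthetic data.

    Each repetition simulates the default 500-cell linked dataset with
    ``n_injected`` mass-coupled genes (no stiffness or dual coupling, so the
    mass-associated truth set is unambiguous), runs QC, the model-specific
    gene exclusion, normalization, Spearman-vs-mass, cross-gene z-scoring
    and the z > threshold gate, then scores the selection against truth.
    Also reports the mean |rho| realized for the injected genes.
    """
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    sens, fps, inj_rho = [], [], []
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        cfg = LinkedSimConfig(
            n_genes=n_genes, n_mass_genes=n_injected, n_stiff_genes=0, n_both_genes=0,
            seed=s,
        )
        dataset, truth = simulate_linked(cfg)
        filtered, _ = qc_filter_cells(dataset.matrix, qc)
        keep_cells = set(filtered.cells)
        cell_mask = np.fromiter((c in keep_cells for c in dataset.matrix.cells), bool)
        models = dataset.models()[cell_mask]
        mass = dataset.biophys_vector("buoyant_mass")[cell_mask]
        gene_keep, _ = exclude_model_specific_genes(
            filtered, models, qc.min_expressing_fraction_per_model
        )
        sub = filtered.subset(gene_mask=gene_keep)
        norm = log_normalize(sub)
        rho = spearman_vs_biophys(norm, mass)
        z = rho_to_z(rho)
        selected = set(select_top(z, sub.genes, threshold=z_threshold))
        truth_set = set(truth.mass_associated)
        sens.append(len(selected & truth_set) / len(truth_set))
        fps.append(len(selected - truth_set))
        inj_mask = np.fromiter((g in truth_set for g in sub.genes), bool)
        inj_rho.append(float(np.abs(rho[inj_mask]).mean()))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positives": float(np.mean(fps)),
        "injected_mean_abs_rho": float(np.mean(inj_rho)),
        "n_seeds": n_seeds,
    }


def permutation_null_exceedance(
    n_genes: int = 2000,
    n_cells: int = 500,
    n_iter: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of independent-null genes whose observed rho exceeds its
    95th-percentile permutation bound; ~0.05 by construction."""
    cfg = LinkedSimConfig(
        n_genes=n_genes,
        cells_per_model=(n_cells // 3 + n_cells % 3, n_cells // 3, n_cells // 3),
        n_mass_genes=0, n_stiff_genes=0, n_both_genes=0,
        frac_lowquality_cells=0.0, seed=seed,
    )
    dataset, _ = simulate_linked(cfg)
    norm = log_normalize(dataset.matrix)
    mass = dataset.biophys_vector("buoyant_mass")
    rho = spearman_vs_biophys(norm, mass)
    bound = permutation_ci(norm, mass, n_iter=n_iter, seed=seed + 1)
    ok = np.isfinite(rho)
    return float((rho[ok] > bound[ok]).mean())


def mass_stiffness_r2(n_seeds: int = 20, seed: int = 0) -> float:
    """Mean R^2 of stiffness on mass over repeated default simulations."""
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    r2 = []
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        dataset, _ = simulate_linked(LinkedSimConfig(seed=s))
        mass = dataset.biophys_vector("buoyant_mass")
        stiff = dataset.biophys_vector("stiffness")
        r2.append(linregress(mass, stiff).rvalue ** 2)
    return float(np.mean(r2))
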