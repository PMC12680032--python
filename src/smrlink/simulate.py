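"""Synthetic paired biophysics + expression data and drug-response triplets.

The study's patient and PDX inputs are not deposited, so every stage of the
pipeline is exercised on synthetic data with the same statistical structure:

* **Linked datasets** — per cell: a model (three PDX-like populations with
  different median buoyant mass), a cell-cycle phase (G0/G1, S, G2/M) whose
  multiplier raises mass through the cycle, a within-phase lognormal mass,
  and an *independent* lognormal stiffness (the platform observes mass and
  stiffness to be essentially decorrelated, R^2 on the order of 1e-3).
  Counts are negative binomial per gene with a lognormal per-cell library
  size; a designated subset of genes has its log-mean coupled linearly to
  the standardized mass and/or stiffness covariate, giving a tunable
  Spearman-scale association with known ground truth.  A configurable
  fraction of cells is made deliberately low-quality (under 1000 reads, or
  over 20% mitochondrial) so QC has known targets.

* **Drug triplets** — reference Z and vehicle Y drawn i.i.d. from a
  lognormal baseline (the vehicle's median perturbed by a small replicate
  jitter), and a drug arm X whose median is reduced by a fixed fraction in
  "sensitive" samples and untouched in "resistant" ones.

Defaults: 3 models x ~167 cells = 500 cells and 2000 genes (a paper-scale
500 x 9442 preset is available via ``paper_scale_config``); model mass
medians 59/47/44 pg (lymphoma-cell magnitudes); cell-cycle multipliers
(1, 1.3, 1.7); NB dispersion 0.5; drug-arm median mass reduction 20% at
1000 cells/arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, PairedDataset, SMREventTable

__all__ = [
    "LinkedSimConfig",
    "DrugSimConfig",
    "LinkedTruth",
    "simulate_linked",
    "simulate_drug_triplet",
    "paper_scale_config",
]

_PHASES = ("G0G1", "S", "G2M")


@dataclass(frozen=True)
class LinkedSimConfig:
    """Configuration of the linked biophysics + expression generator."""

    cells_per_model: tuple[int, ...] = (167, 167, 166)
    n_genes: int = 2000
    mass_median_per_model: tuple[float, ...] = (59.0, 47.0, 44.0)  # pg
    mass_lognormal_sigma: float = 0.25  # log-units within phase
    stiffness_median: float = 1.0  # a.u.
    stiffness_lognormal_sigma: float = 0.3
    cellcycle_fractions: tuple[float, float, float] = (0.65, 0.20, 0.15)
    cellcycle_mass_multipliers: tuple[float, float, float] = (1.0, 1.3, 1.7)
    n_mass_genes: int = 30
    n_stiff_genes: int = 30
    n_both_genes: int = 10
    effect_size: float = 0.3  # log-fold change per SD of the covariate
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    library_size_median: float = 50_000.0
    library_size_sigma: float = 0.35
    mito_fraction_beta: tuple[float, float] = (2.0, 38.0)  # mean 5%
    n_mito_genes: int = 13
    frac_lowquality_cells: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mass_median_per_model) != len(self.cells_per_model):
            raise ValueError("one mass median per model required")
        if abs(sum(self.cellcycle_fractions) - 1.0) > 1e-9:
            raise ValueError("cellcycle_fractions must sum to 1")
        m = self.cellcycle_mass_multipliers
        if not (m[0] < m[1] < m[2]) or m[0] != 1.0:
            raise ValueError("cellcycle multipliers must be (1, m_S, m_G2M) increasing")
        n_special = self.n_mass_genes + self.n_stiff_genes + self.n_both_genes
        if n_special + self.n_mito_genes > self.n_genes:
            raise ValueError("designated gene sets exceed n_genes")
        if not 0 <= self.frac_lowquality_cells < 1:
            raise ValueError("frac_lowquality_cells must be in [0, 1)")


def paper_scale_config(**overrides) -> LinkedSimConfig:
    """Preset at the platform's published scale: 500 cells x 9442 genes."""
    return replace(LinkedSimConfig(n_genes=9442), **overrides)


@dataclass(frozen=True)
class DrugSimConfig:
    """Configuration of the reference/vehicle/drug mass-triplet generator."""

    n_cells: int = 1000  # per arm
    baseline_median: float = 60.0  # pg
    baseline_sigma: float = 0.25  # lognormal log-sd
    sensitivity: str = "sensitive"
    mass_reduction_fraction: float = 0.20
    replicate_jitter: float = 0.01  # log-sd of the vehicle median perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity not in ("sensitive", "resistant"):
            raise ValueError("sensitivity must be 'sensitive' or 'resistant'")
        if not 0.0 <= self.mass_reduction_fraction <= 0.5:
            raise ValueError("mass_reduction_fraction must be in [0, 0.5]")
        if self.n_cells < 50:
            raise ValueError("need at least 50 cells per arm")


@dataclass(frozen=True)
class LinkedTruth:
    """Ground truth of one linked simulation."""

    mass_genes: list[str]
    stiffness_genes: list[str]
    both_genes: list[str]
    effect_size: float
    phase: np.ndarray  # per-cell phase label
    lowquality_cells: list[str]

    @property
    def mass_associated(self) -> list[str]:
        return self.mass_genes + self.both_genes

    @property
    def stiffness_associated(self) -> list[str]:
        return self.stiffness_genes + self.both_genes


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def simulate_linked(cfg: LinkedSimConfig = LinkedSimConfig()) -> tuple[PairedDataset, LinkedTruth]:
    """Generate a paired dataset plus its ground-truth record.

    Bit-identical output for a fixed config (the seed is part of the
    config).
    """
    rng = np.random.default_rng(cfg.seed)
    n_models = len(cfg.cells_per_model)
    n_cells = sum(cfg.cells_per_model)

    model = np.repeat(np.arange(n_models), cfg.cells_per_model)
    phase_idx = rng.choice(3, size=n_cells, p=cfg.cellcycle_fractions)
    medians = np.asarray(cfg.mass_median_per_model)[model]
    multipliers = np.asarray(cfg.cellcycle_mass_multipliers)[phase_idx]
    mass = medians * multipliers * np.exp(rng.normal(0, cfg.mass_lognormal_sigma, n_cells))
    stiffness = cfg.stiffness_median * np.exp(
        rng.normal(0, cfg.stiffness_lognormal_sigma, n_cells)
    )

    # gene identity layout: mito first, then the coupled sets, then background
    genes = []
    genes += [f"MT-G{i}" for i in range(cfg.n_mito_genes)]
    mass_genes = [f"MASSG{i}" for i in range(cfg.n_mass_genes)]
    stiff_genes = [f"STIFFG{i}" for i in range(cfg.n_stiff_genes)]
    both_genes = [f"BOTHG{i}" for i in range(cfg.n_both_genes)]
    genes += mass_genes + stiff_genes + both_genes
    genes += [f"BG{i}" for i in range(cfg.n_genes - len(genes))]

    # relative expression levels (moderately dispersed lognormal) per gene
    rel = np.exp(rng.normal(0, 1.2, cfg.n_genes))
    z_mass = _standardize(np.log(mass))
    z_stiff = _standardize(np.log(stiffness))
    coupling = np.zeros((cfg.n_genes, n_cells))
    sl = slice(cfg.n_mito_genes, cfg.n_mito_genes + cfg.n_mass_genes)
    coupling[sl] = cfg.effect_size * z_mass
    sl = slice(sl.stop, sl.stop + cfg.n_stiff_genes)
    coupling[sl] = cfg.effect_size * z_stiff
    sl = slice(sl.stop, sl.stop + cfg.n_both_genes)
    coupling[sl] = cfg.effect_size * (z_mass + z_stiff) / 2.0

    # per-cell depth; a designated subset is made QC-failing
    depth = cfg.library_size_median * np.exp(rng.normal(0, cfg.library_size_sigma, n_cells))
    n_low = int(round(cfg.frac_lowquality_cells * n_cells))
    low_idx = rng.choice(n_cells, size=n_low, replace=False)
    mito_frac = rng.beta(*cfg.mito_fraction_beta, size=n_cells)
    low_depth_idx, high_mito_idx = [], []
    for j, i in enumerate(low_idx):
        if j % 2 == 0:
            depth[i] = rng.uniform(100, 700)  # fails the read-count gate
            low_depth_idx.append(i)
        else:
            mito_frac[i] = rng.uniform(0.30, 0.60)  # fails the mito gate
            high_mito_idx.append(i)

    # NB mean: depth split between mito block (mito_frac) and the rest
    rel_expr = rel[:, None] * np.exp(coupling)
    is_mito = np.zeros(cfg.n_genes, bool)
    is_mito[: cfg.n_mito_genes] = True
    body = rel_expr[~is_mito]
    body = body / body.sum(axis=0, keepdims=True) * (depth * (1 - mito_frac))
    mito_body = rel_expr[is_mito]
    mito_body = mito_body / mito_body.sum(axis=0, keepdims=True) * (depth * mito_frac)
    mu = np.empty((cfg.n_genes, n_cells))
    mu[~is_mito] = body
    mu[is_mito] = mito_body

    # NB2 via gamma-Poisson: shape r = 1/dispersion, var = mu + dispersion mu^2
    r = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(r, mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    # the low-quality designation is a hard contract (QC tests rely on it);
    # count noise can pull a cell back over a gate, so enforce deterministically
    for i in low_depth_idx:
        total = counts[:, i].sum()
        if total >= 1000:
            counts[:, i] = counts[:, i] * 900 // total
    for i in high_mito_idx:
        m_tot = counts[is_mito, i].sum()
        b_tot = counts[~is_mito, i].sum()
        if m_tot + b_tot == 0 or m_tot / (m_tot + b_tot) <= 0.20:
            k = int(np.ceil((b_tot + 1) / (3 * max(m_tot, 1))))  # push frac above 25%
            counts[is_mito, i] = np.maximum(counts[is_mito, i] * k, 1)

    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    model_names = [f"MODEL{m+1}" for m in range(n_models)]
    events = SMREventTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": [model_names[m] for m in model],
                "condition": "untyped",
                "buoyant_mass": mass,
                "stiffness": stiffness,
            }
        )
    )
    matrix = CountMatrix(
        genes=genes,
        cells=cell_ids,
        counts=counts,
        mito_genes=[g for g in genes if g.startswith("MT-")],
    )
    dataset = PairedDataset(
        events=events,
        matrix=matrix,
        model_label=pd.Series([model_names[m] for m in model], index=cell_ids),
    )
    truth = LinkedTruth(
        mass_genes=mass_genes,
        stiffness_genes=stiff_genes,
        both_genes=both_genes,
        effect_size=cfg.effect_size,
        phase=np.asarray(_PHASES)[phase_idx],
        lowquality_cells=[cell_ids[i] for i in sorted(low_idx)],
    )
    return dataset, truth


def simulate_drug_triplet(cfg: DrugSimConfig = DrugSimConfig()):
    """Generate (Z reference, Y vehicle, X drug) buoyant-mass vectors.

    Z and Y are i.i.d. from the lognormal baseline, except that Y's median
    carries a small multiplicative replicate jitter; X's median is reduced
    by ``mass_reduction_fraction`` when the sample is sensitive and is
    untouched when resistant.  Returns three arrays (z, y, x), bit-identical
    for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    med = cfg.baseline_median
    z = med * np.exp(rng.normal(0, cfg.baseline_sigma, cfg.n_cells))
    y_med = med * np.exp(rng.normal(0, cfg.replicate_jitter)) if cfg.replicate_jitter else med
    y = y_med * np.exp(rng.normal(0, cfg.baseline_sigma, cfg.n_cells))
    x_med = med * (1 - cfg.mass_reduction_fraction) if cfg.sensitivity == "sensitive" else med
    x = x_med * np.exp(rng.normal(0, cfg.baseline_sigma, cfg.n_cells))
    return z, y, x
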