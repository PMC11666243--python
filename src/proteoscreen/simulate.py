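"""Synthetic data generators for the sorted-bin screen, lipidome, and cytometry assays.

The screen generator emulates a pooled CRISPRi FACS screen read out by an
aggregate-binding dye: each cell carries one guide, guides targeting a gene
shift a latent staining phenotype, cells are sorted into top/bottom quartile
bins on the dye intensity after correcting for the correlation between cell
size and staining, and guide abundance in each bin is quantified by
sequencing.  The lipidome generator emulates a perturbation panel in which
log lipid abundance is linearly coupled to the aggregation phenotype with a
class-structured coupling strength.  The flow-cytometry generator produces
event-level tables with spike-in and background populations and a
ratiometric pH calibration series.

All generators return the ground truth used, so downstream estimators can be
tested for recovery, calibration, and error control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimParams",
    "LipidClassSpec",
    "LipidSimParams",
    "FlowPopulation",
    "SimulationTruth",
    "gate_bins",
    "simulate_screen",
    "simulate_lipidome",
    "simulate_flow_fixtures",
    "simulate_ph_series",
]


@dataclass
class ScreenSimParams:
    """Parameters of the sorted-bin screen simulator.

    The defaults describe a scaled-down genome-wide CRISPRi screen: 5 guides
    per gene plus a large non-targeting (NT) negative-control set, quartile
    sorting (``bin_fraction=0.25``), and a per-gene effect on the latent
    staining phenotype expressed in units of the per-cell noise SD.
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    n_nt_guides: int = 500
    #: fraction of genes with a true (non-null) effect
    frac_nonnull: float = 0.10
    #: magnitude of a non-null gene's shift of the latent phenotype (sign random)
    effect_mean: float = 2.0
    #: SD of gene-to-gene jitter around ``effect_mean``
    effect_sd: float = 0.0
    cells_per_guide: int = 250
    n_replicates: int = 2
    #: slope of observed log-intensity on the standard-normal cell-size covariate
    size_coupling_beta: float = 1.0
    #: SD of the per-cell latent phenotype noise
    cell_noise_sd: float = 1.0
    #: SD of measurement noise added on top of the latent phenotype
    intensity_noise_sd: float = 0.1
    #: fraction of gated cells sorted into each of the two bins
    bin_fraction: float = 0.25
    reads_per_bin: int = 1_000_000
    #: Dirichlet concentration scale for overdispersed counts; None = multinomial
    overdispersion: float | None = None
    #: gate on the residual of intensity regressed on size (True) or raw intensity
    gate_on_residual: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.bin_fraction <= 0.5:
            raise ValueError("bin_fraction must lie in (0, 0.5]")
        if min(self.n_genes, self.guides_per_gene, self.cells_per_guide,
               self.n_replicates, self.reads_per_bin) <= 0:
            raise ValueError("counts must be positive")
        if self.n_nt_guides < 0:
            raise ValueError("n_nt_guides must be non-negative")
        if not 0.0 <= self.frac_nonnull <= 1.0:
            raise ValueError("frac_nonnull must lie in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")


@dataclass
class LipidClassSpec:
    """One lipid class: name, species count, class-level phenotype coupling."""

    name: str
    n_species: int
    #: mean slope of species log-abundance on the phenotype
    gamma: float = 0.0
    #: SD of species-level jitter around the class coupling
    jitter_sd: float = 0.05


def _default_lipid_classes() -> list[LipidClassSpec]:
    # Sphingomyelin and cholesterol-ester abundances track the aggregation
    # phenotype; ceramide-family classes serve as uncoupled counterexamples.
    return [
        LipidClassSpec("SM", 12, gamma=1.0),
        LipidClassSpec("CE", 10, gamma=0.8),
        LipidClassSpec("Cer", 15, gamma=0.0),
        LipidClassSpec("LacCer", 8, gamma=0.0),
        LipidClassSpec("HexCer", 10, gamma=0.0),
    ]


@dataclass
class LipidSimParams:
    """Parameters of the lipidome simulator.

    ``n_perturbations`` defaults to 12, the scale of a focused panel of
    lipid-pathway knockdowns; phenotype values are replicate-averaged
    log-scale measurements normalized to a non-targeting control, drawn
    standard normal.
    """

    n_perturbations: int = 12
    classes: list[LipidClassSpec] = field(default_factory=_default_lipid_classes)
    #: residual SD of species log-abundance around the linear model
    noise_sd: float = 0.3
    #: SD of the phenotype across perturbations
    phenotype_sd: float = 1.0
    #: SD of species baseline log-abundance
    baseline_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_perturbations < 3:
            raise ValueError("need at least 3 perturbations (R^2 undefined below)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.classes:
            raise ValueError("at least one lipid class required")
        for c in self.classes:
            if c.n_species < 2:
                raise ValueError(f"class {c.name!r} needs >= 2 species")


@dataclass
class FlowPopulation:
    """A log-normal cytometry population: per-channel median and log-scale CV."""

    label: str
    n_events: int
    #: channel name -> median intensity (arbitrary fluorescence units)
    medians: dict[str, float] = field(default_factory=dict)
    #: SD of log-intensity around log(median)
    log_sd: float = 0.25


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, keyed by gene or lipid class."""

    gene_effects: pd.DataFrame | None = None
    class_coupling: pd.DataFrame | None = None


def gate_bins(intensity: np.ndarray, size: np.ndarray, bin_fraction: float,
              gate_on_residual: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Sort-gate cell indices into (high, low) bins of the staining readout.

    With ``gate_on_residual`` the gate value is the OLS residual of
    intensity on the cell-size covariate, removing the size-driven staining
    component before the quantile cut; otherwise raw intensity is used.
    Each bin holds exactly ``floor(bin_fraction * n_cells)`` cells.
    """
    n = intensity.size
    if gate_on_residual:
        beta_hat = np.cov(intensity, size)[0, 1] / np.var(size)
        gate_value = intensity - beta_hat * (size - size.mean())
    else:
        gate_value = intensity
    n_bin = int(math.floor(bin_fraction * n))
    order = np.argsort(gate_value, kind="stable")
    return order[-n_bin:], order[:n_bin]


def simulate_screen(params: ScreenSimParams) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a sorted-bin CRISPRi screen and return (counts, truth).

    Per cell the latent phenotype is ``z = effect(gene) + N(0, cell_noise_sd)``
    and the observed log staining intensity is ``z + beta*size + eps`` with a
    standard-normal size covariate.  Gating regresses intensity on size (OLS)
    and sorts the top and bottom ``bin_fraction`` quantiles of the residual
    into the high and low bins; guide abundance per bin is then sampled
    multinomially at ``reads_per_bin`` depth (optionally Dirichlet-multinomial).

    Returns a tidy count table with columns ``guide_id, gene, is_nt`` and
    ``high_rep{r}, low_rep{r}`` for each replicate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes = np.array([f"gene{i:05d}" for i in range(params.n_genes)])
    n_nonnull = int(round(params.frac_nonnull * params.n_genes))
    effects = np.zeros(params.n_genes)
    if n_nonnull:
        idx = rng.choice(params.n_genes, size=n_nonnull, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_nonnull)
        effects[idx] = signs * (params.effect_mean
                                + params.effect_sd * rng.standard_normal(n_nonnull))

    guide_gene_idx = np.repeat(np.arange(params.n_genes), params.guides_per_gene)
    n_targeting = guide_gene_idx.size
    n_guides = n_targeting + params.n_nt_guides
    guide_ids = np.array(
        [f"{genes[g]}_sg{i % params.guides_per_gene}" for i, g in
         zip(range(n_targeting), guide_gene_idx)]
        + [f"NT_sg{i:05d}" for i in range(params.n_nt_guides)]
    )
    guide_effect = np.concatenate(
        [effects[guide_gene_idx], np.zeros(params.n_nt_guides)])
    gene_of_guide = np.concatenate(
        [genes[guide_gene_idx], np.repeat("non-targeting", params.n_nt_guides)])
    is_nt = np.concatenate(
        [np.zeros(n_targeting, bool), np.ones(params.n_nt_guides, bool)])

    n_cells = n_guides * params.cells_per_guide
    cell_guide = np.repeat(np.arange(n_guides), params.cells_per_guide)

    data: dict[str, np.ndarray] = {}
    for rep in range(1, params.n_replicates + 1):
        z = guide_effect[cell_guide] + params.cell_noise_sd * rng.standard_normal(n_cells)
        size = rng.standard_normal(n_cells)
        intensity = (z + params.size_coupling_beta * size
                     + params.intensity_noise_sd * rng.standard_normal(n_cells))
        high_idx, low_idx = gate_bins(intensity, size, params.bin_fraction,
                                      params.gate_on_residual)
        low_cells = cell_guide[low_idx]
        high_cells = cell_guide[high_idx]
        for bin_name, members in (("high", high_cells), ("low", low_cells)):
            freq = np.bincount(members, minlength=n_guides).astype(float)
            p = freq / freq.sum()
            if params.overdispersion is not None:
                alpha = np.maximum(p * params.overdispersion, 1e-12)
                p = rng.dirichlet(alpha)
            data[f"{bin_name}_rep{rep}"] = rng.multinomial(params.reads_per_bin, p)

    counts = pd.DataFrame({"guide_id": guide_ids, "gene": gene_of_guide,
                           "is_nt": is_nt, **data})
    truth = SimulationTruth(gene_effects=pd.DataFrame(
        {"gene": genes, "true_effect": effects, "is_null": effects == 0.0}))
    return counts, truth


def simulate_lipidome(
    params: LipidSimParams,
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Simulate a species x perturbation log-abundance table and its phenotype.

    Species ``s`` of class ``c`` under perturbation ``j`` has log-abundance
    ``alpha_s + gamma_s * phenotype_j + N(0, noise_sd)`` with
    ``gamma_s ~ N(gamma_c, jitter_sd)``.  Values mimic replicate-averaged,
    NT-normalized log measurements.

    Returns ``(table, phenotype, truth)`` where ``table`` has columns
    ``species_id, lipid_class`` plus one column per perturbation and
    ``phenotype`` is indexed by perturbation id.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    pert_ids = [f"pert{j:03d}" for j in range(params.n_perturbations)]
    phenotype = pd.Series(
        params.phenotype_sd * rng.standard_normal(params.n_perturbations),
        index=pert_ids, name="proteostat")

    rows = []
    abund = []
    for cls in params.classes:
        gamma_s = cls.gamma + cls.jitter_sd * rng.standard_normal(cls.n_species)
        alpha_s = params.baseline_sd * rng.standard_normal(cls.n_species)
        noise = params.noise_sd * rng.standard_normal(
            (cls.n_species, params.n_perturbations))
        abund.append(alpha_s[:, None] + gamma_s[:, None] * phenotype.values + noise)
        rows.extend((f"{cls.name}_{i:02d}", cls.name) for i in range(cls.n_species))

    table = pd.DataFrame(np.vstack(abund), columns=pert_ids)
    table.insert(0, "species_id", [r[0] for r in rows])
    table.insert(1, "lipid_class", [r[1] for r in rows])
    truth = SimulationTruth(class_coupling=pd.DataFrame(
        {"lipid_class": [c.name for c in params.classes],
         "gamma": [c.gamma for c in params.classes]}))
    return table, phenotype, truth


def simulate_flow_fixtures(
    populations: list[FlowPopulation], seed: int = 0
) -> pd.DataFrame:
    """Generate an event-level cytometry table from log-normal populations.

    Returns a long table with ``event_id``, ``population`` and one column per
    channel; intensities are log-normal around each population's stated
    channel median so that the empirical median converges to it.
    """
    if not populations:
        raise ValueError("at least one population required")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for pop in populations:
        if pop.n_events <= 0:
            raise ValueError(f"population {pop.label!r} is empty")
        if not pop.medians:
            raise ValueError(f"population {pop.label!r} defines no channels")
        cols = {"event_id": np.arange(offset, offset + pop.n_events),
                "population": pop.label}
        for channel, med in pop.medians.items():
            cols[channel] = med * np.exp(
                pop.log_sd * rng.standard_normal(pop.n_events))
        frames.append(pd.DataFrame(cols))
        offset += pop.n_events
    return pd.concat(frames, ignore_index=True)


def simulate_ph_series(
    ph_values: np.ndarray | list[float],
    *,
    n_events: int = 2000,
    pka: float = 5.9,
    ratio_min: float = 0.05,
    ratio_max: float = 3.0,
    mcherry_median: float = 1000.0,
    bg_sfgfp: float = 50.0,
    bg_mcherry: float = 40.0,
    log_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a ratiometric pH-reporter calibration series.

    The pH-sensitive channel (sfGFP-like) follows a Henderson–Hasselbalch
    sigmoid in pH while the reference channel (mCherry-like) is pH-inert, so
    the background-corrected ratio is strictly increasing in pH.  Events
    include an additive background so downstream background subtraction is
    exercised.  Returns event-level rows with columns ``ph, population,
    sfgfp, mcherry``; each pH point also carries a matched ``non-reporter``
    background population.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for ph in np.asarray(ph_values, dtype=float):
        frac = 1.0 / (1.0 + 10.0 ** (pka - ph))
        ratio = ratio_min + (ratio_max - ratio_min) * frac
        sfgfp_med = bg_sfgfp + ratio * (mcherry_median - bg_mcherry)
        for pop, g_med, m_med in (
            ("reporter", sfgfp_med, mcherry_median),
            ("non-reporter", bg_sfgfp, bg_mcherry),
        ):
            frames.append(pd.DataFrame({
                "ph": ph,
                "population": pop,
                "sfgfp": g_med * np.exp(log_sd * rng.standard_normal(n_events)),
                "mcherry": m_med * np.exp(log_sd * rng.standard_normal(n_events)),
            }))
    return pd.concat(frames, ignore_index=True)
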