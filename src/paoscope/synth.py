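"""Design-structured synthetic data with planted treatment effects.

Emulates the study layout this package analyzes: a warming x clipping
factorial grassland experiment (4 treatments x 6 replicates = 24 soil
samples), FACS-sorted PAO 16S OTU tables, PICRUSt2/Tax4Fun2-style function
tables, pooled-replicate single-cell Raman spectra (2 drops x 100 cells per
pooled sample), and environment/ecosystem-flux tables. Effects are planted
with configurable sizes whose default directions follow the study system:
warming raises PAO diversity, abundance and cooperative co-occurrence while
lowering bulk diversity; warming raises glycogen/PHA and lowers polyP/fatty
acids; warming raises soil temperature and lowers moisture and total P.

Every generator draws from a named substream of one root seed, so identical
parameters give bit-identical outputs, and each generator returns (or embeds)
a ground-truth record for downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import substream
from .community import OtuTable, FunctionTable, PAO_GENES, pool_replicates
from .diversity import shannon
from .raman import SpectraSet

__all__ = [
    "TREATMENTS",
    "SynthParams",
    "Band",
    "SpectrumArchetype",
    "default_archetypes",
    "gen_design",
    "gen_otu_table",
    "gen_function_table",
    "gen_spectra",
    "gen_env",
    "gen_all",
]

# treatment code -> (warming, clipping); C/U = clipped/unclipped, C/W = control/warmed
TREATMENTS: dict[str, tuple[int, int]] = {
    "CC": (0, 1),
    "UC": (0, 0),
    "CW": (1, 1),
    "UW": (1, 0),
}

_PAO_GENERA = [
    "Sphingomonas", "Cupriavidus", "Azospirillum", "Pseudomonas",
    "Dechloromonas", "Rhodopseudomonas", "Acinetobacter", "Burkholderia",
    "Ramlibacter", "Massilia", "Variovorax", "Bradyrhizobium",
]


@dataclass
class SynthParams:
    """All tunables of the synthetic study, with the study design as default.

    Shannon-effect sizes are on the natural-log Shannon scale; abundance and
    biomarker effects are multiplicative (keeps everything nonnegative);
    environment effects are additive path coefficients in each variable's
    own units.
    """

    seed: int = 0
    # design
    n_blocks: int = 6
    n_reps: int = 6
    # OTU table
    n_taxa: int = 300
    n_pao_taxa: int = 60
    depth: int = 50_000
    pao_share_base: float = 0.10
    warming_pao_abund_mult: float = 1.25
    pao_shannon_base: float = 2.6
    pao_shannon_gradient: float = 0.0
    warming_pao_shannon: float = 0.5
    clipping_pao_shannon: float = 0.0
    interaction_pao_shannon: float = 0.0
    bulk_shannon_base: float = 4.6
    warming_bulk_shannon: float = -0.3
    block_sd: float = 0.04
    shannon_sd: float = 0.03
    lognormal_sigma: float = 1.2
    abundance_floor_frac: float = 0.15
    dm_concentration: float = 1e5
    taxon_noise_sd: float = 0.18
    # co-occurrence structure (latent factor on PAO taxa)
    factor_scale_warm: float = 1.0
    loaded_frac_warm: float = 0.55
    loaded_frac_ambient: float = 0.2
    factor_scale_ambient: float = 0.75
    loading_pos_frac_warm: float = 1.0
    coop_block_sd: float = 0.8
    loading_pos_frac_ambient: float = 0.35
    # table metadata
    frac_missing_genus: float = 0.05
    frac_low_escore: float = 0.05
    # function table
    gene_prob_nonpao: float = 0.25
    n_categories: int = 25
    redundancy: float = 0.5
    contribution_sigma: float = 0.5
    # spectra
    n_drops: int = 2
    cells_per_drop: int = 100
    spectra_noise_sd: float = 0.05
    baseline_scale: float = 0.5
    band_jitter_sd: float = 0.15
    warming_biomarker_mults: dict = field(
        default_factory=lambda: {"glycogen": 1.6, "pha": 1.3, "polyp": 0.7, "fa": 0.5}
    )
    # functionality-biodiversity coupling (H_fun = a + b ln H_tax + noise)
    fun_intercept: float = 0.3
    fun_slope: float = 1.1
    fun_sd: float = 0.04
    # environment
    env_noise_scale: float = 1.0

    def __post_init__(self):
        if self.n_pao_taxa > self.n_taxa:
            raise ValueError("n_pao_taxa must not exceed n_taxa")
        for name in ("shannon_sd", "block_sd", "taxon_noise_sd", "spectra_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------


def gen_design(n_blocks: int = 6, n_reps: int = 6) -> pd.DataFrame:
    """Factorial sample design: 4 treatments x ``n_reps`` replicates.

    Replicates are assigned to blocks round-robin, so with n_blocks = n_reps
    every block holds one replicate of each treatment (the default 24-sample
    layout).
    """
    if n_blocks < 1 or n_reps < 1:
        raise ValueError("n_blocks and n_reps must be positive")
    rows = []
    for treat, (warm, clip) in TREATMENTS.items():
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{treat}_{rep:02d}",
                    "treatment": treat,
                    "warming": warm,
                    "clipping": clip,
                    "block": (rep - 1) % n_blocks + 1,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# planted-Shannon composition machinery
# --------------------------------------------------------------------------


def _shannon_of_power(profile: np.ndarray, gamma: float, floor_frac: float) -> float:
    p = profile**gamma
    p = (1.0 - floor_frac) * p / p.sum() + floor_frac / len(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _solve_power_for_shannon(
    profile: np.ndarray, h_target: float, floor_frac: float = 0.0
) -> np.ndarray:
    """Tilt ``profile`` by a power so its Shannon equals ``h_target``.

    Raising the exponent sharpens the profile (lower H); gamma -> 0 gives the
    uniform maximum ln(k). ``floor_frac`` of the mass is held as a uniform
    floor so no taxon is ever driven to negligible abundance (keeps every
    planted taxon above downstream abundance filters); the target is clipped
    into the attainable range.
    """
    k = len(profile)
    q = profile / profile.sum()
    h_max = _shannon_of_power(q, 1e-9, floor_frac)
    h_min = _shannon_of_power(q, 40.0, floor_frac)
    h_target = float(np.clip(h_target, h_min + 1e-6, h_max - 1e-6))
    gamma = brentq(
        lambda g: _shannon_of_power(q, g, floor_frac) - h_target, 1e-9, 40.0, xtol=1e-10
    )
    p = q**gamma
    return (1.0 - floor_frac) * p / p.sum() + floor_frac / k


# --------------------------------------------------------------------------
# OTU table
# --------------------------------------------------------------------------


def gen_otu_table(
    design: pd.DataFrame, params: SynthParams
) -> tuple[OtuTable, dict]:
    """Synthesize a FACS-sorted-style OTU count table with planted effects.

    Per sample, the PAO block's composition is a log-normal base profile
    power-tilted to a planted Shannon target (treatment effects + block
    intercept + noise), then perturbed by a sample latent factor (shared
    loadings give the co-occurrence signal; warming uses stronger, more
    positively aligned loadings) and re-tilted to restore the target. The
    bulk (non-PAO) block gets its own planted Shannon with the warming sign
    reversed. Counts are Dirichlet-multinomial draws at fixed depth.

    Returns the table and a ground-truth record of everything planted.
    """
    p = params
    rng = substream(p.seed, "otu_table")
    k, m = p.n_pao_taxa, p.n_taxa - p.n_pao_taxa

    pao_ids = [f"PAO_{i + 1:04d}" for i in range(k)]
    bulk_ids = [f"OTU_{i + 1:04d}" for i in range(m)]
    taxa = pao_ids + bulk_ids

    # taxonomy and quality metadata
    genera = {}
    for i, t in enumerate(pao_ids):
        genera[t] = _PAO_GENERA[i % len(_PAO_GENERA)] + f"_{i // len(_PAO_GENERA)}"
    for i, t in enumerate(bulk_ids):
        genera[t] = f"Genus{i + 1:04d}"
    missing = rng.random(m) < p.frac_missing_genus
    taxonomy = {}
    for t in taxa:
        g = genera[t]
        taxonomy[t] = f"k__Bacteria;p__P;c__C;o__O;f__F;g__{g};s__"
    for t, miss in zip(bulk_ids, missing):
        if miss:
            taxonomy[t] = "k__Bacteria;p__P;c__C;o__O;f__F;g__;s__"
    e_score = pd.Series(99.0 + rng.random(p.n_taxa), index=taxa)
    low = rng.random(m) < p.frac_low_escore
    e_score.loc[np.array(bulk_ids)[low]] = 95.0 + 3.9 * rng.random(int(low.sum()))

    # base profiles (log-normal mean abundances) and latent-factor loadings
    pao_profile = np.sort(rng.lognormal(0.0, p.lognormal_sigma, size=k))[::-1]
    bulk_profile = np.sort(rng.lognormal(0.0, p.lognormal_sigma, size=m))[::-1]
    # factor loadings live on the low-abundance (floor-dominated) taxa: their
    # small total mass keeps the compositional compensation negligible, so
    # loaded taxa genuinely co-vary instead of dragging the head down with
    # them. Warming recruits a larger loaded set (denser cooperative networks).
    # Warming loadings are graded (weak-to-strong pairs), so which pairs clear
    # the significance cut varies with the replicate subset - network
    # complexity and stability then co-vary across subsets. Ambient loadings
    # are few but uniformly strong: stable associations with mixed signs
    # (competitive as well as cooperative), so ambient networks barely vary.
    mag_warm = rng.uniform(0.25, 1.0, size=k)
    mag_amb = rng.uniform(0.75, 1.0, size=k)
    head = max(1, int(0.2 * k))
    eligible = np.arange(k - 1, head - 1, -1)  # tail-first
    n_warm = int(p.loaded_frac_warm * len(eligible))
    n_amb = int(p.loaded_frac_ambient * len(eligible))
    loaded_warm = np.zeros(k, dtype=bool)
    loaded_warm[eligible[:n_warm]] = True
    loaded_amb = np.zeros(k, dtype=bool)
    loaded_amb[eligible[:n_amb]] = True
    sign_warm = np.where(rng.random(k) < p.loading_pos_frac_warm, 1.0, -1.0)
    sign_amb = np.where(rng.random(k) < p.loading_pos_frac_ambient, 1.0, -1.0)
    load_warm = mag_warm * loaded_warm * sign_warm * p.factor_scale_warm
    load_amb = mag_amb * loaded_amb * sign_amb * p.factor_scale_ambient

    blocks = sorted(design["block"].unique())
    b_pao = dict(zip(blocks, rng.normal(0.0, p.block_sd, size=len(blocks))))
    b_bulk = dict(zip(blocks, rng.normal(0.0, p.block_sd, size=len(blocks))))
    # block-level heterogeneity in cooperation strength: blocks differ in how
    # strongly the warming factor binds the community, which makes network
    # complexity and stability co-vary across replicate subsets
    coop = dict(zip(blocks, np.exp(rng.normal(0.0, p.coop_block_sd, size=len(blocks)))))

    counts = {}
    h_targets = {}
    # optional deterministic diversity gradient across samples (for
    # functionality-biodiversity experiments spanning a wide Shannon range)
    grad = (
        np.linspace(-1.0, 1.0, len(design)) * p.pao_shannon_gradient
        if p.pao_shannon_gradient > 0
        else np.zeros(len(design))
    )
    for irow, (_, row) in enumerate(design.iterrows()):
        w, c = int(row["warming"]), int(row["clipping"])
        h_pao = (
            p.pao_shannon_base
            + p.warming_pao_shannon * w
            + p.clipping_pao_shannon * c
            + p.interaction_pao_shannon * w * c
            + b_pao[row["block"]]
            + grad[irow]
            + rng.normal(0.0, p.shannon_sd)
        )
        h_bulk = (
            p.bulk_shannon_base
            + p.warming_bulk_shannon * w
            + b_bulk[row["block"]]
            + rng.normal(0.0, p.shannon_sd)
        )
        h_targets[row["sample_id"]] = h_pao

        base = _solve_power_for_shannon(pao_profile, h_pao, p.abundance_floor_frac)
        f_s = rng.normal()
        loads = (load_warm * coop[row["block"]]) if w else load_amb
        noisy = base * np.exp(loads * f_s + rng.normal(0.0, p.taxon_noise_sd, size=k))
        pao_comp = _solve_power_for_shannon(noisy, h_pao, p.abundance_floor_frac)

        bulk_noisy = bulk_profile ** 1.0 * np.exp(
            rng.normal(0.0, p.taxon_noise_sd, size=m)
        )
        bulk_comp = _solve_power_for_shannon(bulk_noisy, h_bulk, p.abundance_floor_frac)

        # Under warming the PAO share co-varies with the factor swing (the
        # factor recruits whole-block biomass, mutualistic dynamics), so the
        # block normalization plants no anti-correlations on unloaded taxa.
        # Ambient dynamics stay zero-sum (competitive redistribution).
        z_s = float(noisy.sum() / base.sum())
        share = p.pao_share_base * (p.warming_pao_abund_mult if w else 1.0)
        share = float(
            np.clip(share * (z_s if w else 1.0) * np.exp(rng.normal(0.0, 0.08)), 0.01, 0.5)
        )
        comp = np.concatenate([pao_comp * share, bulk_comp * (1.0 - share)])
        comp = rng.dirichlet(np.maximum(comp, 1e-12) * p.dm_concentration)
        counts[row["sample_id"]] = rng.multinomial(p.depth, comp)

    table = OtuTable(
        counts=pd.DataFrame(counts, index=taxa),
        taxonomy=pd.Series(taxonomy),
        e_score=e_score,
        pao_candidate=pd.Series([t in set(pao_ids) for t in taxa], index=pd.Index(taxa)),
    )
    truth = {
        "pao_taxa": pao_ids,
        "h_pao_targets": h_targets,
        "effects": {
            "warming_pao_shannon": p.warming_pao_shannon,
            "clipping_pao_shannon": p.clipping_pao_shannon,
            "warming_bulk_shannon": p.warming_bulk_shannon,
            "warming_pao_abund_mult": p.warming_pao_abund_mult,
        },
        "loadings_warm": dict(zip(pao_ids, load_warm)),
        "loadings_ambient": dict(zip(pao_ids, load_amb)),
    }
    return table, truth


# --------------------------------------------------------------------------
# function table
# --------------------------------------------------------------------------


def gen_function_table(otu_table: OtuTable, params: SynthParams) -> FunctionTable:
    """Gene presence and per-category functional contributions.

    Planted PAO taxa carry all four of ppk1/ppx/phaZ/phaC; other taxa draw
    each gene independently with ``gene_prob_nonpao``. The ``redundancy``
    knob (0..1) sets how many taxa contribute to each function category:
    0 gives one distinct taxon per category, 1 gives every taxon in every
    category; contributions are log-normal.
    """
    p = params
    rng = substream(p.seed, "function_table")
    taxa = list(otu_table.taxa)
    n = len(taxa)
    if n == 0:
        raise ValueError("OTU table has no taxa")
    is_pao = (
        otu_table.pao_candidate.to_numpy()
        if otu_table.pao_candidate is not None
        else np.zeros(n, dtype=bool)
    )
    genes = pd.DataFrame(
        rng.random((n, len(PAO_GENES))) < p.gene_prob_nonpao,
        index=taxa,
        columns=list(PAO_GENES),
    )
    genes.loc[np.array(taxa)[is_pao]] = True

    n_contrib = max(1, int(round(1 + p.redundancy * (n - 1))))
    perm = rng.permutation(n)
    contrib = np.zeros((n, p.n_categories))
    for cat in range(p.n_categories):
        if n_contrib >= n:
            members = np.arange(n)
        elif n_contrib == 1:
            members = np.array([perm[cat % n]])
        else:
            members = rng.choice(n, size=n_contrib, replace=False)
        contrib[members, cat] = rng.lognormal(0.0, p.contribution_sigma, len(members))
    contributions = pd.DataFrame(
        contrib, index=taxa, columns=[f"KO{c + 1:04d}" for c in range(p.n_categories)]
    )
    return FunctionTable(genes=genes, contributions=contributions)


# --------------------------------------------------------------------------
# Raman spectra
# --------------------------------------------------------------------------


@dataclass
class Band:
    center: float
    width: float
    amplitude: float
    tag: str | None = None  # biomarker tag for treatment shifts


@dataclass
class SpectrumArchetype:
    """A cell phenotype: a set of Gaussian Raman bands."""

    name: str
    bands: list[Band]

    def __post_init__(self):
        for b in self.bands:
            if not (400.0 <= b.center <= 2000.0):
                raise ValueError(f"band center {b.center} outside [400, 2000]")
            if b.width <= 0 or b.amplitude < 0:
                raise ValueError("band widths must be > 0 and amplitudes >= 0")


def default_archetypes(n: int = 7) -> list[SpectrumArchetype]:
    """Seven PAO phenotypes sharing the signature bands, distinct fingerprints.

    All archetypes carry peptidoglycan, amide, PHA and polyP bands (so every
    cell passes the PAO phenotype check) plus glycogen/fatty-acid bands whose
    balance varies; each archetype adds two strong unique fingerprint bands
    so cosine distances between archetypes exceed the 0.6 OPU cutoff.
    """
    archs = []
    for i in range(n):
        frac = i / max(n - 1, 1)
        common = [
            Band(726.0, 5.0, 0.5, "peptidoglycan"),
            Band(1421.0, 5.0, 0.4, "peptidoglycan"),
            Band(1577.0, 5.0, 0.4, "peptidoglycan"),
            Band(1002.0, 4.0, 0.7, "amide"),
            Band(1220.0, 6.0, 0.5, "amide"),
            Band(1657.0, 6.0, 0.6, "amide"),
            Band(840.0, 5.0, 0.4 + 0.4 * frac, "pha"),
            Band(1725.0, 5.0, 0.4 + 0.4 * frac, "pha"),
            Band(695.0, 5.0, 0.9 - 0.4 * frac, "polyp"),
            Band(1174.0, 6.0, 0.7 - 0.3 * frac, "polyp"),
            Band(481.0, 3.0, 0.3 + 0.5 * frac, "glycogen"),
            Band(1450.0, 8.0, 0.8 - 0.5 * frac, "fa"),
        ]
        unique = [
            Band(520.0 + 18.0 * i, 6.0, 5.5),
            Band(1760.0 + 14.0 * i, 6.0, 4.5),
            Band(900.0 + 22.0 * i, 7.0, 4.0),
        ]
        archs.append(SpectrumArchetype(name=f"arch{i}", bands=common + unique))
    return archs


def _render(
    grid: np.ndarray,
    arch: SpectrumArchetype,
    mults: dict[str, float],
    jitter: np.ndarray,
) -> np.ndarray:
    y = np.zeros_like(grid)
    for b, j in zip(arch.bands, jitter):
        amp = b.amplitude * mults.get(b.tag, 1.0) * j
        y += amp * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
    return y


def gen_spectra(
    design: pd.DataFrame,
    archetypes: list[SpectrumArchetype] | None = None,
    params: SynthParams | None = None,
    h_fun_targets: pd.Series | None = None,
) -> SpectraSet:
    """Single-cell Raman spectra on the 1 cm^-1 grid 400-2000 (1601 points).

    For each design row, ``n_drops`` x ``cells_per_drop`` cells are drawn
    from an archetype mixture; warmed samples spread weight across all
    archetypes (higher functional diversity) while ambient samples
    concentrate on the first three. When ``h_fun_targets`` maps sample_id to
    a target OPU Shannon, the mixture is power-tilted to hit it. Each cell's
    spectrum is its archetype's Gaussian bands (treatment multipliers applied
    to tagged biomarker bands, log-normal per-band jitter) plus a smooth
    low-order polynomial baseline and white noise. The true archetype of each
    cell is recorded in the metadata.
    """
    p = params if params is not None else SynthParams()
    archs = archetypes if archetypes is not None else default_archetypes()
    n_arch = len(archs)
    grid = np.arange(400.0, 2000.0 + 0.5, 1.0)
    rng = substream(p.seed, "spectra")

    base_weights = rng.lognormal(0.0, 0.6, size=n_arch)
    amb_weights = np.array(
        [5.0, 3.0, 2.0] + [0.25] * (n_arch - 3) if n_arch > 3 else [1.0] * n_arch
    )
    warm_weights = np.ones(n_arch)

    rows_meta = []
    spectra = []
    tvec = (grid - grid[0]) / (grid[-1] - grid[0])
    for _, row in design.iterrows():
        w = int(row["warming"])
        mults = {k: (v if w else 1.0) for k, v in p.warming_biomarker_mults.items()}
        if h_fun_targets is not None and row["sample_id"] in h_fun_targets.index:
            weights = _solve_power_for_shannon(
                base_weights, float(h_fun_targets[row["sample_id"]])
            )
        else:
            weights = (warm_weights if w else amb_weights).astype(float)
            weights = weights / weights.sum()
        for drop in range(1, p.n_drops + 1):
            arch_idx = rng.choice(n_arch, size=p.cells_per_drop, p=weights)
            for ci, ai in enumerate(arch_idx):
                arch = archs[ai]
                jitter = rng.lognormal(0.0, p.band_jitter_sd, size=len(arch.bands))
                y = _render(grid, arch, mults, jitter)
                coefs = rng.normal(0.0, p.baseline_scale, size=3)
                baseline = abs(coefs[0]) + 0.5 * (
                    coefs[1] * tvec + coefs[2] * tvec**2
                )
                y = y + baseline - baseline.min() + rng.normal(
                    0.0, p.spectra_noise_sd, size=len(grid)
                )
                cell_id = f"{row['sample_id']}_d{drop}_c{ci + 1:03d}"
                rows_meta.append(
                    {
                        "cell_id": cell_id,
                        "sample_id": row["sample_id"],
                        "treatment": row.get("treatment", ""),
                        "warming": w,
                        "clipping": int(row["clipping"]),
                        "drop": drop,
                        "archetype": arch.name,
                    }
                )
                spectra.append(y)
    meta = pd.DataFrame(rows_meta).set_index("cell_id")
    return SpectraSet(
        wavenumbers=grid, intensities=np.vstack(spectra), meta=meta
    )


# --------------------------------------------------------------------------
# environment / ecosystem table
# --------------------------------------------------------------------------

# variable -> (intercept, warming coef, clipping coef, noise sd)
DEFAULT_ENV_COEFS: dict[str, tuple[float, float, float, float]] = {
    "soil_T": (15.0, 2.0, 0.3, 0.3),
    "moisture": (22.0, -3.0, -1.0, 0.8),
    "pH": (6.6, -0.25, 0.0, 0.08),
    "TP": (320.0, -35.0, -5.0, 10.0),
    "AP": (50.0, 18.0, 3.0, 3.0),
    "LOI": (8.0, 0.5, -0.2, 0.4),
    "C3_biomass": (120.0, 10.0, -20.0, 8.0),
    "C4_biomass": (180.0, 15.0, -60.0, 10.0),
    "GPP": (6.0, 1.2, 0.2, 0.3),
    "ER": (4.0, 0.6, 0.1, 0.25),
    "Rs": (3.0, 0.5, 0.1, 0.2),
    "Rh": (2.0, 0.3, 0.05, 0.15),
}


def gen_env(
    design: pd.DataFrame,
    params: SynthParams | None = None,
    coefs: dict | None = None,
) -> pd.DataFrame:
    """Environment and ecosystem-flux table from a linear Gaussian system.

    Each variable is intercept + warming/clipping path coefficients + noise;
    the default path signs follow the study system (warming: +T, -moisture,
    -TP, +AP). NEE is derived as ER - GPP, so GPP = ER - NEE holds exactly.
    ``env_noise_scale = 0`` makes every column an exact linear function of
    the treatment flags.
    """
    p = params if params is not None else SynthParams()
    coefs = DEFAULT_ENV_COEFS if coefs is None else coefs
    rng = substream(p.seed, "env")
    w = design["warming"].to_numpy(float)
    c = design["clipping"].to_numpy(float)
    out = {}
    for var, (b0, bw, bc, sd) in coefs.items():
        noise = rng.normal(0.0, sd * p.env_noise_scale, size=len(design))
        out[var] = b0 + bw * w + bc * c + noise
    env = pd.DataFrame(out, index=design["sample_id"])
    env["NEE"] = env["ER"] - env["GPP"]
    return env


# --------------------------------------------------------------------------
# one-call study synthesis
# --------------------------------------------------------------------------


def gen_all(params: SynthParams | None = None) -> dict:
    """Generate a full synthetic study: design, OTU/function/env tables,
    pooled replicates and single-cell spectra with coupled functional
    diversity (H_fun = a + b ln H_tax + noise on the pooled samples).

    Returns a dict with keys design, otu, truth, functions, env, pooled_otu,
    pooled_design, spectra.
    """
    p = params if params is not None else SynthParams()
    design = gen_design(p.n_blocks, p.n_reps)
    otu, truth = gen_otu_table(design, p)
    fn = gen_function_table(otu, p)
    env = gen_env(design, p)
    pooled, pooled_design = pool_replicates(otu, design, k_pools=3, seed=p.seed)

    pao = pooled.subset([t for t in pooled.taxa if t in set(truth["pao_taxa"])])
    rel = pao.relative_abundance()
    rng = substream(p.seed, "fun_coupling")
    h_tax = rel.apply(lambda col: shannon(col.to_numpy()), axis=0)
    h_fun = p.fun_intercept + p.fun_slope * np.log(h_tax) + rng.normal(
        0.0, p.fun_sd, size=len(h_tax)
    )
    truth["h_tax_pooled"] = h_tax.to_dict()
    truth["h_fun_targets"] = dict(zip(h_tax.index, h_fun))
    spectra = gen_spectra(
        pooled_design,
        params=p,
        h_fun_targets=pd.Series(h_fun.to_numpy(), index=h_tax.index),
    )
    return {
        "design": design,
        "otu": otu,
        "truth": truth,
        "functions": fn,
        "env": env,
        "pooled_otu": pooled,
        "pooled_design": pooled_design,
        "spectra": spectra,
    }
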