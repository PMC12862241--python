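"""Synthetic cohort generator emulating the study design.

The generator produces a near-panmictic coral metapopulation sampled at
site x habitat x timepoint groups of 12-26 colonies.  Each site x habitat
group is backed by a larger population *pool*: per-site allele frequencies
follow the Balding-Nichols construction around a common ancestral frequency
(targeting a pairwise Hudson F_ST near the observed 0.013-0.02), genotypes
are Hardy-Weinberg draws, and each colony carries a polygenic liability for
bleaching health with covariate (depth, colony size) and habitat-signed
symbiont-community effects.  The pre-mortality cohort is a random subsample
of the pool; the mass mortality event is truncation selection (the top
~30% of the pool by liability survive per group); the post-mortality cohort
is a fresh subsample of the survivors — so sampling bias between timepoints
is part of the emulated design.  The juvenile generation is drawn
binomially from fecundity-weighted survivor allele frequencies.  Ground
truth (causal loci, pool liabilities, survival, per-generation frequencies)
is retained for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    HABITATS,
    SYMBIONT_GENERA,
    GenotypeMatrix,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Default adult site x habitat sampling layout (nine groups, as in a
#: four-location, three-habitat design with incomplete coverage).
DEFAULT_SITE_HABITATS = {
    "LTER1": ["backreef", "shallow_forereef", "deep_forereef"],
    "LTER2": ["shallow_forereef", "deep_forereef"],
    "LTER3": ["backreef", "deep_forereef"],
    "LTER5": ["backreef", "deep_forereef"],
}

#: Groups not re-sampled post-mortality, so the default design has
#: 9 pre + 7 post + 3 juvenile = 19 site x habitat x timepoint groups.
DEFAULT_POST_DROPPED = [("LTER3", "backreef"), ("LTER5", "backreef")]

#: Juveniles are collected from the deep forereef only.
DEFAULT_JUVENILE_SITES = ["LTER1", "LTER2", "LTER3"]

#: Site-weighted fecundity of the surviving deep-forereef colonies; skewed
#: toward the least-stressed site, which dominates recruitment.
DEFAULT_FECUNDITY = {"LTER1": 0.15, "LTER2": 0.15, "LTER3": 0.6, "LTER5": 0.1}

#: Habitat-signed symbiont-community effects on the health liability
#: (positive: more of that genus goes with healthier colonies).  Signs flip
#: between the shallow and deep forereef.
DEFAULT_SYMBIONT_EFFECTS = {
    "backreef": {"Symbiodinium": 0.0, "Cladocopium": 0.0, "Durusdinium": 0.0},
    "shallow_forereef": {"Symbiodinium": 0.6, "Cladocopium": -0.5,
                         "Durusdinium": -0.4},
    "deep_forereef": {"Symbiodinium": -0.5, "Cladocopium": 0.5,
                      "Durusdinium": 0.0},
}

_DEPTH_RANGE = {"backreef": (1.0, 3.0), "shallow_forereef": (3.0, 5.0),
                "deep_forereef": (10.0, 14.0)}

_BASE_ALPHA = {"backreef": (1.2, 1.2, 0.8), "shallow_forereef": (1.5, 1.0, 0.7),
               "deep_forereef": (0.9, 1.6, 0.6)}


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    site_habitats: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_SITE_HABITATS.items()})
    post_dropped: list = field(default_factory=lambda: list(DEFAULT_POST_DROPPED))
    juvenile_sites: list = field(default_factory=lambda: list(DEFAULT_JUVENILE_SITES))
    n_per_group_min: int = 12
    n_per_group_max: int = 26
    pool_per_group: int = 80
    n_loci: int = 5000
    n_causal: int = 100
    allele_freq_model: str = "beta"  # or "fixed_p"
    beta_a: float = 2.0
    beta_b: float = 2.0
    fixed_p: float = 0.1
    heritability_h2: float = 0.3
    covariate_effects: dict = field(default_factory=lambda: {
        "depth_m": -0.2, "surface_area": 0.3})
    symbiont_effect_by_habitat: dict = field(default_factory=lambda: {
        h: dict(v) for h, v in DEFAULT_SYMBIONT_EFFECTS.items()})
    survival_fraction: float = 0.3
    fst_target: float = 0.015
    fecundity_weights: dict = field(default_factory=lambda: dict(DEFAULT_FECUNDITY))
    mean_symbiont_reads: int = 2000
    n_chromosomes: int = 14
    genome_length_bp: int = 450_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_loci:
            raise ParameterError("n_causal must be <= n_loci")
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ParameterError("survival_fraction must lie in (0, 1]")
        if not 0.0 <= self.heritability_h2 <= 1.0:
            raise ParameterError("heritability_h2 must lie in [0, 1]")
        if self.fst_target > 0.5:
            raise ParameterError("fst_target > 0.5 is infeasible")
        if self.pool_per_group < self.n_per_group_max:
            raise ParameterError("pool_per_group must be >= n_per_group_max")
        for hab, slopes in self.symbiont_effect_by_habitat.items():
            for genus, s in slopes.items():
                if not -1.0 <= s <= 1.0:
                    raise ParameterError(
                        f"symbiont effect {hab}/{genus}={s} outside [-1, 1]")


@dataclass
class SimulationTruth:
    """Ground truth retained for recovery tests.

    ``pools`` maps (site, habitat) to the underlying population pool:
    dosage block, liabilities, and (after :func:`apply_mme`) a survival
    flag per pool member.
    """

    causal_locus_ids: np.ndarray
    causal_betas: np.ndarray
    liability: pd.Series  # by sampled adult sample_id
    survived: pd.Series  # by sampled pre adult sample_id (NaN until apply_mme)
    pools: dict
    parents: pd.DataFrame | None  # explicit-mating mode only
    freqs: dict  # cohort label -> per-locus allele frequency
    config: CohortConfig


def _locus_map(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spread loci evenly over the genome (reduced-representation spacing)."""
    per = int(np.ceil(cfg.n_loci / cfg.n_chromosomes))
    chrom_len = cfg.genome_length_bp // cfg.n_chromosomes
    spacing = chrom_len // (per + 1)
    chrom, pos = [], []
    for j in range(cfg.n_loci):
        c = j // per
        k = j % per
        chrom.append(f"chr{c + 1}")
        pos.append((k + 1) * spacing)
    ids = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    return ids, np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def _ancestral_freqs(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.allele_freq_model == "fixed_p":
        return np.full(cfg.n_loci, cfg.fixed_p)
    if cfg.allele_freq_model == "beta":
        return np.clip(rng.beta(cfg.beta_a, cfg.beta_b, size=cfg.n_loci),
                       0.02, 0.98)
    raise ParameterError(f"unknown allele_freq_model {cfg.allele_freq_model!r}")


def _site_freqs(p_anc: np.ndarray, fst: float, sites: list,
                rng: np.random.Generator) -> dict:
    """Balding-Nichols per-site frequencies targeting the given F_ST."""
    out = {}
    for s in sites:
        if fst <= 0:
            out[s] = p_anc.copy()
        else:
            a = p_anc * (1.0 - fst) / fst
            b = (1.0 - p_anc) * (1.0 - fst) / fst
            out[s] = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)
    return out


def _draw_symbionts(habitat: str, health_z: np.ndarray, slopes: dict,
                    mean_reads: int, rng: np.random.Generator,
                    concentration: float = 25.0, gain: float = 2.5
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet genus proportions whose mean shifts with a health z-score
    by habitat-specific signed slopes, plus multinomial read counts."""
    base = np.array(_BASE_ALPHA[habitat], dtype=float)
    base = base / base.sum()
    slope = np.array([slopes.get(g, 0.0) for g in SYMBIONT_GENERA])
    logits = np.log(base)[None, :] + gain * slope[None, :] * health_z[:, None]
    mean = np.exp(logits)
    mean /= mean.sum(axis=1, keepdims=True)
    props = np.empty((len(health_z), 3))
    for i in range(len(health_z)):
        props[i] = rng.dirichlet(concentration * mean[i])
    totals = rng.poisson(mean_reads, size=len(health_z))
    counts = np.array([rng.multinomial(t, pr) for t, pr in zip(totals, props)])
    return props, counts


def simulate_metapopulation(
    cfg: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Generate the pre-mortality adult cohort with ground truth.

    Each site x habitat group is a population pool of ``pool_per_group``
    colonies; the returned genotypes/metadata are a random subsample of
    12-26 per group.  Liability = standardized polygenic term (variance
    h^2) + covariate and habitat-signed symbiont terms + Gaussian noise
    (jointly variance 1 - h^2); the 1-5 health score cuts the liability at
    its pool quintiles (1 = fully bleached).
    """
    cfg = cfg or CohortConfig()
    rng = rng or np.random.default_rng(cfg.rng_seed)
    locus_ids, chrom, pos = _locus_map(cfg)
    p_anc = _ancestral_freqs(cfg, rng)
    sites = list(cfg.site_habitats)
    site_p = _site_freqs(p_anc, cfg.fst_target, sites, rng)

    pools: dict = {}
    order: list = []
    for site in sites:
        for habitat in cfg.site_habitats[site]:
            n = cfg.pool_per_group
            d = rng.binomial(2, site_p[site][None, :].repeat(n, axis=0)).astype(np.int8)
            lo, hi = _DEPTH_RANGE[habitat]
            pool = {
                "dosages": d,
                "depth_m": rng.uniform(lo, hi, size=n),
                "surface_area": rng.lognormal(mean=3.0, sigma=0.5, size=n),
            }
            slopes = cfg.symbiont_effect_by_habitat[habitat]
            pr, ct = _draw_symbionts(habitat, np.zeros(n), slopes,
                                     cfg.mean_symbiont_reads, rng)
            pool["props"], pool["counts"] = pr, ct
            pools[(site, habitat)] = pool
            order.append((site, habitat))

    # pool-wide liability
    all_d = np.vstack([pools[k]["dosages"] for k in order])
    n_total = all_d.shape[0]
    causal = rng.choice(cfg.n_loci, size=cfg.n_causal, replace=False)
    betas = rng.normal(0.0, 1.0, size=cfg.n_causal)
    G = all_d[:, causal].astype(float) @ betas
    h2 = cfg.heritability_h2
    if h2 > 0 and G.std() > 0:
        G = (G - G.mean()) / G.std() * np.sqrt(h2)
    else:
        G = np.zeros(n_total)

    cov_term = np.zeros(n_total)
    for col, eff in cfg.covariate_effects.items():
        v = np.concatenate([pools[k][col] for k in order])
        if v.std() > 0:
            cov_term += eff * (v - v.mean()) / v.std()
    sym_term = np.zeros(n_total)
    start = 0
    for k in order:
        n = cfg.pool_per_group
        slopes = cfg.symbiont_effect_by_habitat[k[1]]
        slope = np.array([slopes.get(g_, 0.0) for g_ in SYMBIONT_GENERA])
        pr = pools[k]["props"]
        sym_term[start:start + n] = (pr - pr.mean(axis=0)) @ slope
        start += n

    # structured environment carries 40% of the non-genetic variance
    E = cov_term + sym_term
    env_var = 1.0 - h2
    if E.std() > 0 and env_var > 0:
        E = (E - E.mean()) / E.std() * np.sqrt(0.4 * env_var)
        noise_sd = np.sqrt(0.6 * env_var)
    else:
        E = np.zeros(n_total)
        noise_sd = np.sqrt(env_var)
    liability = G + E + rng.normal(0.0, noise_sd, size=n_total)

    qs = np.quantile(liability, [0.2, 0.4, 0.6, 0.8])
    health = (np.searchsorted(qs, liability) + 1).astype(float)
    start = 0
    for k in order:
        n = cfg.pool_per_group
        pools[k]["liability"] = liability[start:start + n]
        pools[k]["health_score"] = health[start:start + n]
        start += n

    # pre-mortality subsample of each pool
    rows, blocks, lias = [], [], []
    for site, habitat in order:
        pool = pools[(site, habitat)]
        n_pre = int(rng.integers(cfg.n_per_group_min, cfg.n_per_group_max + 1))
        idx = np.sort(rng.choice(cfg.pool_per_group, size=n_pre, replace=False))
        pool["pre_idx"] = idx
        blocks.append(pool["dosages"][idx])
        lias.append(pool["liability"][idx])
        for i, pj in enumerate(idx):
            row = {
                "sample_id": f"pre_{site}_{habitat}_{i:03d}",
                "site": site, "habitat": habitat, "timepoint": "pre",
                "depth_m": pool["depth_m"][pj],
                "surface_area": pool["surface_area"][pj],
                "health_score": pool["health_score"][pj],
            }
            for gk, genus in enumerate(SYMBIONT_GENERA):
                row[f"reads_{genus}"] = int(pool["counts"][pj, gk])
            rows.append(row)
    meta = pd.DataFrame(rows)
    dosages = np.vstack(blocks)

    g = GenotypeMatrix(dosages, meta["sample_id"].to_numpy(object), locus_ids,
                       chrom, pos, np.array(["A"] * cfg.n_loci, dtype=object),
                       np.array(["T"] * cfg.n_loci, dtype=object))
    truth = SimulationTruth(
        causal_locus_ids=locus_ids[causal],
        causal_betas=betas,
        liability=pd.Series(np.concatenate(lias), index=meta["sample_id"]),
        survived=pd.Series(np.nan, index=meta["sample_id"], dtype=object),
        pools=pools,
        parents=None,
        freqs={"pre": g.allele_freq(),
               "population": all_d.mean(axis=0) / 2.0},
        config=cfg,
    )
    return g, meta, truth


def apply_mme(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    truth: SimulationTruth,
    survival_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Truncation selection on the population pools.

    Within each site x habitat pool the top ``survival_fraction`` by
    liability survive; the post-mortality cohort is a fresh random
    subsample of 12-26 survivors per retained group (new sample ids),
    emulating field subsampling of the surviving population.
    """
    cfg = truth.config
    frac = cfg.survival_fraction if survival_fraction is None else survival_fraction
    if not 0.0 < frac <= 1.0:
        raise ParameterError("survival_fraction must lie in (0, 1]")
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    dropped = {tuple(t) for t in cfg.post_dropped}
    post_rows, post_blocks = [], []
    surv_blocks = []
    for (site, habitat), pool in truth.pools.items():
        lia = pool["liability"]
        n_surv = max(1, int(round(frac * len(lia))))
        surv_idx = np.argsort(-lia, kind="stable")[:n_surv]
        flag = np.zeros(len(lia), dtype=bool)
        flag[surv_idx] = True
        pool["survived"] = flag
        surv_blocks.append(pool["dosages"][surv_idx])
        if (site, habitat) in dropped:
            continue
        n_post = int(rng.integers(cfg.n_per_group_min, cfg.n_per_group_max + 1))
        if n_post > n_surv:
            logger.warning("group %s/%s: only %d survivors for a %d-sample "
                           "post group", site, habitat, n_surv, n_post)
            n_post = n_surv
        chosen = np.sort(rng.choice(surv_idx, size=n_post, replace=False))
        post_blocks.append(pool["dosages"][chosen])
        for i, pj in enumerate(chosen):
            row = {
                "sample_id": f"post_{site}_{habitat}_{i:03d}",
                "site": site, "habitat": habitat, "timepoint": "post",
                "depth_m": pool["depth_m"][pj],
                "surface_area": pool["surface_area"][pj],
                "health_score": np.nan,
            }
            for gk, genus in enumerate(SYMBIONT_GENERA):
                row[f"reads_{genus}"] = int(pool["counts"][pj, gk])
            post_rows.append(row)
    # survival flags for the sampled pre adults
    survived = {}
    for (site, habitat), pool in truth.pools.items():
        for i, pj in enumerate(pool["pre_idx"]):
            survived[f"pre_{site}_{habitat}_{i:03d}"] = bool(pool["survived"][pj])
    truth.survived = pd.Series(survived)
    all_surv = np.vstack(surv_blocks)
    truth.freqs["survivors"] = all_surv.mean(axis=0) / 2.0
    if not post_rows:
        return g, meta, truth
    post_meta = pd.DataFrame(post_rows)[meta.columns.tolist()]
    g_post = GenotypeMatrix(
        np.vstack(post_blocks), post_meta["sample_id"].to_numpy(object),
        g.locus_ids, g.chrom, g.pos, g.ref_allele, g.alt_allele,
    )
    g_all = g.concat_samples(g_post)
    meta_all = pd.concat([meta, post_meta], ignore_index=True)
    truth.freqs["post"] = g_post.allele_freq()
    return g_all, meta_all, truth


def breed_next_generation(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    truth: SimulationTruth,
    fecundity_weights: dict | None = None,
    n_juveniles: int | None = None,
    mode: str = "binomial",
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Juvenile generation from surviving deep-forereef pool colonies.

    ``binomial`` mode draws each juvenile dosage ~ Binomial(2, p_source)
    where p_source is the fecundity-weighted survivor allele frequency
    across source sites; ``mating`` mode samples two survivor parents per
    juvenile (site-weighted) and transmits one allele from each, recording
    parentage for pedigree checks.
    """
    cfg = truth.config
    weights = fecundity_weights or cfg.fecundity_weights
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    src: dict = {}
    for site in cfg.juvenile_sites:
        pool = truth.pools.get((site, "deep_forereef"))
        if pool is None or "survived" not in pool:
            continue
        surv = np.flatnonzero(pool["survived"])
        if len(surv) >= 2:
            src[site] = pool["dosages"][surv]
    if not src:
        raise ParameterError("need >=2 survivors in at least one source site")
    w = np.array([weights.get(s, 0.0) for s in src], dtype=float)
    if w.sum() <= 0:
        raise ParameterError("zero total fecundity over source sites")
    w = w / w.sum()
    site_freq = {s: d.mean(axis=0) / 2.0 for s, d in src.items()}
    p_source = np.sum([wi * site_freq[s] for wi, s in zip(w, src)], axis=0)

    juv_rows, juv_blocks, parent_rows = [], [], []
    site_list = list(src)
    for site in cfg.juvenile_sites:
        n = (int(rng.integers(cfg.n_per_group_min, cfg.n_per_group_max + 1))
             if n_juveniles is None else n_juveniles)
        if mode == "binomial":
            d = rng.binomial(2, p_source[None, :].repeat(n, axis=0)).astype(np.int8)
        elif mode == "mating":
            d = np.empty((n, g.n_loci), dtype=np.int8)
            for i in range(n):
                si1, si2 = rng.choice(len(site_list), size=2, p=w)
                j1 = rng.integers(len(src[site_list[si1]]))
                j2 = rng.integers(len(src[site_list[si2]]))
                d1 = src[site_list[si1]][j1].astype(float)
                d2 = src[site_list[si2]][j2].astype(float)
                a1 = rng.binomial(1, np.clip(d1 / 2.0, 0, 1))
                a2 = rng.binomial(1, np.clip(d2 / 2.0, 0, 1))
                d[i] = (a1 + a2).astype(np.int8)
                parent_rows.append({"juvenile": f"juv_{site}_{i:03d}",
                                    "parent_site1": site_list[si1],
                                    "parent_site2": site_list[si2],
                                    "parent1": int(j1), "parent2": int(j2)})
        else:
            raise ParameterError(f"unknown mode {mode!r}")
        juv_blocks.append(d)
        depth = rng.uniform(*_DEPTH_RANGE["deep_forereef"], size=n)
        for i in range(n):
            juv_rows.append({
                "sample_id": f"juv_{site}_{i:03d}", "site": site,
                "habitat": "deep_forereef", "timepoint": "juvenile",
                "depth_m": depth[i],
                "surface_area": float(rng.lognormal(1.0, 0.4)),
                "health_score": np.nan,
            })
    juv_meta = pd.DataFrame(juv_rows)
    # juvenile symbiont communities: deep-forereef base, no health signal
    _, counts = _draw_symbionts("deep_forereef", np.zeros(len(juv_meta)),
                                {g_: 0.0 for g_ in SYMBIONT_GENERA},
                                cfg.mean_symbiont_reads, rng)
    for k, genus in enumerate(SYMBIONT_GENERA):
        juv_meta[f"reads_{genus}"] = counts[:, k]
    g_juv = GenotypeMatrix(
        np.vstack(juv_blocks), juv_meta["sample_id"].to_numpy(object),
        g.locus_ids, g.chrom, g.pos, g.ref_allele, g.alt_allele,
    )
    g_all = g.concat_samples(g_juv)
    meta_all = pd.concat([meta, juv_meta[meta.columns.tolist()]],
                         ignore_index=True)
    truth.freqs["juvenile"] = g_juv.allele_freq()
    truth.freqs["juvenile_source"] = p_source
    if parent_rows:
        truth.parents = pd.DataFrame(parent_rows)
    return g_all, meta_all, truth


def simulate_symbiont_profiles(
    meta: pd.DataFrame,
    habitat_assoc: dict | None = None,
    mean_reads: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Redraw symbiont read counts conditional on existing health scores.

    Per-sample genus proportions come from a Dirichlet whose mean shifts
    with the health z-score by habitat-specific signed slopes in [-1, 1];
    read counts are a multinomial draw at a Poisson total depth.
    """
    habitat_assoc = habitat_assoc or DEFAULT_SYMBIONT_EFFECTS
    for hab, slopes in habitat_assoc.items():
        for genus, s in slopes.items():
            if not -1.0 <= s <= 1.0:
                raise ParameterError(
                    f"association magnitude {hab}/{genus}={s} outside [-1, 1]")
    rng = np.random.default_rng(rng)
    out = meta.copy()
    hs = out["health_score"].to_numpy(float)
    if np.isnan(hs).all():
        raise ParameterError("no health scores assigned")
    z = np.where(np.isnan(hs), 0.0, (np.nan_to_num(hs) - 3.0) / 2.0)
    for habitat in HABITATS:
        m = (out["habitat"] == habitat).to_numpy()
        if not m.any():
            continue
        _, counts = _draw_symbionts(habitat, z[m],
                                    habitat_assoc.get(habitat, {}),
                                    mean_reads, rng)
        for k, genus in enumerate(SYMBIONT_GENERA):
            out.loc[m, f"reads_{genus}"] = counts[:, k]
    return out


def simulate_full_cohort(
    cfg: CohortConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Pre-mortality cohort + MME + juvenile generation in one call."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    g, meta, truth = simulate_metapopulation(cfg, rng)
    g, meta, truth = apply_mme(g, meta, truth, rng=rng)
    g, meta, truth = breed_next_generation(g, meta, truth, rng=rng)
    return g, meta, truth


def simulate_shift_pair(
    L: int = 500,
    n_causal: int = 100,
    pool_size: int = 600,
    n_sample: int = 150,
    survival_fraction: float = 0.3,
    shared_selection: bool = True,
    seed: int | None = None,
):
    """Two replicate sites sampled before and after an MME.

    Both sites start from the same allele frequencies; under
    ``shared_selection`` each site independently undergoes truncation
    selection on the same polygenic score (summed dosage over the causal
    loci), otherwise survival is a coin flip (pure drift).  Returns the two
    per-site allele-frequency shift vectors computed from pre/post
    subsamples of ``n_sample`` colonies — the calibration substrate for the
    convergent-correlation statistic.
    """
    from .temporal import ShiftVector

    rng = np.random.default_rng(seed)
    n_surv = int(round(survival_fraction * pool_size))
    if n_sample > min(pool_size, n_surv):
        raise ParameterError("n_sample exceeds the pool or survivor count")
    p0 = rng.uniform(0.2, 0.8, size=L)
    causal = rng.choice(L, size=n_causal, replace=False)
    locus_ids = np.array([f"L{j}" for j in range(L)], dtype=object)
    shifts = []
    for site in ("siteA", "siteB"):
        geno = rng.binomial(2, p0[None, :].repeat(pool_size, axis=0))
        if shared_selection:
            score = geno[:, causal].sum(axis=1).astype(float)
        else:
            score = rng.random(pool_size)
        order = np.lexsort((rng.random(pool_size), -score))
        surv = order[:n_surv]
        pre = rng.choice(pool_size, size=n_sample, replace=False)
        post = rng.choice(surv, size=n_sample, replace=False)
        dp = geno[post].mean(axis=0) / 2.0 - geno[pre].mean(axis=0) / 2.0
        shifts.append(ShiftVector(site=site, delta_p=dp, locus_ids=locus_ids))
    return shifts[0], shifts[1]
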