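"""Synthetic pedigree, genotype and phenotype generator.

Emulates the data structure a single-step evaluation consumes: a
multi-generation pedigree (discrete generations, sires mated to several
dams, so paternal half-sib families arise), gene-dropped SNP genotypes for
a subset of recent animals nested inside a larger phenotyped population,
and continuous traits built from QTL effects plus an optional pedigree
polygenic term, fixed effects and residual noise. The generator knows the
truth (breeding values, family labels, planted data defects), which makes
every pipeline stage testable without proprietary records.

Default profile: a ~1/10-scale population — about 1,400 phenotyped
animals over 11 discrete generations, ~150 genotyped in the last two,
3,500 independent SNPs, and ten traits with heritabilities spanning
0.11-0.40. Phenotypic variance is normalised to 1 per trait, so
sigma_a^2 = h2 in the base generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ValidationError
from .pedigree import Pedigree, parse_pedigree
from .qc import GenotypePanel

DEFAULT_H2 = (0.40, 0.19, 0.20, 0.17, 0.11, 0.39, 0.11, 0.17, 0.16, 0.13)


class ConfigError(ValidationError):
    pass


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the package's study-like profile."""

    founders: int = 150
    n_generations: int = 11
    sires_per_generation: int = 25
    dams_per_sire: int = 5
    offspring_per_mating: int = 1
    n_families: int = 1  # independent subpopulations (disconnected pedigrees)
    n_snps: int = 3500
    n_qtl: int = 300
    allele_freq_beta: tuple[float, float] = (2.0, 2.0)
    h2_true: tuple[float, ...] = DEFAULT_H2
    fixed_effect_levels: tuple[int, ...] = (16, 11)  # contemporary group, birth place
    fixed_effect_sd: float = 0.5
    covariate_range: tuple[float, float] = (330.0, 390.0)  # age at recording, days
    covariate_slope: float = 0.02
    genotyped_last_generations: int = 2
    genotyped_fraction: float = 0.6
    missing_rate: float = 0.02
    genotyping_error_rate: float = 0.0
    tbv_mode: str = "qtl_polygenic"  # or "qtl"
    polygenic_fraction: float = 0.5
    n_duplicate_pairs: int = 0
    n_pedigree_errors: int = 0
    n_high_missing_animals: int = 0
    high_missing_rate: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders < 2:
            raise ConfigError("need at least 2 founders")
        for nm in ("genotyped_fraction", "missing_rate", "genotyping_error_rate",
                   "polygenic_fraction", "high_missing_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{nm} must be in [0, 1]")
        if any(not 0.0 <= h < 1.0 for h in self.h2_true):
            raise ConfigError("h2_true values must be in [0, 1)")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl cannot exceed n_snps")
        if self.tbv_mode not in ("qtl", "qtl_polygenic"):
            raise ConfigError(f"unknown tbv_mode {self.tbv_mode!r}")

    @property
    def n_traits(self) -> int:
        return len(self.h2_true)


@dataclass
class PedigreeSim:
    pedigree: Pedigree  # recorded pedigree (may contain planted errors)
    family: pd.Series  # subpopulation label per animal
    sire_family: pd.Series  # recorded sire id ("" for founders)
    sex: pd.Series  # "M"/"F"
    generation: pd.Series
    true_parents: dict  # animal -> (true_sire|None, true_dam|None)
    pedigree_errors: list  # animals whose recorded sire is wrong


@dataclass
class GenotypeSim:
    panel: GenotypePanel  # observed panel for genotyped animals (with defects)
    genotyped_ids: tuple[str, ...]
    dosages_all: np.ndarray  # true complete dosages, all pedigree animals
    allele_freq: np.ndarray
    duplicate_pairs: list  # (kept_id, duplicate_id)
    high_missing_animals: list


@dataclass
class SimTruth:
    tbv: pd.DataFrame  # animals x traits
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # n_qtl x n_traits
    sigma_a2: np.ndarray
    sigma_e2: np.ndarray


@dataclass
class SimData:
    config: SimConfig
    ped: PedigreeSim
    geno: GenotypeSim
    phenotypes: pd.DataFrame
    truth: SimTruth

    @property
    def trait_names(self) -> list[str]:
        return [f"trait{i + 1}" for i in range(self.config.n_traits)]


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PedigreeSim:
    """Discrete-generation pedigree with paternal half-sib families.

    Each generation, ``sires_per_generation`` males from the previous
    generation are each mated to ``dams_per_sire`` females (sampled
    without replacement when possible); a single generation means founders
    only. With ``n_families > 1`` the whole process is repeated for
    disconnected subpopulations.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    records: list[tuple[str, str | None, str | None]] = []
    family, sire_family, sex, generation = {}, {}, {}, {}
    true_parents: dict[str, tuple[str | None, str | None]] = {}

    for fam in range(1, cfg.n_families + 1):
        pre = f"F{fam}-" if cfg.n_families > 1 else ""
        founders = [f"{pre}G01-{i:04d}" for i in range(1, cfg.founders + 1)]
        n_male = max(cfg.sires_per_generation, int(round(0.3 * cfg.founders)))
        for i, a in enumerate(founders):
            records.append((a, None, None))
            family[a], sire_family[a] = fam, ""
            sex[a] = "M" if i < n_male else "F"
            generation[a] = 1
            true_parents[a] = (None, None)
        prev = founders
        for g in range(2, cfg.n_generations + 1):
            males = [a for a in prev if sex[a] == "M"]
            females = [a for a in prev if sex[a] == "F"]
            if not males or not females:
                raise ConfigError(
                    f"generation {g}: no {'sires' if not males else 'dams'} available"
                )
            n_s = min(cfg.sires_per_generation, len(males))
            sires = list(rng.choice(males, size=n_s, replace=False))
            need = n_s * cfg.dams_per_sire
            if need <= len(females):
                dams_pool = list(rng.choice(females, size=need, replace=False))
            else:
                dams_pool = list(rng.choice(females, size=need, replace=True))
            cur = []
            k = 0
            for s in sires:
                for _ in range(cfg.dams_per_sire):
                    dm = dams_pool[k]
                    k += 1
                    for _ in range(cfg.offspring_per_mating):
                        a = f"{pre}G{g:02d}-{len(cur) + 1:04d}"
                        records.append((a, s, dm))
                        family[a], sire_family[a] = fam, s
                        sex[a] = "M" if rng.random() < 0.5 else "F"
                        generation[a] = g
                        true_parents[a] = (s, dm)
                        cur.append(a)
            prev = cur

    # plant pedigree recording errors: wrong sire on last-generation animals
    errors: list[str] = []
    if cfg.n_pedigree_errors:
        last_gen = max(generation.values())
        candidates = [a for a, g in generation.items() if g == last_gen]
        chosen = rng.choice(candidates, size=min(cfg.n_pedigree_errors, len(candidates)),
                            replace=False)
        rec_map = {a: (s, d) for a, s, d in records}
        # contemporary sires: fathers of other last-generation animals, so a
        # wrong recording creates plausible-looking half-sib families
        contemporary = sorted(
            {rec_map[c][0] for c in candidates if rec_map[c][0] is not None}
        )
        for a in chosen:
            true_s, d = rec_map[a]
            others = [s for s in contemporary if s != true_s]
            if not others:
                continue
            false_s = str(rng.choice(others))
            rec_map[a] = (false_s, d)
            sire_family[a] = false_s
            errors.append(str(a))
        records = [(a, *rec_map[a]) for a, _, _ in records]

    ped = parse_pedigree(records, unknown_tokens=())
    idx = list(ped.ids)
    return PedigreeSim(
        pedigree=ped,
        family=pd.Series({a: family[a] for a in idx}).loc[idx],
        sire_family=pd.Series({a: sire_family[a] for a in idx}).loc[idx],
        sex=pd.Series({a: sex[a] for a in idx}).loc[idx],
        generation=pd.Series({a: generation[a] for a in idx}).loc[idx],
        true_parents=true_parents,
        pedigree_errors=errors,
    )


def drop_genotypes(
    pedsim: PedigreeSim, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeSim:
    """Gene-drop SNP dosages down the *true* pedigree and build the
    observed panel for the genotyped subset, with planted defects.

    Founders draw Binomial(2, p_i) per SNP; offspring receive one allele
    per parent by Mendelian segregation (SNPs independent — no linkage).
    Defects applied to the observed panel in order: genotyping error
    (affected calls re-drawn from Hardy-Weinberg), duplicate pairs (one
    animal's row copied over another's), random missingness, then extra
    high-missingness animals.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ped = pedsim.pedigree
    n, m = ped.n, cfg.n_snps
    a0, b0 = cfg.allele_freq_beta
    p = rng.beta(a0, b0, size=m)
    pos = {a: i for i, a in enumerate(ped.ids)}
    dos = np.zeros((n, m), dtype=np.int8)
    for a in ped.ids:
        i = pos[a]
        ts, td = pedsim.true_parents[a]
        gametes = []
        for par in (ts, td):
            if par is None:
                gametes.append(rng.binomial(1, p))
            else:
                gametes.append(rng.binomial(1, dos[pos[par]] / 2.0))
        dos[i] = gametes[0] + gametes[1]

    gens = pedsim.generation
    last = int(gens.max())
    cutoff = last - cfg.genotyped_last_generations + 1
    pool = [a for a in ped.ids if gens[a] >= cutoff]
    n_geno = max(1, int(round(cfg.genotyped_fraction * len(pool))))
    genotyped = tuple(str(a) for a in rng.choice(pool, size=n_geno, replace=False))
    g_pos = [pos[a] for a in genotyped]
    obs = dos[g_pos].astype(float)

    if cfg.genotyping_error_rate > 0:
        err = rng.random(obs.shape) < cfg.genotyping_error_rate
        redraw = rng.binomial(2, np.broadcast_to(p, obs.shape)).astype(float)
        obs[err] = redraw[err]

    dup_pairs: list[tuple[str, str]] = []
    if cfg.n_duplicate_pairs:
        order = rng.permutation(len(genotyped))
        for k in range(min(cfg.n_duplicate_pairs, len(genotyped) // 2)):
            i, j = order[2 * k], order[2 * k + 1]
            obs[j] = obs[i]
            dup_pairs.append((genotyped[i], genotyped[j]))

    if cfg.missing_rate > 0:
        obs[rng.random(obs.shape) < cfg.missing_rate] = np.nan

    high_missing: list[str] = []
    if cfg.n_high_missing_animals:
        taken = {i for pair in dup_pairs for i in pair}
        cand = [i for i, a in enumerate(genotyped) if a not in taken]
        sel = rng.choice(cand, size=min(cfg.n_high_missing_animals, len(cand)),
                         replace=False)
        for i in sel:
            extra = rng.random(m) < cfg.high_missing_rate
            obs[i, extra] = np.nan
            high_missing.append(genotyped[i])

    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": [str((j % 29) + 1) for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
        }
    )
    panel = GenotypePanel(obs, genotyped, snp_map)
    return GenotypeSim(panel, genotyped, dos, p, dup_pairs, high_missing)


def simulate_phenotypes(
    pedsim: PedigreeSim,
    geno: GenotypeSim,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes for every pedigree animal under the additive model.

    Per trait t: TBV is a QTL sum (centered true dosages times normal
    effects) optionally mixed with an independent pedigree polygenic term
    (Mendelian-sampling recursion down the true pedigree), scaled so the
    base-generation TBV variance equals h2_t; the residual variance is
    1 - h2_t; fixed effects (two factors and an age covariate) are added
    on top. So phenotypic variance is ~1 per trait before fixed effects.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    ped = pedsim.pedigree
    ids = list(ped.ids)
    n = ped.n
    T = cfg.n_traits
    pos = {a: i for i, a in enumerate(ids)}
    founder_rows = [i for i, a in enumerate(ids) if pedsim.generation[a] == 1]

    qtl_idx = np.sort(rng.choice(cfg.n_snps, size=cfg.n_qtl, replace=False))
    effects = rng.normal(size=(cfg.n_qtl, T))
    Cq = geno.dosages_all[:, qtl_idx] - 2.0 * geno.allele_freq[qtl_idx]
    raw_q = Cq @ effects  # n x T
    sd_q = raw_q[founder_rows].std(axis=0, ddof=1)
    sd_q[sd_q == 0.0] = 1.0
    std_q = raw_q / sd_q

    w = cfg.polygenic_fraction if cfg.tbv_mode == "qtl_polygenic" else 0.0
    if w > 0:
        poly = np.zeros((n, T))
        for a in ids:
            i = pos[a]
            ts, td = pedsim.true_parents[a]
            mid = np.zeros(T)
            n_known = 0
            for par in (ts, td):
                if par is not None:
                    mid += 0.5 * poly[pos[par]]
                    n_known += 1
            ms_var = {0: 1.0, 1: 0.75, 2: 0.5}[n_known]
            poly[i] = mid + rng.normal(scale=np.sqrt(ms_var), size=T)
    else:
        poly = np.zeros((n, T))

    h2 = np.asarray(cfg.h2_true)
    sa = np.sqrt(h2)
    tbv = (np.sqrt(1.0 - w) * std_q + np.sqrt(w) * poly) * sa
    sigma_e2 = 1.0 - h2

    lv1, lv2 = (cfg.fixed_effect_levels + (1, 1))[:2]
    cg = rng.integers(1, lv1 + 1, size=n)
    bp = rng.integers(1, lv2 + 1, size=n)
    eff_cg = rng.normal(scale=cfg.fixed_effect_sd, size=(lv1, T))
    eff_bp = rng.normal(scale=cfg.fixed_effect_sd, size=(lv2, T))
    lo, hi = cfg.covariate_range
    age = rng.uniform(lo, hi, size=n)
    age_term = cfg.covariate_slope * (age - 0.5 * (lo + hi))

    resid = rng.normal(size=(n, T)) * np.sqrt(sigma_e2)
    y = tbv + eff_cg[cg - 1] + eff_bp[bp - 1] + age_term[:, None] + resid

    table = pd.DataFrame({"animal": ids, "cg": cg.astype(str),
                          "birth_place": bp.astype(str), "age": age})
    for t in range(T):
        table[f"trait{t + 1}"] = y[:, t]
    truth = SimTruth(
        tbv=pd.DataFrame(tbv, index=ids,
                         columns=[f"trait{t + 1}" for t in range(T)]),
        qtl_indices=qtl_idx,
        qtl_effects=effects * (sa * np.sqrt(1.0 - w) / sd_q[None, :] * 1.0),
        sigma_a2=h2.copy(),
        sigma_e2=sigma_e2,
    )
    return table, truth


def simulate_population(cfg: SimConfig | None = None, seed: int | None = None) -> SimData:
    """One call that runs the three stages with a shared seed stream."""
    cfg = cfg if cfg is not None else SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    pedsim = simulate_pedigree(cfg, rng)
    geno = drop_genotypes(pedsim, cfg, rng)
    phenotypes, truth = simulate_phenotypes(pedsim, geno, cfg, rng)
    return SimData(cfg, pedsim, geno, phenotypes, truth)
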