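"""Synthetic open-pollinated progeny-trial generator with ground truth.

Emulates the statistical structure the analysis assumes: maternal
half-sib families whose members are in truth a mixture of half-sibs,
hidden full-sibs (few effective pollen donors per family) and occasional
selfs; biallelic markers gene-dropped from unrelated founders; traits
driven by additive and dominance QTL effects plus site and
family-by-replicate design effects.

The recorded pedigree lists every sire as unknown — exactly what an OP
breeding program observes — while the realized sires, true breeding
values and dominance deviations are kept in a :class:`TruthSet` for
parameter-recovery tests.

Default configuration mirrors a two-trial OP study: 244 families of ~24
progeny over two sites (one with 6 replicates of multi-tree plots, one
with 30 single-tree replicates), 2,023 biallelic markers, 28 genotyped
families, and trait architectures near h2 = 0.35 with dominance ratios
of 0.4-0.5 for growth traits but none for the wood-chemistry trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PedigreeTable


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study design."""

    n_families: int = 244
    #: int, or (low, high) range sampled per family (inclusive)
    progeny_per_family: int | tuple = 24
    n_sites: int = 2
    reps_per_site: tuple = (6, 30)
    n_markers: int = 2023
    n_qtl: int = 300
    founder_maf: tuple = (0.05, 0.95)
    #: effective pollen donors per family; small values create full-sib clusters
    full_sib_concentration: int = 5
    selfing_rate: float = 0.05
    #: per-trait (target_h2, target_d2) on the adjusted scale
    trait_targets: dict = field(default_factory=lambda: {
        "DBH": (0.35, 0.45), "Ht": (0.38, 0.42), "KPY": (0.35, 0.0)})
    trait_means: dict = field(default_factory=lambda: {
        "DBH": 1.2, "Ht": 140.0, "KPY": 52.0})
    trait_sds: dict = field(default_factory=lambda: {
        "DBH": 0.25, "Ht": 25.0, "KPY": 2.0})
    site_effect_sd: float = 0.5
    site_scales: tuple = (1.0, 1.25)
    famrep_sd: float = 0.3
    n_genotyped_families: int = 28
    genotyped_per_family: int = 16
    #: traits measured only on genotyped trees (wood sampling is expensive)
    genotyped_only_traits: tuple = ("KPY",)
    seed: int = 0

    def __post_init__(self) -> None:
        for trait, (h2, d2) in self.trait_targets.items():
            if h2 + d2 > 1:
                raise ValueError(f"{trait}: target_h2 + target_d2 must be <= 1")
        if not 0 <= self.selfing_rate <= 1:
            raise ValueError("selfing_rate must lie in [0, 1]")
        lo, hi = self.founder_maf
        if not (0 <= lo < hi <= 1):
            raise ValueError("founder_maf must be an increasing range in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")


@dataclass
class TruthSet:
    """Generative ground truth: per-tree genetic values and QTL effects."""

    trees: pd.DataFrame       # tree_id, realized_sire, bv_<trait>, dom_<trait>
    qtl: pd.DataFrame         # trait, marker_id, alpha, delta
    realized_ratios: dict     # trait -> {'h2':, 'd2':} on component variances
    components: dict          # trait -> {'var_a':, 'var_d':, 'var_e':}


@dataclass
class SimData:
    """A complete simulated dataset plus its ground truth."""

    config: SimConfig
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix          # observed (genotyped trees only)
    genotypes_all: GenotypeMatrix      # every progeny, for truth checks
    phenotypes: pd.DataFrame
    truth: TruthSet


def _draw_freqs(cfg: SimConfig, rng) -> np.ndarray:
    lo, hi = cfg.founder_maf
    return rng.uniform(lo, hi, size=cfg.n_markers)


def simulate_founders(cfg: SimConfig, rng=None):
    """Unrelated founder dams and per-family pollen-donor genotypes.

    Returns (allele_freq, dam_codes, donor_codes) where ``donor_codes``
    has shape (n_families, full_sib_concentration, n_markers).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = _draw_freqs(cfg, rng)
    dams = rng.binomial(2, p, size=(cfg.n_families, cfg.n_markers)).astype(float)
    donors = rng.binomial(
        2, p, size=(cfg.n_families, cfg.full_sib_concentration, cfg.n_markers)
    ).astype(float)
    return p, dams, donors


def _gamete(genotypes: np.ndarray, rng) -> np.ndarray:
    """One gamete per row: heterozygous loci transmit a random allele."""
    g = np.asarray(genotypes)
    allele = (g // 2).astype(float)
    het = g == 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()))
    return allele


def simulate_op_progeny(cfg: SimConfig, rng=None, founders=None):
    """Gene-drop OP progeny; recorded sires unknown, realized sires kept.

    Returns (PedigreeTable, GenotypeMatrix over all progeny, realized_sires).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p, dams, donors = simulate_founders(cfg, rng) if founders is None else founders
    ppf = cfg.progeny_per_family
    if isinstance(ppf, tuple):
        fam_sizes = rng.integers(ppf[0], ppf[1] + 1, size=cfg.n_families)
    else:
        fam_sizes = np.full(cfg.n_families, int(ppf))
    n_prog = int(fam_sizes.sum())

    rows = []
    for f in range(cfg.n_families):
        fam = f"FAM{f:04d}"
        rows.append((f"DAM{f:04d}", "", "", fam, "", "", False))
    codes = np.empty((n_prog, cfg.n_markers))
    realized_sires = []
    tree_ids = []
    k = 0
    for f in range(cfg.n_families):
        fam, dam_id = f"FAM{f:04d}", f"DAM{f:04d}"
        m = int(fam_sizes[f])
        dam_g = np.tile(dams[f], (m, 1))
        selfed = rng.random(m) < cfg.selfing_rate
        donor_pick = rng.integers(cfg.full_sib_concentration, size=m)
        sire_g = donors[f][donor_pick]
        sire_g[selfed] = dams[f]
        sire_label = np.where(selfed, dam_id,
                              [f"POL{f:04d}_{d}" for d in donor_pick])
        codes[k:k + m] = _gamete(dam_g, rng) + _gamete(sire_g, rng)
        for j in range(m):
            tid = f"T{k + j:05d}"
            tree_ids.append(tid)
            realized_sires.append(sire_label[j])
            rows.append((tid, dam_id, "", fam, "", "", False))
        k += m

    # field layout: progeny split across sites, replicates dealt per site
    ped = pd.DataFrame(rows, columns=["individual_id", "dam_id", "sire_id",
                                      "family_id", "site_id", "replicate_id",
                                      "genotyped"])
    prog_mask = ped["dam_id"] != ""
    sites = np.concatenate([
        np.tile(np.arange(cfg.n_sites), int(m) // cfg.n_sites + 1)[:int(m)]
        for m in fam_sizes])
    reps = np.array([rng.integers(cfg.reps_per_site[s % len(cfg.reps_per_site)])
                     for s in sites])
    ped.loc[prog_mask, "site_id"] = [f"S{s}" for s in sites]
    ped.loc[prog_mask, "replicate_id"] = [f"R{r}" for r in reps]

    # genotyped subset: whole families, balanced across the family
    fams = rng.choice(cfg.n_families, size=min(cfg.n_genotyped_families,
                                               cfg.n_families), replace=False)
    genotyped = set()
    prog_by_fam = (ped[prog_mask].groupby("family_id")["individual_id"]
                   .apply(list).to_dict())
    for f in fams:
        members = prog_by_fam[f"FAM{f:04d}"]
        take = min(cfg.genotyped_per_family, len(members))
        picked = rng.choice(len(members), size=take, replace=False)
        genotyped.update(members[i] for i in picked)
    ped["genotyped"] = ped["individual_id"].isin(genotyped)

    marker_ids = np.array([f"M{j:05d}" for j in range(cfg.n_markers)], dtype=object)
    geno_all = GenotypeMatrix(np.array(tree_ids, dtype=object), marker_ids, codes,
                              {"founder_freq": p})
    return PedigreeTable(ped), geno_all, pd.Series(realized_sires,
                                                   index=tree_ids,
                                                   name="realized_sire")


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale to an exact sample variance (ddof=1)."""
    x = x - x.mean()
    v = x.var(ddof=1)
    if target_var == 0 or v == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_phenotypes(ped: PedigreeTable, geno_all: GenotypeMatrix,
                        cfg: SimConfig, rng=None):
    """Generate trait values and the ground-truth genetic values.

    Core-scale model per trait: y* = site_shift + scale_s * (a + d + famrep
    + e) with component sample variances rescaled to hit the target ratios
    exactly (a: h2, d: d2, e: 1 - h2 - d2); y = mean + sd * y*.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    prog = ped.table[ped.table["dam_id"] != ""].copy()
    tree_ids = prog["individual_id"].to_numpy()
    g = geno_all.subset(individuals=tree_ids)
    p = g.allele_freq
    wa = g.codes - 2 * p
    pq = p * (1 - p)
    wd = np.where(g.codes == 1, 2 * pq,
                  np.where(g.codes == 2, -2 * (1 - p) ** 2, -2 * p**2))

    cell = (prog["site_id"] + ":" + prog["family_id"] + ":"
            + prog["replicate_id"]).to_numpy()
    cell_levels = pd.unique(cell)
    site_codes = prog["site_id"].str.removeprefix("S").astype(int).to_numpy()
    site_shift = rng.normal(0.0, cfg.site_effect_sd, size=cfg.n_sites)
    scales = np.asarray(cfg.site_scales)[:cfg.n_sites]

    pheno = prog[["individual_id", "site_id", "family_id", "replicate_id"]].copy()
    truth_trees = pd.DataFrame({"tree_id": tree_ids})
    qtl_rows, ratios, components = [], {}, {}
    for trait, (h2, d2) in cfg.trait_targets.items():
        qtl_idx = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
        alpha = rng.normal(size=cfg.n_qtl)
        delta = rng.normal(size=cfg.n_qtl)
        a = _rescale(wa[:, qtl_idx] @ alpha, h2)
        d = _rescale(wd[:, qtl_idx] @ delta, d2)
        e = _rescale(rng.normal(size=len(tree_ids)), max(1.0 - h2 - d2, 0.0))
        famrep = dict(zip(cell_levels,
                          rng.normal(0.0, cfg.famrep_sd, size=len(cell_levels))))
        u = np.array([famrep[c] for c in cell])
        core = a + d + u + e
        y = (cfg.trait_means.get(trait, 0.0)
             + cfg.trait_sds.get(trait, 1.0)
             * (site_shift[site_codes] + scales[site_codes] * core))
        pheno[trait] = y
        truth_trees[f"bv_{trait}"] = a
        truth_trees[f"dom_{trait}"] = d
        va, vd, ve = a.var(ddof=1), d.var(ddof=1), e.var(ddof=1)
        total = va + vd + ve
        ratios[trait] = {"h2": va / total, "d2": vd / total}
        components[trait] = {"var_a": va, "var_d": vd, "var_e": ve}
        for j, m in enumerate(qtl_idx):
            qtl_rows.append({"trait": trait, "marker_id": g.marker_ids[m],
                             "alpha": alpha[j], "delta": delta[j]})
    # traits measured only on the genotyped subset
    genotyped = set(ped.genotyped_ids)
    for trait in cfg.genotyped_only_traits:
        if trait in pheno.columns:
            mask = ~pheno["individual_id"].isin(genotyped)
            pheno.loc[mask, trait] = np.nan
    truth = TruthSet(truth_trees, pd.DataFrame(qtl_rows), ratios, components)
    return pheno.reset_index(drop=True), truth


def simulate_dataset(cfg: SimConfig | None = None, seed: int | None = None) -> SimData:
    """End-to-end dataset: pedigree, genotypes, phenotypes, ground truth."""
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    ped, geno_all, sires = simulate_op_progeny(cfg, rng)
    pheno, truth = simulate_phenotypes(ped, geno_all, cfg, rng)
    truth.trees["realized_sire"] = sires.loc[truth.trees["tree_id"]].to_numpy()
    observed = geno_all.subset(individuals=list(ped.genotyped_ids))
    return SimData(cfg, ped, observed, geno_all, pheno, truth)
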