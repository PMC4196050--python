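"""Synthetic dairy-cattle populations for genomic-prediction experiments.

This module generates pedigreed populations whose structure mirrors a
cow-based reference design: a set of genotyped, progeny-tested sires
(reference bulls), genotyped reference cows, a younger genotyped validation
cow cohort, non-genotyped dams of validation cows that carry de-regressed
proofs (DRP), and large paternal half-sib groups of non-genotyped daughters
of the reference sires.  SNP genotypes are produced by gene dropping on
unlinked loci; true breeding values are additive over a QTL subset of the
SNPs; EBV of a target reliability are generated per animal and converted to
DRP either directly or through parent-average deregression.

Reproducibility: all randomness flows from ``SimConfig.seed`` through three
named sub-streams (pedigree / genotypes / traits), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Pedigree",
    "GenotypeMatrix",
    "TraitRecords",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_population",
    "random_pedigree",
]

COHORTS = (
    "founder_sire",
    "founder_dam",
    "ref_cow",
    "ref_bull",
    "val_cow",
    "nongeno_dam",
    "nongeno_halfsib",
)

#: cohorts whose members carry DRP records (founder dams are relationship
#: placeholders only)
DRP_COHORTS = ("ref_bull", "ref_cow", "val_cow", "nongeno_dam", "nongeno_halfsib")

UNKNOWN = "0"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (ordering or cycles)."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study population.

    Defaults describe the reduced-scale study replica: 24 genotyped
    reference sires, 400 genotyped reference cows, 80 genotyped validation
    cows of which 40 have non-genotyped dams with DRP, and 20 non-genotyped
    paternal half-sisters per sire.  DRP reliabilities are drawn uniformly
    between the cohort floor (0.40 cows / 0.80 bulls) and ``rel_max``.
    """

    n_sires: int = 24
    n_ref_cows: int = 400
    n_val_cows: int = 80
    n_dams_nongeno: int = 40
    n_halfsibs_per_sire: int = 20
    n_snps: int = 2000
    n_qtl: int = 200
    maf_min: float = 0.01
    h2: float = 0.30
    rel_cow: float = 0.40  # DRP reliability floor for cows (strict)
    rel_bull: float = 0.80  # DRP reliability floor for bulls (strict)
    rel_max: float = 0.95
    n_founder_dams: int = 0  # 0 -> n_ref_cows // 2
    drp_mode: Literal["direct", "deregress"] = "direct"
    seed: int = 2014

    def __post_init__(self) -> None:
        counts = {
            "n_sires": self.n_sires,
            "n_ref_cows": self.n_ref_cows,
            "n_val_cows": self.n_val_cows,
            "n_halfsibs_per_sire": self.n_halfsibs_per_sire,
            "n_snps": self.n_snps,
            "n_qtl": self.n_qtl,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_dams_nongeno < 0:
            raise ConfigError("n_dams_nongeno must be >= 0")
        if self.n_dams_nongeno > self.n_val_cows:
            raise ConfigError("n_dams_nongeno cannot exceed n_val_cows")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl cannot exceed n_snps")
        if not 0.0 < self.maf_min <= 0.5:
            raise ConfigError("maf_min must lie in (0, 0.5]")
        if not 0.0 < self.h2 < 1.0:
            raise ConfigError("h2 must lie strictly in (0, 1)")
        if not 0.4 <= self.rel_cow < self.rel_max:
            raise ConfigError("rel_cow must satisfy 0.40 <= rel_cow < rel_max")
        if not 0.8 <= self.rel_bull < self.rel_max:
            raise ConfigError("rel_bull must satisfy 0.80 <= rel_bull < rel_max")
        if not self.rel_max < 1.0:
            raise ConfigError("rel_max must be < 1")
        if self.drp_mode not in ("direct", "deregress"):
            raise ConfigError(f"unknown drp_mode {self.drp_mode!r}")

    @property
    def founder_dam_count(self) -> int:
        return self.n_founder_dams or max(1, self.n_ref_cows // 2)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named per-stage RNG sub-streams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("pedigree", "genotypes", "traits")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class Pedigree:
    """Topologically ordered pedigree with cohort and genotyped flags.

    ``records`` columns: animal, sire, dam, order, genotyped, cohort, sex.
    Unknown parents are encoded as ``"0"``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam", "order", "genotyped", "cohort", "sex"}
        missing = required - set(self.records.columns)
        if missing:
            raise PedigreeError(f"pedigree missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return self.records["animal"].tolist()

    @property
    def genotyped_ids(self) -> list[str]:
        m = self.records["genotyped"].to_numpy(bool)
        return self.records.loc[m, "animal"].tolist()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positional sire/dam indices; -1 encodes an unknown parent."""
        pos = {a: i for i, a in enumerate(self.records["animal"])}
        sire = np.array([pos.get(s, -1) for s in self.records["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.records["dam"]], dtype=np.int64)
        return sire, dam

    def cohort_of(self) -> pd.Series:
        return self.records.set_index("animal")["cohort"]

    def validate(self) -> None:
        """Raise PedigreeError unless parents precede offspring (which also
        rules out any animal being its own ancestor)."""
        seen: set[str] = set()
        for rec in self.records.itertuples(index=False):
            for parent in (rec.sire, rec.dam):
                if parent != UNKNOWN and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent} of {rec.animal} does not precede it"
                    )
            if rec.animal in seen:
                raise PedigreeError(f"duplicate animal id {rec.animal}")
            seen.add(rec.animal)


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (animals x SNPs, coded 0/1/2) for genotyped animals.

    ``freqs`` are reference-allele frequencies computed from the genotyped
    animals themselves.  The simulator additionally stashes the full
    (all-animal) counts in private fields so true breeding values can be
    computed for non-genotyped animals without exposing their genotypes.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray
    freqs: np.ndarray
    _full_ids: list[str] = field(default_factory=list, repr=False)
    _full_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("counts shape does not match id lists")
        if self.counts.size and not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("allele counts must be 0, 1 or 2 (no missing values)")
        self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class TraitRecords:
    """Per-animal trait table: true breeding value, EBV, DRP, reliability.

    ``table`` columns: animal, cohort, trait, true_bv, ebv, rel_ebv, drp,
    rel_drp, phenotype, included.  ``included`` marks records passing the
    cohort-specific DRP reliability floor.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "animal", "cohort", "trait", "true_bv", "ebv", "rel_ebv",
            "drp", "rel_drp", "phenotype", "included",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    def included_subset(self) -> pd.DataFrame:
        return self.table[self.table["included"]].reset_index(drop=True)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Build the study-structured pedigree.

    Layout (in topological order): genotyped reference sires (ref_bull),
    founder dams, genotyped reference cows, non-genotyped dams with DRP,
    genotyped validation cows (the first ``n_dams_nongeno`` of which get
    distinct non-genotyped dams; the rest get genotyped reference-cow dams),
    and ``n_halfsibs_per_sire`` non-genotyped daughters per sire.
    """
    rng = _streams(config.seed)["pedigree"]
    rows: list[tuple] = []
    order = 0

    def add(animal: str, sire: str, dam: str, genotyped: bool, cohort: str, sex: str):
        nonlocal order
        rows.append((animal, sire, dam, order, genotyped, cohort, sex))
        order += 1

    sires = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    for s in sires:
        add(s, UNKNOWN, UNKNOWN, True, "ref_bull", "M")

    fdams = [f"FD{i + 1:04d}" for i in range(config.founder_dam_count)]
    for d in fdams:
        add(d, UNKNOWN, UNKNOWN, False, "founder_dam", "F")

    sire_of: dict[str, str] = {}

    ref_cows = [f"RC{i + 1:04d}" for i in range(config.n_ref_cows)]
    for c in ref_cows:
        s = sires[rng.integers(config.n_sires)]
        d = fdams[rng.integers(len(fdams))]
        sire_of[c] = s
        add(c, s, d, True, "ref_cow", "F")

    ndams = [f"ND{i + 1:04d}" for i in range(config.n_dams_nongeno)]
    for d in ndams:
        s = sires[rng.integers(config.n_sires)]
        fd = fdams[rng.integers(len(fdams))]
        sire_of[d] = s
        add(d, s, fd, False, "nongeno_dam", "F")

    val_cows = [f"VC{i + 1:04d}" for i in range(config.n_val_cows)]
    nd_order = rng.permutation(config.n_dams_nongeno)
    for i, c in enumerate(val_cows):
        if i < config.n_dams_nongeno:
            dam = ndams[nd_order[i]]
        else:
            dam = ref_cows[rng.integers(config.n_ref_cows)]
        # avoid sire-daughter matings: the dam's own sire is excluded
        candidates = [s for s in sires if s != sire_of.get(dam)]
        sire = candidates[rng.integers(len(candidates))]
        add(c, sire, dam, True, "val_cow", "F")

    hs = 0
    for s in sires:
        for _ in range(config.n_halfsibs_per_sire):
            hs += 1
            add(f"HS{hs:05d}", s, UNKNOWN, False, "nongeno_halfsib", "F")

    df = pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "order", "genotyped", "cohort", "sex"]
    )
    ped = Pedigree(df)
    ped.validate()
    return ped


def _gene_drop(
    ped: Pedigree, n_snps: int, maf_min: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Drop unlinked biallelic SNPs through the pedigree.

    Founder allele frequencies p_j ~ Uniform(maf_min, 1 - maf_min); founder
    alleles are Bernoulli(p_j); each non-founder inherits one allele from
    each parent by Mendelian sampling, an unknown parent contributing a
    fresh founder allele.  Returns (paternal, maternal) allele arrays of
    shape (n_animals, n_snps).
    """
    ped.validate()
    n = len(ped)
    p = rng.uniform(maf_min, 1.0 - maf_min, size=n_snps)
    sire_idx, dam_idx = ped.parent_indices()
    pat = np.zeros((n, n_snps), dtype=np.int8)
    mat = np.zeros((n, n_snps), dtype=np.int8)
    for i in range(n):
        for alleles, parent in ((pat, sire_idx[i]), (mat, dam_idx[i])):
            if parent < 0:
                alleles[i] = rng.random(n_snps) < p
            else:
                pick = rng.random(n_snps) < 0.5
                alleles[i] = np.where(pick, pat[parent], mat[parent])
    return pat, mat


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop SNP genotypes and apply the MAF filter.

    Genotypes are simulated for every pedigree member but exposed only for
    genotyped animals.  SNPs with minor allele frequency below
    ``config.maf_min`` *among the genotyped animals* are removed, and the
    reported frequencies are recomputed from the genotyped animals.
    """
    rng = _streams(config.seed)["genotypes"]
    pat, mat = _gene_drop(ped, config.n_snps, config.maf_min, rng)
    full = (pat + mat).astype(np.int8)
    geno_mask = ped.records["genotyped"].to_numpy(bool)
    counts = full[geno_mask]
    freqs = counts.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf >= config.maf_min
    snp_ids = [f"SNP{j + 1:06d}" for j in range(config.n_snps)]
    return GenotypeMatrix(
        animal_ids=[a for a, g in zip(ped.ids, geno_mask) if g],
        snp_ids=[s for s, k in zip(snp_ids, keep) if k],
        counts=counts[:, keep],
        freqs=freqs[keep],
        _full_ids=ped.ids,
        _full_counts=full[:, keep],
    )


def simulate_traits(
    ped: Pedigree,
    geno: GenotypeMatrix,
    config: SimConfig,
    trait: str = "trait1",
) -> TraitRecords:
    """Simulate true breeding values, EBV, DRP and phenotypes.

    A random subset of ``n_qtl`` retained SNPs receives i.i.d. normal
    effects; true breeding values are the centered additive scores, scaled
    to unit variance (one genetic SD = 1).  EBV follow the BLUP shrinkage
    convention: ebv = r^2 * (g + e) with Var(e) = Var(g)(1 - r^2)/r^2, so
    corr^2(ebv, g) = r^2 and the regression of ebv on g has slope r^2.
    Target reliabilities r^2 are Uniform(floor, rel_max) per cohort.

    DRP: in ``direct`` mode drp = g + e (reliability exactly the target);
    in ``deregress`` mode DRP are produced by parent-average deregression
    of the EBV (see :mod:`onestepblend.deregression`).

    Phenotypes are y = g + e_p with Var(e_p) = Var(g)(1 - h2)/h2.
    """
    if geno._full_counts is None or geno._full_ids != ped.ids:
        raise ValueError("genotype matrix does not carry full counts for this pedigree")
    rng = _streams(config.seed)["traits"]
    full = geno._full_counts.astype(float)
    n, m = full.shape

    n_qtl = min(config.n_qtl, m)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    effects = rng.normal(size=n_qtl)
    g = full[:, qtl] @ effects
    g -= g.mean()
    sd = g.std()
    if sd > 0:
        g /= sd
    var_g = float(np.var(g))

    cohorts = ped.records["cohort"].to_numpy()
    rel = np.full(n, np.nan)
    is_bull = cohorts == "ref_bull"
    has_drp = np.isin(cohorts, DRP_COHORTS)
    rel[is_bull] = rng.uniform(config.rel_bull, config.rel_max, is_bull.sum())
    cow_mask = has_drp & ~is_bull
    rel[cow_mask] = rng.uniform(config.rel_cow, config.rel_max, cow_mask.sum())

    noise = rng.normal(size=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_sd = np.sqrt(var_g * (1.0 - rel) / rel)
    unshrunk = g + np.where(has_drp, eps_sd * noise, np.nan)
    ebv = rel * unshrunk  # BLUP-scale shrinkage

    if config.h2 < 1.0:
        pheno_noise = rng.normal(size=n) * np.sqrt(var_g * (1 - config.h2) / config.h2)
    else:  # pragma: no cover - h2 validated in (0,1)
        pheno_noise = np.zeros(n)
    phenotype = g + pheno_noise

    table = pd.DataFrame(
        {
            "animal": ped.ids,
            "cohort": cohorts,
            "trait": trait,
            "true_bv": g,
            "ebv": ebv,
            "rel_ebv": rel,
            "drp": unshrunk,
            "rel_drp": rel,
            "phenotype": phenotype,
            "included": has_drp,
        }
    )

    if config.drp_mode == "deregress":
        from . import deregression

        table = deregression.deregress_table(table, ped)

    floors = {c: (config.rel_bull if c == "ref_bull" else config.rel_cow) for c in DRP_COHORTS}
    ok = np.zeros(n, dtype=bool)
    for c, floor in floors.items():
        mask = (table["cohort"] == c).to_numpy() & table["included"].to_numpy(bool)
        ok |= mask & (table["rel_drp"].to_numpy() > floor)
    table["included"] = ok
    return TraitRecords(table)


def simulate_population(
    config: SimConfig,
) -> tuple[Pedigree, GenotypeMatrix, TraitRecords]:
    """Convenience wrapper: pedigree + genotypes + traits in one call."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    traits = simulate_traits(ped, geno, config)
    return ped, geno, traits


def random_pedigree(
    n: int,
    rng: np.random.Generator,
    n_founders: int | None = None,
    genotyped_fraction: float = 0.5,
) -> Pedigree:
    """Generic random pedigree for property testing: ``n_founders`` base
    animals followed by offspring whose parents are drawn (possibly unknown)
    from earlier animals.  Genotyped flags are random."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    n_founders = n_founders or max(2, n // 5)
    rows = []
    for i in range(n):
        animal = f"X{i + 1:04d}"
        if i < n_founders:
            sire = dam = UNKNOWN
        else:
            sire = f"X{rng.integers(i) + 1:04d}" if rng.random() < 0.9 else UNKNOWN
            dam = f"X{rng.integers(i) + 1:04d}" if rng.random() < 0.9 else UNKNOWN
            if sire == dam:
                dam = UNKNOWN
        rows.append(
            (
                animal,
                sire,
                dam,
                i,
                bool(rng.random() < genotyped_fraction),
                "founder_sire" if i < n_founders else "ref_cow",
                "M" if rng.random() < 0.5 else "F",
            )
        )
    # guarantee at least one genotyped animal
    if not any(r[4] for r in rows):
        rows[0] = rows[0][:4] + (True,) + rows[0][5:]
    ped = Pedigree(
        pd.DataFrame(
            rows,
            columns=["animal", "sire", "dam", "order", "genotyped", "cohort", "sex"],
        )
    )
    ped.validate()
    return ped
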