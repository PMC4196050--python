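"""End-to-end study replica: simulate, deregress/filter, build matrices,
fit GBLUP / one-step / adjusted one-step, and validate.

A :class:`StudyScenario` bundles the simulation configuration with the set
of prediction methods and the sources of non-genotyped information (dams
of validation cows, paternal half-sisters) to include in the one-step
reference.  ``run_scenario`` repeats the full analysis over independent
replicates (seeds derived deterministically from one master seed) and
aggregates validation accuracy per method x subgroup with mean and SD.

Method labels:

* ``gblup`` — K = G over genotyped animals, reference DRP only (genotyped
  bulls + reference cows); predictions are direct genomic values (DGV).
* ``onestep`` — K = H over all pedigree animals, reference DRP plus DRP of
  the selected non-genotyped cohorts; predictions are genomically enhanced
  breeding values (GEBV).
* ``adjusted`` — as ``onestep`` but H is built from G_a = G*beta + alpha.
* ``onestep_dams_only`` — contrast fit with half-sisters' DRP removed,
  quantifying how much information the dams alone contribute.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as obio
from .mme import MixedModelSpec, MMEFit, build_weights, reml_fit, solve_mme
from .popsim import Pedigree, SimConfig, TraitRecords, simulate_population
from .relmat import GAdjustment, adjust_G, build_A, build_G, build_H, extract_A22
from .validation import subgroup_report

__all__ = ["StudyScenario", "ScenarioResult", "analyze_population", "run_scenario",
           "scenario_preset", "replicate_seeds"]

logger = logging.getLogger(__name__)

METHODS = ("gblup", "onestep", "adjusted")

REFERENCE_COHORTS = ("ref_bull", "ref_cow")

_KIND_LABEL = {"gblup": "GBLUP", "onestep": "one_step", "adjusted": "adjusted_one_step"}


@dataclass(frozen=True)
class StudyScenario:
    """One simulated experiment: population design x methods x DRP sources."""

    sim: SimConfig = field(default_factory=SimConfig)
    methods: tuple[str, ...] = METHODS
    include_dams: bool = True
    include_halfsibs: bool = True
    with_dams_only_contrast: bool = False
    replicates: int = 20
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ScenarioResult:
    per_replicate: pd.DataFrame  # replicate, method, trait, subgroup, n_animals, r_v, mean_theo_acc
    aggregate: pd.DataFrame  # method, trait, subgroup, mean/sd of r_v and theoretical accuracy
    adjustments: pd.DataFrame  # replicate, beta, alpha


def replicate_seeds(master_seed: int, replicates: int) -> list[int]:
    """Deterministic per-replicate seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(replicates)
    return [int(s) % (2**31) for s in state]


def _reference_spec(
    traits: pd.DataFrame,
    K,
    cohorts: tuple[str, ...],
    kind_label: str,
) -> MixedModelSpec:
    rows = traits[traits["included"] & traits["cohort"].isin(cohorts)]
    rows = rows[rows["animal"].isin(set(K.animal_ids))]
    return MixedModelSpec(
        y=rows["drp"].to_numpy(float),
        weights=build_weights(rows["rel_drp"].to_numpy(float)),
        K=K,
        record_animal_ids=rows["animal"].tolist(),
        kind_label=kind_label,
    )


def analyze_population(
    ped: Pedigree,
    geno,
    traits: TraitRecords,
    methods: tuple[str, ...] = METHODS,
    include_dams: bool = True,
    include_halfsibs: bool = True,
    with_dams_only_contrast: bool = False,
    trait: str = "trait1",
) -> tuple[dict[str, MMEFit], GAdjustment | None]:
    """Build all matrices and fit every requested method on one population.

    Validation cows never contribute records; in one-step fits the selected
    non-genotyped cohorts' DRP join the genotyped reference.  Variance
    components are re-estimated per method (each K implies its own scale).
    """
    tab = traits.table[traits.table["trait"] == trait]
    A = build_A(ped)
    A22 = extract_A22(A, ped)
    G = build_G(geno=geno)

    onestep_cohorts = list(REFERENCE_COHORTS)
    if include_dams:
        onestep_cohorts.append("nongeno_dam")
    if include_halfsibs:
        onestep_cohorts.append("nongeno_halfsib")

    fits: dict[str, MMEFit] = {}
    adj: GAdjustment | None = None

    if "gblup" in methods:
        spec = _reference_spec(tab, G, REFERENCE_COHORTS, "GBLUP")
        fits["gblup"] = solve_mme(spec, reml_fit(spec))

    if "onestep" in methods or with_dams_only_contrast:
        H = build_H(A, G, ped)
        if "onestep" in methods:
            spec = _reference_spec(tab, H, tuple(onestep_cohorts), "one_step")
            fits["onestep"] = solve_mme(spec, reml_fit(spec))
        if with_dams_only_contrast:
            cohorts = tuple(c for c in onestep_cohorts if c != "nongeno_halfsib")
            if "nongeno_dam" not in cohorts:
                cohorts = cohorts + ("nongeno_dam",)
            spec = _reference_spec(tab, H, cohorts, "one_step")
            fits["onestep_dams_only"] = solve_mme(spec, reml_fit(spec))

    if "adjusted" in methods:
        Ga, adj = adjust_G(G, A22)
        Ha = build_H(A, Ga, ped)
        spec = _reference_spec(tab, Ha, tuple(onestep_cohorts), "adjusted_one_step")
        fits["adjusted"] = solve_mme(spec, reml_fit(spec))

    return fits, adj


def run_scenario(sc: StudyScenario) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate validation accuracy."""
    seeds = replicate_seeds(sc.sim.seed, sc.replicates)
    outdir = Path(sc.outdir) if sc.outdir else None
    per_rep: list[pd.DataFrame] = []
    adjustments: list[dict] = []

    for r, seed in enumerate(seeds):
        cfg = sc.sim.with_seed(seed)
        try:
            ped, geno, traits = simulate_population(cfg)
            fits, adj = analyze_population(
                ped,
                geno,
                traits,
                methods=sc.methods,
                include_dams=sc.include_dams,
                include_halfsibs=sc.include_halfsibs,
                with_dams_only_contrast=sc.with_dams_only_contrast,
            )
            report = subgroup_report(fits, ped, traits)
        except Exception as e:
            raise RuntimeError(
                f"scenario failed in replicate {r}: {type(e).__name__}: {e}"
            ) from e
        report.insert(0, "replicate", r)
        per_rep.append(report)
        if adj is not None:
            adjustments.append({"replicate": r, "beta": adj.beta, "alpha": adj.alpha})
        if outdir is not None:
            rep_dir = outdir / f"rep_{r:02d}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            obio.write_pedigree_csv(ped, rep_dir / "pedigree.csv")
            obio.write_traits_tsv(traits, rep_dir / "traits.tsv")
            report.to_csv(rep_dir / "report.tsv", sep="\t", index=False)

    per_replicate = pd.concat(per_rep, ignore_index=True)
    agg = (
        per_replicate.groupby(["method", "trait", "subgroup"], as_index=False)
        .agg(
            n_replicates=("r_v", "size"),
            mean_n_animals=("n_animals", "mean"),
            mean_r_v=("r_v", "mean"),
            sd_r_v=("r_v", "std"),
            mean_theo_acc=("mean_theo_acc", "mean"),
            sd_theo_acc=("mean_theo_acc", "std"),
        )
        .sort_values(["subgroup", "method"])
        .reset_index(drop=True)
    )
    adj_df = pd.DataFrame(adjustments, columns=["replicate", "beta", "alpha"])
    result = ScenarioResult(per_replicate, agg, adj_df)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        per_replicate.to_csv(outdir / "per_replicate.tsv", sep="\t", index=False)
        agg.to_csv(outdir / "aggregate.tsv", sep="\t", index=False)
        summary = {
            "methods": list(sc.methods),
            "replicates": sc.replicates,
            "aggregate": agg.to_dict(orient="records"),
            "adjustment": adj_df.mean(numeric_only=True).to_dict() if len(adj_df) else {},
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return result


def scenario_preset(name: str, seed: int | None = None, replicates: int | None = None) -> StudyScenario:
    """Named scenario presets for the study's three experimental contrasts.

    * ``all_validation`` — dams + half-sisters included; accuracy reported
      for all validation cows and both dam-status subgroups.
    * ``genotyped_dam_subset`` — identical fits; the contrast of interest
      is the genotyped-dam subgroup row of the report.
    * ``dams_only`` — half-sisters' DRP removed, with the dams-only
      contrast fit included for direct comparison.
    """
    presets = {
        "all_validation": dict(include_dams=True, include_halfsibs=True,
                               with_dams_only_contrast=True),
        "genotyped_dam_subset": dict(include_dams=True, include_halfsibs=True),
        "dams_only": dict(include_dams=True, include_halfsibs=False),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[name])
    sim = SimConfig() if seed is None else SimConfig(seed=int(seed))
    if replicates is not None:
        kwargs["replicates"] = int(replicates)
    return StudyScenario(sim=sim, **kwargs)
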