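"""Validation accuracy of genomic predictions.

Realized accuracy is measured as

    r_v = corr(g_hat, DRP) / mean(sqrt(rel_DRP)),

the Pearson correlation between predictions and de-regressed proofs in the
validation set, corrected for the attenuation caused by the finite
reliability of the DRP themselves.  Because the correction is an average,
r_v can exceed 1 by construction; it is reported as computed.  The
denominator is averaged over exactly the animals entering that row's
correlation (subgroup-specific).

``subgroup_report`` summarizes realized and theoretical accuracy by
prediction method and validation subgroup: all validation cows, cows with
genotyped dams, and cows with non-genotyped dams (who also have
non-genotyped paternal half-sisters in the study design).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mme import MMEFit
from .popsim import Pedigree, TraitRecords

__all__ = ["compute_rv", "subgroup_report", "SUBGROUPS"]

logger = logging.getLogger(__name__)

SUBGROUPS = ("all", "genotyped_dam", "nongeno_dam_and_halfsibs")


class UndefinedStatisticError(ValueError):
    """Correlation undefined (zero variance or too few animals)."""


def compute_rv(g_hat: np.ndarray, drp: np.ndarray, rel_drp: np.ndarray) -> float:
    """Attenuation-corrected validation accuracy r_v."""
    g_hat = np.asarray(g_hat, float)
    drp = np.asarray(drp, float)
    rel_drp = np.asarray(rel_drp, float)
    if not (len(g_hat) == len(drp) == len(rel_drp)):
        raise ValueError("g_hat, drp and rel_drp must be aligned")
    if len(g_hat) < 2:
        raise UndefinedStatisticError("need at least 2 animals")
    if np.std(g_hat) == 0.0 or np.std(drp) == 0.0:
        raise UndefinedStatisticError("zero variance in predictions or DRP")
    r = float(np.corrcoef(g_hat, drp)[0, 1])
    return r / float(np.mean(np.sqrt(rel_drp)))


def _val_subgroups(ped: Pedigree) -> dict[str, list[str]]:
    recs = ped.records
    cohort = recs.set_index("animal")["cohort"]
    val = recs[recs["cohort"] == "val_cow"]
    dam_cohort = val["dam"].map(cohort)
    groups = {
        "all": val["animal"].tolist(),
        "genotyped_dam": val.loc[dam_cohort != "nongeno_dam", "animal"].tolist(),
        "nongeno_dam_and_halfsibs": val.loc[dam_cohort == "nongeno_dam", "animal"].tolist(),
    }
    return groups


def subgroup_report(
    fits: dict[str, MMEFit],
    ped: Pedigree,
    records: TraitRecords,
    trait: str = "trait1",
) -> pd.DataFrame:
    """Accuracy table: one row per (method, trait, subgroup).

    ``fits`` maps a method label (e.g. gblup / onestep / adjusted /
    onestep_dams_only) to its solved mixed model.  Validation animals whose
    DRP is undefined are dropped from the correlations.  Deterministic
    given its inputs.
    """
    groups = _val_subgroups(ped)
    tab = records.table[records.table["trait"] == trait].set_index("animal")
    rows = []
    for method, fit in fits.items():
        have = set(fit.animal_ids)
        for sub, ids in groups.items():
            ids = [a for a in ids if a in have and np.isfinite(tab.loc[a, "drp"])]
            if len(ids) < 2:
                logger.warning("subgroup %s/%s has < 2 animals; row skipped", method, sub)
                continue
            drp = tab.loc[ids, "drp"].to_numpy(float)
            rel = tab.loc[ids, "rel_drp"].to_numpy(float)
            g_hat = fit.g_hat_for(ids)
            try:
                rv = compute_rv(g_hat, drp, rel)
            except UndefinedStatisticError:
                logger.warning("subgroup %s/%s: undefined r_v; row skipped", method, sub)
                continue
            rows.append(
                {
                    "method": method,
                    "trait": trait,
                    "subgroup": sub,
                    "n_animals": len(ids),
                    "r_v": rv,
                    "mean_theo_acc": float(np.mean(fit.theo_acc_for(ids))),
                }
            )
    return pd.DataFrame(rows, columns=["method", "trait", "subgroup", "n_animals", "r_v", "mean_theo_acc"])
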