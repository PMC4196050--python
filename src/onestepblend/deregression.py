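"""De-regressed proofs (DRP) from estimated breeding values.

EBV from a genetic evaluation are shrunken toward the parent average (PA),
so they are unsuitable as response variables in a second evaluation: their
variance is deflated and parental information would be double counted.
Deregression removes both distortions.  With own reliability ``r2`` and
parent-average reliability ``r2_PA``, the information content of the
animal's own data is

    r2_own = (r2 - r2_PA) / (1 - r2_PA),

and the de-regressed proof and its reliability are

    DRP = PA + (EBV - PA) / r2_own,      rel_DRP = r2_own.

An animal whose EBV carries no own information (r2 <= r2_PA) has no DRP and
is flagged excluded rather than raising.  The parent average is
(EBV_sire + EBV_dam)/2 with a missing parent contributing 0 at reliability
0, and r2_PA = (r2_sire + r2_dam)/4.

This is the standard single-animal parent-average deregression; the module
keeps it behind a small interface so a different variant (e.g. a full
progeny-loop form) could be substituted without touching downstream code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popsim import ConfigError, Pedigree, TraitRecords, UNKNOWN

__all__ = ["DeregressionInput", "deregress", "deregress_table", "apply_reliability_filters"]

logger = logging.getLogger(__name__)

#: animals whose own reliability exceeds the parent average by less than
#: this are treated as carrying no own information
MIN_OWN_RELIABILITY = 1e-6


@dataclass
class DeregressionInput:
    """Per-animal EBV, reliabilities and (optional) parent EBV.

    ``table`` columns: animal, ebv, rel_ebv, sire_ebv, sire_rel, dam_ebv,
    dam_rel.  NaN in a parent column means that parent (or its proof) is
    unavailable and contributes nothing to the parent average.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "ebv", "rel_ebv"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"deregression input missing columns: {sorted(missing)}")
        t = self.table.copy()
        for col in ("sire_ebv", "sire_rel", "dam_ebv", "dam_rel"):
            if col not in t.columns:
                t[col] = np.nan
        rel = t["rel_ebv"].to_numpy(float)
        if np.any((rel <= 0.0) | (rel >= 1.0)):
            raise ValueError("rel_ebv must lie strictly in (0, 1)")
        self.table = t.reset_index(drop=True)


def _deregress_arrays(
    ebv: np.ndarray,
    rel: np.ndarray,
    sire_ebv: np.ndarray,
    sire_rel: np.ndarray,
    dam_ebv: np.ndarray,
    dam_rel: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized deregression; returns (drp, rel_drp, included)."""
    s_ebv = np.nan_to_num(sire_ebv)
    d_ebv = np.nan_to_num(dam_ebv)
    s_rel = np.nan_to_num(sire_rel)
    d_rel = np.nan_to_num(dam_rel)
    pa = 0.5 * (s_ebv + d_ebv)
    rel_pa = 0.25 * (s_rel + d_rel)
    own = (rel - rel_pa) / (1.0 - rel_pa)
    included = own > MIN_OWN_RELIABILITY
    own_safe = np.where(included, own, 1.0)
    drp = np.where(included, pa + (ebv - pa) / own_safe, np.nan)
    rel_drp = np.where(included, own, np.nan)
    return drp, rel_drp, included


def deregress(inp: DeregressionInput) -> pd.DataFrame:
    """De-regress EBV; returns the input table with drp, rel_drp, included."""
    t = inp.table
    drp, rel_drp, included = _deregress_arrays(
        t["ebv"].to_numpy(float),
        t["rel_ebv"].to_numpy(float),
        t["sire_ebv"].to_numpy(float),
        t["sire_rel"].to_numpy(float),
        t["dam_ebv"].to_numpy(float),
        t["dam_rel"].to_numpy(float),
    )
    out = t.copy()
    out["drp"] = drp
    out["rel_drp"] = rel_drp
    out["included"] = included
    n_excl = int((~included).sum())
    if n_excl:
        logger.info("deregression excluded %d of %d animals (no own information)", n_excl, len(out))
    return out


def deregress_table(table: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Deregress a popsim-style trait table in place of its drp columns.

    Parent EBV/reliabilities are looked up in the same table through the
    pedigree; a parent without an EBV record (e.g. a founder dam) counts as
    missing.
    """
    by_animal = table.set_index("animal")
    ebv = by_animal["ebv"]
    rel = by_animal["rel_ebv"]

    def parent_cols(parents: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        e = parents.map(ebv).to_numpy(float)
        r = parents.map(rel).to_numpy(float)
        missing = (parents == UNKNOWN).to_numpy()
        e[missing] = np.nan
        r[missing] = np.nan
        return e, r

    recs = ped.records.set_index("animal").loc[table["animal"]]
    s_ebv, s_rel = parent_cols(recs["sire"].reset_index(drop=True))
    d_ebv, d_rel = parent_cols(recs["dam"].reset_index(drop=True))

    has_ebv = table["rel_ebv"].notna().to_numpy()
    drp = np.full(len(table), np.nan)
    rel_drp = np.full(len(table), np.nan)
    included = np.zeros(len(table), dtype=bool)
    drp[has_ebv], rel_drp[has_ebv], included[has_ebv] = _deregress_arrays(
        table.loc[has_ebv, "ebv"].to_numpy(float),
        table.loc[has_ebv, "rel_ebv"].to_numpy(float),
        s_ebv[has_ebv],
        s_rel[has_ebv],
        d_ebv[has_ebv],
        d_rel[has_ebv],
    )
    out = table.copy()
    out["drp"] = drp
    out["rel_drp"] = rel_drp
    out["included"] = included
    return out


def apply_reliability_filters(
    records: TraitRecords, cohort_floors: dict[str, float]
) -> TraitRecords:
    """Mark records excluded unless rel_drp strictly exceeds the cohort floor.

    The comparison is strict ('greater than'), so a cow at exactly the 0.40
    floor is excluded.  Idempotent: re-applying the same floors changes
    nothing.
    """
    t = records.table
    unknown = set(t["cohort"]) - set(cohort_floors)
    if unknown:
        raise ConfigError(f"no reliability floor configured for cohorts: {sorted(unknown)}")
    floors = t["cohort"].map(cohort_floors).to_numpy(float)
    rel = t["rel_drp"].to_numpy(float)
    keep = records.table["included"].to_numpy(bool) & np.where(
        np.isnan(rel), False, rel > floors
    )
    out = t.copy()
    out["included"] = keep
    n_drop = int(t["included"].sum() - keep.sum())
    logger.info(
        "reliability filters: retained %d, newly excluded %d of %d records",
        int(keep.sum()), n_drop, len(out),
    )
    return TraitRecords(out)
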