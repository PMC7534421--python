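"""Phenotype pre-adjustment: tree volume, site standardization, design effects.

The adjustment pipeline runs in a fixed order:

1. conical over-bark volume from DBH and height,
2. linear rescaling of every non-reference site to the reference site's
   sample mean and standard deviation (the classic MEAN/STD
   standardization),
3. removal of the family-by-replicate (within site) design effect, fitted
   as a random effect by REML and subtracted as its BLUP, keeping the
   grand mean so adjusted phenotypes stay on the trait scale.

Downstream genetic models then carry only an intercept as fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .model import RESIDUAL, BLUPModel


@dataclass
class AdjustmentSpec:
    """What to adjust: reference site, traits, and the design factor columns."""

    reference_site: str
    traits: tuple = ("DBH", "Ht", "Vol", "KPY")
    site_col: str = "site_id"
    family_col: str = "family_id"
    replicate_col: str = "replicate_id"


def conical_volume(dbh, ht):
    """Over-bark conical volume index: pi * (DBH/2)^2 * Ht / 3.

    DBH and Ht in dm give volume in dm^3.  NaN propagates; negative
    measurements raise.
    """
    dbh = np.asarray(dbh, dtype=float)
    ht = np.asarray(ht, dtype=float)
    if np.nanmin(dbh, initial=0.0) < 0 or np.nanmin(ht, initial=0.0) < 0:
        raise ValueError("DBH and Ht must be non-negative")
    vol = np.pi * (dbh / 2.0) ** 2 * ht / 3.0
    return float(vol) if vol.ndim == 0 else vol


def standardize_to_reference(values: pd.Series, sites: pd.Series,
                             reference_site: str) -> pd.Series:
    """Rescale each non-reference site to the reference mean and SD (ddof=1).

    Reference-site values pass through unchanged; missing values are
    ignored when computing moments and remain missing.
    """
    values = values.astype(float)
    if reference_site not in set(sites):
        raise ValueError(f"reference site {reference_site!r} absent from data")
    ref = values[sites == reference_site]
    if ref.notna().sum() < 2:
        raise ValueError("reference site needs at least 2 non-missing values")
    m_ref, s_ref = ref.mean(), ref.std(ddof=1)
    if s_ref == 0:
        raise ValueError("reference site has zero standard deviation")
    out = values.copy()
    for site in pd.unique(sites):
        if site == reference_site:
            continue
        mask = sites == site
        vals = values[mask]
        if vals.notna().sum() < 2:
            raise ValueError(f"site {site!r} needs at least 2 non-missing values")
        m, s = vals.mean(), vals.std(ddof=1)
        if s == 0:
            raise ValueError(f"site {site!r} has zero standard deviation")
        out[mask] = (vals - m) / s * s_ref + m_ref
    return out


def adjust_design_effects(values: pd.Series, cells: pd.Series,
                          fixed_vc: dict | None = None
                          ) -> tuple[pd.Series, "object"]:
    """Subtract the BLUP of a random cell (family-by-rep) effect.

    Fits y = mu + u_cell + e with u_cell ~ N(0, I s2_f) by REML, then
    returns y minus the cell BLUPs (grand mean retained), along with the
    fitted results.  ``fixed_vc`` maps {'cell': s2_f, 'residual': s2_e}
    to bypass estimation.
    """
    mask = values.notna()
    y = values[mask].to_numpy(dtype=float)
    cell_ids = cells[mask].astype(str).to_numpy()
    levels = pd.unique(cell_ids)
    if len(levels) < 2:
        raise ValueError("need at least 2 design cells to adjust")
    K = RelationshipMatrix("A", levels, np.eye(len(levels)))
    model = BLUPModel(y, cell_ids, [("additive", K)])
    if fixed_vc is not None:
        res = model.evaluate({"additive": fixed_vc["cell"],
                              RESIDUAL: fixed_vc[RESIDUAL]})
    else:
        res = model.fit()
    blup = res.ranef("additive")
    out = values.copy()
    out[mask] = y - blup.loc[cell_ids].to_numpy()
    return out, res


def adjust_phenotypes(pheno: pd.DataFrame, spec: AdjustmentSpec,
                      compute_volume: bool = True) -> pd.DataFrame:
    """Full adjustment: volume, then site standardization, then design BLUPs.

    Adds one ``<trait>_adj`` column per trait; original columns untouched.
    """
    df = pheno.copy()
    if compute_volume and "Vol" not in df.columns and {"DBH", "Ht"} <= set(df.columns):
        df["Vol"] = conical_volume(df["DBH"], df["Ht"])
    cells = (df[spec.site_col].astype(str) + ":" + df[spec.family_col].astype(str)
             + ":" + df[spec.replicate_col].astype(str))
    for trait in spec.traits:
        if trait not in df.columns:
            continue
        std = standardize_to_reference(df[trait], df[spec.site_col],
                                       spec.reference_site)
        adj, _ = adjust_design_effects(std, cells)
        df[f"{trait}_adj"] = adj
    return df
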