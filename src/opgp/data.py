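"""Tabular inputs for open-pollinated progeny-trial analyses.

Three tables drive everything downstream:

* a pedigree (maternal half-sib families; sires unrecorded),
* a biallelic marker matrix coded 0/1/2 (copies of the counted allele),
* a phenotype table (one row per tree).

Readers accept comma- or tab-delimited text with a header row and
normalise unknown-parent encodings to a single internal sentinel.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: internal sentinel for an unknown parent
UNKNOWN = ""

_UNKNOWN_ALIASES = {"", "0", "na", "nan", ".", "none", "null"}

PEDIGREE_COLUMNS = ["individual_id", "dam_id", "sire_id", "family_id",
                    "site_id", "replicate_id", "genotyped"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, orphans)."""


def _normalise_parent(value) -> str:
    s = "" if value is None else str(value).strip()
    return UNKNOWN if s.lower() in _UNKNOWN_ALIASES else s


def _as_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "t", "y"}


@dataclass
class PedigreeTable:
    """Validated pedigree, stored founders-first in topological order.

    ``table`` columns: individual_id, dam_id, sire_id, family_id, site_id,
    replicate_id, genotyped.  Unknown parents hold the empty-string sentinel.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _validate_pedigree(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["individual_id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def is_founder(self) -> np.ndarray:
        return ((self.table["dam_id"] == UNKNOWN)
                & (self.table["sire_id"] == UNKNOWN)).to_numpy()

    @property
    def founder_ids(self) -> np.ndarray:
        return self.ids[self.is_founder]

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.table.loc[self.table["genotyped"], "individual_id"].to_numpy()

    @property
    def family_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual_id"], self.table["family_id"]))

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.set_index("individual_id").loc[individual]
        return row["dam_id"], row["sire_id"]


def _validate_pedigree(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in PEDIGREE_COLUMNS:
        if col not in df.columns:
            df[col] = False if col == "genotyped" else ""
    df = df[PEDIGREE_COLUMNS]
    for col in ("individual_id", "family_id", "site_id", "replicate_id"):
        df[col] = df[col].astype(str).str.strip()
    for col in ("dam_id", "sire_id"):
        df[col] = df[col].map(_normalise_parent)
    if df["genotyped"].dtype != bool:
        df["genotyped"] = df["genotyped"].map(_as_bool)

    ids = df["individual_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual ids: {sorted(set(dup))[:5]}")
    known = set(ids)
    for col in ("dam_id", "sire_id"):
        missing = set(df[col]) - known - {UNKNOWN}
        if missing:
            raise PedigreeError(
                f"{col} values not present as individuals: {sorted(missing)[:5]}")

    # acyclicity + topological order (parents before offspring)
    graph = {
        r.individual_id: [p for p in (r.dam_id, r.sire_id) if p != UNKNOWN]
        for r in df.itertuples()
    }
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as err:
        raise PedigreeError(f"pedigree cycle detected: {err.args[1]}") from err

    # founders first, then the remaining topological order
    founders = [i for i in ids if not graph[i]]
    founder_set = set(founders)
    order = founders + [i for i in order if i not in founder_set]
    df = df.set_index("individual_id").loc[order].reset_index()

    # progeny inherit the maternal family label
    fam = dict(zip(df["individual_id"], df["family_id"]))
    bad = [
        r.individual_id for r in df.itertuples()
        if r.dam_id != UNKNOWN and r.family_id != fam[r.dam_id]
    ]
    if bad:
        raise PedigreeError(
            f"family_id differs from the dam's family for: {bad[:5]}")
    return df


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if "individual_id" not in df.columns:
        raise PedigreeError("pedigree file lacks an 'individual_id' column")
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    out = ped.table.copy()
    out["genotyped"] = out["genotyped"].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of counted-allele copies (0/1/2, NaN missing)."""

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray  # float, NaN = missing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.codes, initial=0) < 0 or np.nanmax(self.codes, initial=0) > 2:
                raise ValueError("genotype codes must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per marker, from non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=0)

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        g = self
        if individuals is not None:
            pos = {v: i for i, v in enumerate(g.individual_ids)}
            idx = np.array([pos[i] for i in individuals], dtype=int)
            g = GenotypeMatrix(np.asarray(individuals, dtype=object),
                               g.marker_ids, g.codes[idx], dict(g.meta))
        if markers is not None:
            pos = {v: i for i, v in enumerate(g.marker_ids)}
            idx = np.array([pos[m] for m in markers], dtype=int)
            g = GenotypeMatrix(g.individual_ids, np.asarray(markers, dtype=object),
                               g.codes[:, idx], dict(g.meta))
        return g


def apply_marker_qc(g: GenotypeMatrix, maf_min: float = 0.05,
                    call_rate_min: float = 0.90) -> GenotypeMatrix:
    """Drop markers failing the MAF / call-rate filters (strict inequalities).

    A marker is retained when min(p, 1-p) > ``maf_min`` AND its non-missing
    fraction > ``call_rate_min``.  Frequencies are computed on the data as
    given (before imputation) and recomputed on the retained set.
    """
    if not (0 <= maf_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValueError("maf_min and call_rate_min must lie in [0, 1]")
    p = g.allele_freq
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    keep = (maf > maf_min) & (g.call_rate > call_rate_min)
    keep &= ~np.isnan(maf)
    if not keep.any():
        raise ValueError("marker QC removed every marker")
    out = GenotypeMatrix(g.individual_ids, g.marker_ids[keep],
                         g.codes[:, keep], dict(g.meta))
    out.meta["qc"] = {"n_removed": int((~keep).sum()),
                      "maf_min": maf_min, "call_rate_min": call_rate_min}
    return out


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing codes by the marker mean 2*p_j (preserves column means)."""
    codes = g.codes.copy()
    missing = np.isnan(codes)
    if missing.all(axis=0).any():
        bad = g.marker_ids[missing.all(axis=0)]
        raise ValueError(
            f"markers with all entries missing (remove via QC first): {list(bad[:5])}")
    if missing.any():
        fill = np.broadcast_to(2.0 * g.allele_freq, codes.shape)
        codes[missing] = fill[missing]
    return GenotypeMatrix(g.individual_ids, g.marker_ids, codes, dict(g.meta))


def read_genotypes(path, fmt: str = "wide") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``fmt='wide'``: first column individual id, one column per marker.
    ``fmt='long'``: columns individual_id, marker_id, code (triplets).
    """
    if fmt == "wide":
        df = pd.read_csv(path, sep=None, engine="python")
        df = df.set_index(df.columns[0])
        return GenotypeMatrix(df.index.astype(str).to_numpy(),
                              df.columns.astype(str).to_numpy(),
                              df.to_numpy(dtype=float))
    if fmt == "long":
        df = pd.read_csv(path, sep=None, engine="python",
                         dtype={"individual_id": str, "marker_id": str})
        wide = df.pivot(index="individual_id", columns="marker_id", values="code")
        return GenotypeMatrix(wide.index.to_numpy(), wide.columns.to_numpy(),
                              wide.to_numpy(dtype=float))
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(g: GenotypeMatrix, path, fmt: str = "wide") -> None:
    if fmt == "wide":
        df = pd.DataFrame(g.codes, index=pd.Index(g.individual_ids, name="individual_id"),
                          columns=g.marker_ids)
        df.to_csv(path)
    elif fmt == "long":
        long = (pd.DataFrame(g.codes, index=g.individual_ids, columns=g.marker_ids)
                .stack(future_stack=True).rename("code").rename_axis(
                    ["individual_id", "marker_id"]).reset_index())
        long.dropna(subset=["code"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: one row per tree; id/design columns as strings."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "individual_id" not in df.columns:
        raise ValueError("phenotype file lacks an 'individual_id' column")
    for col in ("individual_id", "site_id", "family_id", "replicate_id"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip()
    if df["individual_id"].duplicated().any():
        raise ValueError("phenotype table has duplicated individual ids")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
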