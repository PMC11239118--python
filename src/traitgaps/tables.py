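"""Trait-table data model and pre-processing.

The table mirrors the layout of global tetrapod trait databases: one row
per species with
continuous size attributes (BodyLength_mm, BodyMass_g), binary activity-time
(Diu, Noc) and microhabitat (Fos, Ter, Aqu, Arb, Aer) dummies, taxonomy
columns (Genus, Family), and a per-cell provenance state recording whether a
value was observed, filled by the genus-level rule (taxon_imputed), filled by
the phylogenetic engine (phylo_imputed), or is still missing.

Pre-processing stages: synonym-based name harmonisation, foraging-stratum
binarisation, interquartile-range and allometric outlier screening, and
rule-based taxonomic imputation of binary attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACTIVITY_COLS",
    "BINARY_COLS",
    "CONTINUOUS_COLS",
    "MICROHABITAT_COLS",
    "TraitTable",
    "binarize_stratum_usage",
    "flag_outliers_allometric",
    "flag_outliers_iqr",
    "resolve_names",
    "taxonomic_impute",
    "unique_synonyms",
]

PROV_OBSERVED = "observed"
PROV_TAXON = "taxon_imputed"
PROV_PHYLO = "phylo_imputed"
PROV_MISSING = "missing"
PROVENANCE_STATES = (PROV_OBSERVED, PROV_TAXON, PROV_PHYLO, PROV_MISSING)

CONTINUOUS_COLS = ["BodyLength_mm", "BodyMass_g"]
ACTIVITY_COLS = ["Diu", "Noc"]
MICROHABITAT_COLS = ["Fos", "Ter", "Aqu", "Arb", "Aer"]
BINARY_COLS = ACTIVITY_COLS + MICROHABITAT_COLS + ["Assessed"]
TAXONOMY_COLS = ["Genus", "Family"]


@dataclass
class TraitTable:
    """Species trait matrix plus a parallel provenance matrix.

    ``data`` is indexed by species id and holds taxonomy columns and trait
    columns; ``provenance`` shares the index and holds one state per trait
    cell. A cell is NaN exactly when its provenance is ``missing``.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame

    # -- construction -------------------------------------------------------

    @classmethod
    def from_complete(cls, data: pd.DataFrame) -> "TraitTable":
        """Wrap a fully observed table (no missing trait cells)."""
        data = data.copy()
        data.index.name = "species"
        traits = [c for c in data.columns if c not in TAXONOMY_COLS]
        prov = pd.DataFrame(PROV_OBSERVED, index=data.index, columns=traits)
        prov[data[traits].isna()] = PROV_MISSING
        table = cls(data, prov)
        table.validate()
        return table

    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in TAXONOMY_COLS]

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in CONTINUOUS_COLS if c in self.data.columns]

    @property
    def binary_columns(self) -> list[str]:
        return [c for c in BINARY_COLS if c in self.data.columns]

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy(), self.provenance.copy())

    # -- checks -------------------------------------------------------------

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("species ids must be unique")
        if list(self.provenance.index) != list(self.data.index):
            raise ValueError("data and provenance indices differ")
        for col in self.continuous_columns:
            vals = self.data[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be strictly positive")
        for col in self.binary_columns:
            vals = self.data[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"{col} must be binary")
        for col in self.trait_columns:
            isna = self.data[col].isna()
            is_missing = self.provenance[col] == PROV_MISSING
            if not (isna == is_missing).all():
                raise ValueError(f"provenance of {col} inconsistent with nulls")

    def observed_mask(self, col: str, include_taxon_imputed: bool = True):
        """Boolean mask of cells usable as ground truth for training."""
        states = {PROV_OBSERVED} | ({PROV_TAXON} if include_taxon_imputed else set())
        return self.provenance[col].isin(states)

    # -- serialisation ------------------------------------------------------

    def to_csv(self, path) -> None:
        """One CSV: trait columns plus parallel ``<col>_prov`` columns."""
        out = self.data.copy()
        for col in self.trait_columns:
            out[f"{col}_prov"] = self.provenance[col]
        out.to_csv(path, index_label="species")

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        raw = pd.read_csv(path, index_col="species")
        prov_cols = [c for c in raw.columns if c.endswith("_prov")]
        data = raw[[c for c in raw.columns if c not in prov_cols]]
        prov = raw[prov_cols].rename(columns=lambda c: c[: -len("_prov")])
        table = cls(data, prov[[c for c in data.columns if c not in TAXONOMY_COLS]])
        table.validate()
        return table


# ---------------------------------------------------------------------------
# taxonomic harmonisation


def unique_synonyms(synonyms: pd.DataFrame) -> pd.Series:
    """Map synonym -> valid name, restricted to unique synonyms (a binomial
    applied to exactly one valid name)."""
    counts = synonyms.groupby("name")["valid_name"].nunique()
    uniq = counts[counts == 1].index
    sub = synonyms[synonyms["name"].isin(uniq)]
    return sub.drop_duplicates("name").set_index("name")["valid_name"]


def resolve_names(
    records: pd.DataFrame | list[str],
    reference: list[str],
    synonyms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Match external record names against a reference species list.

    Steps, applied in order per record: (1) exact match; (2) match after
    updating the record name through unique synonyms; (3) match records
    against reference ids updated through unique synonyms; (4) unresolved,
    flagged for manual review (step 0 in the report). Only unique synonyms
    are ever applied automatically. Records resolving to an already-matched
    reference id are flagged as duplicate entries so each data entry is made
    only once.
    """
    if isinstance(records, pd.DataFrame):
        names = records["name"].tolist()
    else:
        names = list(records)
    ref = pd.Index(reference)
    if ref.has_duplicates:
        raise ValueError("reference ids must be unique")
    syn = (
        unique_synonyms(synonyms)
        if synonyms is not None and len(synonyms)
        else pd.Series(dtype=object)
    )
    # step 3 lookup: a reference id whose unique synonym maps it to a newer
    # name matches records carrying that newer name
    ref_updated = {}
    for rid in ref:
        if rid in syn.index and syn[rid] not in ref:
            ref_updated.setdefault(syn[rid], rid)

    seen: set[str] = set()
    rows = []
    for name in names:
        matched, step = None, 0
        if name in ref:
            matched, step = name, 1
        elif name in syn.index and syn[name] in ref:
            matched, step = syn[name], 2
        elif name in ref_updated:
            matched, step = ref_updated[name], 3
        dup = matched is not None and matched in seen
        if matched is not None:
            seen.add(matched)
        rows.append(
            {"record": name, "matched_id": matched, "step": step, "duplicate": dup}
        )
    return pd.DataFrame(rows)


def binarize_stratum_usage(
    usage: pd.DataFrame | np.ndarray, threshold: float = 0.30
):
    """Relative foraging-stratum usage -> binary microhabitat (1 iff usage
    >= threshold; the 30% boundary is inclusive)."""
    arr = np.asarray(usage, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("usages must lie in [0, 1]")
    out = (arr >= threshold).astype(int)
    if isinstance(usage, pd.DataFrame):
        return pd.DataFrame(out, index=usage.index, columns=usage.columns)
    if isinstance(usage, pd.Series):
        return pd.Series(out, index=usage.index)
    return out


# ---------------------------------------------------------------------------
# outlier screening


def flag_outliers_iqr(values, k: float = 1.5) -> np.ndarray:
    """Tukey fences on log10 values: flag x with log10(x) outside
    [q25 - k*IQR, q75 + k*IQR]. Quartiles use linear interpolation between
    order statistics (numpy's default convention). Fewer than 4 non-null
    values -> no flags, with a warning."""
    arr = np.asarray(values, dtype=float)
    flags = np.zeros(arr.shape, dtype=bool)
    ok = ~np.isnan(arr)
    if (arr[ok] <= 0).any():
        raise ValueError("values must be strictly positive")
    if ok.sum() < 4:
        warnings.warn("fewer than 4 values: outlier screen skipped")
        return flags
    logv = np.log10(arr[ok])
    q25, q75 = np.quantile(logv, [0.25, 0.75])
    iqr = q75 - q25
    lo, hi = q25 - k * iqr, q75 + k * iqr
    flags[ok] = (logv < lo) | (logv > hi)
    return flags


def flag_outliers_allometric(
    lengths,
    masses,
    groups=None,
    z_cut: float = 3.5,
    min_group: int = 5,
) -> pd.DataFrame:
    """Flag species deviating from the within-group allometry of log10 mass
    on log10 length.

    The line is fit robustly (Theil–Sen) per group, residuals are scaled by
    1.4826 * MAD, and |z| > z_cut is flagged. Groups with fewer than
    ``min_group`` complete pairs are skipped with a warning, as is any group
    whose residual MAD is zero (collinear data).
    """
    lengths = np.asarray(lengths, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = len(lengths)
    groups = np.asarray(["all"] * n if groups is None else groups)
    flags = np.zeros(n, dtype=bool)
    zres = np.full(n, np.nan)
    complete = ~np.isnan(lengths) & ~np.isnan(masses)
    if np.any((lengths[complete] <= 0) | (masses[complete] <= 0)):
        raise ValueError("lengths and masses must be strictly positive")
    for g in np.unique(groups):
        idx = np.where((groups == g) & complete)[0]
        if len(idx) < min_group:
            warnings.warn(f"group {g!r}: fewer than {min_group} pairs, skipped")
            continue
        x = np.log10(lengths[idx])
        y = np.log10(masses[idx])
        if np.allclose(x, x[0]):
            warnings.warn(f"group {g!r}: no length variation, skipped")
            continue
        slope, intercept, *_ = stats.theilslopes(y, x)
        resid = y - (intercept + slope * x)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            warnings.warn(f"group {g!r}: zero residual MAD, skipped")
            continue
        z = resid / (1.4826 * mad)
        zres[idx] = z
        flags[idx] = np.abs(z) > z_cut
    return pd.DataFrame({"flagged": flags, "std_residual": zres})


# ---------------------------------------------------------------------------
# taxonomic imputation


def taxonomic_impute(
    table: TraitTable,
    threshold: float = 0.70,
    overrides: list[tuple[str, str, int]] = (),
    denominator: str = "all",
) -> TraitTable:
    """Genus-level rule-based filling of binary attributes.

    For each genus and each binary attribute, if the share of the genus's
    species observed to have the attribute reaches ``threshold`` (default
    70%), species missing that attribute get value 1 with provenance
    ``taxon_imputed``. The denominator is all species in the genus
    (``denominator="all"``); set ``"observed"`` to divide by observed species
    only. Fixed-group ``overrides`` of (group, attribute, value) — matching
    Genus or Family labels — are applied first. Continuous attributes are
    never taxon-imputed, and observed cells are never overwritten.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if denominator not in ("all", "observed"):
        raise ValueError("denominator must be 'all' or 'observed'")
    out = table.copy()
    bin_cols = out.binary_columns
    for group, attr, value in overrides:
        if attr not in bin_cols:
            warnings.warn(f"override attribute {attr!r} not binary, skipped")
            continue
        in_group = (out.data.get("Genus") == group) | (out.data.get("Family") == group)
        if not in_group.any():
            warnings.warn(f"override group {group!r} not found, skipped")
            continue
        fill = in_group & (out.provenance[attr] == PROV_MISSING)
        out.data.loc[fill, attr] = value
        out.provenance.loc[fill, attr] = PROV_TAXON
    if "Genus" not in out.data.columns:
        return out
    for genus, idx in out.data.groupby("Genus").groups.items():
        size = len(idx)
        for attr in bin_cols:
            observed = out.provenance.loc[idx, attr] == PROV_OBSERVED
            npos = int((out.data.loc[idx, attr][observed] == 1).sum())
            denom = size if denominator == "all" else int(observed.sum())
            if denom == 0 or npos / denom < threshold:
                continue
            fill = out.provenance.loc[idx, attr] == PROV_MISSING
            fill_idx = fill[fill].index
            out.data.loc[fill_idx, attr] = 1
            out.provenance.loc[fill_idx, attr] = PROV_TAXON
    return out
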