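"""How gap filling shifts clade- and assemblage-level attribute properties.

Continuous attributes are summarised by the geometric mean (robust to the
right-skew of body sizes); binary activity-time and microhabitat dummies are
first collapsed into two 0–1 scores — nocturnality (0 strictly diurnal,
0.5 cathemeral, 1 strictly nocturnal) and verticality (0 strictly fossorial
up to 1 strictly arboreal/aerial) — and summarised by their mean. The shift
a gap-filling step induces is the relative change
``1 − property(obs+imputed) / property(obs)``; because that printed form is
negative for increases, reports also carry the negated convention
(``ratio − 1``) so either reading is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "attribute_property",
    "change_report",
    "geometric_mean",
    "kruskal_wallis",
    "nocturnality_score",
    "per_assemblage_property",
    "rank_correlation",
    "relative_change",
    "verticality_score",
]

#: Vertical-stratum level of each microhabitat category; a species' score is
#: the mean level over its categories, which reproduces every anchor:
#: fossorial 0, fossorial+terrestrial 0.25, terrestrial or aquatic 0.5,
#: terrestrial+arboreal 0.75, arboreal or aerial 1.
VERTICALITY_LEVELS = {"Fos": 0.0, "Ter": 0.5, "Aqu": 0.5, "Arb": 1.0, "Aer": 1.0}
NOCTURNALITY_LEVELS = {"Diu": 0.0, "Noc": 1.0}


def _score(cols, levels, names):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    mat = np.stack(arrs, axis=-1)
    lev = np.array([levels[n] for n in names])
    total = mat.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("every species needs at least one category set to 1")
    score = (mat * lev).sum(axis=-1) / total
    return float(score) if score.ndim == 0 else score


def verticality_score(fos, ter, aqu, arb, aer):
    """Vertical habitat-use score in [0, 1]; accepts scalars or arrays."""
    return _score((fos, ter, aqu, arb, aer), VERTICALITY_LEVELS,
                  ("Fos", "Ter", "Aqu", "Arb", "Aer"))


def nocturnality_score(diu, noc):
    """Activity-time score: 0 diurnal, 0.5 cathemeral, 1 nocturnal."""
    return _score((diu, noc), NOCTURNALITY_LEVELS, ("Diu", "Noc"))


def geometric_mean(values) -> float:
    """10 ** mean(log10 values); all values must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(10.0 ** np.mean(np.log10(arr)))


def attribute_property(values, kind: str) -> float:
    """Clade/assemblage summary: geometric mean for continuous attributes,
    arithmetic mean for verticality/nocturnality scores."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if kind == "continuous":
        return geometric_mean(arr)
    if kind == "score":
        return float(arr.mean())
    raise ValueError(f"kind must be 'continuous' or 'score', got {kind!r}")


def relative_change(prop_obs: float, prop_comb: float) -> float:
    """1 − prop_comb / prop_obs (negative when gap filling raises the
    property)."""
    if prop_obs == 0:
        raise ValueError("relative change undefined for prop_obs = 0")
    return 1.0 - prop_comb / prop_obs


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def rank_correlation(x, y) -> float:
    """Spearman correlation (product-moment correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# scores from a trait table


def _block_scores(table, score: str, which: str) -> pd.Series:
    """Per-species score restricted to species whose activity (or
    microhabitat) block has the requested provenance status."""
    from .tables import ACTIVITY_COLS, MICROHABITAT_COLS, PROV_MISSING, PROV_OBSERVED

    cols = ACTIVITY_COLS if score == "nocturnality" else MICROHABITAT_COLS
    prov = table.provenance[cols]
    if which == "obs":
        keep = (prov == PROV_OBSERVED).all(axis=1)
    else:  # anything with values, observed or imputed
        keep = (prov != PROV_MISSING).all(axis=1)
    sub = table.data.loc[keep, cols]
    if sub.empty:
        return pd.Series(dtype=float)
    fn = nocturnality_score if score == "nocturnality" else verticality_score
    return pd.Series(fn(*(sub[c].to_numpy() for c in cols)), index=sub.index)


SCORE_KINDS = {
    "BodyLength_mm": "continuous",
    "BodyMass_g": "continuous",
    "nocturnality": "score",
    "verticality": "score",
}


def _attribute_values(table, attribute: str, which: str) -> pd.Series:
    from .tables import PROV_MISSING, PROV_OBSERVED

    if attribute in ("nocturnality", "verticality"):
        return _block_scores(table, attribute, which)
    prov = table.provenance[attribute]
    keep = prov == PROV_OBSERVED if which == "obs" else prov != PROV_MISSING
    return table.data.loc[keep, attribute].astype(float)


def change_report(
    table,
    groupby: str = "Genus",
    attributes: tuple[str, ...] = tuple(SCORE_KINDS),
) -> pd.DataFrame:
    """Per-taxon attribute properties before and after gap filling.

    ``table`` should already contain imputed values (provenance
    ``taxon_imputed`` / ``phylo_imputed``). For each taxon and attribute the
    report gives the observed-only property, the combined property, both
    relative-change conventions, and the direction of the shift.
    """
    rows = []
    for taxon, idx in table.data.groupby(groupby).groups.items():
        sub = _subset(table, idx)
        for attr in attributes:
            kind = SCORE_KINDS[attr]
            obs = _attribute_values(sub, attr, "obs")
            comb = _attribute_values(sub, attr, "comb")
            if len(obs) == 0 or len(comb) == 0:
                continue
            p_obs = attribute_property(obs, kind)
            p_comb = attribute_property(comb, kind)
            # a zero observed-only property (e.g. every observed species
            # strictly diurnal) leaves the ratio undefined
            rc = relative_change(p_obs, p_comb) if p_obs != 0 else np.nan
            rows.append(
                {
                    groupby.lower(): taxon,
                    "attribute": attr,
                    "property_obs": p_obs,
                    "property_comb": p_comb,
                    "n_obs": len(obs),
                    "n_imputed": len(comb) - len(obs),
                    "relative_change": rc,
                    "relative_change_increase": -rc if not np.isnan(rc) else np.nan,
                    "direction": (
                        "none" if p_comb == p_obs
                        else "increase" if p_comb > p_obs else "decrease"
                    ),
                }
            )
    return pd.DataFrame(rows)


def _subset(table, idx):
    from .tables import TraitTable

    return TraitTable(table.data.loc[idx], table.provenance.loc[idx])


def per_assemblage_property(
    table,
    membership: pd.DataFrame,
    attribute: str,
    mode: str = "comb",
    log_continuous: bool = True,
) -> pd.DataFrame:
    """Per grid cell: completeness (fraction of member species with observed
    values for the attribute) and the unweighted mean attribute value over
    member species under ``mode`` ('obs' or 'comb'). Continuous attributes
    are log10-transformed before averaging (as for map summaries); cells
    with no members are reported empty (NaN)."""
    from .tables import PROV_MISSING

    unknown = membership.index.difference(table.data.index)
    if len(unknown):
        raise ValueError(f"species in membership absent from table: {sorted(unknown)}")
    if mode not in ("obs", "comb"):
        raise ValueError("mode must be 'obs' or 'comb'")
    values = _attribute_values(table, attribute, mode)
    if SCORE_KINDS[attribute] == "continuous" and log_continuous:
        values = np.log10(values)
    observed = _attribute_values(table, attribute, "obs")
    rows = []
    for cell in membership.columns:
        members = membership.index[membership[cell] == 1]
        if len(members) == 0:
            rows.append({"cell": cell, "n_species": 0,
                         "completeness": np.nan, "average": np.nan})
            continue
        have = values.index.intersection(members)
        rows.append(
            {
                "cell": cell,
                "n_species": len(members),
                "completeness": len(observed.index.intersection(members)) / len(members),
                "average": float(values.loc[have].mean()) if len(have) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cell")
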