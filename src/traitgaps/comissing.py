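"""Shared-missingness analysis via the checkerboard C-score.

Gaps in trait knowledge tend to cluster: a poorly known species is often
missing its body size, activity time and threat assessment all at once. To
quantify this, missing-data indicators for each attribute block form a
binary presence-absence matrix (PAM; rows = attributes, columns = species of
one genus or family), and every attribute pair is scored with the
checkerboard C-score C = (R_i - S)(R_j - S), where R are row sums and S the
number of species missing both attributes. Low C relative to a null that
fixes row sums but treats species as equiprobable means gaps co-occur more
than chance (aggregated); high C means they avoid each other (segregated).
Effect sizes are standardised against the null distribution (SES) and taxa
are ranked by their median SES across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PROV_OBSERVED, TraitTable

__all__ = [
    "CScoreReport",
    "analyze_comissingness",
    "build_missing_pam",
    "classify_and_aggregate",
    "cscore_pair",
    "null_distribution",
    "ses_and_p",
]

#: Default attribute blocks whose missingness indicators form the PAM rows.
DEFAULT_BLOCKS = ("body_length", "body_mass", "activity", "microhabitat",
                  "assessed")

_BLOCK_COLS = {
    "body_length": ("BodyLength_mm",),
    "body_mass": ("BodyMass_g",),
    "activity": ("Diu", "Noc"),
    "microhabitat": ("Fos", "Ter", "Aqu", "Arb", "Aer"),
    "assessed": ("Assessed",),
}


def build_missing_pam(
    table: TraitTable,
    attributes: tuple[str, ...] = DEFAULT_BLOCKS,
    taxon: str = "Genus",
    count_imputed_as_missing: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-taxon missing-attribute PAMs (rows = attributes, columns =
    species), for every taxon with at least two species.

    An entry is 1 when the attribute block lacks observed data for that
    species. By default cells later filled by taxonomic or phylogenetic
    imputation still count as missing, because the analysis concerns gaps in
    the observed record; set ``count_imputed_as_missing=False`` to treat
    imputed cells as present.
    """
    for attr in attributes:
        if attr not in _BLOCK_COLS:
            raise ValueError(f"unknown attribute {attr!r}; known: {sorted(_BLOCK_COLS)}")
    indicators = {}
    for attr in attributes:
        cols = [c for c in _BLOCK_COLS[attr] if c in table.data.columns]
        if not cols:
            raise ValueError(f"attribute {attr!r} has no columns in the table")
        prov = table.provenance[cols]
        if count_imputed_as_missing:
            miss = (prov != PROV_OBSERVED).all(axis=1)
        else:
            miss = (prov == "missing").all(axis=1)
        indicators[attr] = miss.astype(int)
    indicator_df = pd.DataFrame(indicators).T  # attributes x species
    pams = {}
    for tax, idx in table.data.groupby(taxon).groups.items():
        if len(idx) < 2:
            continue
        pams[tax] = indicator_df[idx]
    return pams


def cscore_pair(row_i, row_j) -> float:
    """Checkerboard score (R_i - S)(R_j - S) for one attribute pair."""
    ri = np.asarray(row_i, dtype=int)
    rj = np.asarray(row_j, dtype=int)
    if ri.shape != rj.shape:
        raise ValueError("rows must have equal length")
    s = int(np.sum(ri & rj))
    return float((ri.sum() - s) * (rj.sum() - s))


def null_distribution(
    pam: pd.DataFrame,
    pair: tuple,
    iterations: int = 10_000,
    burn_in: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Null C-score samples under fixed row sums and equiprobable species.

    Each sample redraws, for each of the two rows, its R ones uniformly
    without replacement over the species. Draws are independent, so the
    burn-in only discards the first ``burn_in`` samples (kept for interface
    fidelity with sequential null-model workflows); ``iterations`` retained
    samples are returned.
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    i, j = pair
    ri = int(pam.loc[i].sum())
    rj = int(pam.loc[j].sum())
    n = pam.shape[1]
    if ri > n or rj > n:
        raise ValueError("row sum exceeds the number of species: impossible matrix")
    rng = np.random.default_rng(seed)
    total = iterations + burn_in
    s = _null_overlaps(n, ri, rj, total, rng)
    c = (ri - s) * (rj - s)
    return c[burn_in:].astype(float)


def _null_overlaps(n, ri, rj, draws, rng):
    """Vectorised overlap counts S for `draws` independent fixed-row-sum
    redraws of two rows over n columns."""
    # top-R indices of random keys give a uniform R-subset per draw
    keys_i = rng.random((draws, n))
    keys_j = rng.random((draws, n))
    sel_i = np.argpartition(keys_i, ri - 1, axis=1)[:, :ri] if ri else None
    sel_j = np.argpartition(keys_j, rj - 1, axis=1)[:, :rj] if rj else None
    if ri == 0 or rj == 0:
        return np.zeros(draws, dtype=int)
    occ_i = np.zeros((draws, n), dtype=bool)
    occ_i[np.arange(draws)[:, None], sel_i] = True
    occ_j = np.zeros((draws, n), dtype=bool)
    occ_j[np.arange(draws)[:, None], sel_j] = True
    return (occ_i & occ_j).sum(axis=1)


def ses_and_p(observed: float, null_samples) -> tuple[float, float]:
    """Standardised effect size and two-tailed p-value of an observed
    C-score against its null distribution.

    SES = (observed - null mean) / null sd. The p-value is rank-based with
    the observed value counted as one extra sample (add-one correction):
    p = 2 * min(P(null <= obs), P(null >= obs)), capped at 1. A degenerate
    null (sd = 0) gives SES = NaN with p from the same counting rule.
    """
    null = np.asarray(null_samples, dtype=float)
    if len(null) < 100:
        raise ValueError("need at least 100 null samples")
    mean = null.mean()
    sd = null.std(ddof=1)
    n = len(null)
    p_low = (np.sum(null <= observed) + 1) / (n + 1)
    p_high = (np.sum(null >= observed) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    ses = (observed - mean) / sd if sd > 0 else np.nan
    return float(ses), float(p)


@dataclass
class CScoreReport:
    """Pairwise C-score results plus per-taxon median-SES aggregation.

    ``pairs`` columns: taxon, pair, observed_c, null_mean, null_sd, ses, p,
    pattern. ``taxa`` carries the per-taxon median SES across all pairs and
    across pairs involving the focal attribute (threat-status analogue).
    """

    pairs: pd.DataFrame
    taxa: pd.DataFrame


def classify_and_aggregate(
    pair_rows: pd.DataFrame,
    focal: str = "assessed",
    alpha: float = 0.05,
) -> CScoreReport:
    """Classify each pair (aggregated: SES < 0 and p < alpha; segregated:
    SES > 0 and p < alpha; else random) and aggregate per taxon: the median
    SES across all pairs and across pairs involving ``focal``."""
    rows = pair_rows.copy()

    def _cls(r):
        if np.isnan(r["ses"]) or r["p"] >= alpha:
            return "random"
        return "aggregated" if r["ses"] < 0 else "segregated"

    rows["pattern"] = rows.apply(_cls, axis=1)
    taxa = []
    for taxon, grp in rows.groupby("taxon"):
        with_focal = grp[grp["pair"].map(lambda pr: focal in pr)]
        taxa.append({
            "taxon": taxon,
            "median_ses": float(grp["ses"].median()),
            "median_ses_focal": (
                float(with_focal["ses"].median()) if len(with_focal) else np.nan
            ),
            "n_pairs": len(grp),
        })
    taxa_df = pd.DataFrame(taxa).sort_values("median_ses").reset_index(drop=True)
    return CScoreReport(rows, taxa_df)


def analyze_comissingness(
    table: TraitTable,
    attributes: tuple[str, ...] = DEFAULT_BLOCKS,
    taxon: str = "Genus",
    iterations: int = 10_000,
    burn_in: int = 500,
    seed: int = 0,
    focal: str = "assessed",
    alpha: float = 0.05,
) -> CScoreReport:
    """End-to-end shared-missingness analysis: PAM per taxon, C-score and
    null SES per attribute pair, classification and per-taxon medians."""
    pams = build_missing_pam(table, attributes, taxon)
    rows = []
    rng = np.random.default_rng(seed)
    for tax, pam in pams.items():
        attrs = list(pam.index)
        for a in range(len(attrs)):
            for b in range(a + 1, len(attrs)):
                pair = (attrs[a], attrs[b])
                obs = cscore_pair(pam.loc[pair[0]], pam.loc[pair[1]])
                null = null_distribution(
                    pam, pair, iterations, burn_in,
                    seed=int(rng.integers(2**31)),
                )
                ses, p = ses_and_p(obs, null)
                rows.append({
                    "taxon": tax, "pair": pair, "observed_c": obs,
                    "null_mean": float(null.mean()),
                    "null_sd": float(null.std(ddof=1)),
                    "ses": ses, "p": p,
                })
    return classify_and_aggregate(pd.DataFrame(rows), focal=focal, alpha=alpha)
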