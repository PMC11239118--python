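"""Synthetic clades with the statistical structure trait gap-filling assumes.

This module generates everything the downstream analyses consume: an
ultrametric phylogeny, a nested genus/family taxonomy, continuous body-size
traits evolved by Brownian motion with an allometric length--mass relation,
binary activity-time and microhabitat traits from a threshold (liability)
model, contiguous-block geographic ranges, and missingness imposed under
MCAR, MAR or MNAR mechanisms with an optional shared "poorly known species"
latent factor that induces co-missing attributes.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .tables import (
    ACTIVITY_COLS,
    MICROHABITAT_COLS,
    PROV_MISSING,
    PROV_OBSERVED,
    TraitTable,
)
from .change import nocturnality_score, verticality_score

__all__ = [
    "ATTRIBUTE_BLOCKS",
    "AttributeMissingness",
    "MissingnessSpec",
    "SimulatedClade",
    "assign_taxonomy",
    "build_clade",
    "impose_missingness",
    "perturb_branch_lengths",
    "simulate_binary_traits",
    "simulate_continuous_traits",
    "simulate_ranges",
    "simulate_tree",
]

#: Attribute blocks as they appear in real trait databases: a data source
#: reports (or fails to report) a whole category set, not a single dummy.
ATTRIBUTE_BLOCKS: dict[str, tuple[str, ...]] = {
    "body_length": ("BodyLength_mm",),
    "body_mass": ("BodyMass_g",),
    "activity": tuple(ACTIVITY_COLS),
    "microhabitat": tuple(MICROHABITAT_COLS),
    "assessed": ("Assessed",),
}


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    seed: int = 0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
) -> dendropy.Tree:
    """Simulate a rooted, bifurcating, ultrametric tree with root depth 1.

    Parameters
    ----------
    n_tips:
        Number of extant tips (>= 2).
    model:
        ``"yule"`` (pure birth) or ``"birth-death"``. Under birth--death,
        extinct lineages are pruned so exactly ``n_tips`` extant tips remain
        and the tree is re-ultrametrised by construction.
    seed:
        Seed for the random stream; identical inputs give byte-identical
        Newick output.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    if model not in ("yule", "birth-death"):
        raise ValueError(f"model must be 'yule' or 'birth-death', got {model!r}")
    mu = death_rate if model == "birth-death" else 0.0
    if mu >= birth_rate:
        raise ValueError("death_rate must be smaller than birth_rate")
    rng = np.random.default_rng(seed)

    while True:  # retry on total extinction (birth-death only)
        # each lineage: (parent_index, birth_time); nodes stored as records
        nodes: list[dict] = [{"parent": None, "time": 0.0, "children": []}]
        active = [0]
        t = 0.0
        ok = True
        while len(active) < n_tips:
            k = len(active)
            t += rng.exponential(1.0 / ((birth_rate + mu) * k))
            idx = active[rng.integers(k)]
            if mu > 0 and rng.random() < mu / (birth_rate + mu):
                active.remove(idx)
                nodes[idx]["dead"] = t
                if not active:
                    ok = False
                    break
                continue
            # speciation: idx becomes internal at time t with two children
            nodes[idx]["split"] = t
            for _ in range(2):
                nodes.append({"parent": idx, "time": t, "children": []})
                nodes[idx]["children"].append(len(nodes) - 1)
                active.append(len(nodes) - 1)
            active.remove(idx)
        if ok:
            break

    # extend extant tips to the time of the next (unrealised) event
    t_end = t + rng.exponential(1.0 / ((birth_rate + mu) * n_tips))
    tree = _records_to_tree(nodes, active, t_end)
    _normalise_depth(tree)
    _label_tips(tree)
    return tree


def _records_to_tree(nodes, active, t_end):
    """Build a dendropy tree from simulation records, pruning extinct lines."""
    active = set(active)

    def build(idx):
        rec = nodes[idx]
        if rec["children"]:
            kids = [build(c) for c in rec["children"]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:  # suppress unifurcation from an extinct sister
                child, clen = kids[0]
                return child, clen + (rec["split"] - rec["time"])
            node = dendropy.Node()
            for child, clen in kids:
                child.edge.length = clen
                node.add_child(child)
            return node, rec["split"] - rec["time"]
        if idx in active:
            return dendropy.Node(), t_end - rec["time"]
        return None  # extinct tip

    root, _ = build(0)
    # the surviving root may itself be a late node; its edge length is dropped
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    root.edge.length = None
    return tree


def _normalise_depth(tree):
    depth = tree.max_distance_from_root()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth


def _label_tips(tree):
    ns = dendropy.TaxonNamespace()
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        taxon = ns.new_taxon(f"sp{i:04d}")
        leaf.taxon = taxon
    tree.taxon_namespace = ns


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in stable (preorder leaf) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def perturb_branch_lengths(
    tree: dendropy.Tree, sd: float = 0.2, seed: int = 0
) -> dendropy.Tree:
    """Jitter edge lengths by lognormal noise, emulating phylogenetic
    uncertainty across a posterior tree set. Topology and tip labels are
    preserved; the result is generally not ultrametric (the covariance
    construction does not require it)."""
    rng = np.random.default_rng(seed)
    clone = tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.lognormal(0.0, sd))
    return clone


# ---------------------------------------------------------------------------
# taxonomy


def assign_taxonomy(
    tree: dendropy.Tree, n_families: int, n_genera: int
) -> pd.DataFrame:
    """Cut an ultrametric tree at two depths to get monophyletic genera
    nested within monophyletic families.

    Returns a DataFrame indexed by species id with columns Genus, Family.
    """
    tips = tip_labels(tree)
    n = len(tips)
    if not (1 <= n_families <= n_genera <= n):
        raise ValueError(
            f"need 1 <= n_families <= n_genera <= n_tips={n}; "
            f"got n_families={n_families}, n_genera={n_genera}"
        )
    fam = _cut_groups(tree, n_families)
    gen = _cut_groups(tree, n_genera)
    fam_name = {}
    gen_name = {}
    fam_of_gen = {}
    rows = {}
    for sp in tips:
        f = fam[sp]
        g = gen[sp]
        if f not in fam_name:
            fam_name[f] = f"Fam{len(fam_name) + 1:02d}"
        if g not in gen_name:
            gen_name[g] = f"Gen{len(gen_name) + 1:03d}"
            fam_of_gen[g] = f
        if fam_of_gen[g] != f:  # cannot happen with nested cuts; guard anyway
            raise RuntimeError("genus spans two families")
        rows[sp] = (gen_name[g], fam_name[f])
    return pd.DataFrame.from_dict(rows, orient="index", columns=["Genus", "Family"])


def _cut_groups(tree, g):
    """Map tip label -> group index for a cut yielding exactly g groups."""
    tips = tip_labels(tree)
    if g == 1:
        return {sp: 0 for sp in tips}
    n = len(tips)
    depths = sorted(
        nd.distance_from_root() for nd in tree.preorder_internal_node_iter()
    )
    # number of lineages crossing depth t is 1 + #{internal nodes shallower
    # than t}; exactly g groups need a depth between the (g-1)th and gth
    # internal split
    upper = depths[g - 1] if g - 1 < len(depths) else 1.0
    lower = depths[g - 2] if g >= 2 else 0.0
    if not upper > lower:
        achievable = 1 + sum(1 for d in depths if d < upper)
        raise ValueError(
            f"cannot cut exactly {g} monophyletic groups on this topology "
            f"(tied split depths); achievable counts near {g}: {achievable}, "
            f"maximum {n}"
        )
    cut = 0.5 * (lower + upper)
    groups = {}
    idx = 0
    for nd in tree.preorder_node_iter():
        d = nd.distance_from_root()
        pd_ = d - (nd.edge.length or 0.0)
        if d >= cut > pd_:
            for leaf in nd.leaf_iter():
                groups[leaf.taxon.label] = idx
            idx += 1
    assert idx == g
    return groups


# ---------------------------------------------------------------------------
# trait simulation


def _brownian(tree, sigma, root_state, rng):
    """One Brownian-motion realisation over the tree; returns {tip: value}."""
    values = {}
    state = {id(tree.seed_node): root_state}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent = state[id(nd.parent_node)]
        step = rng.normal(0.0, sigma * math.sqrt(nd.edge.length))
        state[id(nd)] = parent + step
        if nd.is_leaf():
            values[nd.taxon.label] = state[id(nd)]
    return values


def simulate_continuous_traits(
    tree: dendropy.Tree,
    sigma_bm: float = 1.0,
    allometry: tuple[float, float, float] = (-4.0, 3.0, 0.05),
    root_state: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Brownian-motion log10 body length plus allometric log10 body mass.

    ``allometry = (a, b, s)`` gives log10 mass = a + b * log10 length +
    Normal(0, s). Returns columns ``log10_length``, ``log10_mass`` indexed
    by species.
    """
    a, b, s = allometry
    if sigma_bm <= 0:
        raise ValueError("sigma_bm must be > 0")
    if s < 0:
        raise ValueError("allometric residual sd must be >= 0")
    rng = np.random.default_rng(seed)
    length = _brownian(tree, sigma_bm, root_state, rng)
    tips = tip_labels(tree)
    loglen = np.array([length[sp] for sp in tips])
    logmass = a + b * loglen + rng.normal(0.0, s, size=len(tips)) if s > 0 else a + b * loglen
    return pd.DataFrame(
        {"log10_length": loglen, "log10_mass": logmass}, index=pd.Index(tips, name="species")
    )


def simulate_binary_traits(
    tree: dendropy.Tree,
    attributes: list[str],
    liability_sigma: float = 1.0,
    thresholds: dict[str, float] | None = None,
    seed: int = 0,
    repair: bool = True,
) -> pd.DataFrame:
    """Threshold-model binary traits: attribute = 1 iff a Brownian liability
    exceeds its threshold. With ``repair`` on, all-zero microhabitat rows and
    all-zero activity rows are fixed by switching on the category whose
    liability sits closest to (least below) its threshold, because the real
    schema guarantees every species at least one category."""
    if not attributes:
        raise ValueError("attribute list must be non-empty")
    thresholds = dict(thresholds or {})
    rng = np.random.default_rng(seed)
    tips = tip_labels(tree)
    liab = pd.DataFrame(index=pd.Index(tips, name="species"), dtype=float)
    out = pd.DataFrame(index=pd.Index(tips, name="species"), dtype=int)
    for attr in attributes:
        thr = thresholds.get(attr, 0.0)
        values = _brownian(tree, liability_sigma, 0.0, rng)
        liab[attr] = [values[sp] for sp in tips]
        if thr == -math.inf:
            out[attr] = 1
        elif thr == math.inf:
            out[attr] = 0
        else:
            out[attr] = (liab[attr] > thr).astype(int)
    if repair:
        for block in (MICROHABITAT_COLS, ACTIVITY_COLS):
            cols = [c for c in block if c in out.columns]
            if not cols:
                continue
            margins = liab[cols].to_numpy() - np.array(
                [thresholds.get(c, 0.0) for c in cols]
            )
            zero = out[cols].sum(axis=1).to_numpy() == 0
            best = np.argmax(margins, axis=1)
            vals = out[cols].to_numpy()
            vals[zero, best[zero]] = 1
            out[cols] = vals
    return out


def simulate_ranges(
    tree: dendropy.Tree,
    n_cells: int,
    size_covariate: pd.Series | np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Contiguous-block species x cell membership; block width increases
    monotonically with the rank of ``size_covariate`` and every species
    occupies at least one cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    tips = tip_labels(tree)
    cov = np.asarray(
        size_covariate.reindex(tips) if isinstance(size_covariate, pd.Series) else size_covariate,
        dtype=float,
    )
    if cov.shape[0] != len(tips):
        raise ValueError("size_covariate length must equal tip count")
    rng = np.random.default_rng(seed)
    from scipy.stats import rankdata

    n = len(tips)
    frac = (rankdata(cov, method="average") - 1) / (n - 1) if n > 1 else np.ones(n)
    widths = 1 + np.rint(frac * (n_cells - 1)).astype(int)
    mat = np.zeros((n, n_cells), dtype=int)
    for i, w in enumerate(widths):
        start = int(rng.integers(0, n_cells - w + 1))
        mat[i, start : start + w] = 1
    cells = [f"cell{j:03d}" for j in range(n_cells)]
    return pd.DataFrame(mat, index=pd.Index(tips, name="species"), columns=cells)


# ---------------------------------------------------------------------------
# missingness


@dataclass
class AttributeMissingness:
    """Missingness mechanism for one attribute block.

    ``coefficient`` is the logistic slope linking the z-scored driver to the
    missingness probability: for MAR the driver is the (always-observed)
    column named in ``driver``; for MNAR it is the block's own value; MCAR
    has no driver.
    """

    mechanism: str = "MCAR"
    rate: float = 0.1
    coefficient: float = -1.0
    driver: str | None = None

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.mechanism == "MAR" and not self.driver:
            raise ValueError("MAR requires a driver column")


@dataclass
class MissingnessSpec:
    """Per-block mechanisms plus a shared latent 'poorly known species'
    factor whose weight ``shared_gap_strength`` induces co-missing gaps
    across attributes."""

    attributes: dict[str, AttributeMissingness] = field(default_factory=dict)
    shared_gap_strength: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.shared_gap_strength <= 1.0:
            raise ValueError("shared_gap_strength must be in [0, 1]")
        for name in self.attributes:
            if name not in ATTRIBUTE_BLOCKS:
                raise ValueError(
                    f"unknown attribute block {name!r}; known: {sorted(ATTRIBUTE_BLOCKS)}"
                )

    def to_json(self, path) -> None:
        payload = {
            "shared_gap_strength": self.shared_gap_strength,
            "attributes": {
                name: {
                    "mechanism": am.mechanism,
                    "rate": am.rate,
                    "coefficient": am.coefficient,
                    "driver": am.driver,
                }
                for name, am in self.attributes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MissingnessSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            attributes={
                name: AttributeMissingness(**kw)
                for name, kw in payload["attributes"].items()
            },
            shared_gap_strength=payload["shared_gap_strength"],
        )


def _block_driver(data: pd.DataFrame, block: str) -> np.ndarray:
    """The MNAR driving variable for a block, on a sensible scale."""
    cols = ATTRIBUTE_BLOCKS[block]
    if block == "body_length":
        return np.log10(data["BodyLength_mm"].to_numpy(dtype=float))
    if block == "body_mass":
        return np.log10(data["BodyMass_g"].to_numpy(dtype=float))
    if block == "activity":
        return nocturnality_score(data["Diu"].to_numpy(), data["Noc"].to_numpy())
    if block == "microhabitat":
        return verticality_score(*(data[c].to_numpy() for c in MICROHABITAT_COLS))
    return data[cols[0]].to_numpy(dtype=float)


def _zscore(x):
    sd = x.std()
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def impose_missingness(
    traits_true: TraitTable, spec: MissingnessSpec, seed: int = 0
) -> tuple[TraitTable, pd.DataFrame]:
    """Hide cells of a complete trait table per the missingness spec.

    Returns the table with missing cells (provenance ``missing``) and a
    boolean species x block mask recording which blocks were hidden, for
    later scoring against ground truth.
    """
    data = traits_true.data
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(len(data))
    masked = traits_true.copy()
    mask = pd.DataFrame(
        False, index=data.index, columns=list(spec.attributes), dtype=bool
    )
    for block, am in spec.attributes.items():
        if am.mechanism == "MCAR":
            eta = np.zeros(len(data))
        else:
            if am.mechanism == "MAR":
                if am.driver in {
                    c for b in spec.attributes for c in ATTRIBUTE_BLOCKS[b]
                }:
                    raise ValueError(
                        f"MAR driver {am.driver!r} is itself subject to "
                        "missingness: invalid configuration"
                    )
                if am.driver not in data.columns:
                    raise ValueError(f"MAR driver {am.driver!r} not in table")
                drv = data[am.driver].to_numpy(dtype=float)
            else:
                drv = _block_driver(data, block)
            eta = am.coefficient * _zscore(drv)
        eta = eta + spec.shared_gap_strength * latent
        if am.rate <= 0.0:
            p = np.zeros(len(data))
        elif am.rate >= 1.0:
            p = np.ones(len(data))
        else:
            p = 1.0 / (1.0 + np.exp(-(math.log(am.rate / (1 - am.rate)) + eta)))
        hide = rng.random(len(data)) < p
        mask[block] = hide
        for col in ATTRIBUTE_BLOCKS[block]:
            if col in masked.data.columns:
                masked.data.loc[hide, col] = np.nan
                masked.provenance.loc[hide, col] = PROV_MISSING
    return masked, mask


# ---------------------------------------------------------------------------
# whole-clade assembly


@dataclass
class SimulatedClade:
    """A complete synthetic study system: tree, taxonomy, true traits,
    assemblages, and the seed that made them."""

    tree: dendropy.Tree
    taxonomy: pd.DataFrame
    traits_true: TraitTable
    assemblages: pd.DataFrame
    seed: int

    def validate(self) -> None:
        tips = set(tip_labels(self.tree))
        assert tips == set(self.traits_true.data.index)
        assert tips == set(self.taxonomy.index)
        g2f = self.taxonomy.groupby("Genus")["Family"].nunique()
        assert (g2f == 1).all(), "a genus maps to more than one family"
        assert (self.assemblages.sum(axis=1) >= 1).all()


#: Liability thresholds chosen for realistic category prevalences on a
#: depth-1 tree with liability sigma 1 (Ter common, Aer rare, roughly half
#: of species nocturnal, most species assessed).
DEFAULT_THRESHOLDS = {
    "Diu": 0.0,
    "Noc": 0.0,
    "Fos": 0.8,
    "Ter": -0.8,
    "Aqu": 0.5,
    "Arb": 0.3,
    "Aer": 1.2,
    "Assessed": -0.5,
}


def build_clade(
    n_tips: int = 300,
    n_families: int = 5,
    n_genera: int = 30,
    n_cells: int = 50,
    sigma_bm: float = 1.0,
    allometry: tuple[float, float, float] = (-4.0, 3.0, 0.05),
    liability_sigma: float = 1.0,
    thresholds: dict[str, float] | None = None,
    seed: int = 0,
) -> SimulatedClade:
    """Assemble a full synthetic clade under the package's study conditions."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    ss = np.random.SeedSequence(seed)
    s_tree, s_cont, s_bin, s_rng = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    tree = simulate_tree(n_tips, seed=s_tree)
    taxonomy = assign_taxonomy(tree, n_families, n_genera)
    cont = simulate_continuous_traits(tree, sigma_bm, allometry, seed=s_cont)
    binary = simulate_binary_traits(
        tree, list(thresholds), liability_sigma, thresholds, seed=s_bin
    )
    data = pd.DataFrame(
        {
            "Genus": taxonomy["Genus"],
            "Family": taxonomy["Family"],
            "BodyLength_mm": 10.0 ** cont["log10_length"],
            "BodyMass_g": 10.0 ** cont["log10_mass"],
        }
    )
    for col in binary.columns:
        data[col] = binary[col]
    table = TraitTable.from_complete(data)
    ranges = simulate_ranges(tree, n_cells, cont["log10_length"], seed=s_rng)
    clade = SimulatedClade(tree, taxonomy, table, ranges, seed)
    clade.validate()
    return clade
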