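"""Chronogram handling: reading, validation, clade-constrained tip
imputation, species ages, and the DR tip speciation-rate statistic.

A chronogram is a rooted, time-calibrated, ultrametric tree whose branch
lengths are in Ma and whose tips sit at the present (age 0). Node ages are
stored explicitly so that operations that rewire the topology (grafting
unsampled species into clades) preserve ultrametricity exactly rather than
to rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Chronogram",
    "read_chronogram",
    "write_chronogram",
    "augment_tree",
    "tip_species_ages",
    "dr_statistic",
]


class ChronogramError(ValueError):
    """Raised for structurally invalid chronograms or invalid operations."""


@dataclass
class Chronogram:
    """A rooted ultrametric tree with node ages in Ma before present.

    Attributes
    ----------
    tree:
        The underlying dendropy tree. Every node carries an ``age_ma``
        attribute (tips exactly 0.0) and a stable ``node_id`` label of the
        form ``N<k>`` assigned in preorder.
    clade_labels:
        Optional map clade-name -> set of tip labels; every labeled clade
        must be monophyletic.
    """

    tree: dendropy.Tree
    clade_labels: dict[str, frozenset[str]] = field(default_factory=dict)

    # ---- basic accessors -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def crown_age(self) -> float:
        return float(self.tree.seed_node.age_ma)

    def node_ages(self) -> dict[str, float]:
        """Map node_id -> age (Ma) for every node."""
        return {nd.node_id: float(nd.age_ma) for nd in self.tree.preorder_node_iter()}

    def total_branch_length(self) -> float:
        return float(
            sum(
                nd.parent_node.age_ma - nd.age_ma
                for nd in self.tree.preorder_node_iter()
                if nd.parent_node is not None
            )
        )

    def branching_ages(self) -> np.ndarray:
        """Ages of internal nodes (Ma), descending; first entry is the crown."""
        ages = sorted(
            (float(nd.age_ma) for nd in self.tree.preorder_internal_node_iter()),
            reverse=True,
        )
        return np.asarray(ages)

    # ---- clade labels ----------------------------------------------------
    def attach_clades(self, clades: dict[str, set[str]]) -> None:
        """Attach clade labels, checking monophyly of each tip set."""
        tipset = set(self.tip_labels)
        for name, members in clades.items():
            members = frozenset(members)
            missing = members - tipset
            if missing:
                raise ChronogramError(
                    f"clade {name!r} lists tips absent from the tree: {sorted(missing)[:5]}"
                )
            mrca = self.mrca(members)
            below = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
            if below != members:
                raise ChronogramError(
                    f"clade {name!r} is not monophyletic: its MRCA also contains "
                    f"{sorted(below - members)[:5]}"
                )
            self.clade_labels[name] = members

    def mrca(self, labels) -> dendropy.Node:
        """Most recent common ancestor of a set of tip labels.

        Walks ancestor paths directly (no cached bipartition encoding, so
        it stays correct while the tree is being edited)."""
        labels = set(labels)
        leaves = {
            lf.taxon.label: lf
            for lf in self.tree.leaf_node_iter()
            if lf.taxon.label in labels
        }
        if len(leaves) != len(labels):
            raise ChronogramError(
                f"unknown tip label(s) in MRCA query: {sorted(labels - set(leaves))[:5]}"
            )
        it = iter(leaves.values())
        first = next(it)
        path = []
        nd = first
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        rank = {n: i for i, n in enumerate(path)}
        deepest = 0
        for lf in it:
            nd = lf
            while nd not in rank:
                nd = nd.parent_node
            deepest = max(deepest, rank[nd])
        return path[deepest]

    def divergence_time(self, a: str, b: str) -> float:
        """Age of the MRCA of two tips (Ma)."""
        return float(self.mrca([a, b]).age_ma)

    def clone(self) -> "Chronogram":
        t = self.tree.clone(depth=1)
        # clone(depth=1) copies node attributes by reference; ages/ids are
        # immutable scalars so that is safe, but re-assert presence.
        for nd in t.preorder_node_iter():
            nd.age_ma = float(nd.age_ma)
        return Chronogram(t, {k: frozenset(v) for k, v in self.clade_labels.items()})

    def copy_with_recomputed_edges(self) -> None:
        """Recompute every edge length from the stored node ages."""
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = nd.parent_node.age_ma - nd.age_ma


def _assign_node_ids(tree: dendropy.Tree) -> None:
    for i, nd in enumerate(tree.preorder_node_iter()):
        nd.node_id = f"N{i}"


def _compute_ages(tree: dendropy.Tree, ultrametric_tol: float) -> None:
    """Compute node ages from branch lengths; enforce ultrametricity.

    Ages are (max root-to-tip depth) - depth; tips are then snapped to 0
    exactly so downstream arithmetic is free of dating round-off.
    """
    tree.seed_node.depth = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            raise ChronogramError(
                f"missing branch length on the edge above node "
                f"{nd.taxon.label if nd.taxon else '<internal>'}"
            )
        if nd.edge.length < 0:
            raise ChronogramError("negative branch length")
        nd.depth = nd.parent_node.depth + nd.edge.length

    leaves = [lf for lf in tree.leaf_node_iter()]
    depths = np.array([lf.depth for lf in leaves])
    t_c = float(depths.max())
    if t_c <= 0:
        raise ChronogramError("tree has zero depth")
    rel_dev = np.abs(depths - t_c) / t_c
    worst = int(np.argmax(rel_dev))
    if rel_dev[worst] > ultrametric_tol:
        raise ChronogramError(
            f"tree is not ultrametric within tolerance {ultrametric_tol:g}: tip "
            f"{leaves[worst].taxon.label!r} has depth {depths[worst]:.6g} vs crown "
            f"depth {t_c:.6g}"
        )
    for nd in tree.preorder_node_iter():
        nd.age_ma = 0.0 if nd.is_leaf() else t_c - nd.depth
    # parents of tips must not dip below the present
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.age_ma < 0:
            nd.age_ma = 0.0


def read_chronogram(
    path_or_string: str | Path,
    ultrametric_tol: float = 1e-4,
    clade_file: str | Path | None = None,
) -> Chronogram:
    """Read a Newick chronogram and validate ultrametricity.

    Parameters
    ----------
    path_or_string:
        Path to a Newick file, or a Newick string (detected by a leading
        ``(``).
    ultrametric_tol:
        Maximum allowed relative deviation of any root-to-tip depth from
        the crown depth. Dated trees from external pipelines carry rounding
        noise, hence the permissive default.
    clade_file:
        Optional two-column delimited file (species, clade) of clade labels
        to attach.
    """
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    tree.is_rooted = True
    _compute_ages(tree, ultrametric_tol)
    _assign_node_ids(tree)
    chrono = Chronogram(tree)
    if clade_file is not None:
        chrono.attach_clades(read_clade_table(clade_file))
    return chrono


def read_clade_table(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    sp_col, clade_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for sp, clade in zip(df[sp_col], df[clade_col]):
        out.setdefault(str(clade), set()).add(str(sp))
    return out


def write_chronogram(chrono: Chronogram, path: str | Path | None = None) -> str:
    """Write Newick with edge lengths derived from node ages (17 sig figs)."""
    chrono.copy_with_recomputed_edges()
    newick = chrono.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


# ---- clade-constrained augmentation -------------------------------------


def augment_tree(
    chrono: Chronogram, assignments: dict[str, str], seed: int
) -> Chronogram:
    """Graft unsampled species into their assigned clades at random.

    Each species is attached at a uniformly chosen time point on a
    uniformly chosen branch lying wholly inside its clade (the clade's stem
    edge is excluded); the new terminal branch extends to the present so the
    tree stays ultrametric. Earlier grafts within a clade are eligible
    attachment branches for later ones, mirroring sequential random
    addition. Identical seed gives identical output.
    """
    for sp, clade in assignments.items():
        if clade not in chrono.clade_labels:
            raise ChronogramError(f"unknown clade {clade!r} for species {sp!r}")
        if sp in set(chrono.tip_labels):
            raise ChronogramError(f"species {sp!r} is already in the tree")

    out = chrono.clone()
    if not assignments:
        return out
    rng = np.random.default_rng(seed)
    clade_tips = {k: set(v) for k, v in out.clade_labels.items()}

    # deterministic order: sorted species names
    for sp in sorted(assignments):
        clade = assignments[sp]
        crown = out.mrca(clade_tips[clade])
        if crown.is_leaf():
            raise ChronogramError(
                f"clade {clade!r} has a single tip; no internal branch to graft onto"
            )
        # every edge strictly below the crown node
        edges = [nd for nd in crown.preorder_iter() if nd is not crown]
        child = edges[rng.integers(len(edges))]
        parent = child.parent_node
        lo, hi = float(child.age_ma), float(parent.age_ma)
        t_att = float(rng.uniform(lo, hi))

        taxon = out.tree.taxon_namespace.new_taxon(label=sp)
        new_internal = dendropy.Node()
        new_internal.age_ma = t_att
        new_tip = dendropy.Node(taxon=taxon)
        new_tip.age_ma = 0.0
        parent.remove_child(child)
        parent.add_child(new_internal)
        new_internal.add_child(child)
        new_internal.add_child(new_tip)
        clade_tips[clade].add(sp)

    out.copy_with_recomputed_edges()
    _assign_node_ids(out.tree)
    out.clade_labels = {k: frozenset(v) for k, v in clade_tips.items()}
    return out


# ---- tip statistics ------------------------------------------------------


def tip_species_ages(chrono: Chronogram, method: str = "parent_node") -> pd.Series:
    """Species age per tip, in Ma.

    ``parent_node`` (default): age of the tip's parent node — the tip's stem
    age, equal to its terminal branch length for present-day tips.
    ``labeled_clade``: crown age of the smallest labeled clade containing
    the tip (requires clade labels covering the tip).
    """
    ages = {}
    if method == "parent_node":
        for lf in chrono.tree.leaf_node_iter():
            ages[lf.taxon.label] = float(lf.parent_node.age_ma)
    elif method == "labeled_clade":
        for lf in chrono.tree.leaf_node_iter():
            label = lf.taxon.label
            containing = [
                (len(v), k) for k, v in chrono.clade_labels.items() if label in v
            ]
            if not containing:
                raise ChronogramError(f"tip {label!r} is in no labeled clade")
            _, clade = min(containing)
            ages[label] = float(chrono.mrca(chrono.clade_labels[clade]).age_ma)
    else:
        raise ValueError(f"unknown species-age method {method!r}")
    return pd.Series(ages, name="age_ma").sort_index()


def equal_splits(chrono: Chronogram) -> pd.Series:
    """Equal-splits measure ES_i = sum_j l_j 2^-(j-1) along each root-to-tip
    path, with l_1 the terminal edge. Units: Ma."""
    es = {}
    for lf in chrono.tree.leaf_node_iter():
        total = 0.0
        weight = 1.0
        nd = lf
        while nd.parent_node is not None:
            length = nd.parent_node.age_ma - nd.age_ma
            total += weight * length
            weight *= 0.5
            nd = nd.parent_node
        if lf.parent_node.age_ma - lf.age_ma <= 0:
            raise ChronogramError(
                f"tip {lf.taxon.label!r} has a zero-length terminal edge; "
                "DR is undefined"
            )
        es[lf.taxon.label] = total
    return pd.Series(es, name="es_ma").sort_index()


def dr_statistic(chrono: Chronogram) -> pd.Series:
    """DR tip speciation-rate statistic: the inverse equal-splits measure,
    in species/Ma. Multifurcations are tolerated; each edge on the path
    contributes once, halving the weight per step toward the root."""
    es = equal_splits(chrono)
    dr = (1.0 / es).rename("dr_per_ma")
    return dr


def write_tipstat(series: pd.Series, path: str | Path) -> None:
    series.rename_axis("species").to_frame().to_csv(path, sep="\t")


def read_tipstat(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="species")
    return df[df.columns[0]]
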