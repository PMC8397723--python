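"""Alpha diversity with rarefaction.

Counts are rarefied to a fixed depth (5000 sequences by default) by sampling
without replacement, so samples sequenced more deeply do not appear more
diverse.  Diversity is summarised as the number of phylotypes observed, the
Shannon index (natural log) and, when a phylogeny is supplied, Faith's
phylogenetic diversity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

DEFAULT_DEPTH = 5000


def rarefy(counts, depth: int = DEFAULT_DEPTH, rng=None):
    """Subsample integer counts to ``depth`` without replacement.

    Returns the rarefied count vector, or ``None`` when the sample has fewer
    than ``depth`` sequences (the sample is flagged for exclusion rather than
    raising).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total < depth:
        return None
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.multivariate_hypergeometric(counts, depth)


@dataclass
class AlphaDiversity:
    observed: int
    shannon: float
    faith_pd: float | None = None


def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    if isinstance(tree, str) and "(" in tree:
        return TreeNode.read(io.StringIO(tree))
    return TreeNode.read(str(tree))


def faith_pd(observed_taxa, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the subtree
    spanning the observed taxa and the root.

    Computed directly on the tree so multifurcating (e.g. star) trees are
    accepted; agrees with scikit-bio's ``faith_pd`` on strictly rooted trees.
    """
    observed = set(observed_taxa)
    tips = {t.name for t in tree.tips()}
    missing = observed - tips
    if missing:
        raise ValueError(f"observed taxa absent from tree: {sorted(missing)}")
    total = 0.0
    for node in tree.postorder(include_self=False):
        node._pd_hit = (
            node.name in observed if node.is_tip()
            else any(getattr(c, "_pd_hit", False) for c in node.children)
        )
        if node._pd_hit and node.length is not None:
            total += node.length
    for node in tree.postorder(include_self=False):
        if hasattr(node, "_pd_hit"):
            del node._pd_hit
    return total


def alpha_diversity(counts, taxa=None, tree=None) -> AlphaDiversity:
    """Observed phylotypes, Shannon index (natural log) and Faith's PD.

    Faith's PD is the total branch length of the tree subgraph spanning the
    observed taxa and the root; it is omitted (None) when no tree is given.
    ``taxa`` names the count entries and must match tree tip names.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    observed = int(np.count_nonzero(counts))
    p = counts[counts > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    pd_value = None
    if tree is not None:
        if taxa is None:
            raise ValueError("taxa names are required to compute Faith's PD")
        present = [t for t, c in zip(taxa, counts) if c > 0]
        pd_value = float(faith_pd(present, _as_tree(tree)))
    return AlphaDiversity(observed=observed, shannon=shannon, faith_pd=pd_value)


def alpha_diversity_table(
    count_table: pd.DataFrame, depth: int = DEFAULT_DEPTH, tree=None, rng=None
) -> pd.DataFrame:
    """Rarefy each row of a samples x taxa count table and summarise diversity.

    Samples below the rarefaction depth are returned with ``included=False``
    and NaN indices; they are excluded here but retained elsewhere in the
    pipeline.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    taxa = list(count_table.columns)
    tree_obj = _as_tree(tree) if tree is not None else None
    rows = []
    for sample, counts in count_table.iterrows():
        sub = rarefy(counts.to_numpy(), depth=depth, rng=rng)
        if sub is None:
            rows.append(
                {"sample_id": sample, "included": False, "observed": np.nan,
                 "shannon": np.nan, "faith_pd": np.nan}
            )
            continue
        res = alpha_diversity(sub, taxa=taxa, tree=tree_obj)
        rows.append(
            {"sample_id": sample, "included": True, "observed": res.observed,
             "shannon": res.shannon,
             "faith_pd": res.faith_pd if res.faith_pd is not None else np.nan}
        )
    return pd.DataFrame(rows).set_index("sample_id")
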