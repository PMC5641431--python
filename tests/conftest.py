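import itertools

import numpy as np
import pytest

from phylogeo.core import Tree, TreeNode


def all_unrooted_topologies(taxa):
    """Enumerate all unrooted binary topologies over the given taxa.

    Built by sequential leaf insertion on every edge; (2n-5)!! trees for n
    taxa (15 for n=5, 105 for n=6).
    """
    taxa = list(taxa)

    def insert_on_each_edge(tree, label):
        out = []
        edges = [n for n in tree.postorder() if n is not tree.root]
        for k in range(len(edges)):
            t2 = tree.copy()
            target = [n for n in t2.postorder() if n is not t2.root][k]
            parent = target.parent
            mid = TreeNode(length=1.0)
            new_leaf = TreeNode(label=label, length=1.0)
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(new_leaf)
            out.append(t2)
        return out

    root = TreeNode()
    for lab in taxa[:3]:
        root.add_child(TreeNode(label=lab, length=1.0))
    trees = [Tree(root, rooted=False)]
    for lab in taxa[3:]:
        trees = [t2 for t in trees for t2 in insert_on_each_edge(t, lab)]
    return trees


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced8():
    return Tree.from_newick(
        "(((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5):0.3,"
        "((E:0.05,F:0.05):0.5,(G:0.05,H:0.05):0.5):0.3);")


def brute_force_min_changes(tree, column, taxa):
    """Parsimony length by enumerating all internal-node labelings."""
    from phylogeo.core import GAP, MISSING
    obs = set()
    for c in column:
        if c not in (GAP, MISSING):
            obs |= c
    if len(obs) <= 1:
        return 0
    states = sorted(obs)
    cell_of = dict(zip(taxa, column))
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    best = None
    for assign in itertools.product(states, repeat=len(internal)):
        amap = {id(n): a for n, a in zip(internal, assign)}
        cost = 0
        feasible = True
        for n in nodes:
            if n is tree.root:
                continue
            pa = amap[id(n.parent)]
            if n.is_leaf:
                cell = cell_of[n.label]
                if cell in (GAP, MISSING):
                    continue
                if pa not in cell:
                    cost += 1
            else:
                if amap[id(n)] != pa:
                    cost += 1
        if feasible and (best is None or cost < best):
            best = cost
    return best
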