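"""Shared brute-force oracles for the acceptance checks (kept independent of
the package's vectorized implementations)."""

import numpy as np
from skbio import TreeNode

from stomabiome.bundle_io import PhyloTree


def random_small_tree(n_tips, seed):
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


def unifrac_pair_oracle(tree, rel_table, i, j, weighted):
    """Per-branch summation over an explicit tip-set traversal."""
    vi = dict(zip(rel_table.feature_ids, rel_table.values[i]))
    vj = dict(zip(rel_table.feature_ids, rel_table.values[j]))
    num = den = 0.0
    for node in tree.tree.postorder():
        if node.is_root():
            continue
        tips = {t.name for t in node.tips()} or {node.name}
        pi = sum(vi.get(t, 0.0) for t in tips)
        pj = sum(vj.get(t, 0.0) for t in tips)
        if weighted:
            num += node.length * abs(pi - pj)
        else:
            if pi > 0 or pj > 0:
                den += node.length
                if (pi > 0) != (pj > 0):
                    num += node.length
    return num if weighted else (num / den if den else 0.0)
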