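import numpy as np
import pytest

from qsevo.interface_geometry import call_regions, compute_assembly_sasa
from qsevo.structure_sasa import partition_complex
from qsevo.synthetic_data import gen_cn_complex


@pytest.fixture(scope="session")
def dimer_truth():
    """A C2 toy dimer with known buried residues."""
    return gen_cn_complex(2, 30, seed=42)


@pytest.fixture(scope="session")
def dimer_sasa(dimer_truth):
    partition = partition_complex(dimer_truth.assembly)
    sasa_cx, sasa_sub = compute_assembly_sasa(partition)
    return partition, sasa_cx, sasa_sub


@pytest.fixture(scope="session")
def dimer_profile(dimer_truth, dimer_sasa):
    partition, sasa_cx, sasa_sub = dimer_sasa
    return call_regions(
        partition, sasa_cx, sasa_sub, reference_areas=dimer_truth.reference_areas
    )


def make_labeled_topologies(leaf_names, lengths=None):
    """All labeled rooted binary topologies over the given leaves.

    Built by inserting each successive leaf on every existing edge and
    above the root; branch lengths cycle deterministically.
    """
    from qsevo.phylo_ancestral import RootedTree, TreeNode

    if lengths is None:
        lengths = [0.3, 0.7, 0.5, 1.1, 0.2, 0.9, 0.4, 0.8, 0.6, 1.3]

    def clone(node):
        new = TreeNode(name=node.name, length=node.length)
        for child in node.children:
            new.add_child(clone(child))
        return new

    def all_nodes(node):
        yield node
        for child in node.children:
            yield from all_nodes(child)

    roots = [TreeNode(name=leaf_names[0], length=1.0)]
    for leaf_name in leaf_names[1:]:
        next_roots = []
        for root in roots:
            targets = list(all_nodes(root))
            for t_index in range(len(targets)):
                new_root = clone(root)
                target = list(all_nodes(new_root))[t_index]
                parent = target.parent
                joint = TreeNode(name=None, length=target.length / 2)
                target.length = target.length / 2
                new_leaf = TreeNode(name=leaf_name, length=1.0)
                if parent is None:
                    joint.add_child(target)
                    joint.add_child(new_leaf)
                    joint.length = 0.0
                    new_root = joint
                else:
                    parent.children[parent.children.index(target)] = joint
                    joint.parent = parent
                    joint.add_child(target)
                    joint.add_child(new_leaf)
                next_roots.append(new_root)
        roots = next_roots

    trees = []
    for root in roots:
        i = 0
        tree = RootedTree(root)
        for node in tree.preorder():
            if node.parent is not None:
                node.length = lengths[i % len(lengths)]
                i += 1
        trees.append(tree)
    return trees
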