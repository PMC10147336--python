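"""Dated, rooted, bifurcating phylogenies.

Thin array-backed container over dendropy trees.  Branch lengths are in
million years (myr); node ages are myr before present, with extant tips at
age 0 (within a tolerance).  Internal structure is stored as parent /
children index arrays so the likelihood, mapping and simulation code can
iterate in post- or preorder without touching dendropy objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class DatedTree:
    """A rooted, bifurcating, time-calibrated tree.

    Node ids are integers ``0..n_nodes-1`` in postorder (tips and internals
    interleaved as encountered); ``root`` is the last postorder id.
    """

    parent: list[int | None]
    children: list[tuple[int, ...]]
    age: list[float]
    label: list[str | None]
    node_name: list[str | None] = field(default=None)

    def __post_init__(self):
        if self.node_name is None:
            self.node_name = [None] * len(self.parent)
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise ValueError(f"node {i} is not bifurcating ({len(ch)} children)")
            for c in ch:
                if self.age[c] >= self.age[i]:
                    raise ValueError(
                        f"child {c} (age {self.age[c]}) not younger than "
                        f"parent {i} (age {self.age[i]})"
                    )

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return next(i for i, p in enumerate(self.parent) if p is None)

    @property
    def tips(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if ch]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def root_age(self) -> float:
        return self.age[self.root]

    def postorder(self):
        """Node ids, children before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return 0.0 if p is None else self.age[p] - self.age[node]

    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tips]

    def descend_tips(self, node: int) -> list[int]:
        """Tip ids below (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if not self.children[n]:
                out.append(n)
            else:
                stack.extend(self.children[n])
        return out

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        nodes = list(tree.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        # depth from root, then age = max tip depth - depth
        depth = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[id(nd)] = 0.0
            else:
                el = nd.edge.length if nd.edge.length is not None else 0.0
                depth[id(nd)] = depth[id(nd.parent_node)] + el
        max_depth = max(depth[id(nd)] for nd in tree.leaf_node_iter())
        parent: list[int | None] = [None] * len(nodes)
        children: list[tuple[int, ...]] = [()] * len(nodes)
        age: list[float] = [0.0] * len(nodes)
        label: list[str | None] = [None] * len(nodes)
        name: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = idx[id(nd)]
            age[i] = max_depth - depth[id(nd)]
            kids = nd.child_nodes()
            children[i] = tuple(idx[id(c)] for c in kids)
            for c in kids:
                parent[idx[id(c)]] = i
            if not kids:
                label[i] = nd.taxon.label if nd.taxon else None
                if abs(age[i]) > ultrametric_tol * max(1.0, max_depth):
                    age[i] = age[i]  # non-contemporaneous tip kept as-is
            elif nd.label:
                name[i] = nd.label
        return cls(parent=parent, children=children, age=age, label=label,
                   node_name=name)

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted"
        )
        return cls.from_dendropy(tree)

    @classmethod
    def read(cls, path) -> "DatedTree":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if not self.children[node]:
                return f"{self.label[node]}:{self.branch_length(node):.10g}"
            inner = ",".join(fmt(c) for c in self.children[node])
            name = self.node_name[node] or ""
            if self.parent[node] is None:
                return f"({inner}){name}"
            return f"({inner}){name}:{self.branch_length(node):.10g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
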