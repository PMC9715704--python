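"""SNP-annotated haplogroup trees.

A haplogroup tree is a rooted tree whose nodes are haplogroup labels, each
carrying the set of SNPs that define the branch leading to it.  Some input
trees mark a node as an unplaced bundle (the ISOGG "~" convention): a set of
SNPs known to belong below a parent but whose internal order is uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


@dataclass
class TreeNode:
    name: str
    parent: str | None
    snps: frozenset[str]
    bundle: bool = False
    children: list[str] = field(default_factory=list)


class HaplogroupTree:
    """Rooted haplogroup tree; every defining SNP appears at exactly one node."""

    def __init__(self, nodes: list[TreeNode]):
        self.nodes: dict[str, TreeNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].name
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise ValueError(f"orphan node {node.name!r}: parent {node.parent!r} unknown")
                self.nodes[node.parent].children.append(node.name)
        self._check_acyclic()
        self._snp_to_node: dict[str, str] = {}
        for node in self.nodes.values():
            for snp in node.snps:
                if snp in self._snp_to_node:
                    raise ValueError(
                        f"SNP {snp!r} defined at both {self._snp_to_node[snp]!r} "
                        f"and {node.name!r}"
                    )
                self._snp_to_node[snp] = node.name
        self._depth: dict[str, int] = {}
        self._compute_depths()

    def _check_acyclic(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValueError("cycle detected")
            seen.add(name)
            stack.extend(self.nodes[name].children)
        if len(seen) != len(self.nodes):
            unreached = set(self.nodes) - seen
            raise ValueError(f"nodes unreachable from root (cycle or orphan): {sorted(unreached)}")

    def _compute_depths(self) -> None:
        for name in self.nodes:
            d, cur = 0, name
            while self.nodes[cur].parent is not None:
                cur = self.nodes[cur].parent
                d += 1
            self._depth[name] = d

    # -- queries -----------------------------------------------------------

    def depth(self, name: str) -> int:
        return self._depth[name]

    def path(self, name: str) -> list[str]:
        """Node names from root to ``name`` inclusive."""
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def path_snps(self, name: str) -> set[str]:
        """All branch-defining SNPs on the root-to-node path (root's own SNPs
        included: they define membership in the tree's base haplogroup)."""
        snps: set[str] = set()
        for node_name in self.path(name):
            snps |= self.nodes[node_name].snps
        return snps

    def node_of_snp(self, snp: str) -> str | None:
        return self._snp_to_node.get(snp)

    def all_snps(self) -> set[str]:
        return set(self._snp_to_node)

    def children_snps(self, name: str) -> set[str]:
        snps: set[str] = set()
        for child in self.nodes[name].children:
            snps |= self.nodes[child].snps
        return snps

    def descendants(self, name: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.nodes[name].children)
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self.nodes[cur].children)
        return out

    def is_leaf(self, name: str) -> bool:
        return not self.nodes[name].children

    def __len__(self) -> int:
        return len(self.nodes)

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dicts(cls, records: list[dict]) -> "HaplogroupTree":
        nodes = []
        for rec in records:
            snps = rec.get("snps", [rec["name"]])
            nodes.append(
                TreeNode(
                    name=str(rec["name"]),
                    parent=rec.get("parent"),
                    snps=frozenset(str(s) for s in snps),
                    bundle=bool(rec.get("bundle", False)),
                )
            )
        return cls(nodes)

    def to_dicts(self) -> list[dict]:
        out = []
        for name in sorted(self.nodes, key=lambda n: (self._depth[n], n)):
            node = self.nodes[name]
            rec: dict = {"name": node.name, "parent": node.parent, "snps": sorted(node.snps)}
            if node.bundle:
                rec["bundle"] = True
            out.append(rec)
        return out

    @classmethod
    def from_yaml(cls, path) -> "HaplogroupTree":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dicts(data["nodes"] if isinstance(data, dict) else data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"nodes": self.to_dicts()}, fh, sort_keys=False)

    def to_newick(self) -> str:
        def rec(name: str) -> str:
            node = self.nodes[name]
            if not node.children:
                return name
            inner = ",".join(rec(c) for c in sorted(node.children))
            return f"({inner}){name}"

        return rec(self.root) + ";"


# Schematic refined structure of the R1b-DF27 subtree (ISOGG 2019-2020 names),
# with the nine-SNP "~" bundle resolved into four basal branches and the
# Z205 -> {Z208, CTS8289} -> CTS4299 chain placed under M167.
DF27_TREE_RECORDS: list[dict] = [
    {"name": "DF27", "parent": None},
    {"name": "A432", "parent": "DF27"},
    {"name": "CTS11567", "parent": "DF27", "snps": ["CTS11567", "Z2572"]},
    {"name": "CTS6519.1", "parent": "DF27", "snps": ["CTS6519.1", "S4247.1"]},
    {"name": "DF81", "parent": "DF27"},
    {"name": "Z222", "parent": "DF27"},
    {"name": "Z195", "parent": "DF27"},
    {"name": "L176.2", "parent": "Z195"},
    {"name": "Z272", "parent": "Z195"},
    {"name": "Z292", "parent": "L176.2"},
    {"name": "CTS4188", "parent": "L176.2"},
    {"name": "M167", "parent": "Z292", "snps": ["M167", "SRY2627"]},
    {"name": "Z205", "parent": "M167"},
    {"name": "Z208", "parent": "Z205", "snps": ["Z208", "S362", "CTS8289"]},
    {"name": "CTS4299", "parent": "Z208"},
    {"name": "Z220", "parent": "Z272"},
    {"name": "DF17", "parent": "Z272"},
    {"name": "Z295", "parent": "Z220"},
    {"name": "Z278", "parent": "Z295"},
    {"name": "S348", "parent": "Z295"},
    {"name": "M153", "parent": "Z278"},
    {"name": "CTS4065", "parent": "Z278"},
]


def default_df27_tree() -> HaplogroupTree:
    """The 22-haplogroup R1b-DF27 subtree used as the packaged default."""
    return HaplogroupTree.from_dicts(DF27_TREE_RECORDS)
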