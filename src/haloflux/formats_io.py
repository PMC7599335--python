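"""Readers and writers for the external formats the pipeline touches.

The central contract of this module is the stable *branch identifier*: every
node of the species tree carries an id that reconciliation tables refer to.
A "branch" is identified by its child node; the root's branch row is
permitted and used only for originations (matching ALE's branch tables).

Formats handled here:

* rooted newick species trees (internal node labels honoured);
* a TSV dialect for branch-wise reconciliation-frequency tables
  (duplications / transfers / losses / originations / expected copies per
  branch, an optional donor->recipient transfer section, and an optional
  per-family extinction probability) emulating ALE ``uml_rec`` summaries;
* jplace (JSON) phylogenetic placements plus an edge -> taxonomy table;
* small TSV tables (family membership, annotations, singletons).

All tables are TSV with ``#``-prefixed comment lines, UTF-8, no quoting.
Sub-protein coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "FormatError",
    "SpeciesTreeNode",
    "SpeciesTree",
    "ReconciliationSummary",
    "PlacementProfile",
    "read_species_tree",
    "write_species_tree",
    "read_rec_summary",
    "write_rec_summary",
    "read_jplace",
    "write_jplace",
    "read_edge_taxonomy",
    "write_edge_taxonomy",
    "read_singletons",
    "write_singletons",
]


class FormatError(ValueError):
    """Raised on malformed input or a violated format invariant."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeNode:
    branch_id: str
    parent: str | None
    children: tuple[str, ...]
    is_leaf: bool
    leaf_name: str | None = None


@dataclass
class SpeciesTree:
    """Rooted binary species tree keyed by stable branch identifiers.

    Each node owns the branch above it; ``branch_id`` is the key used by
    reconciliation tables to address that branch.
    """

    nodes: dict[str, SpeciesTreeNode]
    root_id: str

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].branch_id != self.root_id:
            raise FormatError("species tree must have exactly one root")
        leaf_names = [n.leaf_name for n in self.nodes.values() if n.is_leaf]
        if len(set(leaf_names)) != len(leaf_names):
            raise FormatError("duplicate leaf names in species tree")

    # -- queries ------------------------------------------------------------

    @property
    def branch_ids(self) -> list[str]:
        return list(self.nodes)

    @property
    def leaf_ids(self) -> list[str]:
        return [b for b, n in self.nodes.items() if n.is_leaf]

    def leaf_id_by_name(self, name: str) -> str:
        for b, n in self.nodes.items():
            if n.is_leaf and n.leaf_name == name:
                return b
        raise KeyError(f"no leaf named {name!r}")

    def parent_of(self, branch_id: str) -> str | None:
        return self.nodes[branch_id].parent

    def children_of(self, branch_id: str) -> tuple[str, ...]:
        return self.nodes[branch_id].children

    def postorder(self) -> list[str]:
        order: list[str] = []

        def _walk(b: str) -> None:
            for c in self.nodes[b].children:
                _walk(c)
            order.append(b)

        _walk(self.root_id)
        return order

    def preorder(self) -> list[str]:
        order: list[str] = []
        stack = [self.root_id]
        while stack:
            b = stack.pop()
            order.append(b)
            stack.extend(reversed(self.nodes[b].children))
        return order

    def subtree_ids(self, branch_id: str) -> set[str]:
        """All branch ids in the clade rooted at ``branch_id`` (inclusive)."""
        out: set[str] = set()
        stack = [branch_id]
        while stack:
            b = stack.pop()
            out.add(b)
            stack.extend(self.nodes[b].children)
        return out

    def is_descendant(self, branch_id: str, ancestor_id: str) -> bool:
        b: str | None = branch_id
        while b is not None:
            if b == ancestor_id:
                return True
            b = self.nodes[b].parent
        return False


def _check_binary(node: dendropy.Node) -> None:
    k = len(node.child_nodes())
    if k not in (0, 2):
        raise FormatError(
            f"tree is not strictly binary: node with {k} children "
            "(reconciliation assumes a binary species tree)"
        )


def read_species_tree(path: str | Path, id_source: str = "node_labels") -> SpeciesTree:
    """Read a rooted newick species tree and assign branch identifiers.

    ``id_source='node_labels'`` requires every internal node to be labelled;
    ``id_source='postorder_index'`` assigns ids 0..n-1 in postorder.
    """
    if id_source not in ("node_labels", "postorder_index"):
        raise ValueError(f"unknown id_source {id_source!r}")
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return species_tree_from_dendropy(tree, id_source)


def species_tree_from_string(newick: str, id_source: str = "node_labels") -> SpeciesTree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return species_tree_from_dendropy(tree, id_source)


def species_tree_from_dendropy(tree: dendropy.Tree, id_source: str) -> SpeciesTree:
    for nd in tree.preorder_node_iter():
        _check_binary(nd)

    ids: dict[dendropy.Node, str] = {}
    if id_source == "node_labels":
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                ids[nd] = nd.taxon.label if nd.taxon else (nd.label or "")
                if not ids[nd]:
                    raise FormatError("unlabeled leaf in species tree")
            else:
                if not nd.label:
                    kids = ",".join(
                        (c.taxon.label if c.taxon else (c.label or "?"))
                        for c in nd.child_nodes()
                    )
                    raise FormatError(
                        f"internal node above ({kids}) has no label; "
                        "label all internal nodes or use id_source='postorder_index'"
                    )
                ids[nd] = nd.label
    else:
        # ALE-style numbering: leaves 0..n_leaves-1 in postorder appearance,
        # then internal nodes n_leaves..2n-2 in postorder.
        leaves = [nd for nd in tree.postorder_node_iter() if nd.is_leaf()]
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for i, nd in enumerate(leaves + internals):
            ids[nd] = str(i)

    if len(set(ids.values())) != len(ids):
        raise FormatError("branch identifiers are not unique")

    nodes: dict[str, SpeciesTreeNode] = {}
    root_id = ids[tree.seed_node]
    for nd, b in ids.items():
        parent = ids[nd.parent_node] if nd.parent_node is not None else None
        nodes[b] = SpeciesTreeNode(
            branch_id=b,
            parent=parent,
            children=tuple(ids[c] for c in nd.child_nodes()),
            is_leaf=nd.is_leaf(),
            leaf_name=(nd.taxon.label if nd.taxon else nd.label) if nd.is_leaf() else None,
        )
    return SpeciesTree(nodes=nodes, root_id=root_id)


def write_species_tree(tree: SpeciesTree, path: str | Path | None = None) -> str:
    """Serialize to newick with branch_ids as node labels; returns the string."""

    def _nwk(b: str) -> str:
        node = tree.nodes[b]
        if node.is_leaf:
            return node.leaf_name or b
        inner = ",".join(_nwk(c) for c in node.children)
        return f"({inner}){b}"

    s = _nwk(tree.root_id) + ";"
    if path is not None:
        Path(path).write_text(s + "\n", encoding="utf-8")
    return s


# ---------------------------------------------------------------------------
# Reconciliation-frequency summaries
# ---------------------------------------------------------------------------

_REC_COLUMNS = ("branch", "duplications", "transfers", "losses", "originations", "copies")


@dataclass
class BranchRow:
    duplications: float = 0.0
    transfers_in: float = 0.0
    losses: float = 0.0
    originations: float = 0.0
    copies: float = 0.0


@dataclass
class ReconciliationSummary:
    """Per-family branch-wise event frequencies and expected copy numbers.

    Frequencies are means over sampled reconciliations and may exceed 1 when
    a branch hosts multiple events of one type; negative values are invalid.
    """

    family_id: str
    branch_rows: dict[str, BranchRow]
    transfer_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    extinction_prob: float = 0.0
    n_samples: int = 0

    def validate(self, tree: SpeciesTree | None = None) -> None:
        for b, row in self.branch_rows.items():
            if tree is not None and b not in tree.nodes:
                raise FormatError(
                    f"family {self.family_id}: branch {b!r} absent from species tree"
                )
            for name in ("duplications", "transfers_in", "losses", "originations", "copies"):
                if getattr(row, name) < 0:
                    raise FormatError(
                        f"family {self.family_id}: negative {name} on branch {b}"
                    )
        if not 0.0 <= self.extinction_prob < 1.0:
            raise FormatError(
                f"family {self.family_id}: extinction probability "
                f"{self.extinction_prob} outside [0, 1)"
            )
        if self.transfer_pairs:
            for d, r, f in self.transfer_pairs:
                if f < 0:
                    raise FormatError(f"family {self.family_id}: negative transfer frequency")
                if tree is not None and (d not in tree.nodes or r not in tree.nodes):
                    raise FormatError(
                        f"family {self.family_id}: transfer pair ({d},{r}) not in tree"
                    )
            pair_sum = sum(f for _, _, f in self.transfer_pairs)
            in_sum = sum(r.transfers_in for r in self.branch_rows.values())
            if abs(pair_sum - in_sum) > 1e-6:
                raise FormatError(
                    f"family {self.family_id}: transfer pair frequencies sum to "
                    f"{pair_sum:.6g} but transfers_in sum to {in_sum:.6g}"
                )


def read_rec_summary(path: str | Path, tree: SpeciesTree) -> ReconciliationSummary:
    """Parse one branch-wise reconciliation frequency table.

    Layout: an optional ``#family <id>`` line, a header naming the columns
    branch / duplications / transfers / losses / originations / copies, one
    row per branch, then optional ``#transfers`` (donor recipient frequency
    triples), ``#extinction <p>`` and ``#n_samples <k>`` sections.
    """
    path = Path(path)
    family_id = path.name
    for suffix in (".rec.tsv", ".tsv"):
        if family_id.endswith(suffix):
            family_id = family_id[: -len(suffix)]
            break
    branch_rows: dict[str, BranchRow] = {}
    transfer_pairs: list[tuple[str, str, float]] = []
    extinction = 0.0
    n_samples = 0
    section = "rows"
    header_seen = False

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            key = parts[0].lower()
            if key == "family" and len(parts) > 1:
                family_id = parts[1]
            elif key == "transfers":
                section = "transfers"
            elif key == "extinction":
                extinction = float(parts[1])
            elif key == "n_samples":
                n_samples = int(parts[1])
            continue
        fields = line.split("\t")
        if section == "transfers":
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: transfer row needs 3 fields")
            d, r, f = fields[0], fields[1], float(fields[2])
            transfer_pairs.append((d, r, f))
            continue
        if not header_seen:
            if tuple(f.lower() for f in fields) != _REC_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected header {'/'.join(_REC_COLUMNS)}"
                )
            header_seen = True
            continue
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: branch row needs 6 fields")
        b = fields[0]
        if b not in tree.nodes:
            raise FormatError(f"{path}:{lineno}: branch {b!r} absent from species tree")
        vals = [float(x) for x in fields[1:]]
        if any(v < 0 for v in vals):
            raise FormatError(f"{path}:{lineno}: negative frequency on branch {b}")
        branch_rows[b] = BranchRow(
            duplications=vals[0],
            transfers_in=vals[1],
            losses=vals[2],
            originations=vals[3],
            copies=vals[4],
        )

    if not header_seen:
        raise FormatError(f"{path}: missing header line")
    summary = ReconciliationSummary(
        family_id=family_id,
        branch_rows=branch_rows,
        transfer_pairs=transfer_pairs,
        extinction_prob=extinction,
        n_samples=n_samples,
    )
    summary.validate(tree)
    return summary


def write_rec_summary(summary: ReconciliationSummary, path: str | Path) -> None:
    lines = [f"#family {summary.family_id}"]
    if summary.n_samples:
        lines.append(f"#n_samples {summary.n_samples}")
    lines.append("\t".join(_REC_COLUMNS))
    for b, row in summary.branch_rows.items():
        lines.append(
            "\t".join(
                [
                    b,
                    f"{row.duplications:.6g}",
                    f"{row.transfers_in:.6g}",
                    f"{row.losses:.6g}",
                    f"{row.originations:.6g}",
                    f"{row.copies:.6g}",
                ]
            )
        )
    if summary.transfer_pairs:
        lines.append("#transfers")
        for d, r, f in summary.transfer_pairs:
            lines.append(f"{d}\t{r}\t{f:.6g}")
    lines.append(f"#extinction {summary.extinction_prob:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Phylogenetic placements (jplace) and edge taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    edge_id: str
    like_weight_ratio: float
    likelihood: float


@dataclass
class PlacementProfile:
    """Likelihood-weighted placements of one family's sequences on an
    annotated reference tree.

    ``edge_taxonomy`` maps each edge id to its root-to-leaf taxonomic label
    path. Per sequence, like_weight_ratios sum to at most 1.
    """

    family_id: str
    placements: dict[str, list[Placement]]
    edge_taxonomy: dict[str, tuple[str, ...]]

    def validate(self) -> None:
        for seq, plist in self.placements.items():
            total = sum(p.like_weight_ratio for p in plist)
            if total > 1.0 + 1e-6:
                raise FormatError(
                    f"family {self.family_id}, sequence {seq}: "
                    f"like_weight_ratios sum to {total:.6g} > 1"
                )
            for p in plist:
                if p.edge_id not in self.edge_taxonomy:
                    raise FormatError(
                        f"family {self.family_id}: edge {p.edge_id!r} "
                        "missing from edge taxonomy"
                    )


def read_edge_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """TSV of edge_num -> semicolon-delimited root-to-leaf label path."""
    out: dict[str, tuple[str, ...]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 2:
            raise FormatError(f"edge taxonomy row needs 2 fields: {raw!r}")
        out[fields[0]] = tuple(x.strip() for x in fields[1].split(";") if x.strip())
    return out


def write_edge_taxonomy(taxonomy: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = ["#edge_num\tlabel_path"]
    for e, p in taxonomy.items():
        lines.append(f"{e}\t{';'.join(p)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_jplace(path: str | Path, taxonomy_path: str | Path) -> PlacementProfile:
    """Read a jplace (version >= 3) file plus its edge-taxonomy table.

    Placements per sequence come back sorted by descending like_weight_ratio.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    version = doc.get("version", 0)
    if int(version) < 3:
        raise FormatError(f"{path}: jplace version {version} < 3")
    fields = doc.get("fields", [])
    try:
        i_edge = fields.index("edge_num")
        i_like = fields.index("likelihood")
        i_lwr = fields.index("like_weight_ratio")
    except ValueError as exc:
        raise FormatError(f"{path}: missing required jplace fields") from exc

    taxonomy = read_edge_taxonomy(taxonomy_path)
    placements: dict[str, list[Placement]] = {}
    for entry in doc.get("placements", []):
        names = entry.get("n") or [nm for nm, _ in entry.get("nm", [])]
        plist = [
            Placement(
                edge_id=str(p[i_edge]),
                like_weight_ratio=float(p[i_lwr]),
                likelihood=float(p[i_like]),
            )
            for p in entry.get("p", [])
        ]
        plist.sort(key=lambda p: -p.like_weight_ratio)
        for name in names:
            placements[name] = list(plist)

    profile = PlacementProfile(
        family_id=doc.get("metadata", {}).get("family_id", path.stem),
        placements=placements,
        edge_taxonomy=taxonomy,
    )
    profile.validate()
    return profile


def write_jplace(profile: PlacementProfile, path: str | Path) -> None:
    doc = {
        "version": 3,
        "tree": "",
        "fields": ["edge_num", "likelihood", "like_weight_ratio"],
        "metadata": {"family_id": profile.family_id},
        "placements": [
            {
                "n": [seq],
                "p": [[p.edge_id, p.likelihood, p.like_weight_ratio] for p in plist],
            }
            for seq, plist in profile.placements.items()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Small TSV tables
# ---------------------------------------------------------------------------

def read_singletons(path: str | Path) -> dict[str, str]:
    """Singleton-family table: family_id -> leaf branch id."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 2:
            raise FormatError(f"singleton row needs 2 fields: {raw!r}")
        out[fields[0]] = fields[1]
    return out


def write_singletons(singletons: Mapping[str, str], path: str | Path) -> None:
    lines = ["#family_id\tleaf"]
    lines += [f"{f}\t{leaf}" for f, leaf in singletons.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Annotation table: protein_id -> set of COG/NOG ids (comma separated)."""
    out: dict[str, set[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        cogs = {c.strip() for c in fields[1].split(",") if c.strip()} if len(fields) > 1 else set()
        out[fields[0]] = cogs
    return out


def read_family_members(path: str | Path) -> dict[str, list[str]]:
    """Family membership table: family_id, protein_id (one row per member)."""
    out: dict[str, list[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise FormatError(f"family membership row needs >= 2 fields: {raw!r}")
        out.setdefault(fields[0], []).append(fields[1])
    return out
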