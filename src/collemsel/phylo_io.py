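"""Trees, trait tables and codon alignments: containers and file I/O.

Newick parsing is delegated to dendropy (quoted labels and bracket comments
are therefore handled natively); the package keeps its own lightweight node
structure because every downstream stage needs parent pointers, node ages in
Ma, and stable integer node ids.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

from .codes import GeneticCode, get_code

#: the shipped life-form scheme, in a fixed order used for tie-breaking
LIFE_FORMS = ("aquatic", "myrmecophilous", "euedaphic", "hemiedaphic",
              "epiedaphic")


class TreeError(ValueError):
    pass


class Node:
    """One node of a :class:`DatedTree`."""

    __slots__ = ("label", "length", "parent", "children", "age", "index")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length          # branch length to parent, Ma
        self.parent = None
        self.children = []
        self.age = None               # Ma before present
        self.index = None             # postorder index

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or self.index} age={self.age}>"


class DatedTree:
    """Rooted phylogeny with branch lengths and node ages in Ma.

    Node ages are computed from root-to-tip path sums: the tree height is the
    maximum root-to-tip distance and ``age(v) = height - depth(v)``, so on an
    ultrametric tree every tip has age 0 and ``age(parent) = age(child) +
    branch_length(child)`` for every branch.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # -- construction ----------------------------------------------------
    def _index(self):
        post = []

        def walk(node):
            for ch in node.children:
                ch.parent = node
                walk(ch)
            post.append(node)

        self.root.parent = None
        walk(self.root)
        self.postorder_nodes = post
        for i, nd in enumerate(post):
            nd.index = i
        self.leaves = [nd for nd in post if nd.is_leaf]
        labels = [lf.label for lf in self.leaves]
        if any(lb is None for lb in labels):
            raise TreeError("unlabeled terminal node")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate taxon labels")
        self.leaf_by_label = {lf.label: lf for lf in self.leaves}
        for nd in post:
            if nd is not self.root:
                if nd.length is None:
                    raise TreeError(f"missing branch length above "
                                    f"{nd.label or 'an internal node'}")
                if nd.length < 0:
                    raise TreeError("negative branch length")
        self._compute_ages()

    def _compute_ages(self):
        depth = {self.root: 0.0}
        for nd in reversed(self.postorder_nodes):   # preorder
            if nd is not self.root:
                depth[nd] = depth[nd.parent] + nd.length
        height = max(depth[lf] for lf in self.leaves)
        for nd in self.postorder_nodes:
            nd.age = height - depth[nd]
        self.height = height

    # -- properties ------------------------------------------------------
    @property
    def taxon_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def is_ultrametric(self) -> bool:
        if self.height == 0:
            return True
        tol = 1e-6 * self.height
        return all(abs(lf.age) <= tol for lf in self.leaves)

    def preorder(self):
        return reversed(self.postorder_nodes)

    def branches(self):
        """All non-root nodes (each identifies the branch to its parent)."""
        return [nd for nd in self.postorder_nodes if nd is not self.root]

    # -- queries ---------------------------------------------------------
    def mrca(self, taxa) -> Node:
        """Most recent common ancestor of a set of tip labels.

        A singleton set returns the terminal node itself.
        """
        taxa = list(taxa)
        if not taxa:
            raise TreeError("mrca of an empty taxon set")
        try:
            nodes = [self.leaf_by_label[t] for t in taxa]
        except KeyError as exc:
            raise TreeError(f"unknown taxon label: {exc.args[0]!r}") from None
        chain = []          # ancestor chain of the running MRCA, tip->root
        cur = nodes[0]
        while cur is not None:
            chain.append(cur)
            cur = cur.parent
        common = set(chain)
        for nd in nodes[1:]:
            cur = nd
            while cur not in common:
                cur = cur.parent
            chain = chain[chain.index(cur):]
            common = set(chain)
        return chain[0]

    def clade_leaves(self, node: Node) -> list[Node]:
        out = []

        def walk(nd):
            if nd.is_leaf:
                out.append(nd)
            for ch in nd.children:
                walk(ch)

        walk(node)
        return out

    def clade_nodes(self, node: Node) -> list[Node]:
        out = []

        def walk(nd):
            out.append(nd)
            for ch in nd.children:
                walk(ch)

        walk(node)
        return out

    def extract_clade(self, node: Node) -> "DatedTree":
        """A deep copy of the subtree rooted at ``node`` as a new tree."""

        def copy(nd):
            new = Node(nd.label, nd.length)
            new.children = [copy(ch) for ch in nd.children]
            return new

        root = copy(node)
        root.length = None
        return DatedTree(root)

    # -- serialisation ---------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                body = _quote(node.label)
            else:
                body = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
                if node.label:
                    body += _quote(node.label)
            if node.length is not None:
                body += f":{node.length:.17g}"
            return body

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_tree(newick_text: str, require_ultrametric: bool = False) -> DatedTree:
    """Parse a rooted newick string into a :class:`DatedTree`.

    Quoted labels and square-bracket comments are accepted (and comments
    stripped); polytomies are kept as-is.  Raises :class:`TreeError` on
    malformed input, negative branch lengths, or -- when
    ``require_ultrametric`` -- unequal tip depths (relative tolerance 1e-6).
    """
    try:
        dtree = dendropy.Tree.get(data=newick_text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"unparseable newick: {exc}") from None

    def convert(dnode):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        node.children = [convert(ch) for ch in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = None  # any root edge is ignored
    tree = DatedTree(root)
    if require_ultrametric and not tree.is_ultrametric:
        raise TreeError("tree is not ultrametric (tip depths differ by more "
                        "than relative 1e-6)")
    return tree


def read_tree(path, require_ultrametric: bool = False) -> DatedTree:
    return parse_tree(Path(path).read_text(),
                      require_ultrametric=require_ultrametric)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Mapping from taxon label to a discrete state."""

    states: tuple[str, ...]
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.states)

    def state_index(self, taxon: str) -> int:
        return self.states.index(self.assignments[taxon])

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in self.states}
        for st in self.assignments.values():
            out[st] += 1
        return out

    def taxa_in_state(self, state: str) -> list[str]:
        return [t for t, s in self.assignments.items() if s == state]

    def validate_against(self, tree: DatedTree, prune: bool = False):
        """Check taxon/tree consistency.

        Returns ``(table, tree)``; with ``prune`` untraited tips would have
        to be dropped by the caller -- here we simply restrict the table.
        Missing traits for tree tips are a hard error unless ``prune``.
        """
        tree_taxa = set(tree.taxon_labels)
        missing = tree_taxa - set(self.assignments)
        if missing and not prune:
            raise ValueError(f"tips without a trait assignment: "
                             f"{sorted(missing)}")
        extra = set(self.assignments) - tree_taxa
        table = TraitTable(self.states,
                           {t: s for t, s in self.assignments.items()
                            if t in tree_taxa})
        return table, sorted(extra)


def read_trait_table(path, header: bool = False,
                     states: tuple[str, ...] | None = LIFE_FORMS,
                     open_state_set: bool = False) -> TraitTable:
    """Read a two-column (taxon, state) TSV.

    With the default closed state set, states outside ``states`` are
    rejected; ``open_state_set`` infers the state set from the file (sorted,
    with any states from ``states`` first in their given order).
    """
    return parse_trait_table(Path(path).read_text(), header=header,
                             states=states, open_state_set=open_state_set)


def parse_trait_table(text: str, header: bool = False,
                      states: tuple[str, ...] | None = LIFE_FORMS,
                      open_state_set: bool = False) -> TraitTable:
    """Parse trait-table TSV text; see :func:`read_trait_table`."""
    rows = []
    for i, line in enumerate(text.splitlines()):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if header and i == 0:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 tab-separated columns, got "
                             f"{len(parts)}: {line!r}")
        rows.append((parts[0].strip(), parts[1].strip()))
    assignments = {}
    for taxon, state in rows:
        if taxon in assignments:
            raise ValueError(f"duplicate taxon in trait table: {taxon!r}")
        assignments[taxon] = state
    seen = sorted({s for _, s in rows})
    if open_state_set or states is None:
        base = [s for s in (states or ()) if s in seen]
        state_set = tuple(base + [s for s in seen if s not in base])
    else:
        unknown = [s for s in seen if s not in states]
        if unknown:
            raise ValueError(f"unknown states {unknown}; pass "
                             f"open_state_set=True to accept them")
        state_set = tuple(states)
    if len(state_set) < 2:
        raise ValueError("a discrete character needs at least 2 states")
    return TraitTable(state_set, assignments)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame codon matrix over taxa, bound to a genetic code.

    ``mask[taxon][site]`` is True when that codon contains a gap or an
    ambiguity character; ``site_mask`` flags columns where any taxon is
    masked (such columns are dropped from site totals and change counts).
    """

    gene_name: str
    sequences: dict[str, str]             # taxon -> nucleotide string
    code: GeneticCode
    mask: dict[str, list[bool]] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_name}: unequal sequence lengths")
        (nt_len,) = lengths
        if nt_len % 3:
            raise ValueError(f"{self.gene_name}: length {nt_len} not "
                             f"divisible by 3")
        self.n_codons = nt_len // 3
        if not self.mask:
            for taxon, seq in self.sequences.items():
                row = []
                for i in range(self.n_codons):
                    codon = seq[3 * i:3 * i + 3].upper()
                    row.append(not all(c in "ACGT" for c in codon))
                self.mask[taxon] = row
        for taxon, seq in self.sequences.items():
            for i in range(self.n_codons):
                if self.mask[taxon][i]:
                    continue
                codon = seq[3 * i:3 * i + 3].upper()
                if self.code.is_stop(codon):
                    raise ValueError(
                        f"{self.gene_name}: internal stop codon {codon} at "
                        f"codon {i + 1} in {taxon!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def site_mask(self) -> list[bool]:
        return [any(self.mask[t][i] for t in self.sequences)
                for i in range(self.n_codons)]

    def codon(self, taxon: str, site: int) -> str:
        return self.sequences[taxon][3 * site:3 * site + 3].upper()

    def codon_columns(self) -> list[dict[str, str]]:
        return [{t: self.codon(t, i) for t in self.sequences}
                for i in range(self.n_codons)]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")


def read_codon_alignment(path, genetic_code_id: int = 5,
                         gene_name: str | None = None) -> CodonAlignment:
    """Read an in-frame nucleotide FASTA as a codon alignment."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seqs = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return CodonAlignment(gene_name or path.stem, seqs,
                          get_code(genetic_code_id))


# ---------------------------------------------------------------------------
# packaged fixture and validation
# ---------------------------------------------------------------------------

def load_fixture():
    """The packaged 35-taxon dated tree and life-form table.

    The topology encodes the clade structure and node ages of the springtail
    study system this package models: 32 collembolan taxa (22 hemiedaphic,
    5 epiedaphic, 3 euedaphic, 1 myrmecophilous, 1 aquatic) plus three
    outgroups.  Ages not pinned by the described clades are interpolated.
    """
    data = importlib.resources.files("collemsel") / "data"
    tree = parse_tree((data / "fig1_topology.nwk").read_text(),
                      require_ultrametric=True)
    traits = parse_trait_table((data / "life_forms.tsv").read_text())
    return tree, traits


def validate_inputs(tree: DatedTree, traits: TraitTable | None = None,
                    alignments: list[CodonAlignment] | None = None) -> list[str]:
    """Cross-file consistency report; returns a list of problem strings."""
    problems = []
    if not tree.is_ultrametric:
        problems.append("tree is not ultrametric")
    tree_taxa = set(tree.taxon_labels)
    if traits is not None:
        missing = tree_taxa - set(traits.assignments)
        extra = set(traits.assignments) - tree_taxa
        if missing:
            problems.append(f"tips without trait: {sorted(missing)}")
        if extra:
            problems.append(f"traited taxa absent from tree: {sorted(extra)}")
    for aln in alignments or []:
        missing = tree_taxa - set(aln.taxa)
        extra = set(aln.taxa) - tree_taxa
        if missing:
            problems.append(f"{aln.gene_name}: tips without sequence: "
                            f"{sorted(missing)}")
        if extra:
            problems.append(f"{aln.gene_name}: sequences absent from tree: "
                            f"{sorted(extra)}")
    return problems
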