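"""Tree and alignment I/O for the delimitation pipeline.

Trees are rooted phylograms whose branch lengths are in expected
substitutions/site and whose internal nodes may carry two kinds of support:
a bootstrap percentage (0-100) and a posterior probability (0-1).  Both
common Newick dialects are accepted: supports as internal-node labels
(``(A,B)95:0.1``, ``(A,B)95/0.98:0.1``) and BEAST/NHX-style comment
metadata (``(A,B)[&posterior=0.98]:0.1``).  Internally both supports are
normalised into the node label in the canonical ``bootstrap/posterior``
form so that every dendropy structural operation (cloning, pruning,
writing) carries them along for free.

Alignments are thin wrappers around equal-length IUPAC DNA strings with
named locus partitions (half-open, 0-based column ranges) and an optional
excluded-column mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
from Bio import AlignIO
from Bio.Nexus import Nexus

__all__ = [
    "PhyloTree",
    "Alignment",
    "TreeError",
    "AlignmentError",
    "read_tree",
    "write_tree",
    "read_alignment",
    "write_alignment",
    "detect_conflicts",
]

IUPAC_DNA = set("ACGTUMRWSYKVHDBN-?")
UNAMBIGUOUS = set("ACGT")


class TreeError(ValueError):
    """Malformed, inconsistent or unusable tree input."""


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


def _parse_support_label(label, label_as="bootstrap"):
    """Parse an internal-node label into (bootstrap, posterior).

    Accepts "95", "0.98", "95/0.98", "/0.98", "95/"; bare numbers are
    interpreted according to *label_as*.  Non-numeric labels (clade names)
    yield (None, None).
    """
    if label is None:
        return None, None
    label = label.strip()
    if not label:
        return None, None
    if "/" in label:
        left, _, right = label.partition("/")
        bs = _maybe_float(left)
        pp = _maybe_float(right)
        return bs, pp
    value = _maybe_float(label)
    if value is None:
        return None, None
    if label_as == "posterior":
        return None, value
    return value, None


def _maybe_float(text):
    text = text.strip()
    if not text or text == "-":
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _format_support_label(bootstrap, posterior):
    if bootstrap is None and posterior is None:
        return None
    bs = "" if bootstrap is None else _fmt_num(bootstrap)
    if posterior is None:
        return bs
    return f"{bs}/{_fmt_num(posterior)}"


def _fmt_num(x):
    return f"{x:g}"


def get_support(node):
    """(bootstrap, posterior) for a node, parsed from its canonical label."""
    return _parse_support_label(getattr(node, "label", None))


def set_support(node, bootstrap=None, posterior=None):
    node.label = _format_support_label(bootstrap, posterior)


@dataclass
class PhyloTree:
    """A rooted phylogram wrapping a :class:`dendropy.Tree`.

    Tip labels are unique non-empty strings; internal-node labels hold
    support in canonical ``bootstrap/posterior`` form (see module docs).
    """

    tree: dendropy.Tree
    _dist_cache: tuple | None = field(default=None, repr=False, compare=False)

    # -- construction -------------------------------------------------

    @classmethod
    def from_string(cls, text, schema="newick", label_as="bootstrap"):
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema=schema,
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"could not parse {schema} tree: {exc}") from exc
        return cls._finalise(tree, label_as)

    @classmethod
    def from_file(cls, path, schema="newick", label_as="bootstrap"):
        try:
            tree = dendropy.Tree.get(
                path=str(path),
                schema=schema,
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=True,
            )
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise TreeError(f"could not parse {schema} tree {path}: {exc}") from exc
        return cls._finalise(tree, label_as)

    @classmethod
    def _finalise(cls, tree, label_as):
        # normalise supports into canonical labels, folding in comment metadata
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            bs, pp = _parse_support_label(nd.label, label_as=label_as)
            for ann in nd.annotations:
                if ann.name.lower() in ("posterior", "pp", "posterior_probability"):
                    val = _maybe_float(str(ann.value))
                    if val is not None:
                        pp = val
                elif ann.name.lower() in ("bootstrap", "bs", "support") and bs is None:
                    val = _maybe_float(str(ann.value))
                    if val is not None:
                        bs = val
            nd.label = _format_support_label(bs, pp)
        tree.is_rooted = True
        obj = cls(tree=tree)
        obj.validate()
        return obj

    def validate(self):
        self.tree.is_rooted = True
        seen = set()
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if not label:
                raise TreeError("tip with empty label")
            if label in seen:
                raise TreeError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                who = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                raise TreeError(f"negative branch length at node {who!r}")
            bs, pp = get_support(nd)
            if bs is not None and not (0 <= bs <= 100):
                raise TreeError(f"bootstrap out of range: {bs}")
            if pp is not None and not (0 <= pp <= 1):
                raise TreeError(f"posterior out of range: {pp}")
        if len(seen) >= 2 and len(self.tree.seed_node.child_nodes()) < 2:
            # collapse a degree-one root (common artifact of pruning)
            self.tree.suppress_unifurcations()
            if len(self.tree.seed_node.child_nodes()) < 2:
                raise TreeError("tree is not rooted with >= 2 root children")
        return self

    # -- basic queries ------------------------------------------------

    def tips(self):
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def tip_set(self):
        return frozenset(self.tips())

    def __len__(self):
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def has_branch_lengths(self):
        return all(
            nd.edge.length is not None
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def _require_lengths(self):
        if not self.has_branch_lengths:
            raise TreeError("operation requires branch lengths on all edges")

    def mrca(self, tip_labels):
        tip_labels = set(tip_labels)
        missing = tip_labels - self.tip_set()
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        if len(tip_labels) == 1:
            (label,) = tip_labels
            return self.find_tip(label)
        return self.tree.mrca(taxon_labels=list(tip_labels))

    def find_tip(self, label):
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise TreeError(f"unknown tip: {label!r}")

    @staticmethod
    def clade_tips(node):
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    def sister_tips(self, node):
        """Tip set of the sister group (other children of the parent)."""
        parent = node.parent_node
        if parent is None:
            raise TreeError("root has no sister group")
        out = set()
        for sib in parent.child_nodes():
            if sib is not node:
                out |= self.clade_tips(sib)
        return frozenset(out)

    # -- distances ----------------------------------------------------

    def distance_matrix(self):
        """(ordered tip labels, dense numpy patristic matrix), cached."""
        if self._dist_cache is None:
            import numpy as np

            self._require_lengths()
            labels = sorted(self.tips())
            index = {lab: i for i, lab in enumerate(labels)}
            pdm = self.tree.phylogenetic_distance_matrix()
            n = len(labels)
            mat = np.zeros((n, n))
            taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in index}
            labs = list(taxa)
            for i, la in enumerate(labs):
                for lb in labs[i + 1 :]:
                    d = pdm.patristic_distance(taxa[la], taxa[lb])
                    mat[index[la], index[lb]] = mat[index[lb], index[la]] = d
            self._dist_cache = (labels, mat)
        return self._dist_cache

    def patristic_distance(self, tip_a, tip_b):
        if tip_a == tip_b:
            self.find_tip(tip_a)
            return 0.0
        labels, mat = self.distance_matrix()
        try:
            ia, ib = labels.index(tip_a), labels.index(tip_b)
        except ValueError as exc:
            raise TreeError(f"unknown tip in {tip_a!r}, {tip_b!r}") from exc
        return float(mat[ia, ib])

    def node_depth(self, node, from_node=None):
        """Path length from *from_node* (default root) down to *node*."""
        total = 0.0
        while node is not from_node and node.parent_node is not None:
            if node.edge.length is not None:
                total += node.edge.length
            node = node.parent_node
            if from_node is None and node.parent_node is None:
                break
        return total

    # -- manipulation -------------------------------------------------

    def _clone(self):
        # clone into a private taxon namespace: dendropy's depth-1 clone
        # shares the namespace, so in-place pruning would corrupt the source
        tree = self.tree.clone(depth=1)
        tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
        return tree

    def copy(self):
        return PhyloTree(tree=self._clone())

    def prune_tips(self, tip_labels):
        """Remove the given tips; unary nodes suppressed with lengths summed."""
        tip_labels = set(tip_labels)
        missing = tip_labels - self.tip_set()
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        keep = self.tip_set() - tip_labels
        if len(keep) < 2:
            raise TreeError("fewer than 2 tips would remain")
        return self.retain_tips(keep)

    def retain_tips(self, tip_labels):
        tip_labels = set(tip_labels)
        missing = tip_labels - self.tip_set()
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        if len(tip_labels) < 2:
            raise TreeError("fewer than 2 tips would remain")
        if tip_labels == self.tip_set():
            return self.copy()
        tree = self._clone()
        tree.retain_taxa_with_labels(list(tip_labels))
        tree.purge_taxon_namespace()
        out = PhyloTree(tree=tree)
        out.validate()
        return out

    # -- serialisation ------------------------------------------------

    def to_string(self, schema="newick"):
        return self.tree.as_string(
            schema=schema, unquoted_underscores=True, suppress_rooting=True
        )

    def to_file(self, path, schema="newick"):
        with open(path, "w") as fh:
            fh.write(self.to_string(schema=schema))


def read_tree(path, format="newick", label_as="bootstrap"):
    if format not in ("newick", "nexus"):
        raise TreeError(f"unsupported tree format: {format}")
    return PhyloTree.from_file(path, schema=format, label_as=label_as)


def write_tree(tree, path, format="newick"):
    tree.to_file(path, schema=format)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Equal-length IUPAC DNA sequences with locus partitions and a mask.

    Partitions are named half-open 0-based column ranges; the mask is a set
    of column indices excluded from downstream site counting/collapsing.
    User-facing reports are 1-based; everything here is 0-based.
    """

    ids: tuple
    seqs: tuple
    partitions: dict = field(default_factory=dict)
    mask: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            short = min(self.seqs, key=len)
            sid = self.ids[self.seqs.index(short)]
            raise AlignmentError(
                f"ragged alignment: sequence {sid!r} has length {len(short)}"
            )
        for sid, seq in zip(self.ids, self.seqs):
            for col, ch in enumerate(seq):
                if ch not in IUPAC_DNA:
                    raise AlignmentError(
                        f"illegal character {ch!r} in {sid!r} at column {col + 1}"
                    )
        length = self.length
        spans = sorted(self.partitions.values())
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise AlignmentError("overlapping partitions")
        for name, (s, e) in self.partitions.items():
            if not (0 <= s <= e <= length):
                raise AlignmentError(f"partition {name!r} out of bounds")
        if any(c < 0 or c >= length for c in self.mask):
            raise AlignmentError("mask index out of range")

    @property
    def length(self):
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def nseq(self):
        return len(self.ids)

    def sequence(self, sid):
        try:
            return self.seqs[self.ids.index(sid)]
        except ValueError as exc:
            raise AlignmentError(f"unknown sequence id: {sid!r}") from exc

    def column(self, i):
        return "".join(seq[i] for seq in self.seqs)

    def subset_rows(self, keep_ids):
        keep = [i for i, sid in enumerate(self.ids) if sid in set(keep_ids)]
        return replace(
            self,
            ids=tuple(self.ids[i] for i in keep),
            seqs=tuple(self.seqs[i] for i in keep),
        )

    def drop_columns(self, cols):
        """New alignment without *cols*; partitions re-indexed, mask remapped."""
        cols = set(cols)
        bad = [c for c in cols if c < 0 or c >= self.length]
        if bad:
            raise AlignmentError(f"column index out of range: {sorted(bad)[0]}")
        keep = [c for c in range(self.length) if c not in cols]
        newpos = {c: i for i, c in enumerate(keep)}
        seqs = tuple("".join(seq[c] for c in keep) for seq in self.seqs)
        parts = {}
        for name, (s, e) in self.partitions.items():
            kept_in = [newpos[c] for c in keep if s <= c < e]
            if kept_in:
                parts[name] = (kept_in[0], kept_in[-1] + 1)
            else:
                parts[name] = (len(keep), len(keep))
        mask = frozenset(newpos[c] for c in self.mask if c in newpos)
        return Alignment(ids=self.ids, seqs=seqs, partitions=parts, mask=mask)

    def included_columns(self):
        return [c for c in range(self.length) if c not in self.mask]


def _normalise_seq(seq):
    return str(seq).upper().replace("U", "T").replace(".", "-")


def read_alignment(path, format="fasta"):
    """Read a FASTA or NEXUS alignment; NEXUS charsets become partitions."""
    if format not in ("fasta", "nexus"):
        raise AlignmentError(f"unsupported alignment format: {format}")
    partitions = {}
    if format == "nexus":
        try:
            nex = Nexus.Nexus(str(path))
        except Exception as exc:
            raise AlignmentError(f"could not parse NEXUS {path}: {exc}") from exc
        ids = tuple(str(t) for t in nex.taxlabels) if nex.taxlabels else tuple(
            nex.matrix
        )
        seqs = tuple(_normalise_seq(nex.matrix[t]) for t in ids)
        for name, cols in (nex.charsets or {}).items():
            cols = sorted(cols)
            if cols and cols == list(range(cols[0], cols[-1] + 1)):
                partitions[name] = (cols[0], cols[-1] + 1)
    else:
        try:
            msa = AlignIO.read(str(path), "fasta")
        except Exception as exc:
            raise AlignmentError(f"could not parse FASTA {path}: {exc}") from exc
        ids = tuple(rec.id for rec in msa)
        seqs = tuple(_normalise_seq(rec.seq) for rec in msa)
    return Alignment(ids=ids, seqs=seqs, partitions=partitions)


def write_alignment(alignment, path):
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Topological conflict detection
# ---------------------------------------------------------------------------


def _supported_bipartitions(tree, threshold):
    """Clade tip-sets with bootstrap support >= threshold (non-trivial only)."""
    full = tree.tip_set()
    out = {}
    for nd in tree.tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        bs, pp = get_support(nd)
        if bs is None or bs < threshold:
            continue
        clade = PhyloTree.clade_tips(nd)
        if 1 < len(clade) < len(full):
            out[clade] = bs
    return out


def _incompatible(a, b, universe):
    ra, rb = universe - a, universe - b
    return all((a & b, a & rb, ra & b, ra & rb))


def detect_conflicts(tree_a, tree_b, support_threshold=70.0):
    """Pairs of well-supported, mutually incompatible bipartitions.

    Both trees are restricted to their shared tips; an empty result means
    the datasets are combinable at the given bootstrap threshold.
    """
    shared = tree_a.tip_set() & tree_b.tip_set()
    if len(shared) < 4:
        if not shared:
            raise TreeError("trees share no tips")
        return set()
    ra = tree_a if tree_a.tip_set() == shared else tree_a.retain_tips(shared)
    rb = tree_b if tree_b.tip_set() == shared else tree_b.retain_tips(shared)
    splits_a = _supported_bipartitions(ra, support_threshold)
    splits_b = _supported_bipartitions(rb, support_threshold)
    conflicts = set()
    for ca in splits_a:
        for cb in splits_b:
            if _incompatible(ca, cb, shared):
                conflicts.add(frozenset((ca, cb)))
    return conflicts
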