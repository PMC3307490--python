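"""Ingestion and standardization of source trees and sequence metadata.

Source trees collected from the literature (and gene trees built from sequence
data) use heterogeneous taxonomies.  Before they can be combined into one
matrix they are standardized against a reference species list: synonyms are
mapped to valid names, higher-taxon terminals are replaced by their
name-bearing type species, and taxa flagged for deletion (e.g. non-ingroup
species) are pruned.  When synonymy makes one species appear on several leaves
of the same tree, every placement permutation is emitted as a separate record
so that the duplicated evidence can be down-weighted later.

Sequence metadata filtering mirrors the rules used to assemble per-gene data
sets from a GenBank dump: minimum lengths (with a lower floor for tRNAs), a
cap on undefined nucleotides, retention of only the longest sequence lengths
per species and gene, and a minimum number of species per gene.
"""

from __future__ import annotations

import csv
import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import dendropy

from ._tree_utils import leaf_labels

logger = logging.getLogger(__name__)

DELETE = "DELETE"

#: The twelve subjective data categories used to group literature source trees
#: for non-independence down-weighting.
LITERATURE_CATEGORIES = (
    "karyotype",
    "scent gland",
    "isozyme",
    "general morphology",
    "mixed morphology and molecular",
    "DNA-DNA hybridization",
    "immunological distances",
    "mixed molecular",
    "satellite DNA",
    "hemoglobin",
    "crystalline",
    "vocalization",
)

MOLECULAR_GENE_CATEGORY = "molecular-gene"


class StandardizationError(ValueError):
    """A source tree cannot be standardized (unknown label, or uninformative)."""


@dataclass(frozen=True)
class TaxonRegistry:
    """Reference taxonomy: valid species names, synonyms and type species.

    ``synonym_map`` maps aliases to valid names, or to the :data:`DELETE`
    sentinel for names that must be pruned outright (e.g. taxa outside the
    ingroup).  ``type_species_map`` maps higher-taxon names to the valid name
    of their name-bearing type species.
    """

    valid_names: frozenset
    synonym_map: dict = field(default_factory=dict)
    type_species_map: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "valid_names", frozenset(self.valid_names))
        for alias, target in self.synonym_map.items():
            if target != DELETE and target not in self.valid_names:
                raise ValueError(f"synonym target {target!r} (for {alias!r}) is not a valid name")
        for taxon, sp in self.type_species_map.items():
            if sp not in self.valid_names:
                raise ValueError(f"type species {sp!r} (for {taxon!r}) is not a valid name")

    def resolve(self, label: str) -> Optional[str]:
        """Map a leaf label to a valid name, DELETE, or None (unknown)."""
        if label in self.valid_names:
            return label
        if label in self.synonym_map:
            return self.synonym_map[label]
        if label in self.type_species_map:
            return self.type_species_map[label]
        return None

    @classmethod
    def from_csv(cls, valid_names: Iterable[str], synonyms_path: str) -> "TaxonRegistry":
        """Build a registry from a species list and a two-column CSV
        (alias,target) where target may be the DELETE sentinel."""
        syn = {}
        with open(synonyms_path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                syn[row[0].strip()] = row[1].strip()
        return cls(valid_names=frozenset(valid_names), synonym_map=syn)


@dataclass
class SourceTreeRecord:
    """A standardized source tree plus its bookkeeping.

    ``permutation_count`` is the number of sibling records emitted from the
    same original tree (1 for an unduplicated tree); weighting divides by it
    so that the original tree's total evidential weight is conserved.
    """

    tree: dendropy.Tree
    rooted: bool
    publication_id: str
    data_category: str
    permutation_count: int = 1
    gene_name: Optional[str] = None

    def __post_init__(self):
        if self.permutation_count < 1:
            raise ValueError("permutation_count must be >= 1")
        labels = leaf_labels(self.tree)
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for node in self.tree.preorder_internal_node_iter():
            s = node_support(node)
            if s is not None and not (0.0 <= s <= 100.0):
                raise ValueError(f"support {s} outside [0, 100]")

    @property
    def taxa(self) -> frozenset:
        return frozenset(leaf_labels(self.tree))


def node_support(node: dendropy.Node) -> Optional[float]:
    """Bootstrap support of an internal node, parsed from its label, or None."""
    if node.is_leaf() or node.label in (None, ""):
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# taxon standardization
# ---------------------------------------------------------------------------

def read_source_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Parse a raw source tree, tolerating duplicate leaf labels (which the
    synonymization step resolves) and keeping underscores verbatim."""
    import os

    kwargs = dict(
        schema=schema,
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
        preserve_underscores=True,
    )
    if os.path.exists(source):
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)


def _leaf_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _tree_to_struct(tree: dendropy.Tree):
    """Nested (children, label, support) representation with leaf indices."""
    leaves = []

    def rec(node):
        if node.is_leaf():
            leaves.append(_leaf_name(node))
            return ("leaf", len(leaves) - 1)
        return ("int", node_support(node), [rec(c) for c in node.child_nodes()])

    return rec(tree.seed_node), leaves


def _struct_to_tree(struct, names: dict, rooted: bool) -> Optional[dendropy.Tree]:
    """Rebuild a dendropy tree keeping only leaves present in *names*
    (index -> final label); unifurcations are suppressed."""

    def rec(node):
        if node[0] == "leaf":
            return ("leaf", names[node[1]]) if node[1] in names else None
        kids = [k for k in (rec(c) for c in node[2]) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return ("int", node[1], kids)

    built = rec(struct)
    if built is None or built[0] == "leaf":
        return None
    labels = sorted(names.values())
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = rooted

    def attach(parent, node):
        if node[0] == "leaf":
            parent.add_child(dendropy.Node(taxon=tns.get_taxon(node[1])))
        else:
            n = dendropy.Node()
            if node[1] is not None:
                n.label = str(node[1])
            parent.add_child(n)
            for c in node[2]:
                attach(n, c)

    # the root itself
    root_struct = built
    if root_struct[1] is not None:
        tree.seed_node.label = str(root_struct[1])
    for c in root_struct[2]:
        attach(tree.seed_node, c)
    return tree


def standardize_taxa(
    tree: dendropy.Tree,
    registry: TaxonRegistry,
    publication_id: str = "",
    data_category: str = LITERATURE_CATEGORIES[3],
    rooted: bool = False,
    gene_name: Optional[str] = None,
    max_permutations: int = 64,
) -> list[SourceTreeRecord]:
    """Standardize leaf names against *registry* and emit placement permutations.

    Unknown labels reject the tree.  DELETE-marked leaves are pruned, and (as
    they typically mark non-ingroup taxa that positioned the root) their
    presence marks the record as rooted.  If synonymy leaves one species on
    ``k > 1`` leaves, one record is emitted per way of keeping the species at
    exactly one of those positions; the cartesian product over duplicated
    species is capped at *max_permutations* (beyond which only the
    first-encountered placements are kept, with ``permutation_count = 1``).
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise StandardizationError("tree has fewer than 2 leaves")

    struct, orig_labels = _tree_to_struct(tree)
    resolved: dict[int, str] = {}
    any_deleted = False
    for idx, label in enumerate(orig_labels):
        target = registry.resolve(label)
        if target is None:
            raise StandardizationError(f"unknown label {label!r} has no registry entry")
        if target == DELETE:
            any_deleted = True
            continue
        resolved[idx] = target

    is_rooted = rooted or any_deleted

    # positions per species, in leaf order
    positions: dict[str, list[int]] = {}
    for idx in sorted(resolved):
        positions.setdefault(resolved[idx], []).append(idx)
    duplicated = {sp: pos for sp, pos in positions.items() if len(pos) > 1}

    n_perm = 1
    for pos in duplicated.values():
        n_perm *= len(pos)

    if n_perm > max_permutations:
        logger.warning(
            "%s: %d placement permutations exceed cap %d; keeping first-encountered placements",
            publication_id, n_perm, max_permutations,
        )
        choices = [(pos[0],) for pos in duplicated.values()]
        combos = [tuple(c[0] for c in choices)]
        n_perm = 1
    else:
        combos = list(itertools.product(*duplicated.values())) if duplicated else [()]

    dup_species = list(duplicated)
    records = []
    for combo in combos:
        keep = dict(resolved)
        for sp, chosen in zip(dup_species, combo):
            for idx in duplicated[sp]:
                if idx != chosen:
                    del keep[idx]
        sub = _struct_to_tree(struct, keep, is_rooted)
        if sub is None or sum(1 for _ in sub.leaf_node_iter()) < 2:
            raise StandardizationError("uninformative after standardization")
        records.append(
            SourceTreeRecord(
                tree=sub,
                rooted=is_rooted,
                publication_id=publication_id,
                data_category=data_category,
                permutation_count=n_perm,
                gene_name=gene_name,
            )
        )
    return records


# ---------------------------------------------------------------------------
# sequence metadata filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """Metadata for one sequence: species, gene, length and N content."""

    species: str
    gene: str
    length: int
    fraction_undefined: float = 0.0
    is_trna: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not (0.0 <= self.fraction_undefined <= 1.0):
            raise ValueError("fraction_undefined must lie in [0, 1]")


def filter_sequences(
    records: Sequence[SequenceRecord],
    min_len_bp: int = 200,
    min_len_trna_bp: int = 50,
    min_species: int = 20,
    max_undefined: float = 0.05,
    keep_longest: int = 10,
) -> list[SequenceRecord]:
    """Apply the sequence-retention rules.

    A record survives if its length reaches the floor for its class (tRNA or
    not) and its undefined fraction is at most *max_undefined*; per
    species-gene pair only records among the *keep_longest* longest distinct
    lengths are retained; genes left with *min_species* or fewer species are
    dropped entirely.
    """
    stage1 = [
        r for r in records
        if r.length >= (min_len_trna_bp if r.is_trna else min_len_bp)
        and r.fraction_undefined <= max_undefined
    ]

    lengths_by_pair: dict[tuple, set] = {}
    for r in stage1:
        lengths_by_pair.setdefault((r.species, r.gene), set()).add(r.length)
    allowed = {
        pair: set(sorted(lens, reverse=True)[:keep_longest])
        for pair, lens in lengths_by_pair.items()
    }
    stage2 = [r for r in stage1 if r.length in allowed[(r.species, r.gene)]]

    species_by_gene: dict[str, set] = {}
    for r in stage2:
        species_by_gene.setdefault(r.gene, set()).add(r.species)
    return [r for r in stage2 if len(species_by_gene[r.gene]) > min_species]


def select_consensus_closest(sequences: Sequence[str]) -> str:
    """Pick the aligned sequence nearest the column-majority consensus.

    Ties (equal mismatch count, or equal column majorities) resolve by input
    order and are logged.  A singleton is returned unchanged.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if len(sequences) == 1:
        return sequences[0]
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must share a length")

    consensus = []
    for col in range(length):
        counts: dict[str, int] = {}
        order: dict[str, int] = {}
        for i, s in enumerate(sequences):
            ch = s[col]
            counts[ch] = counts.get(ch, 0) + 1
            order.setdefault(ch, i)
        best = max(counts, key=lambda ch: (counts[ch], -order[ch]))
        if sum(1 for ch in counts if counts[ch] == counts[best]) > 1:
            logger.debug("consensus tie at column %d resolved by input order", col)
        consensus.append(best)
    consensus = "".join(consensus)

    dists = [sum(a != b for a, b in zip(s, consensus)) for s in sequences]
    best_d = min(dists)
    winners = [i for i, d in enumerate(dists) if d == best_d]
    if len(winners) > 1:
        logger.debug("consensus-distance tie among %s resolved by input order", winners)
    return sequences[winners[0]]


def _overlap(a: str, b: str) -> int:
    return sum(
        1 for x, y in zip(a, b)
        if x not in "-N?" and y not in "-N?"
    )


def check_pairwise_overlap(
    alignment: Sequence[tuple],
    min_overlap_bp: int = 100,
    min_overlap_trna_bp: int = 20,
    is_trna: bool = False,
) -> list[tuple]:
    """Report overlap (shared non-gap, non-N columns) for every sequence pair.

    *alignment* is a sequence of ``(name, aligned_sequence)`` pairs.  Returns
    ``(name_a, name_b, overlap, passed)`` tuples.
    """
    threshold = min_overlap_trna_bp if is_trna else min_overlap_bp
    report = []
    for (na, sa), (nb, sb) in itertools.combinations(alignment, 2):
        ov = _overlap(sa, sb)
        report.append((na, nb, ov, ov >= threshold))
    return report


def prune_to_overlap(
    alignment: Sequence[tuple],
    min_overlap_bp: int = 100,
    min_overlap_trna_bp: int = 20,
    is_trna: bool = False,
) -> list[tuple]:
    """Greedily drop sequences (fewest-overlapping first) until all pairs pass."""
    current = list(alignment)
    threshold = min_overlap_trna_bp if is_trna else min_overlap_bp
    while len(current) > 1:
        fails: dict[str, int] = {name: 0 for name, _ in current}
        totals: dict[str, int] = {name: 0 for name, _ in current}
        any_fail = False
        for (na, sa), (nb, sb) in itertools.combinations(current, 2):
            ov = _overlap(sa, sb)
            totals[na] += ov
            totals[nb] += ov
            if ov < threshold:
                fails[na] += 1
                fails[nb] += 1
                any_fail = True
        if not any_fail:
            break
        # drop the worst offender: most failing pairs, then least total overlap
        order = {name: i for i, (name, _) in enumerate(current)}
        victim = max(
            fails, key=lambda n: (fails[n], -totals[n], -order[n])
        )
        logger.debug("pruning %s for insufficient pairwise overlap", victim)
        current = [(n, s) for n, s in current if n != victim]
    return current


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_TREE_LINE = re.compile(
    r"TREE\s+\S+\s*=\s*"
    r"\[&publication_id=(?P<pub>[^,\]]*),category=(?P<cat>[^,\]]*),"
    r"permutation_count=(?P<perm>\d+),rooted=(?P<rooted>yes|no)\]\s*"
    r"(?P<newick>.+?;)",
    re.IGNORECASE,
)


def read_records_nexus(path: str) -> list[SourceTreeRecord]:
    """Read records written by :func:`write_records_nexus`."""
    records = []
    with open(path) as fh:
        for line in fh:
            m = _TREE_LINE.search(line)
            if not m:
                continue
            tree = dendropy.Tree.get(data=m.group("newick"), schema="newick")
            records.append(
                SourceTreeRecord(
                    tree=tree,
                    rooted=(m.group("rooted") == "yes"),
                    publication_id=m.group("pub"),
                    data_category=m.group("cat"),
                    permutation_count=int(m.group("perm")),
                )
            )
    return records


def write_records_nexus(records: Sequence[SourceTreeRecord], path: str) -> None:
    """Write standardized source trees to a NEXUS TREES block, one tree per
    record, with a comment recording publication, category and permutation count."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TREES;\n")
        for i, rec in enumerate(records):
            newick = rec.tree.as_string(schema="newick", suppress_rooting=True).strip()
            meta = (
                f"[&publication_id={rec.publication_id},"
                f"category={rec.data_category},"
                f"permutation_count={rec.permutation_count},"
                f"rooted={'yes' if rec.rooted else 'no'}]"
            )
            fh.write(f"    TREE source_{i + 1} = {meta} {newick}\n")
        fh.write("END;\n")
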