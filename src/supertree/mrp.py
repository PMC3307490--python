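"""Matrix representation with parsimony (MRP) encoding and weighting.

Each internal node of a source tree becomes one partial binary character:
species descended from the node are scored 1, other species on the tree 0,
and species absent from the tree ``?``.  Semi-rooted coding adds a fictional
outgroup taxon scored 0 when the source tree is rooted and ``?`` when it is
unrooted, so rooted and unrooted evidence can be combined in one matrix.

Characters carry a three-layer weight: the node's bootstrap support (or the
matrix-wide mean support for nodes lacking one), divided by the number of
source trees in the same literature data category (non-independence of data
sources), and divided by the number of placement permutations emitted from
the same original tree.  A taxonomy seed tree, added only to guarantee taxon
overlap, is down-weighted to a tenth of the minimum weight of any real
character so real source trees can always overrule it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._tree_utils import clade_leafsets, leaf_labels, tree_from_clades
from .sources import MOLECULAR_GENE_CATEGORY, SourceTreeRecord, node_support

logger = logging.getLogger(__name__)

#: integer codes used in array form: state 0, state 1, missing
MISSING = 2


@dataclass
class MRPCharacter:
    """One partial binary character (a source-tree node)."""

    states: dict  # species -> 0 or 1; species not scored are missing
    weight: float = 1.0
    source_id: str = ""
    support: Optional[float] = None
    data_category: str = ""
    permutation_count: int = 1

    def __post_init__(self):
        ones = sum(1 for v in self.states.values() if v == 1)
        zeros = sum(1 for v in self.states.values() if v == 0)
        if ones < 2 or zeros < 1:
            raise ValueError("character is uninformative (needs >=2 ones and >=1 zero)")
        if self.support is not None and not (0.0 <= self.support <= 100.0):
            raise ValueError("support must lie in [0, 100]")


@dataclass
class MRPMatrix:
    """Taxa x characters matrix with per-character weights and provenance."""

    taxa: list
    outgroup: str
    characters: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels")
        if self.outgroup not in self.taxa:
            raise ValueError("outgroup label must be among the taxa")
        known = set(self.taxa)
        for c in self.characters:
            extra = set(c.states) - known
            if extra:
                raise ValueError(f"character scores unknown taxa: {sorted(extra)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def to_arrays(self):
        """(ntaxa x nchar) uint8 state-code array and float weight vector."""
        codes = np.full((len(self.taxa), len(self.characters)), MISSING, dtype=np.uint8)
        index = {t: i for i, t in enumerate(self.taxa)}
        for j, c in enumerate(self.characters):
            for sp, v in c.states.items():
                codes[index[sp], j] = v
        weights = np.array([c.weight for c in self.characters], dtype=float)
        return codes, weights


def encode_tree(record: SourceTreeRecord, outgroup_label: str = "MRP_outgroup") -> list[MRPCharacter]:
    """Encode one standardized source tree as partial binary characters.

    One character per informative internal node (the root and trivial nodes
    are skipped).  The fictional outgroup is scored 0 for rooted source trees
    and left missing for unrooted ones.  A star tree yields no characters.
    """
    tree = record.tree
    species = leaf_labels(tree)
    if len(species) < 3:
        raise ValueError("need at least 3 leaves to encode")
    if outgroup_label in species:
        raise ValueError("outgroup label collides with a species name")
    universe = set(species)
    sets = clade_leafsets(tree)
    chars = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = sets[node]
        if len(clade) < 2 or len(universe - clade) < 1:
            continue
        states = {sp: (1 if sp in clade else 0) for sp in species}
        if record.rooted:
            states[outgroup_label] = 0
        chars.append(
            MRPCharacter(
                states=states,
                weight=1.0,
                source_id=record.publication_id,
                support=node_support(node),
                data_category=record.data_category,
                permutation_count=record.permutation_count,
            )
        )
    return chars


def matrix_from_records(
    records: Sequence[SourceTreeRecord], outgroup_label: str = "MRP_outgroup"
) -> MRPMatrix:
    """Encode and pool a set of standardized records into one matrix."""
    taxa: list = []
    seen = set()
    chars: list = []
    for rec in records:
        for sp in leaf_labels(rec.tree):
            if sp not in seen:
                seen.add(sp)
                taxa.append(sp)
        chars.extend(encode_tree(rec, outgroup_label))
    taxa.append(outgroup_label)
    return MRPMatrix(taxa=taxa, outgroup=outgroup_label, characters=chars)


def assign_weights(
    matrix: MRPMatrix,
    category_counts: Optional[dict] = None,
    seed_source_id: Optional[str] = None,
    seed_factor: float = 10.0,
) -> MRPMatrix:
    """Apply the three-layer weighting scheme in place (and return the matrix).

    Base weight is the node's bootstrap where present, else the mean bootstrap
    over all support-bearing characters (neutral weighting); if no character
    carries support at all, the base weight is 1 for every character.  The
    base is divided by the character's literature-category tree count and its
    permutation count.  Seed-tree characters finally receive one
    ``seed_factor``-th of the minimum weight among all non-seed characters.
    """
    category_counts = category_counts or {}
    supports = [c.support for c in matrix.characters if c.support is not None]
    mean_support = float(np.mean(supports)) if supports else None

    non_seed_weights = []
    for c in matrix.characters:
        if mean_support is None:
            base = 1.0
        else:
            base = c.support if c.support is not None else mean_support
        w = base
        is_seed = seed_source_id is not None and c.source_id == seed_source_id
        if not is_seed and c.data_category != MOLECULAR_GENE_CATEGORY:
            w /= max(1, category_counts.get(c.data_category, 1))
        w /= max(1, c.permutation_count)
        c.weight = w
        if not is_seed:
            non_seed_weights.append(w)

    if seed_source_id is not None:
        seed_chars = [c for c in matrix.characters if c.source_id == seed_source_id]
        if not seed_chars:
            logger.warning("seed source %r not found in matrix; seed step skipped", seed_source_id)
        elif non_seed_weights:
            seed_w = min(non_seed_weights) / seed_factor
            for c in seed_chars:
                c.weight = seed_w
    return matrix


def concatenate(matrices: Sequence[MRPMatrix]) -> MRPMatrix:
    """Pool matrices over a shared fictional outgroup; taxa are unioned and
    characters appended with provenance preserved."""
    if not matrices:
        raise ValueError("need at least one matrix")
    outgroup = matrices[0].outgroup
    if any(m.outgroup != outgroup for m in matrices):
        raise ValueError("matrices must share the outgroup label")
    taxa: list = []
    seen = set()
    for m in matrices:
        for t in m.taxa:
            if t == outgroup:
                continue
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    if outgroup in seen:
        raise ValueError(f"outgroup label {outgroup!r} conflicts with a species name")
    taxa.append(outgroup)
    chars = [c for m in matrices for c in m.characters]
    return MRPMatrix(taxa=taxa, outgroup=outgroup, characters=chars)


def decode_single_source(
    characters: Sequence[MRPCharacter], outgroup_label: str = "MRP_outgroup"
):
    """Rebuild the (rooted) source topology from one tree's characters.

    Valid only for characters encoded from a single tree, whose state-1 sets
    are mutually compatible clades; used for round-trip checks.  The fictional
    outgroup is excluded from the reconstruction.
    """
    scored = sorted(
        {sp for c in characters for sp in c.states} - {outgroup_label}
    )
    clades = [frozenset(sp for sp, v in c.states.items() if v == 1) for c in characters]
    return tree_from_clades(clades, scored, rooted=True)


# ---------------------------------------------------------------------------
# NEXUS serialization
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: MRPMatrix, path: str) -> None:
    """Write the matrix as a NEXUS DATA block plus an ASSUMPTIONS weight set.

    Real-valued weights are written both verbatim (``WTSET * RealWeights``)
    and as a x1000 integer rendering for parsers requiring integer weights.
    Character provenance is stored in ``[%CHAR ...]`` comments so the matrix
    round-trips losslessly through :func:`read_nexus`.
    """
    codes, weights = matrix.to_arrays()
    sym = {0: "0", 1: "1", MISSING: "?"}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("    MATRIX\n")
        width = max(len(_quote(t)) for t in matrix.taxa) + 2
        for i, t in enumerate(matrix.taxa):
            row = "".join(sym[v] for v in codes[i])
            fh.write(f"        {_quote(t):<{width}}{row}\n")
        fh.write("    ;\nEND;\n")
        fh.write("BEGIN ASSUMPTIONS;\n")
        fh.write("    WTSET * RealWeights (VECTOR) = "
                 + " ".join(repr(float(w)) for w in weights) + ";\n")
        fh.write("    WTSET IntWeights (VECTOR) = "
                 + " ".join(str(max(1, round(float(w) * 1000))) for w in weights) + ";\n")
        fh.write("END;\n")
        fh.write(f"[%OUTGROUP {_quote(matrix.outgroup)}]\n")
        for j, c in enumerate(matrix.characters):
            sup = "NA" if c.support is None else repr(c.support)
            fh.write(
                f"[%CHAR {j} source={_quote(c.source_id or 'NA')} "
                f"category={_quote(c.data_category or 'NA')} "
                f"perm={c.permutation_count} support={sup}]\n"
            )


_TOKEN = re.compile(r"'((?:[^']|'')*)'|([\w.?\-]+)")


def _tokens(text: str) -> list[str]:
    return [m.group(1).replace("''", "'") if m.group(1) is not None else m.group(2)
            for m in _TOKEN.finditer(text)]


def read_nexus(path: str) -> MRPMatrix:
    """Read a matrix written by :func:`write_nexus` (bit-exact round trip)."""
    with open(path) as fh:
        text = fh.read()

    dims = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+)", text, re.I)
    if not dims:
        raise ValueError("missing DIMENSIONS statement")
    ntax, nchar = int(dims.group(1)), int(dims.group(2))

    mat = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I)
    if not mat:
        raise ValueError("missing MATRIX block")
    taxa, rows = [], []
    for line in mat.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        m = re.match(r"'((?:[^']|'')*)'\s+(\S+)|(\S+)\s+(\S+)", line)
        if not m:
            raise ValueError(f"unparseable matrix row: {line!r}")
        if m.group(1) is not None:
            label, row = m.group(1).replace("''", "'"), m.group(2)
        else:
            label, row = m.group(3), m.group(4)
        taxa.append(label)
        rows.append(row)
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise ValueError("matrix dimensions do not match DIMENSIONS")

    wt = re.search(r"WTSET \* RealWeights \(VECTOR\) =([^;]*);", text)
    weights = [float(x) for x in wt.group(1).split()] if wt else [1.0] * nchar

    og = re.search(r"\[%OUTGROUP (.*?)\]", text)
    outgroup = _tokens(og.group(1))[0] if og else taxa[-1]

    meta = {}
    for m in re.finditer(
        r"\[%CHAR (\d+) source=(\S+|'(?:[^']|'')*') category=(\S+|'(?:[^']|'')*') "
        r"perm=(\d+) support=(\S+?)\]",
        text,
    ):
        j = int(m.group(1))
        src = _tokens(m.group(2))[0]
        cat = _tokens(m.group(3))[0]
        sup = None if m.group(5) == "NA" else float(m.group(5))
        meta[j] = (
            "" if src == "NA" else src,
            "" if cat == "NA" else cat,
            int(m.group(4)),
            sup,
        )

    chars = []
    for j in range(nchar):
        states = {}
        for i, t in enumerate(taxa):
            ch = rows[i][j]
            if ch in "01":
                states[t] = int(ch)
        src, cat, perm, sup = meta.get(j, ("", "", 1, None))
        chars.append(
            MRPCharacter(
                states=states, weight=weights[j], source_id=src,
                support=sup, data_category=cat, permutation_count=perm,
            )
        )
    return MRPMatrix(taxa=taxa, outgroup=outgroup, characters=chars)
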