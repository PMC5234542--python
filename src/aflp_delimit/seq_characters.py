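"""Sequence-track analysis: indel coding, character accounting, parsimony.

Covers the nrDNA (ITS/ETS) and plastid (trnL intron + trnL-F spacer) side of
the species-delimitation workflow:

* alignment gaps are converted to binary characters by *simple indel
  coding*: every positionally distinct internal gap (identical start and
  end across the taxa sharing it) becomes one 0/1 character, with taxa whose
  longer gap strictly contains the span scored as missing (?), and terminal
  missing-data runs never coded;
* variable and parsimony-informative characters are counted over any taxon
  subset (e.g. with or without outgroups), with ambiguity codes and missing
  cells excluded from state counting;
* most-parsimonious trees are found either exactly (branch and bound) or
  heuristically (random addition + NNI), zero-minimum-length branches are
  collapsed in reported trees, and clade support is estimated by bootstrap
  resampling of nucleotide and indel characters jointly.

Gaps inside nucleotide columns are treated as missing data for counting and
for parsimony; the appended binary characters carry the indel signal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from . import trees as _trees
from .trees import UnrootedTree

__all__ = [
    "Alignment",
    "CharacterMatrix",
    "CharacterCounts",
    "TreeSet",
    "read_alignment",
    "simple_indel_coding",
    "character_counts",
    "fitch_length",
    "search_mp_trees",
    "bootstrap_support",
]

# IUPAC nucleotide codes as bitmasks over (A, C, G, T)
_A, _C, _G, _T = 1, 2, 4, 8
IUPAC_MASK = {
    "A": _A, "C": _C, "G": _G, "T": _T, "U": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T, "V": _A | _C | _G,
    "N": _A | _C | _G | _T, "?": _A | _C | _G | _T, "-": _A | _C | _G | _T,
}
_DETERMINATE = {"A", "C", "G", "T", "U"}
_BINARY_MASK = {"0": 1, "1": 2, "?": 0b1111}


@dataclass
class Alignment:
    """Equal-length sequences over the nucleotide alphabet plus '-' and IUPAC codes."""

    taxa: list[str]
    rows: list[str]
    region: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if self.rows:
            L = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != L:
                    raise ValueError(
                        f"alignment is ragged: taxon {t!r} has length {len(r)}, "
                        f"expected {L}"
                    )
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset(self, taxa: list[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment([self.taxa[i] for i in idx], [self.rows[i] for i in idx],
                         self.region)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


def read_alignment(path, format: str = "fasta", region: str = "") -> Alignment:
    """Read a FASTA or NEXUS alignment; gap characters are normalized to '-'."""
    fmt = format.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        return Alignment([r.id for r in records], [str(r.seq) for r in records], region)
    if fmt == "nexus":
        aln = AlignIO.read(path, "nexus")
        return Alignment([r.id for r in aln], [str(r.seq) for r in aln], region)
    raise ValueError(f"unsupported alignment format {format!r}")


@dataclass
class CharacterMatrix:
    """Aligned nucleotide columns plus appended binary indel characters.

    ``indel`` is a (taxa x characters) array over {'0', '1', '?'};
    ``indel_spans`` gives each character's [start, end) alignment span.
    """

    taxa: list[str]
    nucleotide: list[str]
    indel: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0), dtype="<U1")
    )
    indel_spans: list[tuple[int, int]] = field(default_factory=list)
    region: str = ""

    def __post_init__(self) -> None:
        self.indel = np.asarray(self.indel, dtype="<U1")
        if self.indel.size == 0:
            self.indel = np.empty((len(self.taxa), 0), dtype="<U1")
        if self.indel.shape[0] != len(self.taxa):
            raise ValueError("indel rows do not match taxa")
        if self.indel.shape[1] != len(self.indel_spans):
            raise ValueError("indel spans do not match characters")

    @property
    def n_nucleotide(self) -> int:
        return len(self.nucleotide[0]) if self.nucleotide else 0

    @property
    def n_indel(self) -> int:
        return self.indel.shape[1]

    @property
    def n_columns(self) -> int:
        return self.n_nucleotide + self.n_indel

    def _taxa_indices(self, taxa_subset) -> list[int]:
        if taxa_subset is None:
            return list(range(len(self.taxa)))
        missing = [t for t in taxa_subset if t not in self.taxa]
        if missing:
            raise ValueError(f"unknown taxa in subset: {missing}")
        if len(list(taxa_subset)) == 0:
            raise ValueError("empty taxon subset")
        return [self.taxa.index(t) for t in taxa_subset]

    def column_states(
        self, taxa_subset=None, include_nucleotide=True, include_indel=True
    ) -> list[list[str]]:
        """Raw per-column symbols restricted to a taxon subset."""
        idx = self._taxa_indices(taxa_subset)
        cols: list[list[str]] = []
        if include_nucleotide and self.nucleotide:
            for j in range(self.n_nucleotide):
                cols.append([self.nucleotide[i][j] for i in idx])
        if include_indel:
            for j in range(self.n_indel):
                cols.append([self.indel[i, j] for i in idx])
        return cols

    def to_masks(
        self, taxa_order=None, include_nucleotide=True, include_indel=True
    ) -> np.ndarray:
        """(taxa x columns) uint8 state-set bitmasks for parsimony.

        Gaps, '?' and 'N' map to the full mask (missing data).
        """
        idx = self._taxa_indices(taxa_order)
        blocks = []
        if include_nucleotide and self.nucleotide:
            nuc = np.array(
                [[IUPAC_MASK[ch] for ch in self.nucleotide[i]] for i in idx],
                dtype=np.uint8,
            )
            blocks.append(nuc)
        if include_indel and self.n_indel:
            ind = np.array(
                [[_BINARY_MASK[self.indel[i, j]] for j in range(self.n_indel)]
                 for i in idx],
                dtype=np.uint8,
            )
            blocks.append(ind)
        if not blocks:
            return np.empty((len(idx), 0), dtype=np.uint8)
        return np.hstack(blocks)

    def to_nexus(self, path) -> None:
        """NEXUS with a DNA CHARACTERS block followed by a standard-datatype
        block holding the coded indel characters."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={len(self.taxa)};\n    TAXLABELS\n")
            for t in self.taxa:
                fh.write(f"        '{t}'\n")
            fh.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
            fh.write(f"    DIMENSIONS NCHAR={self.n_nucleotide};\n")
            fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
            for t, r in zip(self.taxa, self.nucleotide):
                fh.write(f"        '{t}' {r}\n")
            fh.write("    ;\nEND;\n")
            if self.n_indel:
                fh.write("\nBEGIN CHARACTERS;\n")
                fh.write(f"    [indel characters] DIMENSIONS NCHAR={self.n_indel};\n")
                fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
                fh.write("    MATRIX\n")
                for i, t in enumerate(self.taxa):
                    fh.write(f"        '{t}' {''.join(self.indel[i])}\n")
                fh.write("    ;\nEND;\n")


def _gap_runs(row: str) -> list[tuple[int, int, bool]]:
    """Maximal '-' runs as (start, end, terminal) with end exclusive."""
    runs = []
    L = len(row)
    i = 0
    while i < L:
        if row[i] == "-":
            j = i
            while j < L and row[j] == "-":
                j += 1
            runs.append((i, j, i == 0 or j == L))
            i = j
        else:
            i += 1
    return runs


def simple_indel_coding(a: Alignment) -> CharacterMatrix:
    """Append one binary character per positionally distinct internal gap.

    A taxon scores 1 when it bears a gap with exactly that start and end,
    ? when one of its (internal or terminal) gap runs properly contains the
    span, and 0 otherwise. Terminal runs are leading/trailing missing data:
    they generate no characters and render any span they cover as missing.
    Nucleotide columns are retained unchanged (gap cells are treated as
    missing downstream). Coding the output again adds nothing: the binary
    characters contain no gaps.
    """
    runs_per_taxon = [_gap_runs(r) for r in a.rows]
    spans = sorted(
        {(s, e) for runs in runs_per_taxon for (s, e, term) in runs if not term}
    )
    n = len(a.taxa)
    coded = np.full((n, len(spans)), "0", dtype="<U1")
    for i, runs in enumerate(runs_per_taxon):
        internal = {(s, e) for (s, e, term) in runs if not term}
        for k, (s, e) in enumerate(spans):
            if (s, e) in internal:
                coded[i, k] = "1"
            else:
                for rs, re, term in runs:
                    if rs <= s and e <= re and (term or (rs, re) != (s, e)):
                        coded[i, k] = "?"
                        break
    return CharacterMatrix(
        taxa=list(a.taxa),
        nucleotide=list(a.rows),
        indel=coded,
        indel_spans=spans,
        region=a.region,
    )


@dataclass(frozen=True)
class CharacterCounts:
    """Constant / variable / parsimony-informative character tally."""

    n_constant: int
    n_variable: int
    n_parsimony_informative: int

    def __post_init__(self) -> None:
        if self.n_variable < self.n_parsimony_informative:
            raise ValueError("variable count below informative count")


def _column_tally(col: list[str], binary: bool) -> dict[str, int]:
    det = {"0", "1"} if binary else _DETERMINATE
    tally: dict[str, int] = {}
    for ch in col:
        if ch in det:
            ch = "T" if ch == "U" else ch
            tally[ch] = tally.get(ch, 0) + 1
    return tally


def character_counts(
    m: CharacterMatrix,
    taxa_subset=None,
    include_nucleotide: bool = True,
    include_indels: bool = True,
) -> CharacterCounts:
    """Count constant, variable and parsimony-informative characters.

    Restricted to ``taxa_subset`` when given. A column is variable when it
    shows >= 2 distinct determinate states, and parsimony-informative when
    >= 2 states are each borne by >= 2 taxa; ambiguity codes, gaps and ?
    never count as states.
    """
    cols = m.column_states(taxa_subset, include_nucleotide, include_indels)
    n_nuc = m.n_nucleotide if include_nucleotide else 0
    variable = informative = 0
    for j, col in enumerate(cols):
        tally = _column_tally(col, binary=j >= n_nuc)
        if len(tally) >= 2:
            variable += 1
            if sum(1 for c in tally.values() if c >= 2) >= 2:
                informative += 1
    return CharacterCounts(
        n_constant=len(cols) - variable,
        n_variable=variable,
        n_parsimony_informative=informative,
    )


def _as_tree(tree, taxa: list[str]) -> UnrootedTree:
    if isinstance(tree, UnrootedTree):
        if set(tree.taxa) != set(taxa):
            raise ValueError("tree taxa do not match the character matrix")
        return tree
    return _trees.tree_from_newick(tree, taxa=taxa)


def fitch_length(tree, m: CharacterMatrix) -> int:
    """Minimal total unordered state changes of the matrix on the topology.

    Accepts an :class:`~aflp_delimit.trees.UnrootedTree` or a newick string;
    ambiguity codes enter as polymorphic state sets, gaps and ? as missing.
    """
    t = _as_tree(tree, m.taxa)
    masks = m.to_masks(taxa_order=t.taxa)
    return _trees.tree_length(t, masks)


@dataclass
class TreeSet:
    """Most-parsimonious trees with their length and strict consensus.

    ``trees`` are the reported topologies with zero-minimum-length branches
    collapsed; ``binary_trees`` keeps the uncollapsed search results.
    """

    trees: list[UnrootedTree]
    binary_trees: list[UnrootedTree]
    length: int
    strict_consensus: UnrootedTree

    @property
    def n_trees(self) -> int:
        return len(self.binary_trees)

    def newicks(self) -> list[str]:
        return [t.to_newick() for t in self.trees]


def search_mp_trees(
    m: CharacterMatrix,
    strategy: str = "exact",
    seed: int = 0,
    n_starts: int = 10,
    max_saved: int = 1000,
) -> TreeSet:
    """Find most-parsimonious trees.

    ``exact`` runs a branch-and-bound search guaranteed to return all
    minimal-length topologies (refused above 14 taxa — use the heuristic);
    ``heuristic`` runs seeded random-addition + nearest-neighbor-interchange.
    Reported trees have branches of minimum length zero collapsed; the
    strict consensus is computed from the uncollapsed topologies.
    """
    taxa = list(m.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa for a tree search")
    masks = m.to_masks()
    if strategy == "exact":
        if len(taxa) > 14:
            raise ValueError(
                f"exact search on {len(taxa)} taxa is infeasible; "
                "use strategy='heuristic'"
            )
        found, length = _trees.branch_and_bound_search(taxa, masks)
    elif strategy == "heuristic":
        found, length = _trees.heuristic_search(
            taxa, masks, n_starts=n_starts, seed=seed, max_saved=max_saved
        )
    else:
        raise ValueError(f"unknown search strategy {strategy!r}")
    collapsed = _dedupe_collapsed(
        [_trees.collapse_zero_length_edges(t, masks) for t in found]
    )
    return TreeSet(
        trees=collapsed,
        binary_trees=found,
        length=int(length),
        strict_consensus=_trees.strict_consensus(found),
    )


def _dedupe_collapsed(ts: list[UnrootedTree]) -> list[UnrootedTree]:
    seen: set[frozenset] = set()
    out = []
    for t in ts:
        key = frozenset(t.splits())
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def bootstrap_support(
    m: CharacterMatrix,
    replicates: int = 1000,
    seed: int = 0,
    strategy: str = "heuristic",
    n_starts: int = 2,
    max_saved: int = 1000,
) -> dict[frozenset, float]:
    """Bootstrap clade support by joint resampling of all characters.

    Columns (nucleotide and indel together) are resampled with replacement;
    each replicate is searched for most-parsimonious trees (saving at most
    ``max_saved`` per replicate) and a clade counts when it appears in the
    replicate's strict consensus. Returns canonical split -> support %.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    taxa = list(m.taxa)
    masks = m.to_masks()
    n_cols = masks.shape[1]
    if n_cols == 0:
        raise ValueError("cannot bootstrap an empty character matrix")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for rep in range(replicates):
        draw = rng.integers(0, n_cols, size=n_cols)
        weights = np.bincount(draw, minlength=n_cols).astype(np.int64)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if strategy == "exact":
            found, _ = _trees.branch_and_bound_search(taxa, masks, weights)
            found = found[:max_saved]
        else:
            found, _ = _trees.heuristic_search(
                taxa, masks, weights, n_starts=n_starts, seed=rep_seed,
                max_saved=max_saved,
            )
        for split in _trees.strict_consensus(found).splits():
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / replicates for s, c in counts.items()}
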