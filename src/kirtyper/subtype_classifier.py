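"""SNP decision-table classification of alleles into subtype groups, with
sequence-homology and neighbor-joining support for novel sequences.

The decision table mirrors the assay: the null group is recognized first
(its diagnostic 193G takes precedence because it shares 202A/607T with the
*005-group), then the exon-3/exon-4 site combination splits the remaining
inhibitory groups, and the transmembrane dinucleotide separates the
*007-group from the *002-group.  The *002-group states are shared with the
activating gene, which CDS sites alone cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .allele_catalog import Allele, SNPProfile, SubtypeGroup, extract_snp_profile

__all__ = [
    "ClassificationResult",
    "PhyloTree",
    "classify_snp_profile",
    "classify_sequence",
    "nearest_reference",
    "build_nj_tree",
    "p_distance_matrix",
]


@dataclass
class ClassificationResult:
    group: SubtypeGroup
    rule_fired: str
    needs_gene_disambiguation: bool = False
    nearest: Optional[tuple[str, float]] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.needs_gene_disambiguation and self.rule_fired != "rule5-high2-or-s1":
            raise ValueError("gene disambiguation applies only to the shared "
                             "*002-group/activating rule")


def classify_snp_profile(profile: SNPProfile) -> ClassificationResult:
    """Apply the SNP decision table to one profile.

    Rule order: (1) 193G -> NULL; (2) 202A+607T -> LOW1; (3) 202A+607C ->
    HIGH1; (4) 202G+607C+CG -> LOW2; (5) 202G+607C+CA -> HIGH2-or-S1
    (flagged for gene disambiguation); (6) anything else UNCLASSIFIED.
    An ``N`` at any consulted site yields UNCLASSIFIED, never a forced call.
    """
    for site in ("p193", "p202", "p607"):
        if not profile.is_complete(site):
            raise ValueError(f"cannot classify: {site} not readable")
    if profile.p193 == "N" or profile.p202 == "N" or profile.p607 == "N":
        return ClassificationResult(SubtypeGroup.UNCLASSIFIED, "rule6-unclassified",
                                    note="ambiguous base at a diagnostic site")
    if profile.p193 == "G":
        return ClassificationResult(SubtypeGroup.NULL, "rule1-null")
    if profile.p202 == "A" and profile.p607 == "T":
        return ClassificationResult(SubtypeGroup.LOW1, "rule2-low1")
    if profile.p202 == "A" and profile.p607 == "C":
        return ClassificationResult(SubtypeGroup.HIGH1, "rule3-high1")
    if profile.p202 == "G" and profile.p607 == "C":
        dinuc = profile.p1021_1022
        if dinuc is None or "N" in dinuc:
            return ClassificationResult(
                SubtypeGroup.UNCLASSIFIED, "rule6-unclassified",
                note="202G/607C but the transmembrane dinucleotide is unreadable")
        if dinuc == "CG":
            return ClassificationResult(SubtypeGroup.LOW2, "rule4-low2")
        if dinuc == "CA":
            return ClassificationResult(SubtypeGroup.HIGH2, "rule5-high2-or-s1",
                                        needs_gene_disambiguation=True)
    return ClassificationResult(SubtypeGroup.UNCLASSIFIED, "rule6-unclassified",
                                note="site states match no designed reaction")


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


def _allele_sort_key(name: str) -> tuple:
    import re
    m = re.search(r"\*(\d+)", name)
    return (int(m.group(1)) if m else 10**9, name)


def nearest_reference(query: str, references: Sequence[Allele]) -> tuple[str, float]:
    """Closest reference by percent identity over the ungapped columns of a
    global alignment.  Ties break toward the lowest numeric designation."""
    if not query:
        raise ValueError("empty query sequence")
    if not references:
        raise ValueError("empty reference set")
    best: Optional[tuple[str, float]] = None
    for ref in sorted(references, key=lambda a: _allele_sort_key(a.name)):
        aln = _aligner.align(query, ref.cds)[0]
        a, b = aln[0], aln[1]
        matches = ungapped = 0
        for x, y in zip(a, b):
            if x == "-" or y == "-":
                continue
            ungapped += 1
            matches += x == y
        ident = 100.0 * matches / ungapped if ungapped else 0.0
        if best is None or ident > best[1]:
            best = (ref.name, ident)
    return best


def classify_sequence(allele: Allele, references: Sequence[Allele] = (),
                      coordinate_offset: int = 0) -> ClassificationResult:
    """Classify a coding sequence; resolve the shared *002-group/activating
    rule by gene annotation in the name, else by whole-CDS homology."""
    profile = extract_snp_profile(allele, coordinate_offset)
    result = classify_snp_profile(profile)
    if result.needs_gene_disambiguation:
        gene = allele.gene
        if gene == "KIR3DS1":
            result.group = SubtypeGroup.S1
            result.needs_gene_disambiguation = False
            result.note = "resolved by gene annotation"
        elif gene == "KIR3DL1":
            result.group = SubtypeGroup.HIGH2
            result.needs_gene_disambiguation = False
            result.note = "resolved by gene annotation"
        else:
            if not references:
                raise ValueError("gene disambiguation needed but no references "
                                 "supplied and the name carries no gene")
            name, ident = nearest_reference(allele.cds, references)
            result.nearest = (name, ident)
            if "KIR3DS1" in name:
                result.group = SubtypeGroup.S1
            elif "KIR3DL1" in name:
                result.group = SubtypeGroup.HIGH2
            else:
                return result  # flag stays set
            result.needs_gene_disambiguation = False
            result.note = f"resolved by nearest reference {name} ({ident:.1f}%)"
    if result.group is SubtypeGroup.UNCLASSIFIED and references:
        result.nearest = nearest_reference(allele.cds, references)
    return result


# ---------------------------------------------------------------------------
# Neighbor joining with bootstrap
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """An unrooted NJ tree with per-bipartition bootstrap support."""

    tree: TreeNode
    taxa: tuple[str, ...]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree, set(self.taxa))

    def has_clade(self, names: set[str]) -> bool:
        """True if the taxon set forms one side of an internal bipartition
        (or is trivial: a single taxon or all/all-but-one taxa)."""
        names = frozenset(names)
        full = frozenset(self.taxa)
        if len(names) <= 1 or len(full - names) <= 1:
            return True
        return names in self.bipartitions() or (full - names) in self.bipartitions()

    def to_newick(self, with_support: bool = True) -> str:
        t = self.tree.copy()
        if with_support and self.supports:
            for node in t.non_tips():
                side = frozenset(tip.name for tip in node.tips())
                key = _canonical(side, frozenset(self.taxa))
                if key in self.supports:
                    node.name = str(int(round(self.supports[key])))
        return str(t).strip()


def _canonical(side: frozenset, full: frozenset) -> frozenset:
    """Canonical representative of a bipartition: the side not containing
    the lexicographically smallest taxon."""
    anchor = min(full)
    return full - side if anchor in side else side


def _bipartitions(tree: TreeNode, taxa: set[str]) -> set[frozenset]:
    full = frozenset(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if 1 < len(side) < len(full) - 1:
            out.add(_canonical(side, full))
    return out


def p_distance_matrix(names: Sequence[str], matrix: np.ndarray) -> np.ndarray:
    """Pairwise p-distance (proportion of differing columns), ignoring
    columns where either sequence carries N or a gap."""
    n = len(names)
    informative = (matrix != ord("N")) & (matrix != ord("-"))
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = informative[i] & informative[j]
            denom = int(ok.sum())
            d = float(((matrix[i] != matrix[j]) & ok).sum()) / denom if denom else 0.0
            dm[i, j] = dm[j, i] = d
    return dm


def _encode(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    L = lengths.pop()
    if L == 0:
        raise ValueError("zero-length alignment")
    matrix = np.array([np.frombuffer(alignment[n].upper().encode(), dtype=np.uint8)
                       for n in names])
    return names, matrix


def _nj_from_dm(names: Sequence[str], dm: np.ndarray) -> TreeNode:
    tree = nj(DistanceMatrix(dm, ids=list(names)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # clamp negative NJ estimates
    return tree


def build_nj_tree(alignment: dict[str, str], bootstrap_reps: int = 0,
                  seed: int = 0) -> PhyloTree:
    """Neighbor joining on p-distance with column-resampling bootstrap.

    Replicate ``r`` resamples columns with a generator seeded ``seed + r``;
    support is the percentage of replicate trees containing each internal
    bipartition of the main tree.  Deterministic given the seed.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa")
    names, matrix = _encode(alignment)
    tree = _nj_from_dm(names, p_distance_matrix(names, matrix))
    result = PhyloTree(tree=tree, taxa=tuple(names))
    if bootstrap_reps > 0:
        counts: dict[frozenset, int] = {bp: 0 for bp in result.bipartitions()}
        L = matrix.shape[1]
        for r in range(bootstrap_reps):
            rng = np.random.default_rng(seed + r)
            cols = rng.integers(0, L, size=L)
            rep = _nj_from_dm(names, p_distance_matrix(names, matrix[:, cols]))
            rep_bps = _bipartitions(rep, set(names))
            for bp in counts:
                if bp in rep_bps:
                    counts[bp] += 1
        result.supports = {bp: 100.0 * c / bootstrap_reps
                           for bp, c in counts.items()}
    return result
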