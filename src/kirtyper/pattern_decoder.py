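"""Invert band patterns to genotype hypotheses, reproduce the documented
typing ambiguity, search extended (polyallelic) haplotypes, and check
pedigree transmission consistency.

With the designed panel every unordered pair of subtype groups maps to a
unique band pattern except one: homozygosity for the *007-group is
indistinguishable from *002-group/*007-group heterozygosity, because the
*007-group fires both the shared reaction and its own exon-7 reaction.
Supplying exon-7 dinucleotide reads resolves that collision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .allele_catalog import SubtypeGroup
from .insilico_pcr import BandPattern, Panel, load_panel

__all__ = [
    "GenotypeHypothesis",
    "DecodeResult",
    "Pedigree",
    "TYPEABLE_GROUPS",
    "subtype_signature",
    "enumerate_pattern_table",
    "decode_pattern",
    "check_pedigree",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
]

TYPEABLE_GROUPS = (SubtypeGroup.NULL, SubtypeGroup.LOW1, SubtypeGroup.LOW2,
                   SubtypeGroup.HIGH1, SubtypeGroup.HIGH2, SubtypeGroup.S1)

#: Transmembrane dinucleotide each group contributes to exon-7 sequencing
#: of the shared-reaction amplicon class.
_EXON7_READ = {SubtypeGroup.HIGH2: "CA", SubtypeGroup.S1: "CA",
               SubtypeGroup.LOW2: "CG"}


@dataclass(frozen=True)
class GenotypeHypothesis:
    """An unordered multiset of 2 (or, for extended haplotypes, 3) groups."""

    groups: tuple[SubtypeGroup, ...]
    extended: bool = False

    def __post_init__(self) -> None:
        if len(self.groups) not in (2, 3):
            raise ValueError("hypothesis must contain 2 or 3 groups")
        if len(self.groups) == 3 and not self.extended:
            raise ValueError("3-group hypotheses must be flagged extended")
        object.__setattr__(self, "groups",
                           tuple(sorted(self.groups, key=lambda g: g.value)))

    def __str__(self) -> str:
        return "/".join(g.value for g in self.groups)


@dataclass
class DecodeResult:
    pattern: BandPattern
    hypotheses: frozenset[GenotypeHypothesis]
    notes: str = ""

    @property
    def ambiguous(self) -> bool:
        return len(self.hypotheses) > 1


# ---------------------------------------------------------------------------
# Forward enumeration
# ---------------------------------------------------------------------------

def _pattern_key(pattern: BandPattern) -> frozenset:
    return frozenset((rid, size) for rid, sizes in pattern.bands.items()
                     for size in sizes)


def _keys_equal(a: frozenset, b: frozenset, tolerance: int) -> bool:
    """Band-pattern equality up to the gel size tolerance, per reaction."""
    def by_rxn(key):
        out: dict[str, list[int]] = {}
        for rid, size in key:
            out.setdefault(rid, []).append(size)
        return {rid: sorted(v) for rid, v in out.items()}
    da, db = by_rxn(a), by_rxn(b)
    if da.keys() != db.keys():
        return False
    for rid in da:
        if len(da[rid]) != len(db[rid]):
            return False
        if any(abs(x - y) > tolerance for x, y in zip(da[rid], db[rid])):
            return False
    return True


def subtype_signature(group: SubtypeGroup,
                      panel: Optional[Panel] = None) -> dict[str, frozenset[int]]:
    """Per-reaction band sets of a homozygote of one group, derived by
    forward simulation on the group's fixture template."""
    from . import synthetic_fixtures  # local import avoids a cycle
    if group is SubtypeGroup.UNCLASSIFIED:
        raise ValueError("no signature for UNCLASSIFIED")
    pattern = synthetic_fixtures.pattern_for_genotype((group, group), panel)
    return {rid: sizes for rid, sizes in pattern.bands.items() if sizes}


def enumerate_pattern_table(panel: Optional[Panel] = None, max_groups: int = 2
                            ) -> dict[frozenset, frozenset[GenotypeHypothesis]]:
    """Forward-simulate every unordered genotype of up to ``max_groups``
    typeable groups and invert the map; collisions are preserved as
    multi-hypothesis entries."""
    from . import synthetic_fixtures
    panel = panel or load_panel()
    table: dict[frozenset, set[GenotypeHypothesis]] = {}
    for k in range(2, max_groups + 1):
        for combo in itertools.combinations_with_replacement(TYPEABLE_GROUPS, k):
            pattern = synthetic_fixtures.pattern_for_genotype(combo, panel)
            key = _pattern_key(pattern)
            hyp = GenotypeHypothesis(groups=combo, extended=(k == 3))
            table.setdefault(key, set()).add(hyp)
    return {k: frozenset(v) for k, v in table.items()}


_table_cache: dict[tuple, dict] = {}


def _cached_table(panel: Panel, max_groups: int) -> dict:
    key = (panel.key, max_groups)
    if key not in _table_cache:
        _table_cache[key] = enumerate_pattern_table(panel, max_groups)
    return _table_cache[key]


def decode_pattern(pattern: BandPattern, panel: Optional[Panel] = None,
                   allow_extended: bool = False,
                   exon7_reads: Optional[Iterable[str]] = None,
                   gel_tolerance: int = 25) -> DecodeResult:
    """Look a band pattern up in the forward-enumeration table.

    If no 2-group genotype fits and ``allow_extended`` is set, unordered
    triples are searched and minimal-cardinality fits returned with
    ``extended=True``.  ``exon7_reads`` (the set of transmembrane
    dinucleotides seen by sequencing the shared-reaction amplicons)
    optionally resolves the documented *002-group/*007-group collision.
    """
    panel = panel or load_panel()
    if not pattern.valid or not all(pattern.control_ok.get(r.id, False)
                                    for r in panel):
        raise ValueError(f"sample {pattern.sample_id} invalid "
                         "(control failure), cannot decode")
    key = _pattern_key(pattern)
    if not key:
        return DecodeResult(pattern=pattern, hypotheses=frozenset(),
                            notes="no bands: no call / possible novel or "
                                  "unclassified allele")
    pairs = _cached_table(panel, 2)
    hyps: frozenset[GenotypeHypothesis] = frozenset()
    for tab_key, tab_hyps in pairs.items():
        if _keys_equal(key, tab_key, gel_tolerance):
            hyps = tab_hyps
            break
    notes = ""
    if not hyps and allow_extended:
        triples = _cached_table(panel, 3)
        matches: set[GenotypeHypothesis] = set()
        for tab_key, tab_hyps in triples.items():
            if _keys_equal(key, tab_key, gel_tolerance):
                matches |= {h for h in tab_hyps if len(h.groups) == 3}
        hyps = frozenset(matches)
        if hyps:
            notes = "extended (3-group) haplotype hypothesis"
    if not hyps:
        return DecodeResult(pattern=pattern, hypotheses=frozenset(),
                            notes=notes or "pattern matches no simulated genotype")
    if len(hyps) > 1:
        if exon7_reads is not None:
            reads = frozenset(exon7_reads)
            kept = frozenset(
                h for h in hyps
                if frozenset(_EXON7_READ[g] for g in h.groups
                             if g in _EXON7_READ) == reads)
            if kept:
                hyps = kept
                notes = "ambiguity resolved by exon-7 dinucleotide reads"
        else:
            notes = ("ambiguous: *002-group/*007-group heterozygote vs "
                     "*007-group homozygote; exon-7 sequencing resolves")
    return DecodeResult(pattern=pattern, hypotheses=hyps, notes=notes)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Individuals with optional parent links and per-individual calls.

    A call may be a :class:`GenotypeHypothesis`, a :class:`DecodeResult`, a
    :class:`BandPattern` (decoded on demand) or ``None`` (missing data)."""

    parents: dict[str, tuple[Optional[str], Optional[str]]]
    calls: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iid, (f, m) in self.parents.items():
            for p in (f, m):
                if p is not None and p not in self.parents:
                    raise ValueError(f"{iid}: parent {p} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self.parents}

        def visit(i: str) -> None:
            color[i] = GREY
            for p in self.parents[i]:
                if p is None:
                    continue
                if color[p] == GREY:
                    raise ValueError(f"cyclic pedigree at {i} -> {p}")
                if color[p] == WHITE:
                    visit(p)
            color[i] = BLACK

        for i in self.parents:
            if color[i] == WHITE:
                visit(i)


def _hypotheses_for(call: object, panel: Panel,
                    allow_extended: bool) -> Optional[frozenset[GenotypeHypothesis]]:
    """Normalize any call representation to a hypothesis set.

    ``None`` means no data (the individual is unconstrained); an *empty*
    set means the individual was typed but its pattern is undecodable
    under the current settings.
    """
    if call is None:
        return None
    if isinstance(call, GenotypeHypothesis):
        return frozenset({call})
    if isinstance(call, DecodeResult):
        return call.hypotheses
    if isinstance(call, BandPattern):
        res = decode_pattern(call, panel, allow_extended=allow_extended)
        return res.hypotheses
    if isinstance(call, (tuple, list)):
        return frozenset({GenotypeHypothesis(groups=tuple(call),
                                             extended=len(call) == 3)})
    raise TypeError(f"unsupported call type {type(call).__name__}")


def _units(hyp: GenotypeHypothesis, allow_extended: bool) -> set[tuple]:
    """Transmissible haplotype units of a parent genotype: any single group;
    with extended transmission, also any pair (the linkage phase within a
    multi-group genotype is unobserved)."""
    groups = hyp.groups
    units: set[tuple] = {(g,) for g in groups}
    if allow_extended:
        for pair in itertools.combinations(range(len(groups)), 2):
            units.add(tuple(sorted((groups[pair[0]], groups[pair[1]]),
                                   key=lambda g: g.value)))
    return units


def _partitions(hyp: GenotypeHypothesis) -> list[tuple[tuple, tuple]]:
    """All splits of a child genotype into two parental units."""
    groups = list(hyp.groups)
    out = []
    n = len(groups)
    for idx in range(1, n):
        for combo in itertools.combinations(range(n), idx):
            a = tuple(sorted((groups[i] for i in combo), key=lambda g: g.value))
            rest = tuple(sorted((groups[i] for i in range(n) if i not in combo),
                                key=lambda g: g.value))
            out.append((a, rest))
            out.append((rest, a))
    return out


def check_pedigree(ped: Pedigree, panel: Optional[Panel] = None,
                   allow_extended: bool = False) -> dict:
    """Check Mendelian transmission for every child with at least one known
    parent.

    A child is consistent when some hypothesis of the child splits into one
    transmissible unit from each parent (units are single groups or, when
    extended transmission is enabled, linked pairs).  Parents without data
    are unconstrained and logged as such.  Returns a report with per-child
    verdicts and witness assignments.
    """
    panel = panel or load_panel()
    children = {i: (f, m) for i, (f, m) in ped.parents.items()
                if f is not None or m is not None}
    if not children:
        raise ValueError("pedigree contains no parent-child relation")
    verdicts = {}
    for child, (father, mother) in sorted(children.items()):
        child_hyps = _hypotheses_for(ped.calls.get(child), panel, allow_extended)
        if child_hyps is None:
            verdicts[child] = {"consistent": True, "witness": None,
                               "note": "child untyped: unconstrained"}
            continue
        if not child_hyps:
            verdicts[child] = {"consistent": False, "witness": None,
                               "note": "child pattern undecodable under "
                                       "current settings"}
            continue
        parent_units = []
        notes = []
        for role, pid in (("father", father), ("mother", mother)):
            hyps = (_hypotheses_for(ped.calls.get(pid), panel, allow_extended)
                    if pid is not None else None)
            if not hyps:
                parent_units.append(None)
                notes.append(f"{role} unconstrained"
                             + ("" if hyps is None else " (undecodable pattern)"))
            else:
                units: set[tuple] = set()
                for h in hyps:
                    units |= _units(h, allow_extended)
                parent_units.append(units)
        witness = None
        for hyp in sorted(child_hyps, key=str):
            if len(hyp.groups) == 3 and not allow_extended:
                continue
            for u_f, u_m in _partitions(hyp):
                ok_f = parent_units[0] is None or u_f in parent_units[0]
                ok_m = parent_units[1] is None or u_m in parent_units[1]
                if ok_f and ok_m:
                    witness = {"child_genotype": str(hyp),
                               "from_father": "/".join(g.value for g in u_f),
                               "from_mother": "/".join(g.value for g in u_m)}
                    break
            if witness:
                break
        verdicts[child] = {"consistent": witness is not None,
                           "witness": witness,
                           "note": "; ".join(notes)}
    n_bad = sum(not v["consistent"] for v in verdicts.values())
    return {"children": verdicts,
            "n_children": len(verdicts),
            "n_consistent": len(verdicts) - n_bad,
            "n_inconsistent": n_bad,
            "extended_transmission": allow_extended}


# ---------------------------------------------------------------------------
# Pedigree I/O (4-column TSV: id, father, mother, pattern-or-genotype)
# ---------------------------------------------------------------------------

def _format_call(call: object) -> str:
    if call is None:
        return "-"
    if isinstance(call, GenotypeHypothesis):
        return str(call)
    if isinstance(call, (tuple, list)):
        return "/".join(g.value for g in call)
    if isinstance(call, BandPattern):
        parts = []
        for rid in sorted(call.bands):
            sizes = ",".join(str(s) for s in sorted(call.bands[rid]))
            parts.append(f"{rid}={sizes or '-'}")
        return ";".join(parts)
    raise TypeError(f"cannot format call of type {type(call).__name__}")


def _parse_call(text: str, sample_id: str) -> object:
    if text in ("-", ""):
        return None
    if "=" in text:  # band pattern, e.g. R1=2019;R4=1573,1933
        bands: dict[str, frozenset[int]] = {}
        for part in text.split(";"):
            rid, _, sizes = part.partition("=")
            bands[rid] = (frozenset(int(s) for s in sizes.split(","))
                          if sizes not in ("", "-") else frozenset())
        return BandPattern(sample_id=sample_id, bands=bands,
                           control_ok={rid: True for rid in bands}, valid=True)
    groups = tuple(SubtypeGroup(g) for g in text.split("/"))
    return GenotypeHypothesis(groups=groups, extended=len(groups) == 3)


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tfather\tmother\tcall\n")
        for iid in ped.parents:
            f, m = ped.parents[iid]
            fh.write(f"{iid}\t{f or '-'}\t{m or '-'}\t"
                     f"{_format_call(ped.calls.get(iid))}\n")


def read_pedigree_tsv(path) -> Pedigree:
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    calls: dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "father", "mother", "call"]:
            raise ValueError(f"{path}: unexpected pedigree header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(fields)}")
            iid, father, mother, call = fields
            parents[iid] = (father if father != "-" else None,
                            mother if mother != "-" else None)
            try:
                calls[iid] = _parse_call(call, iid)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad call {call!r}: {exc}") from exc
    return Pedigree(parents=parents, calls=calls)
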