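"""Virtual sequence-specific-primer PCR: primer binding-site search with
IUPAC degeneracy, amplicon prediction, and multiplex panel simulation.

The typing panel comprises five reactions (R1..R5), each a forward/reverse
pair whose 3' termini sit on diagnostic polymorphisms, multiplexed with a
shared internal-control pair.  Specificity in the wet assay comes from
annealing-temperature optimization; here it is modeled as strict full-length
matching (no internal mismatches, exact 3'-anchor match).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .allele_catalog import SubtypeGroup

__all__ = [
    "IUPAC",
    "Primer",
    "Reaction",
    "Panel",
    "GenomicTemplate",
    "Feature",
    "Amplicon",
    "BandPattern",
    "MatchParams",
    "reverse_complement",
    "find_binding_sites",
    "predict_amplicons",
    "run_panel",
    "load_panel",
]

# IUPAC nucleotide codes -> the set of bases each matches.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC codes mapped correctly (R<->Y, K<->M,
    B<->V, D<->H; S, W, N self-complementary)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    role: str  # forward | reverse | control

    def __post_init__(self) -> None:
        s = self.seq.upper()
        bad = set(s) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")
        if len(s) < 15:
            raise ValueError(f"primer {self.name}: length {len(s)} < 15")
        object.__setattr__(self, "seq", s)
        if self.role not in ("forward", "reverse", "control"):
            raise ValueError(f"primer {self.name}: bad role {self.role!r}")


@dataclass(frozen=True)
class MatchParams:
    """Binding-site stringency.  Defaults model an optimized SSP assay:
    exact full-length IUPAC-expanded match."""

    max_internal_mismatches: int = 0
    three_prime_anchor: int = 3


@dataclass
class Reaction:
    id: str
    target_groups: frozenset[SubtypeGroup]
    forward: Primer
    reverse: Primer
    control_pair: tuple[Primer, Primer]
    expected_sizes: dict[str, int]  # template class -> bp
    metadata: dict = field(default_factory=dict)  # inert wet-lab conditions

    def __post_init__(self) -> None:
        for cls, size in self.expected_sizes.items():
            if size <= 0:
                raise ValueError(f"{self.id}: non-positive expected size for {cls}")


@dataclass
class Panel:
    reactions: list[Reaction]
    control_forward: Primer
    control_reverse: Primer
    control_size: int
    notes: str = ""

    def __iter__(self):
        return iter(self.reactions)

    @property
    def key(self) -> tuple:
        """Hashable identity used for signature caching."""
        return tuple((r.id, r.forward.seq, r.reverse.seq) for r in self.reactions)


@dataclass(frozen=True)
class Feature:
    kind: str  # utr5 | exon | intron | utr3
    start: int  # 0-based half-open on the template
    end: int


@dataclass
class GenomicTemplate:
    """A genomic sequence with its exon/intron structure and known subtype."""

    allele_name: str
    seq: str
    feature_map: list[Feature]
    group: Optional[SubtypeGroup] = None

    def __post_init__(self) -> None:
        prev_end = 0
        for f in self.feature_map:
            if not (0 <= f.start <= f.end <= len(self.seq)):
                raise ValueError(f"feature {f} outside template bounds")
            if f.start < prev_end:
                raise ValueError(f"feature {f} overlaps/disordered")
            prev_end = f.end

    @property
    def cds(self) -> str:
        return "".join(self.seq[f.start:f.end] for f in self.feature_map
                       if f.kind == "exon")


@dataclass(frozen=True)
class Amplicon:
    reaction_id: str
    start: int  # 0-based plus-strand, 5' end of forward footprint
    end: int    # half-open, far end of reverse footprint
    primer_pair: tuple[str, str]

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class BandPattern:
    sample_id: str
    bands: dict[str, frozenset[int]]      # reaction id -> amplicon sizes
    control_ok: dict[str, bool]
    valid: bool = True
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "bands": {rid: sorted(sz) for rid, sz in self.bands.items()},
            "control_ok": dict(self.control_ok),
            "valid": self.valid,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# Binding-site search
# ---------------------------------------------------------------------------

def _match_mask(template: np.ndarray, code: str) -> np.ndarray:
    """Boolean mask of template positions matched by one IUPAC code.
    Template 'N' (unknown base) matches nothing."""
    allowed = IUPAC[code]
    mask = np.zeros(template.shape, dtype=bool)
    for b in allowed:
        mask |= template == ord(b)
    return mask


def _scan(template: np.ndarray, pattern: str, anchor_positions: range,
          max_internal: int) -> list[tuple[int, int]]:
    """Slide `pattern` (IUPAC) along `template`; return (position, mismatches)
    for windows where every base in `anchor_positions` matches exactly and
    the remaining mismatches are <= max_internal."""
    L = len(pattern)
    n = len(template) - L + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int32)
    anchor_ok = np.ones(n, dtype=bool)
    anchor = set(anchor_positions)
    for k, code in enumerate(pattern):
        ok = _match_mask(template[k:k + n], code)
        if k in anchor:
            anchor_ok &= ok
        else:
            mism += ~ok
    hits = np.nonzero(anchor_ok & (mism <= max_internal))[0]
    return [(int(i), int(mism[i])) for i in hits]


def find_binding_sites(template: str, primer: Primer,
                       max_internal_mismatches: int = 0,
                       three_prime_anchor: int = 3,
                       role: Optional[str] = None) -> list[tuple[int, str, int]]:
    """Locate primer binding sites on a template.

    Forward primers are matched against the plus strand; reverse primers are
    reverse-complemented and matched so that their 3' end is the *leftmost*
    plus-strand position of the footprint.  A site qualifies when the final
    ``three_prime_anchor`` primer bases match exactly (IUPAC-expanded) and
    the remaining mismatches do not exceed ``max_internal_mismatches``.

    Returns (plus-strand footprint start, strand, mismatch count) tuples.
    """
    if three_prime_anchor < 1:
        raise ValueError("three_prime_anchor must be >= 1")
    t = template.upper()
    bad = set(t) - set("ACGTN")
    if bad:
        raise ValueError(f"template contains non-ACGTN characters: {sorted(bad)}")
    arr = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
    role = role or primer.role
    L = len(primer.seq)
    anchor = min(three_prime_anchor, L)
    if role in ("forward", "control"):
        # 3' end of a forward primer is its last base.
        hits = _scan(arr, primer.seq, range(L - anchor, L), max_internal_mismatches)
        return [(pos, "+", mm) for pos, mm in hits]
    # Reverse primer: footprint on plus strand is the primer's reverse
    # complement; the primer 3' end corresponds to footprint position 0.
    rc = reverse_complement(primer.seq)
    hits = _scan(arr, rc, range(0, anchor), max_internal_mismatches)
    return [(pos, "-", mm) for pos, mm in hits]


def predict_amplicons(template: GenomicTemplate | str, forward: Primer,
                      reverse: Primer, reaction_id: str = "",
                      max_product: int = 5000,
                      match: MatchParams = MatchParams()) -> list[Amplicon]:
    """Predict all products of one primer pair on one template.

    Product size runs from the 5' end of the forward footprint to the far
    (plus-strand) end of the reverse footprint, inclusive of both primers.
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    seq = template.seq if isinstance(template, GenomicTemplate) else template
    fwd_sites = find_binding_sites(seq, forward, match.max_internal_mismatches,
                                   match.three_prime_anchor, role="forward")
    rev_sites = find_binding_sites(seq, reverse, match.max_internal_mismatches,
                                   match.three_prime_anchor, role="reverse")
    out = []
    Lf, Lr = len(forward.seq), len(reverse.seq)
    for fpos, _, _ in fwd_sites:
        for rpos, _, _ in rev_sites:
            if rpos < fpos + Lf:  # reverse 3' end must be downstream
                continue
            end = rpos + Lr
            if end - fpos <= max_product:
                out.append(Amplicon(reaction_id=reaction_id, start=fpos, end=end,
                                    primer_pair=(forward.name, reverse.name)))
    return sorted(out, key=lambda a: (a.start, a.end))


def _dedupe_sizes(sizes: Iterable[int], tolerance: int) -> frozenset[int]:
    """Collapse sizes closer than the gel tolerance; the smallest member of
    each cluster represents it."""
    out: list[int] = []
    for s in sorted(set(sizes)):
        if out and s - out[-1] <= tolerance:
            continue
        out.append(s)
    return frozenset(out)


def run_panel(templates: Sequence[GenomicTemplate], panel: Optional[Panel] = None,
              sample_id: str = "sample", gel_tolerance: int = 25,
              max_product: int = 5000, match: MatchParams = MatchParams(),
              control_template: Optional[GenomicTemplate] = None) -> BandPattern:
    """Run the full multiplex panel on one DNA sample (1-3 templates).

    Per reaction, bands are the union of amplicon sizes over all templates,
    deduplicated within the gel tolerance.  The internal-control pair is
    evaluated against the sample templates (plus an optional dedicated
    control template); a reaction whose control fails reports no bands and
    ``control_ok=False``.
    """
    panel = panel or load_panel()
    if not templates:
        return BandPattern(sample_id=sample_id, bands={}, control_ok={},
                           valid=False, notes="no templates: sample invalid")
    ctrl_templates = list(templates)
    if control_template is not None:
        ctrl_templates.append(control_template)
    ctrl_sizes: set[int] = set()
    for t in ctrl_templates:
        for amp in predict_amplicons(t, panel.control_forward, panel.control_reverse,
                                     reaction_id="control", max_product=max_product,
                                     match=match):
            ctrl_sizes.add(amp.size)
    control_present = bool(ctrl_sizes)

    bands: dict[str, frozenset[int]] = {}
    control_ok: dict[str, bool] = {}
    for rxn in panel:
        control_ok[rxn.id] = control_present
        if not control_present:
            bands[rxn.id] = frozenset()
            continue
        sizes: set[int] = set()
        for t in templates:
            for amp in predict_amplicons(t, rxn.forward, rxn.reverse,
                                         reaction_id=rxn.id, max_product=max_product,
                                         match=match):
                sizes.add(amp.size)
        bands[rxn.id] = _dedupe_sizes(sizes, gel_tolerance)
    notes = "" if control_present else "control amplification failed on all reactions"
    return BandPattern(sample_id=sample_id, bands=bands, control_ok=control_ok,
                       valid=control_present, notes=notes)


# ---------------------------------------------------------------------------
# Packaged panel configuration
# ---------------------------------------------------------------------------

_panel_cache: Optional[Panel] = None


def load_panel(path=None) -> Panel:
    """Load the reaction panel, defaulting to the packaged five-reaction
    configuration."""
    global _panel_cache
    if path is None and _panel_cache is not None:
        return _panel_cache
    if path is None:
        text = resources.files("kirtyper.data").joinpath("panel.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    ctrl_f = Primer(cfg["control"]["forward"]["name"],
                    cfg["control"]["forward"]["seq"], "control")
    ctrl_r = Primer(cfg["control"]["reverse"]["name"],
                    cfg["control"]["reverse"]["seq"], "reverse")
    reactions = []
    for r in cfg["reactions"]:
        reactions.append(Reaction(
            id=r["id"],
            target_groups=frozenset(SubtypeGroup(g) for g in r["targets"]),
            forward=Primer(r["forward"]["name"], r["forward"]["seq"], "forward"),
            reverse=Primer(r["reverse"]["name"], r["reverse"]["seq"], "reverse"),
            control_pair=(ctrl_f, ctrl_r),
            expected_sizes={k: int(v) for k, v in r["expected_sizes"].items()},
            metadata=r.get("metadata", {}),
        ))
    panel = Panel(reactions=reactions, control_forward=ctrl_f,
                  control_reverse=ctrl_r,
                  control_size=int(cfg["control"]["expected_size"]),
                  notes=cfg.get("notes", ""))
    if path is None:
        _panel_cache = panel
    return panel


def write_band_patterns_tsv(patterns: Sequence[BandPattern], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\treaction\tsizes\tcontrol_ok\n")
        for p in patterns:
            for rid in sorted(p.bands):
                sizes = ",".join(str(s) for s in sorted(p.bands[rid])) or "-"
                fh.write(f"{p.sample_id}\t{rid}\t{sizes}\t{int(p.control_ok.get(rid, False))}\n")


def read_band_patterns_tsv(path) -> list[BandPattern]:
    """Inverse of :func:`write_band_patterns_tsv`."""
    rows: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample", "reaction"]:
            raise ValueError(f"{path}: unexpected band-pattern header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            sample, rid, sizes, ok = fields
            entry = rows.setdefault(sample, {"bands": {}, "control_ok": {}})
            entry["bands"][rid] = frozenset(
                int(s) for s in sizes.split(",")) if sizes != "-" else frozenset()
            entry["control_ok"][rid] = bool(int(ok))
    return [BandPattern(sample_id=sid, bands=e["bands"], control_ok=e["control_ok"],
                        valid=all(e["control_ok"].values()) if e["control_ok"] else False)
            for sid, e in rows.items()]
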