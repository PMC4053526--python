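"""Deterministic synthetic fixtures: genomic templates carrying the
documented diagnostic SNP states and primer footprints, diploid cohorts
drawn from population frequencies, and multi-generation pedigrees.

Scaffold geometry is calibrated so that the designed reactions reproduce
the published product sizes on fixture templates: 2019 bp (R1, null group),
1573 bp (R4, inhibitory gene), 1933 bp (R4, activating gene; the intron-3
insertion adds exactly 360 bp) and 1408 bp (R5, *007 group).  R2/R3
products land within gel resolution of their printed 1573 bp (their forward
footprints start a few bases away from the R4 footprint).  Absolute sizes
on real IPD-KIR genomic sequences remain the authoritative check.

Diagnostic exon regions are spelled out by the primer sequences themselves
(the published primers overlap consistently around CDS 193/202, 607 and
1021/1022), so the fixtures cannot drift from the panel.  Non-diagnostic
sequence is seeded-random and then overwritten at footprints; accidental
off-target sites are bounded by (1/4)^15 per position and asserted absent
in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allele_catalog import SubtypeGroup
from .insilico_pcr import (BandPattern, Feature, GenomicTemplate, Panel,
                           load_panel, reverse_complement, run_panel)

__all__ = [
    "ScaffoldSpec",
    "DEFAULT_SCAFFOLD",
    "GROUP_SNPS",
    "CohortDonor",
    "make_template",
    "make_allele_cds",
    "pattern_for_genotype",
    "simulate_cohort",
    "simulate_pedigree",
    "add_band_noise",
    "make_group_alignment",
    "random_genotype",
    "write_templates_fasta",
]

#: Diagnostic site states (p193, p202, p607, 1021/1022) per subtype group.
#: Where the published states list alternatives (LOW1 and HIGH1 tolerate
#: either transmembrane dinucleotide), one is fixed for fixtures.
GROUP_SNPS: dict[SubtypeGroup, tuple[str, str, str, str]] = {
    SubtypeGroup.NULL: ("G", "A", "T", "TG"),
    SubtypeGroup.LOW1: ("A", "A", "T", "CA"),
    SubtypeGroup.HIGH1: ("A", "A", "C", "TG"),
    SubtypeGroup.HIGH2: ("A", "G", "C", "CA"),
    SubtypeGroup.LOW2: ("A", "G", "C", "CG"),
    SubtypeGroup.S1: ("A", "G", "C", "CA"),
}

_GROUP_ALLELE = {
    SubtypeGroup.NULL: "KIR3DL1*004",
    SubtypeGroup.LOW1: "KIR3DL1*005",
    SubtypeGroup.HIGH1: "KIR3DL1*001",
    SubtypeGroup.HIGH2: "KIR3DL1*002",
    SubtypeGroup.LOW2: "KIR3DL1*007",
    SubtypeGroup.S1: "KIR3DS1*013",
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometry of the synthetic gene: exon/intron lengths, footprint
    placements and the activating-gene intron-3 insertion."""

    utr5_len: int = 120
    exon_lens: tuple[int, ...] = (34, 36, 285, 300, 300, 51, 102, 53, 174)
    # intron lengths; intron 3 (index 2) is calibrated for the R4 product,
    # introns 1-2 for R1, intron 6 for R5.  Introns 7-8 pad the template so
    # that every off-design primer pairing exceeds the product-size cap.
    intron_lens: tuple[int, ...] = (900, 862, 1128, 200, 200, 1400, 2000, 2200)
    utr3_len: int = 700
    s1_intron3_extra: int = 360
    s1_insert_offset: int = 500      # where in intron 3 the insertion sits
    consf_utr5_offset: int = 80      # R1 forward footprint start in the 5'UTR
    int6f_offset: int = 24           # R5 forward footprint start in intron 6
    control_utr3_offset: int = 20    # control forward footprint start in 3'UTR
    control_product: int = 607

    def __post_init__(self) -> None:
        if len(self.intron_lens) != len(self.exon_lens) - 1:
            raise ValueError("need one fewer intron than exons")
        bounds = self.exon_cds_bounds()
        for pos, exon_idx in ((193, 2), (202, 2), (607, 3), (1021, 6), (1022, 6)):
            lo, hi = bounds[exon_idx]
            if not (lo <= pos <= hi):
                raise ValueError(f"CDS {pos} falls outside exon {exon_idx + 1}")

    def exon_cds_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive CDS interval of each exon."""
        out, start = [], 1
        for L in self.exon_lens:
            out.append((start, start + L - 1))
            start += L
        return out

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lens)


DEFAULT_SCAFFOLD = ScaffoldSpec()


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _primers(panel: Panel) -> dict[str, str]:
    by_name = {}
    for r in panel:
        by_name[r.forward.name] = r.forward.seq
        by_name[r.reverse.name] = r.reverse.seq
    by_name[panel.control_forward.name] = panel.control_forward.seq
    by_name[panel.control_reverse.name] = panel.control_reverse.seq
    return by_name


def _diagnostic_regions(panel: Panel) -> dict[str, tuple[int, str]]:
    """Template sequence of each diagnostic region, spelled by the primers.

    Returns {region: (1-based CDS start, sequence)} with the variable sites
    left as placeholders to be filled per group.
    """
    p = _primers(panel)
    # Exon 3, CDS 168..217: the LOW1 forward primer covers 168..193 (its 3'
    # base sits on 193) and the reverse-complemented null-group reverse
    # primer covers 193..217 (3' base on 193).  Their overlap is consistent;
    # 193 and 202 are set per group afterwards.
    ex3 = list(p["202A2-F"]) + list(reverse_complement(p["193G-R"]))[1:]
    assert len(ex3) == 50
    # Exon 4, CDS 607..627: reverse-complemented 607C-R; site 607 per group.
    ex4 = list(reverse_complement(p["607C-R"]))
    # Exon 7, CDS 1021..1038: reverse-complemented exon-7 reverse primer;
    # the 1021/1022 dinucleotide is set per group.
    ex7 = list(reverse_complement(p["1021/22-S-R"]))
    return {"ex3": (168, "".join(ex3)), "ex4": (607, "".join(ex4)),
            "ex7": (1021, "".join(ex7))}


_template_cache: dict[tuple, GenomicTemplate] = {}


def make_template(group: SubtypeGroup, scaffold: ScaffoldSpec = DEFAULT_SCAFFOLD,
                  seed: int = 0, panel: Optional[Panel] = None,
                  include_control_sites: bool = True) -> GenomicTemplate:
    """Build the genomic template of a subtype group's canonical allele.

    Templates built from the same scaffold and seed are identical across
    groups except at the diagnostic sites (and the intron-3 insertion for
    the activating group), mirroring the conservation the assay relies on.
    Deterministic per (group, scaffold, seed).
    """
    if group is SubtypeGroup.UNCLASSIFIED:
        raise ValueError("no fixture template for UNCLASSIFIED")
    panel = panel or load_panel()
    key = (group, scaffold, seed, panel.key, include_control_sites)
    if key in _template_cache:
        return _template_cache[key]

    rng = np.random.default_rng(seed)
    p = _primers(panel)
    regions = _diagnostic_regions(panel)
    p193, p202, p607, dinuc = GROUP_SNPS[group]

    # Background segments, drawn in fixed order so every group shares them.
    utr5 = _rand_bases(rng, scaffold.utr5_len)
    exons = [_rand_bases(rng, L) for L in scaffold.exon_lens]
    introns = [_rand_bases(rng, L) for L in scaffold.intron_lens]
    utr3 = _rand_bases(rng, scaffold.utr3_len)
    insert = _rand_bases(np.random.default_rng((seed, 3360)),
                         scaffold.s1_intron3_extra)

    bounds = scaffold.exon_cds_bounds()

    def overwrite_cds(cds_start: int, text: str) -> None:
        for i, ch in enumerate(text):
            pos = cds_start + i
            for exon_idx, (lo, hi) in enumerate(bounds):
                if lo <= pos <= hi:
                    exons[exon_idx][pos - lo] = ch
                    break
            else:
                raise ValueError(f"CDS position {pos} not exonic")

    for name in ("ex3", "ex4", "ex7"):
        start, text = regions[name]
        overwrite_cds(start, text)
    overwrite_cds(193, p193)
    overwrite_cds(202, p202)
    overwrite_cds(607, p607)
    overwrite_cds(1021, dinuc)

    # Conserved non-CDS footprints.
    utr5[scaffold.consf_utr5_offset:
         scaffold.consf_utr5_offset + len(p["ConsF"])] = list(p["ConsF"])
    introns[5][scaffold.int6f_offset:
               scaffold.int6f_offset + len(p["int6-F"])] = list(p["int6-F"])
    if include_control_sites:
        cf, cr = p["FDRA-360"], p["RDRA-633"]
        o = scaffold.control_utr3_offset
        utr3[o:o + len(cf)] = list(cf)
        rc = reverse_complement(cr)
        utr3[o + scaffold.control_product - len(cr):
             o + scaffold.control_product] = list(rc)

    if group is SubtypeGroup.S1:
        i3 = introns[2]
        introns[2] = (i3[:scaffold.s1_insert_offset] + insert
                      + i3[scaffold.s1_insert_offset:])

    parts: list[tuple[str, list[str]]] = [("utr5", utr5)]
    for i, ex in enumerate(exons):
        parts.append(("exon", ex))
        if i < len(introns):
            parts.append(("intron", introns[i]))
    parts.append(("utr3", utr3))

    seq_parts, features, pos = [], [], 0
    for kind, segment in parts:
        seq_parts.append("".join(segment))
        features.append(Feature(kind=kind, start=pos, end=pos + len(segment)))
        pos += len(segment)

    template = GenomicTemplate(allele_name=_GROUP_ALLELE[group],
                               seq="".join(seq_parts), feature_map=features,
                               group=group)
    _template_cache[key] = template
    return template


def make_allele_cds(group: SubtypeGroup, scaffold: ScaffoldSpec = DEFAULT_SCAFFOLD,
                    seed: int = 0) -> str:
    """Coding sequence of the group's fixture template."""
    return make_template(group, scaffold, seed).cds


# ---------------------------------------------------------------------------
# Band-pattern cache (templates are identical across donors, so a genotype's
# pattern is computed once per panel/scaffold/seed)
# ---------------------------------------------------------------------------

_pattern_cache: dict[tuple, BandPattern] = {}


def pattern_for_genotype(groups: Sequence[SubtypeGroup],
                         panel: Optional[Panel] = None,
                         scaffold: ScaffoldSpec = DEFAULT_SCAFFOLD,
                         seed: int = 0, sample_id: str = "sample") -> BandPattern:
    """Band pattern of a sample carrying the given group multiset (1-3
    templates).  Cached by genotype; the returned pattern is re-labeled with
    ``sample_id``."""
    panel = panel or load_panel()
    gkey = tuple(sorted(g.value for g in groups))
    key = (gkey, panel.key, scaffold, seed)
    if key not in _pattern_cache:
        templates = [make_template(g, scaffold, seed, panel) for g in groups]
        _pattern_cache[key] = run_panel(templates, panel, sample_id="genotype")
    base = _pattern_cache[key]
    return BandPattern(sample_id=sample_id, bands=dict(base.bands),
                       control_ok=dict(base.control_ok), valid=base.valid,
                       notes=base.notes)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDonor:
    sample_id: str
    genotype: tuple[SubtypeGroup, ...]
    templates: list[GenomicTemplate]


def _normalize(freqs: dict[SubtypeGroup, float]) -> tuple[list[SubtypeGroup], np.ndarray]:
    groups = sorted(freqs, key=lambda g: g.value)
    probs = np.array([freqs[g] for g in groups], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError("group frequencies must have positive total mass")
    return groups, probs / total


def random_genotype(freqs: dict[SubtypeGroup, float],
                    rng: np.random.Generator) -> tuple[SubtypeGroup, SubtypeGroup]:
    groups, probs = _normalize(freqs)
    i, j = rng.choice(len(groups), size=2, p=probs)
    pair = sorted((groups[i], groups[j]), key=lambda g: g.value)
    return (pair[0], pair[1])


def simulate_cohort(freqs: dict[SubtypeGroup, float], n: int, seed: int = 0,
                    scaffold: ScaffoldSpec = DEFAULT_SCAFFOLD) -> list[CohortDonor]:
    """Simulate ``n`` diploid donors: 2n independent allele draws from the
    normalized group frequencies, paired per donor.  Deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    groups, probs = _normalize(freqs)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(groups), size=2 * n, p=probs)
    donors = []
    for d in range(n):
        pair = sorted((groups[draws[2 * d]], groups[draws[2 * d + 1]]),
                      key=lambda g: g.value)
        templates = [make_template(g, scaffold) for g in pair]
        donors.append(CohortDonor(sample_id=f"D{d + 1:05d}",
                                  genotype=tuple(pair), templates=templates))
    return donors


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def simulate_pedigree(founder_genotypes: dict[str, tuple[SubtypeGroup, ...]],
                      generations: int = 1,
                      duplicated_haplotype: Optional[tuple[str, tuple[SubtypeGroup, SubtypeGroup]]] = None,
                      seed: int = 0, children_per_couple: int = 2,
                      scaffold: ScaffoldSpec = DEFAULT_SCAFFOLD,
                      panel: Optional[Panel] = None):
    """Simulate a multi-generation pedigree with Mendelian transmission.

    Each individual carries two haplotype units; a unit is normally a single
    group but may be a linked pair when ``duplicated_haplotype`` marks a
    founder as carrying two genes on one haplotype (such carriers must be
    given a 3-group genotype, or a 2-group genotype whose second haplotype
    is then empty).  Children of each couple receive one unit per parent;
    spouses marrying into later generations are drawn from the founder
    genotype pool.  Returns a :class:`~kirtyper.pattern_decoder.Pedigree`
    whose calls are band patterns, with ``truth`` holding true genotypes.
    """
    from .pattern_decoder import Pedigree  # local import avoids a cycle

    if len(founder_genotypes) < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    panel = panel or load_panel()
    if duplicated_haplotype and duplicated_haplotype[0] not in founder_genotypes:
        raise ValueError(f"duplicated haplotype carrier {duplicated_haplotype[0]} "
                         "is not a founder")

    haplotypes: dict[str, list[tuple[SubtypeGroup, ...]]] = {}
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for fid, genotype in founder_genotypes.items():
        parents[fid] = (None, None)
        if duplicated_haplotype and duplicated_haplotype[0] == fid:
            linked = tuple(duplicated_haplotype[1])
            rest = list(genotype)
            for g in linked:
                if g not in rest:
                    raise ValueError(f"duplicated haplotype groups {linked} not "
                                     f"carried by founder {fid}")
                rest.remove(g)
            haplotypes[fid] = [linked, tuple(rest)]
        else:
            if len(genotype) != 2:
                raise ValueError(f"founder {fid}: genotype must have 2 groups "
                                 "unless it carries the duplicated haplotype")
            haplotypes[fid] = [(genotype[0],), (genotype[1],)]

    founder_pool = list(founder_genotypes.values())
    current = list(founder_genotypes)
    next_id = 1
    for gen in range(1, generations + 1):
        couples = [(current[i], current[i + 1])
                   for i in range(0, len(current) - 1, 2)]
        children: list[str] = []
        for father, mother in couples:
            for _ in range(children_per_couple):
                cid = f"G{gen}-{next_id:03d}"
                next_id += 1
                parents[cid] = (father, mother)
                units = []
                for par in (father, mother):
                    units.append(haplotypes[par][int(rng.integers(0, 2))])
                haplotypes[cid] = units
                children.append(cid)
        # children pair with fresh spouses sampled from the founder pool
        current = []
        for cid in children:
            current.append(cid)
            if gen < generations:
                sid = f"S{gen}-{next_id:03d}"
                next_id += 1
                geno = founder_pool[int(rng.integers(0, len(founder_pool)))]
                if len(geno) != 2:
                    geno = tuple(geno[:2])
                parents[sid] = (None, None)
                haplotypes[sid] = [(geno[0],), (geno[1],)]
                current.append(sid)

    truth = {iid: tuple(sorted((g for unit in units for g in unit),
                               key=lambda g: g.value))
             for iid, units in haplotypes.items()}
    calls = {iid: pattern_for_genotype(truth[iid], panel, scaffold,
                                       sample_id=iid)
             for iid in parents}
    ped = Pedigree(parents=parents, calls=calls)
    ped.truth = truth
    ped.haplotypes = haplotypes
    return ped


# ---------------------------------------------------------------------------
# Noise and alignments
# ---------------------------------------------------------------------------

def add_band_noise(pattern: BandPattern, dropout_prob: float,
                   seed: int = 0) -> BandPattern:
    """Drop each band independently with probability ``dropout_prob``;
    control flags are never touched.  Deterministic per seed."""
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bands = {}
    for rid in sorted(pattern.bands):
        kept = frozenset(s for s in sorted(pattern.bands[rid])
                         if rng.random() >= dropout_prob)
        bands[rid] = kept
    return BandPattern(sample_id=pattern.sample_id, bands=bands,
                       control_ok=dict(pattern.control_ok),
                       valid=pattern.valid, notes=pattern.notes)


def make_group_alignment(members_per_group: int = 3, noise_rate: float = 0.01,
                         length: int = 1100, seed: int = 0,
                         groups: Optional[Sequence[SubtypeGroup]] = None
                         ) -> dict[str, str]:
    """Equal-length alignment with one random reference per group (carrying
    the group's diagnostic states) and noisy members around it, for
    phylogeny fixtures.  Noise avoids the diagnostic sites."""
    if length < 1022:
        raise ValueError("length must cover CDS position 1022")
    groups = list(groups or GROUP_SNPS)
    rng = np.random.default_rng(seed)
    diag_sites = [192, 201, 606, 1020, 1021]  # 0-based
    out: dict[str, str] = {}
    for gi, group in enumerate(groups):
        ref = _rand_bases(np.random.default_rng((seed, gi)), length)
        p193, p202, p607, dinuc = GROUP_SNPS[group]
        ref[192], ref[201], ref[606] = p193, p202, p607
        ref[1020], ref[1021] = dinuc[0], dinuc[1]
        for m in range(members_per_group):
            seq = list(ref)
            n_sub = rng.binomial(length, noise_rate)
            for pos in rng.choice(length, size=n_sub, replace=False):
                if int(pos) in diag_sites:
                    continue
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(0, 3))]
            out[f"{group.value}_{m + 1}"] = "".join(seq)
    return out


def write_templates_fasta(templates: Sequence[GenomicTemplate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in templates:
            group = t.group.value if t.group else "NA"
            fh.write(f">{t.allele_name} group={group}\n")
            for i in range(0, len(t.seq), 70):
                fh.write(t.seq[i:i + 70] + "\n")
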