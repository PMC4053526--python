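"""Data model and I/O for KIR3DL1/KIR3DS1 alleles, subtype groups and
population frequency tables.

The locus carries six functionally distinct allele subtypes (one null, two
low-expression, two high-expression, one activating) distinguishable by the
states of four diagnostic coding-sequence sites: 193, 202, 607 and the
1021/1022 dinucleotide (1-based from the A of the initiator ATG).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeGroup",
    "Allele",
    "SNPProfile",
    "FrequencyTable",
    "FrequencyEntry",
    "ALLELE_GROUPS",
    "HIGH_FREQUENCY_ALLELES",
    "read_allele_fasta",
    "extract_snp_profile",
    "load_frequency_table",
    "write_frequency_table",
    "expected_phenotype",
    "parse_allele_name",
    "collapse_allele_name",
]

DNA_ALPHABET = set("ACGTN")

_ALLELE_NAME_RE = re.compile(r"(KIR3D[LS]1)\*(\d{3,})(N?)")


class SubtypeGroup(Enum):
    """The six functional allele subtypes, plus a bin for sequences that
    match no decision rule."""

    NULL = "NULL"
    LOW1 = "LOW1"
    LOW2 = "LOW2"
    HIGH1 = "HIGH1"
    HIGH2 = "HIGH2"
    S1 = "S1"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # cleaner report output
        return self.value

    @property
    def canonical_allele(self) -> Optional[str]:
        return _CANONICAL_ALLELE.get(self)

    @property
    def expression_class(self) -> str:
        return _EXPRESSION_CLASS.get(self, "unknown")


_CANONICAL_ALLELE = {
    SubtypeGroup.NULL: "KIR3DL1*004",
    SubtypeGroup.LOW1: "KIR3DL1*005",
    SubtypeGroup.LOW2: "KIR3DL1*007",
    SubtypeGroup.HIGH1: "KIR3DL1*001",
    SubtypeGroup.HIGH2: "KIR3DL1*002",
    SubtypeGroup.S1: "KIR3DS1*013",
}

_EXPRESSION_CLASS = {
    SubtypeGroup.NULL: "null",
    SubtypeGroup.LOW1: "low",
    SubtypeGroup.LOW2: "low",
    SubtypeGroup.HIGH1: "high",
    SubtypeGroup.HIGH2: "high",
    SubtypeGroup.S1: "activating",
    SubtypeGroup.UNCLASSIFIED: "unknown",
}

#: The 11 high-frequency alleles and their subtype group.
HIGH_FREQUENCY_ALLELES = {
    "KIR3DL1*004": SubtypeGroup.NULL,
    "KIR3DL1*005": SubtypeGroup.LOW1,
    "KIR3DL1*007": SubtypeGroup.LOW2,
    "KIR3DL1*001": SubtypeGroup.HIGH1,
    "KIR3DL1*016": SubtypeGroup.HIGH1,
    "KIR3DL1*002": SubtypeGroup.HIGH2,
    "KIR3DL1*015": SubtypeGroup.HIGH2,
    "KIR3DL1*008": SubtypeGroup.HIGH2,
    "KIR3DL1*009": SubtypeGroup.HIGH2,
    "KIR3DL1*020": SubtypeGroup.HIGH2,
    "KIR3DS1*013": SubtypeGroup.S1,
}

# Full published group membership, low-frequency alleles included.  *042 and
# *073 carry site states matching no reaction and stay unclassified.
_LOW_FREQUENCY_GROUPS = {
    SubtypeGroup.NULL: ["019", "021", "036", "037", "039", "040", "056",
                        "063", "072"],
    SubtypeGroup.LOW1: ["041", "044", "053"],
    SubtypeGroup.HIGH1: ["026", "027", "043", "052", "059", "060", "061",
                         "064", "065", "067", "075"],
    SubtypeGroup.HIGH2: ["006", "017", "018", "022", "023", "024N", "025",
                         "028", "029", "030", "031", "034", "035", "038",
                         "051", "054", "057", "062", "066", "074", "076",
                         "077"],
    SubtypeGroup.LOW2: ["032", "033", "068"],
    SubtypeGroup.S1: ["010", "011", "012", "014", "045", "046", "047",
                      "048", "049N", "050", "055", "058"],
}

ALLELE_GROUPS: dict[str, SubtypeGroup] = dict(HIGH_FREQUENCY_ALLELES)
for _grp, _nums in _LOW_FREQUENCY_GROUPS.items():
    _gene = "KIR3DS1" if _grp is SubtypeGroup.S1 else "KIR3DL1"
    for _num in _nums:
        ALLELE_GROUPS[f"{_gene}*{_num}"] = _grp
ALLELE_GROUPS["KIR3DL1*042"] = SubtypeGroup.UNCLASSIFIED
ALLELE_GROUPS["KIR3DL1*073"] = SubtypeGroup.UNCLASSIFIED


@dataclass(frozen=True)
class SNPProfile:
    """States of the four diagnostic CDS sites of one allele.

    A site is ``None`` when the sequence is too short to read it; it is
    then reported as incomplete rather than guessed.
    """

    p193: Optional[str]
    p202: Optional[str]
    p607: Optional[str]
    p1021_1022: Optional[str]

    def __post_init__(self) -> None:
        for attr in ("p193", "p202", "p607"):
            v = getattr(self, attr)
            if v is not None and v not in DNA_ALPHABET:
                raise ValueError(f"{attr} must be one of A/C/G/T/N, got {v!r}")
        d = self.p1021_1022
        if d is not None:
            if len(d) != 2 or any(b not in DNA_ALPHABET for b in d):
                raise ValueError(f"dinucleotide must be 2 nt over A/C/G/T/N, got {d!r}")

    def is_complete(self, site: str) -> bool:
        return getattr(self, site) is not None

    def to_dict(self) -> dict:
        return {
            "p193": self.p193,
            "p202": self.p202,
            "p607": self.p607,
            "p1021_1022": self.p1021_1022,
        }


@dataclass
class Allele:
    """A single allele: name, coding sequence, optional genomic sequence."""

    name: str
    cds: str
    genomic: Optional[str] = None
    group: Optional[SubtypeGroup] = None
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.cds:
            raise ValueError(f"{self.name}: empty coding sequence")
        bad = set(self.cds.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-ACGTN characters in CDS: {sorted(bad)}")
        self.cds = self.cds.upper()

    @property
    def gene(self) -> Optional[str]:
        m = _ALLELE_NAME_RE.search(self.name)
        return m.group(1) if m else None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cds": self.cds,
            "genomic": self.genomic,
            "group": self.group.value if self.group else None,
            "frequency": self.frequency,
        }


def parse_allele_name(text: str) -> tuple[str, str, str]:
    """Extract (gene, designation digits, null suffix) from a FASTA header.

    Raises ``ValueError`` if no IPD-style allele name is present.
    """
    m = _ALLELE_NAME_RE.search(text)
    if m is None:
        raise ValueError(f"no parsable allele name in header: {text!r}")
    return m.group(1), m.group(2), m.group(3)


def collapse_allele_name(name: str) -> str:
    """Reduce a suballele designation to its three-digit canonical allele
    (``KIR3DL1*0040101`` -> ``KIR3DL1*004``).  Idempotent."""
    gene, digits, null = parse_allele_name(name)
    if len(digits) > 3:
        digits = digits[:3]
    return f"{gene}*{digits}{null}"


def read_allele_fasta(path, collapse_suballeles: bool = True) -> list[Allele]:
    """Read a multi-FASTA of coding sequences into :class:`Allele` records.

    Suballeles differing only beyond the three-digit designation collapse
    onto their canonical allele; the first-seen sequence wins and later
    duplicates are dropped with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: dict[str, Allele] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        gene, digits, null = parse_allele_name(rec.description)
        name = f"{gene}*{digits}{null}"
        if collapse_suballeles:
            name = collapse_allele_name(name)
        if name in seen:
            logger.info("duplicate canonical allele %s (record %s): keeping first-seen sequence",
                        name, rec.id)
            continue
        seen[name] = Allele(name=name, cds=str(rec.seq),
                            group=ALLELE_GROUPS.get(name))
    if n_records == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return list(seen.values())


def extract_snp_profile(allele: Allele, coordinate_offset: int = 0) -> SNPProfile:
    """Read the four diagnostic sites from an allele's CDS.

    ``coordinate_offset`` shifts the transmembrane dinucleotide only: 0 reads
    1021/1022, -1 reads 1020/1021 (both coordinate conventions appear in the
    literature for the same physical sites).
    """
    if coordinate_offset not in (0, -1):
        raise ValueError("coordinate_offset must be 0 or -1")
    cds = allele.cds
    if len(cds) < 193:
        raise ValueError(f"{allele.name}: sequence too short for typing "
                         f"({len(cds)} nt < 193)")

    def base(pos: int) -> Optional[str]:
        return cds[pos - 1] if len(cds) >= pos else None

    lo = 1021 + coordinate_offset
    dinuc = cds[lo - 1:lo + 1] if len(cds) >= lo + 1 else None
    return SNPProfile(p193=base(193), p202=base(202), p607=base(607),
                      p1021_1022=dinuc)


# ---------------------------------------------------------------------------
# Population frequency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyEntry:
    allele: str          # may be a joint label, e.g. "KIR3DL1*001/*016"
    frequency: float     # percent
    n_alleles: int = 1   # printed allele count for joint rows


@dataclass
class FrequencyTable:
    entries: list[FrequencyEntry]
    source_n: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.frequency < 0:
                raise ValueError(f"negative frequency for {e.allele}: {e.frequency}")
        total = sum(e.frequency for e in self.entries)
        if total > 100.1:
            raise ValueError(f"frequencies sum to {total:.2f}% > 100.1%")

    @property
    def allele_observations(self) -> int:
        """Number of allele observations: two per diploid donor."""
        return 2 * self.source_n

    def total_percent(self) -> float:
        return sum(e.frequency for e in self.entries)


def load_frequency_table(path) -> FrequencyTable:
    """Load a tab-separated allele frequency table.

    Columns: allele, frequency_pct and optionally n_alleles.  ``#`` lines
    are comments; a ``# donors: N`` comment sets the cohort size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[FrequencyEntry] = []
    source_n = 0
    header_skipped = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"donors:\s*(\d+)", line)
                if m:
                    source_n = int(m.group(1))
                continue
            fields = line.split("\t")
            if not header_skipped and fields[0].lower() in ("allele", "name"):
                header_skipped = True
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated "
                                 f"columns, got {len(fields)}")
            try:
                freq = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad frequency {fields[1]!r}") from exc
            n_alleles = 1
            if len(fields) >= 3 and fields[2]:
                n_alleles = int(fields[2])
            entries.append(FrequencyEntry(fields[0], freq, n_alleles))
    return FrequencyTable(entries=entries, source_n=source_n)


def write_frequency_table(table: FrequencyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# donors: {table.source_n}\n")
        fh.write("allele\tfrequency_pct\tn_alleles\n")
        for e in table.entries:
            fh.write(f"{e.allele}\t{e.frequency:.2f}\t{e.n_alleles}\n")


_PHENOTYPES = {
    SubtypeGroup.HIGH1: "DX9+Z27+ high",
    SubtypeGroup.HIGH2: "DX9+Z27+ high",
    SubtypeGroup.LOW1: "DX9+Z27+ low",
    SubtypeGroup.LOW2: "DX9+Z27+ low",
    SubtypeGroup.NULL: "surface-negative",
    SubtypeGroup.S1: "Z27+DX9-",
}


def expected_phenotype(group: SubtypeGroup) -> str:
    """NK surface phenotype (DX9/Z27 antibody staining) predicted for a
    subtype group."""
    if group is SubtypeGroup.UNCLASSIFIED:
        raise ValueError("no phenotype defined for UNCLASSIFIED")
    return _PHENOTYPES[group]
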