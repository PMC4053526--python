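"""Frequency arithmetic: cumulative allele frequencies, Hardy-Weinberg
genotype frequencies, typing-ambiguity rates, and EM estimation of group
frequencies from typed cohorts."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .allele_catalog import (ALLELE_GROUPS, FrequencyTable, SubtypeGroup,
                             collapse_allele_name)
from .pattern_decoder import DecodeResult, GenotypeHypothesis

logger = logging.getLogger(__name__)

__all__ = [
    "GroupFrequencyTable",
    "group_frequencies",
    "cumulative_frequency",
    "hwe_genotype_frequency",
    "ambiguity_rate",
    "estimate_group_frequencies",
]


@dataclass
class GroupFrequencyTable:
    """Subtype-group frequencies as proportions in [0, 1]."""

    frequencies: dict[SubtypeGroup, float]
    derived_from: str = ""
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, f in self.frequencies.items():
            if f < 0:
                raise ValueError(f"negative frequency for {g}")
        total = sum(self.frequencies.values())
        if total > 1 + 1e-9:
            raise ValueError(f"group frequencies sum to {total} > 1")

    def __getitem__(self, group: SubtypeGroup) -> float:
        return self.frequencies.get(group, 0.0)

    def total(self) -> float:
        return sum(self.frequencies.values())

    def normalized(self) -> "GroupFrequencyTable":
        """Renormalize to unit total (mandatory before HWE arithmetic; the
        renormalization is logged)."""
        total = self.total()
        if total <= 0:
            raise ValueError("cannot normalize a zero-mass table")
        if abs(total - 1.0) > 1e-12:
            logger.info("renormalizing group frequencies from total %.6f to 1",
                        total)
        return GroupFrequencyTable(
            frequencies={g: f / total for g, f in self.frequencies.items()},
            derived_from=self.derived_from + " (normalized)")


def group_frequencies(table: FrequencyTable,
                      mapping: Optional[dict[str, SubtypeGroup]] = None,
                      min_percent: float = 0.0) -> GroupFrequencyTable:
    """Aggregate an allele-frequency table into group frequencies.

    Joint rows (``A/*B``) are assigned to the group of their first-listed
    allele, which holds for the one joint row in the packaged table (both
    alleles belong to the same group).  Unmapped alleles are skipped; the
    aggregation is lossless for mapped mass.  ``min_percent=1.0`` restricts
    the mass to the high-frequency alleles the assay was designed around.
    """
    mapping = mapping or ALLELE_GROUPS
    out: dict[SubtypeGroup, float] = {}
    for entry in table.entries:
        if entry.frequency <= min_percent and min_percent > 0:
            continue
        name = entry.allele.split("/")[0]
        try:
            name = collapse_allele_name(name)
        except ValueError:
            pass
        group = mapping.get(name)
        if group is None or group is SubtypeGroup.UNCLASSIFIED:
            continue
        out[group] = out.get(group, 0.0) + entry.frequency / 100.0
    return GroupFrequencyTable(frequencies=out, derived_from="allele table")


def cumulative_frequency(table: FrequencyTable,
                         min_percent: float) -> tuple[int, float]:
    """(allele count, cumulative percent) over entries whose printed
    frequency strictly exceeds the threshold.  Joint rows contribute their
    printed allele count."""
    count = 0
    cum = 0.0
    for e in table.entries:
        if e.frequency > min_percent:
            count += e.n_alleles
            cum += e.frequency
    return count, round(cum, 10)


def hwe_genotype_frequency(groups: GroupFrequencyTable,
                           pair: Sequence[SubtypeGroup]) -> float:
    """Hardy-Weinberg genotype frequency: p^2 for a homozygous pair, 2pq
    for a heterozygous pair.  Symmetric in the pair; a group with zero or
    missing frequency gives 0."""
    if len(pair) != 2:
        raise ValueError("pair must contain exactly 2 groups")
    a, b = pair
    p, q = groups[a], groups[b]
    if p == 0 or q == 0:
        logger.debug("zero-frequency group in pair %s/%s", a, b)
        return 0.0
    return p * p if a == b else 2 * p * q


def ambiguity_rate(groups: GroupFrequencyTable,
                   collisions: Iterable[Iterable[GenotypeHypothesis]]) -> float:
    """Total HWE probability of genotypes whose band patterns are not
    uniquely decodable (each collision is a set of hypotheses sharing one
    pattern)."""
    seen: set[tuple] = set()
    rate = 0.0
    for collision in collisions:
        for hyp in collision:
            if len(hyp.groups) != 2 or hyp.groups in seen:
                continue
            seen.add(hyp.groups)
            rate += hwe_genotype_frequency(groups, hyp.groups)
    return rate


def _hwe_prob(freqs: dict[SubtypeGroup, float],
              hyp: GenotypeHypothesis) -> float:
    a, b = hyp.groups[0], hyp.groups[-1]
    p, q = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return p * p if a == b else 2 * p * q


def estimate_group_frequencies(cohort: Sequence[DecodeResult],
                               max_em_iters: int = 200,
                               tol: float = 1e-8) -> GroupFrequencyTable:
    """Maximum-likelihood group frequencies from decoded genotypes by EM.

    Unambiguous calls count their two groups directly; ambiguous calls
    contribute fractionally by their HWE posterior under the current
    estimate.  Converges when the largest frequency change drops below
    ``tol``; the observed-data log-likelihood trace is retained and is
    non-decreasing.
    """
    if not cohort:
        raise ValueError("empty cohort")
    observations = [res.hypotheses for res in cohort
                    if res.hypotheses
                    and all(len(h.groups) == 2 for h in res.hypotheses)]
    if not observations:
        raise ValueError("cohort contains no decodable diploid samples")
    groups = sorted({g for hyps in observations for h in hyps
                     for g in h.groups}, key=lambda g: g.value)
    freqs = {g: 1.0 / len(groups) for g in groups}
    trace: list[float] = []
    n_alleles = 2 * len(observations)
    for _ in range(max_em_iters):
        counts = {g: 0.0 for g in groups}
        loglik = 0.0
        for hyps in observations:
            probs = {h: _hwe_prob(freqs, h) for h in hyps}
            total = sum(probs.values())
            loglik += math.log(total) if total > 0 else -math.inf
            if total <= 0:  # degenerate start: spread evenly
                probs = {h: 1.0 / len(hyps) for h in hyps}
                total = 1.0
            for h, p in probs.items():
                w = p / total
                counts[h.groups[0]] += w
                counts[h.groups[-1]] += w
        trace.append(loglik)
        new = {g: counts[g] / n_alleles for g in groups}
        delta = max(abs(new[g] - freqs[g]) for g in groups)
        freqs = new
        if delta < tol:
            break
    return GroupFrequencyTable(frequencies=freqs, derived_from="EM estimate",
                               loglik_trace=trace)
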