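"""Per-embryo haplotype support counting, calling and recombination scan.

For each embryo biopsy the pipeline counts, over the informative markers,
how many sites support the paternal X (F(X)) and each maternal haplotype
(M(X1), M(X2)).  A maternal haplotype is called when the winning count is
large enough and the contradicting minority small enough; the disposition
then follows from the called haplotype, the embryo sex and which haplotype
is mutant-linked (X-linked recessive convention: hemizygous mutant male is
Affected, heterozygous female is Carrier).

Single-cell WGA data are noisy: allele drop-out can silence a marker or
flip an apparent genotype, so thresholds below are deliberately
conservative and exact ties are never broken by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import ConfigError, SnpTable
from .phasing import CLASS_MALE_ONLY, PhasedMaternalHaplotypes

SUPPORT_X1 = "X1"
SUPPORT_X2 = "X2"
SUPPORT_AMBIG = "ambiguous"
SUPPORT_NOCALL = "no-call"

DISP_NORMAL = "N"
DISP_AFFECTED = "A"
DISP_CARRIER = "C"
DISP_UNDETERMINED = "-"


class DirectTestInconsistencyError(ValueError):
    """Direct-assay results contradict each other (possible contamination)."""


@dataclass(frozen=True)
class CallParams:
    """Thresholds governing when an embryo is called.

    min_informative: minimum winning-haplotype support count.
    max_minority_fraction: tolerated contradicting fraction
        minority / (m_x1 + m_x2).
    recomb_min_segment: minimum run of consecutive concordant markers for a
        haplotype segment to be trusted in the recombination scan.
    sex_min_het / sex_het_fraction / sex_min_fx: evidence thresholds for sex
        inference from SNPs (see :func:`infer_sex`).
    """

    min_informative: int = 10
    max_minority_fraction: float = 0.05
    recomb_min_segment: int = 5
    sex_min_het: int = 3
    sex_het_fraction: float = 0.2
    sex_min_fx: int = 2
    min_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_informative < 1:
            raise ConfigError("min_informative must be >= 1")
        if not 0.0 <= self.max_minority_fraction < 0.5:
            raise ConfigError("max_minority_fraction must be in [0, 0.5)")
        if self.recomb_min_segment < 1:
            raise ConfigError("recomb_min_segment must be >= 1")


@dataclass
class SupportCounts:
    """Informative-marker support for one embryo.

    ``per_site`` keeps the ordered (position, support label) vector over the
    maternal-informative markers for the recombination scan.
    """

    f_x: int = 0
    m_x1: int = 0
    m_x2: int = 0
    per_site: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class EmbryoCall:
    """Final per-embryo result row."""

    embryo: str
    sex: str  # "F" | "M" | "unknown"
    haplotype: str | None  # "X1" | "X2" | None
    disposition: str  # "N" | "A" | "C" | "-"
    counts: SupportCounts
    recombinant: bool = False
    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    undetermined_reason: str | None = None


def _usable(g, depth, min_depth) -> bool:
    return g is not None and depth > min_depth


def count_support(
    table: SnpTable,
    embryo: str,
    phase: PhasedMaternalHaplotypes,
    sex: str,
    min_depth: int = 10,
) -> SupportCounts:
    """Count paternal-X and maternal-haplotype support for one embryo.

    Male logic: at every maternal-informative site the embryo's hemizygous
    allele (observed as a homozygous diploid-style call) is matched against
    X1/X2; an apparently heterozygous call is a drop-in artifact and counts
    as ambiguous.  Female logic: only the x1-/x2-detecting sites are used;
    the paternal allele is subtracted and the residual maternal allele
    attributed.  A homozygous call for the allele shared by the father and
    one maternal haplotype cannot be attributed (paternal vs maternal copy)
    and is ambiguous.  F(X) counts paternal-informative markers at which the
    paternal allele is observed.
    """
    calls = table.calls[embryo]
    depths = table.depths[embryo]
    counts = SupportCounts()

    for k in range(phase.n_informative):
        i = int(phase.indices[k])
        pos = int(phase.positions[k])
        g = calls[i]
        if not _usable(g, depths[i], min_depth):
            counts.per_site.append((pos, SUPPORT_NOCALL))
            continue
        x1, x2, f = int(phase.x1[k]), int(phase.x2[k]), int(phase.father[k])
        alleles = set(g)
        label = SUPPORT_AMBIG
        if sex == "M":
            if len(alleles) == 1:
                a = alleles.pop()
                label = SUPPORT_X1 if a == x1 else SUPPORT_X2
        else:  # female (or unknown treated as female: requires paternal call)
            if phase.site_class[k] != CLASS_MALE_ONLY:
                if len(alleles) == 2:
                    residual = (alleles - {f}).pop()
                    label = SUPPORT_X1 if residual == x1 else SUPPORT_X2
                else:
                    a = alleles.pop()
                    if a != f:
                        label = SUPPORT_X1 if a == x1 else SUPPORT_X2
        if label == SUPPORT_X1:
            counts.m_x1 += 1
        elif label == SUPPORT_X2:
            counts.m_x2 += 1
        counts.per_site.append((pos, label))

    for k in range(len(phase.paternal_indices)):
        i = int(phase.paternal_indices[k])
        g = calls[i]
        if _usable(g, depths[i], min_depth) and int(phase.paternal_allele[k]) in g:
            counts.f_x += 1
    return counts


def infer_sex(
    table: SnpTable,
    embryo: str,
    phase: PhasedMaternalHaplotypes,
    params: CallParams = CallParams(),
    sry_flag: bool | None = None,
) -> str:
    """Infer embryo sex from marker evidence (or an authoritative SRY assay).

    A female embryo carries a paternal X, so she is heterozygous at the
    detecting sites where the paternal allele differs from her transmitted
    maternal allele (about half of them) and shows the paternal allele at
    paternal-informative markers.  A male is hemizygous everywhere.  The
    heterozygosity criterion is a fraction of usable sites rather than an
    absolute count, and paternal-marker evidence requires ``sex_min_fx``
    sites, so that rare drop-in artifacts do not masquerade as a paternal X.
    """
    if sry_flag is not None:
        return "M" if sry_flag else "F"
    calls = table.calls[embryo]
    depths = table.depths[embryo]
    n_usable = 0
    n_het = 0
    for k in range(phase.n_informative):
        i = int(phase.indices[k])
        g = calls[i]
        if not _usable(g, depths[i], params.min_depth):
            continue
        n_usable += 1
        if len(set(g)) == 2:
            n_het += 1
    f_x = 0
    for k in range(len(phase.paternal_indices)):
        i = int(phase.paternal_indices[k])
        g = calls[i]
        if _usable(g, depths[i], params.min_depth) and int(phase.paternal_allele[k]) in g:
            f_x += 1
    if f_x >= params.sex_min_fx:
        return "F"
    if n_usable < params.sex_min_het:
        return "unknown"
    threshold = max(params.sex_min_het, math.ceil(params.sex_het_fraction * n_usable))
    return "F" if n_het >= threshold else "M"


def call_embryo(
    counts: SupportCounts,
    sex: str,
    mutant_linked: str,
    params: CallParams = CallParams(),
) -> EmbryoCall:
    """Call the inherited maternal haplotype and the disposition.

    The winner w = argmax(m_x1, m_x2) is called iff its count reaches
    ``min_informative`` and the minority fraction stays within
    ``max_minority_fraction``; exact ties and insufficient support give
    Undetermined.  Disposition: haplotype != mutant-linked -> Normal;
    mutant-linked in a male -> Affected, in a female -> Carrier.
    """
    total = counts.m_x1 + counts.m_x2
    if counts.m_x1 == counts.m_x2:
        hap, reason = None, ("tie" if total else "no_data")
    else:
        winner = SUPPORT_X1 if counts.m_x1 > counts.m_x2 else SUPPORT_X2
        w, minority = max(counts.m_x1, counts.m_x2), min(counts.m_x1, counts.m_x2)
        if w < params.min_informative:
            hap, reason = None, "insufficient_support"
        elif minority / total > params.max_minority_fraction:
            hap, reason = None, "contradictory_support"
        else:
            hap, reason = winner, None

    if hap is None:
        disposition = DISP_UNDETERMINED
    elif hap != mutant_linked:
        disposition = DISP_NORMAL
    elif sex == "M":
        disposition = DISP_AFFECTED
    elif sex == "F":
        disposition = DISP_CARRIER
    else:
        # mutant-linked haplotype but sex unresolved: Affected vs Carrier
        # cannot be distinguished
        disposition, reason = DISP_UNDETERMINED, "sex_unknown"
    return EmbryoCall(
        embryo="",
        sex=sex,
        haplotype=hap,
        disposition=disposition,
        counts=counts,
        undetermined_reason=reason,
    )


def _runs(per_site: list[tuple[int, str]]) -> list[tuple[str, list[int]]]:
    """Collapse a support vector to (label, positions) runs over X1/X2 sites."""
    runs: list[tuple[str, list[int]]] = []
    for pos, label in per_site:
        if label not in (SUPPORT_X1, SUPPORT_X2):
            continue
        if runs and runs[-1][0] == label:
            runs[-1][1].append(pos)
        else:
            runs.append((label, [pos]))
    return runs


def _smooth_runs(
    runs: list[tuple[str, list[int]]], min_segment: int
) -> list[tuple[str, list[int]]]:
    """Absorb isolated artifact runs into their surroundings.

    A run shorter than ``min_segment`` that sits between two runs of the
    same label is a WGA-artifact island, not a double crossover at marker
    scale; it is dropped and its neighbours merged.  Shortest islands are
    absorbed first, so a single stray marker can never fragment the long
    runs that flank a genuine crossover.
    """
    runs = [(label, list(positions)) for label, positions in runs]
    while True:
        candidates = [
            i
            for i in range(1, len(runs) - 1)
            if len(runs[i][1]) < min_segment and runs[i - 1][0] == runs[i + 1][0]
        ]
        if not candidates:
            return runs
        i = min(candidates, key=lambda j: len(runs[j][1]))
        merged = (runs[i - 1][0], runs[i - 1][1] + runs[i + 1][1])
        runs[i - 1 : i + 2] = [merged]


def _smoothed_runs(
    per_site: list[tuple[int, str]], params: CallParams
) -> list[tuple[str, list[int]]]:
    return _smooth_runs(_runs(per_site), params.recomb_min_segment)


def detect_recombination(
    per_site: list[tuple[int, str]], params: CallParams = CallParams()
) -> list[tuple[int, int]]:
    """Locate haplotype-switch breakpoints in an embryo's support vector.

    Ambiguous/no-call sites are skipped and isolated sub-threshold artifact
    runs are absorbed (see :func:`_smooth_runs`); a breakpoint is then
    reported between adjacent runs only when both flanking runs span at
    least ``recomb_min_segment`` concordant markers, which suppresses
    isolated WGA-artifact flips.  Each breakpoint is the open interval
    (last bp of the left run, first bp of the right run).
    """
    runs = _smoothed_runs(per_site, params)
    breakpoints = []
    for left, right in zip(runs, runs[1:]):
        if len(left[1]) >= params.recomb_min_segment and len(right[1]) >= params.recomb_min_segment:
            breakpoints.append((left[1][-1], right[1][0]))
    return breakpoints


def mutation_segment_unsafe(
    per_site: list[tuple[int, str]],
    breakpoints: list[tuple[int, int]],
    mutation_pos: int,
    params: CallParams = CallParams(),
) -> bool:
    """True when recombination leaves the mutation poorly covered.

    After a detected crossover, only the markers on the mutation's side of
    the breakpoint speak for the haplotype actually present at the mutation.
    If the mutation falls inside a breakpoint interval, or its flanking
    run of concordant markers is shorter than ``recomb_min_segment``, the
    linkage call at the mutation is not trustworthy.
    """
    if not breakpoints:
        return False
    for lo, hi in breakpoints:
        if lo < mutation_pos < hi:
            return True
    # length of the run of concordant markers containing/nearest the mutation
    runs = _smoothed_runs(per_site, params)
    best_len = None
    for label, positions in runs:
        if positions[0] <= mutation_pos <= positions[-1]:
            best_len = len(positions)
            break
    if best_len is None:
        # mutation outside all runs: use the nearest run
        dist = [
            min(abs(positions[0] - mutation_pos), abs(positions[-1] - mutation_pos))
            for _, positions in runs
        ]
        best_len = len(runs[dist.index(min(dist))][1])
    return best_len < params.recomb_min_segment


def interpret_direct_test(mutation_genotype: str, sry_present: bool) -> EmbryoCall:
    """Interpret the direct (nested-PCR / Sanger) mutation + SRY assay.

    ``mutation_genotype`` is one of ``"ref"``, ``"alt"``, ``"het"``,
    ``"failed"``.  SRY+ with an apparently heterozygous mutation call is
    contradictory (a male has one X) and raises
    :class:`DirectTestInconsistencyError` rather than being silently
    resolved.
    """
    if mutation_genotype not in ("ref", "alt", "het", "failed"):
        raise ConfigError(f"mutation_genotype invalid: {mutation_genotype!r}")
    counts = SupportCounts()
    if mutation_genotype == "failed":
        return EmbryoCall(
            embryo="",
            sex="unknown",
            haplotype=None,
            disposition=DISP_UNDETERMINED,
            counts=counts,
            undetermined_reason="failed_amplification",
        )
    sex = "M" if sry_present else "F"
    if sry_present:
        if mutation_genotype == "het":
            raise DirectTestInconsistencyError(
                "SRY-positive embryo with heterozygous mutation call: "
                "possible contamination or allele drop-in"
            )
        disposition = DISP_AFFECTED if mutation_genotype == "alt" else DISP_NORMAL
    else:
        if mutation_genotype == "het":
            disposition = DISP_CARRIER
        elif mutation_genotype == "alt":
            # homozygous mutant female: possible but extraordinary; report as
            # affected-equivalent
            disposition = DISP_AFFECTED
        else:
            disposition = DISP_NORMAL
    return EmbryoCall(
        embryo="", sex=sex, haplotype=None, disposition=disposition, counts=counts
    )
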