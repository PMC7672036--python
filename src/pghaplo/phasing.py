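"""Informative-marker classification and maternal haplotype phasing.

Phasing is trio-based: at every site where the mother is heterozygous and
the hemizygous phase-reference sample (affected proband, or villus/child of
known status) has a usable call, the reference's allele pins down one
maternal haplotype.  By convention X1 is the haplotype carried by the
reference, so an affected reference makes X1 mutant-linked and an
unaffected reference makes X2 mutant-linked.

Site classes
------------
``x1_detecting``
    father's allele != X1 allele: seeing the X1 allele alongside the paternal
    allele in a female embryo is unambiguous evidence for X1.
``x2_detecting``
    father's allele != X2 allele (for biallelic markers every site with a
    paternal call is exactly one of the two classes).
``male_only``
    mother heterozygous but no usable paternal call; usable for hemizygous
    (male) embryos only.

Paternal-informative markers are the separate, rarer configuration where the
mother is homozygous and the father's allele differs from hers: observing
the paternal allele there directly demonstrates a paternal X (a female
embryo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SnpTable, TargetLocus

log = logging.getLogger(__name__)

CLASS_X1 = "x1_detecting"
CLASS_X2 = "x2_detecting"
CLASS_MALE_ONLY = "male_only"


@dataclass
class PhasedMaternalHaplotypes:
    """The two phased maternal X haplotypes at informative sites.

    Arrays are parallel and ordered by position; ``indices`` point back into
    the (filtered) :class:`~pghaplo.model.SnpTable` rows.  ``father`` is the
    paternal allele index or -1 where the father has no usable call.
    """

    positions: np.ndarray
    indices: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    father: np.ndarray
    site_class: list[str]
    mutant_linked: str  # "X1" | "X2"
    # paternal-informative markers (mother homozygous, father discordant)
    paternal_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    paternal_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    paternal_allele: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    maternal_allele: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_informative(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        """Per-site classification table (exported as marker TSV)."""
        return pd.DataFrame(
            {
                "pos": self.positions,
                "x1_allele": self.x1,
                "x2_allele": self.x2,
                "father_allele": self.father,
                "class": self.site_class,
            }
        )


@dataclass(frozen=True)
class MarkerSummary:
    """Counts of usable markers by what they can detect."""

    n_paternal_informative: int
    n_x1_informative: int
    n_x2_informative: int


def classify_sites(
    table: SnpTable, locus: TargetLocus
) -> tuple[PhasedMaternalHaplotypes, MarkerSummary]:
    """Phase the maternal haplotypes and classify marker informativeness.

    Expects a filtered table (window + parental depth already applied).
    Returns the phase and a :class:`MarkerSummary`; with zero informative
    sites an empty phase is returned with a warning.
    """
    mother = table.calls[table.mother]
    father = table.calls[table.father]
    reference = table.calls[table.reference]

    pos = table.sites["pos"].to_numpy()
    idx_l, x1_l, x2_l, f_l, cls_l = [], [], [], [], []
    pidx_l, pf_l, pm_l = [], [], []
    for i in range(table.n_sites):
        m, f, r = mother[i], father[i], reference[i]
        f_allele = f[0] if f is not None and len(set(f)) == 1 else None
        if m is None:
            continue
        if len(set(m)) == 2:
            if r is None or len(r) != 1:
                continue
            x1 = r[0]
            x2 = ({0, 1} - {x1}).pop()
            if f_allele is None:
                cls = CLASS_MALE_ONLY
            elif f_allele != x1:
                cls = CLASS_X1
            else:
                cls = CLASS_X2
            idx_l.append(i)
            x1_l.append(x1)
            x2_l.append(x2)
            f_l.append(-1 if f_allele is None else f_allele)
            cls_l.append(cls)
        else:
            # mother homozygous: paternal-informative iff father discordant
            if f_allele is not None and f_allele != m[0]:
                pidx_l.append(i)
                pf_l.append(f_allele)
                pm_l.append(m[0])

    mutant_linked = "X1" if locus.reference_status == "affected" else "X2"
    if not idx_l:
        log.warning("zero maternally informative sites; phase is empty")
    phase = PhasedMaternalHaplotypes(
        positions=pos[idx_l].astype(np.int64),
        indices=np.asarray(idx_l, dtype=np.int64),
        x1=np.asarray(x1_l, dtype=np.int64),
        x2=np.asarray(x2_l, dtype=np.int64),
        father=np.asarray(f_l, dtype=np.int64),
        site_class=cls_l,
        mutant_linked=mutant_linked,
        paternal_positions=pos[pidx_l].astype(np.int64),
        paternal_indices=np.asarray(pidx_l, dtype=np.int64),
        paternal_allele=np.asarray(pf_l, dtype=np.int64),
        maternal_allele=np.asarray(pm_l, dtype=np.int64),
    )
    return phase, summarize_markers(phase)


def summarize_markers(phase: PhasedMaternalHaplotypes) -> MarkerSummary:
    """Recount marker classes from a phase object."""
    return MarkerSummary(
        n_paternal_informative=len(phase.paternal_positions),
        n_x1_informative=phase.site_class.count(CLASS_X1),
        n_x2_informative=phase.site_class.count(CLASS_X2),
    )
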