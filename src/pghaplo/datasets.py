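"""Small worked-example datasets from a clinical XLP (SH2D1A) PGT-M cycle.

These are the published-style summary inputs of a real X-linked
lymphoproliferative disease case: per-embryo informative-marker support
counts from the haplotyping cycle, the direct nested-PCR outcomes of the
first cycle, and the 100-lymphocyte single-cell validation counts.  They
drive the package's worked examples and regression tests.
"""

from __future__ import annotations

import pandas as pd

from .qc import QcCounts

#: Haplotyping-cycle support counts: ten embryo biopsies around *SH2D1A*.
#: The phase reference was chorionic villus from a known-unaffected
#: conceptus, so X1 is the normal maternal haplotype and X2 mutant-linked.
_SUPPORT_ROWS = [
    ("Embryo1", "F", 0, 0, 0),
    ("Embryo2", "M", 0, 137, 1),
    ("Embryo3", "F", 0, 0, 0),
    ("Embryo4", "F", 0, 63, 0),
    ("Embryo5", "F", 1, 95, 0),
    ("Embryo6", "F", 0, 0, 0),
    ("Embryo7", "F", 2, 96, 1),
    ("Embryo8", "F", 1, 69, 1),
    ("Embryo9", "F", 0, 0, 0),
    ("Embryo10", "F", 2, 26, 0),
]

#: mutant-linked haplotype in the clinical cycle (unaffected villus reference)
CLINICAL_MUTANT_LINKED = "X2"


def clinical_support_counts() -> pd.DataFrame:
    """Per-embryo support counts of the clinical haplotyping cycle.

    Columns: embryo, sex, f_x, m_x1, m_x2.
    """
    return pd.DataFrame(
        _SUPPORT_ROWS, columns=["embryo", "sex", "f_x", "m_x1", "m_x2"]
    )


def first_cycle_direct_results() -> pd.DataFrame:
    """Direct nested-PCR outcomes of the six first-cycle embryo biopsies.

    One reaction failed outright; three embryos showed only the reference
    base at the mutation site; two SRY-positive embryos were hemizygous for
    the mutant base.  Columns: embryo, mutation_genotype, sry_present.
    """
    rows = [
        ("Embryo1", "failed", False),
        ("Embryo2", "ref", False),
        ("Embryo3", "ref", True),
        ("Embryo4", "alt", True),
        ("Embryo5", "ref", False),
        ("Embryo6", "alt", True),
    ]
    return pd.DataFrame(rows, columns=["embryo", "mutation_genotype", "sry_present"])


def lymphocyte_panel_counts() -> QcCounts:
    """Single-cell validation panel: 100 lymphocytes, 2 without signal,
    8 amplifications affected by allele drop-out; all blanks negative."""
    return QcCounts(
        n_cells=100, n_no_signal=2, n_ado=8, n_blank_controls=100, n_blank_positive=0
    )
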