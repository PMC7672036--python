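"""Worked example: calling embryos from published-style clinical inputs.

Feeds the per-embryo informative-marker support counts of an XLP (SH2D1A)
haplotyping cycle through the calling rule, computes the single-cell PCR
validation statistics, and interprets the direct nested-PCR cycle.
"""

import pghaplo as pg
from pghaplo.datasets import (
    CLINICAL_MUTANT_LINKED,
    clinical_support_counts,
    first_cycle_direct_results,
    lymphocyte_panel_counts,
)

params = pg.CallParams()

print("=== Haplotyping cycle: linkage calls from support counts ===")
print(f"(phase reference: unaffected villus, so mutant-linked = {CLINICAL_MUTANT_LINKED})")
df = clinical_support_counts()
for _, row in df.iterrows():
    call = pg.call_embryo(
        pg.SupportCounts(f_x=row.f_x, m_x1=row.m_x1, m_x2=row.m_x2),
        row.sex, CLINICAL_MUTANT_LINKED, params,
    )
    hap = f"M({call.haplotype})" if call.haplotype else "-"
    print(f"{row.embryo:>9}  {row.sex}  F(X)={row.f_x:>2} M(X1)={row.m_x1:>3} "
          f"M(X2)={row.m_x2:>2}  ->  {hap:>6}  {call.disposition}")
# Six embryos inherited the normal maternal haplotype (N); four biopsies
# yielded no usable markers and stay Undetermined (-).

print()
print("=== Single-cell PCR validation (100-lymphocyte panel) ===")
rates = pg.qc_rates(lymphocyte_panel_counts())
print(f"cell amplification rate: {rates.cell_amplification_rate.pct}%")
print(f"ADO rate:                {rates.ado_rate.pct}%  (below the 10% safety bound)")
print(f"successful amplification: {rates.success_rate.pct}%")
ok, msg = pg.validate_blanks(lymphocyte_panel_counts())
print(f"blank controls: {msg}")

print()
print("=== First cycle: direct mutation + SRY interpretation ===")
for r in first_cycle_direct_results().itertuples():
    call = pg.interpret_direct_test(r.mutation_genotype, bool(r.sry_present))
    print(f"{r.embryo:>8}  mutation={r.mutation_genotype:>6}  "
          f"SRY={'+' if r.sry_present else '-'}  ->  sex {call.sex}, {call.disposition}")
# One failed reaction is Undetermined; three unaffected; two hemizygous
# affected males.
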