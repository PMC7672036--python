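# Methods

## The problem

In a family segregating an X-linked recessive disease, a carrier mother has
two X haplotypes: one physically linked to the pathogenic variant
("mutant-linked") and one normal. PGT-M by direct mutation assay on a
single biopsied blastomere is vulnerable to allele drop-out (ADO): after
whole-genome amplification (WGA) of one cell, one allele of a heterozygous
locus frequently fails to amplify, and a carrier or affected embryo can
genotype as normal. Preimplantation genetic haplotyping (PGH) instead asks
which *haplotype* the embryo inherited, aggregating dozens to hundreds of
flanking SNP markers so that no single locus — and no single drop-out — can
decide the outcome.

## Model and procedure

### Phasing by a hemizygous reference

Maternal phase cannot be read from the mother's genotypes alone. A
hemizygous relative of known disease status — the affected proband, or
chorionic villus from a conceptus known to be unaffected — carries exactly
one maternal haplotype and serves as the phase anchor. We define **X1** as
the haplotype carried by the reference; the polarity rule is then purely
mechanical:

* reference affected ⟹ X1 is mutant-linked;
* reference unaffected ⟹ X2 is mutant-linked.

A site is *maternally informative* iff the mother is heterozygous and the
reference has a usable single-allele call there. With biallelic markers and
a usable paternal call, each informative site is exactly one of:

* **X1-detecting** (father ≠ X1): in a female embryo, after subtracting the
  paternal allele the residual maternal allele distinguishes X1;
* **X2-detecting** (father ≠ X2, i.e. father = X1): symmetric;
* **male-only** when the father has no usable call — male embryos have no
  paternal X, so any maternal-het site types them.

*Paternal-informative* markers are the separate configuration mother
homozygous + father discordant: observing the father's allele there is
unambiguous evidence of a paternal X (i.e. a female embryo). These are rare
in real data because spouses share population haplotypes; the simulator
reproduces their scarcity (see below). In the clinical X-linked decision
rule F(X) is reported as tracking evidence and used for sex corroboration,
but does not enter the maternal-haplotype call.

### Counting and calling

For embryo *e* at each informative site with a usable call (depth > 10 in
that embryo):

* **male logic** — the hemizygous allele (observed as a homozygous
  diploid-style call) increments M(X1) or M(X2); an apparently heterozygous
  call is a drop-in artifact and is ambiguous;
* **female logic** — only detecting sites are used; a heterozygous call has
  the paternal allele subtracted and the residual attributed; a homozygous
  call for the allele shared by father and one maternal haplotype cannot be
  attributed (the paternal copy may have dropped out) and is ambiguous; a
  homozygous call differing from the father attributes directly.

The winner w = argmax(M(X1), M(X2)) is called iff

* max(M(X1), M(X2)) ≥ `min_informative` = **10**, and
* minority fraction min/(M(X1)+M(X2)) ≤ `max_minority_fraction` = **0.05**.

Exact ties are never broken stochastically. The thresholds are this
package's own: published clinical tables print calls but no rule. They are
set so that a winner as small as 26 with zero contradiction calls cleanly,
while ~5% contradicting markers — far beyond what independent per-site
artifacts produce on a clean sample — voids the call. Disposition then
follows X-linked recessive convention: non-mutant haplotype → Normal;
mutant-linked in a male → Affected; in a female → Carrier; mutant-linked
with unresolved sex → Undetermined (Affected vs Carrier cannot be
distinguished), with the haplotype still reported.

### Sex inference

An SRY assay result, when supplied, is authoritative. From markers alone:
a female is heterozygous at the detecting sites where the paternal allele
differs from her transmitted maternal allele (≈ half of them), a male only
at drop-in artifacts. We therefore call female when the het fraction over
usable informative sites reaches `sex_het_fraction` = **0.2** (with at
least `sex_min_het` = 3 usable sites), or when the paternal allele is seen
at ≥ `sex_min_fx` = **2** paternal-informative markers; male otherwise;
unknown below 3 usable sites. Fractional rather than absolute het
thresholds matter: at drop-in rate 0.01 over ~150 markers a male shows ~1.5
spurious het calls, so any small absolute cutoff misclassifies a
non-negligible share of males, and a single spurious paternal-marker hit
must likewise not suffice.

### Recombination

The ordered support vector is collapsed to X1/X2 runs (ambiguous and
no-call sites skipped). Isolated runs shorter than `recomb_min_segment`
sandwiched between two runs of the same label are artifact islands — a
genuine double crossover within a few markers' span is vastly less likely
than one WGA artifact — and are absorbed before breakpoints are read off.
A breakpoint is reported between adjacent runs when both span ≥
`recomb_min_segment` = **5** concordant markers; its interval is (last bp
of left run, first bp of right run), the native resolution of the marker
map. If the mutation falls inside a breakpoint interval, or its flanking
concordant run is shorter than `recomb_min_segment`, the linkage call at
the mutation is not trustworthy and the embryo is reported
Undetermined-recombinant.

### Single-cell QC

For a validation panel of n cells with n₀ giving no signal and k of the
amplified showing ADO: cell amplification rate = (n−n₀)/n, ADO rate =
k/(n−n₀), successful amplification rate = (n−n₀−k)/(n−n₀). The ADO
denominator is amplified cells — a cell that never amplified cannot exhibit
drop-out, and only this denominator makes the canonical 100/2/8 panel's
91.8% success figure arithmetically exact (90/98). Success and ADO rates
are exact complements. Intervals are Wilson 95% (statsmodels), chosen over
Wald for small counts. A separately quoted per-locus amplification rate can
be passed through if locus-level counts are supplied, but is not derivable
from cell-level counts. Blank (wash-drop) controls must all be negative.

## The simulator

`simulate_family` emulates the study conditions of a clinical X-linked PGH
workup. Defaults (chosen once, as the package's study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| `n_snps` | 300 | with het fraction 0.5 → ~150 maternal informative markers in the 2 Mb window, the scale clinical cycles report (tens to ~150) |
| `window_span` | 2 Mb | ±1 Mb around the gene |
| `maternal_het_fraction` | 0.5 | markers are ascertained for informativeness |
| `paternal_discord_rate` | 0.02 | father usually shares the population allele at maternal-homozygous sites; yields the observed handful (~3) of paternal-informative markers |
| `ado_rate` | 0.05 | per allele, per site; the regime a validated assay maintains (below 10%) |
| `adi_rate` | 0.005 | rare drop-in/contamination |
| `sample_fail_rate` | 0.2 | whole-biopsy WGA failure, a realistic clinical fraction |
| `recomb_rate_per_mb` | 0.013 | human sex-averaged ≈ 1.3 cM/Mb |
| `depth_mean` | 30 | capture sequencing; Poisson per site |
| `depth_min_usable` | 10 | usability threshold, strict `>` |

Mechanics: maternal haplotypes are assigned per site (the mutant-bearing
one fixed by construction); the reference carries the haplotype its disease
status implies; each embryo's maternal gamete follows a Haldane process
(crossover count Poisson(rate × window), uniform positions, no
interference); female embryos add the paternal X. Observation then corrupts
truth: each allele drops independently with `ado_rate` (both dropped → 
no-call), a spurious allele appears with `adi_rate` per site, and a whole
sample fails with `sample_fail_rate`. Embryos are emitted as diploid-style
calls (a variant caller does not know the sex); father and reference can be
written in either hemizygous VCF dialect (`0` or `0/0`). Every corruption
is recorded in the ground-truth sidecar, enabling site-level audits.

What the simulator does **not** model: read-level errors, capture/GC bias,
linkage disequilibrium between markers, population allele frequencies,
aneuploidy/CNV, mosaicism in the biopsy, or depth-correlated ADO.
Recovery results on simulations therefore demonstrate the logic's
correctness under independent per-site artifacts, not clinical performance
on real WGA libraries.

## Numerical and design choices

* Coordinates 1-based inclusive; the analysis window is a closed interval;
  the depth gate is strictly `> min_depth`.
* Parental/reference depth gates a site globally; embryo depth gates only
  that embryo's call there (one embryo's dropout must not discard a marker
  for its siblings).
* Multiallelic and non-SNP records are dropped, not decomposed: support
  counting assumes biallelic markers.
* A heterozygous call in a hemizygous sample (father/reference) is
  contradictory and becomes a no-call, counted and logged.
* Determinism everywhere: one seeded `numpy` Generator drives a simulation;
  ties yield Undetermined rather than a coin flip; reports are
  byte-reproducible under a fixed seed and config.
* Undetermined-by-recombination is reported distinctly (reason field) from
  Undetermined-no-data, though the summary table prints both as `-`.

## Verification scales

The test suite and `scripts/acceptance.py` run everything at desk scale:
brute-force oracle agreement on 100 random 200-site tables; disposition
recovery on 1,000 simulated embryos at ADO 0.10 / drop-in 0.01 (≥ 99%
observed); breakpoint localisation on ~100 qualifying single-crossover
embryos (≥ 95% observed; a crossover qualifies when ≥ 5 markers speak for
each flanking segment — for a female only the sites detecting her
transmitted haplotype can); ADO estimator bias over 10,000 panels
(consistent with zero at Monte-Carlo precision). Residual localisation
misses come from an artifact adjacent to the true breakpoint that mimics
the incoming haplotype — irreducible at marker resolution.

## Known limitations

* X-linked recessive, single-gene analysis only; autosomal and
  compound-heterozygous modes are out of scope (types permit extension).
* No population-LD phasing or imputation: a usable hemizygous reference is
  required, and missing parental genotypes shrink the usable marker set.
* The marker summary counts (paternal / X1- / X2-detecting) depend on this
  package's informativeness definitions; published counts from other
  pipelines are comparable in magnitude, not reproducible exactly.
* The calling thresholds are calibrated for ~50–150 usable markers; panels
  with only a handful of informative SNPs should rely on the direct assay.
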