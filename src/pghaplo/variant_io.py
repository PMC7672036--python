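"""Read the multi-sample VCF and apply the window/depth usability filter."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    ConfigError,
    Genotype,
    ROLE_EMBRYO,
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_REFERENCE,
    SnpTable,
    TargetLocus,
)

log = logging.getLogger(__name__)

_KNOWN_ROLES = {ROLE_FATHER, ROLE_MOTHER, ROLE_REFERENCE, ROLE_EMBRYO}


def load_vcf(path, roles: dict[str, str]) -> SnpTable:
    """Load biallelic SNPs from a VCF 4.2 file into a :class:`SnpTable`.

    ``roles`` maps sample name to role; samples present in the VCF but not in
    ``roles`` are treated as embryos.  Multiallelic and non-SNP records are
    excluded (count logged).  Hemizygous calls on the father and reference are
    normalised to a single allele whether encoded haploid (``0``) or
    homozygous-diploid (``0/0``); a heterozygous call in a hemizygous sample
    is contradictory and becomes a no-call (count logged).
    """
    for sample, role in roles.items():
        if role not in _KNOWN_ROLES:
            raise ConfigError(f"unknown role {role!r} for sample {sample!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    full_roles = {s: roles.get(s, ROLE_EMBRYO) for s in samples}
    for required in (ROLE_FATHER, ROLE_MOTHER, ROLE_REFERENCE):
        if sum(1 for r in full_roles.values() if r == required) != 1:
            raise ConfigError(f"role map must assign exactly one {required}")
    hemi = {s for s, r in full_roles.items() if r in (ROLE_FATHER, ROLE_REFERENCE)}

    rows = []
    calls: dict[str, list[Genotype]] = {s: [] for s in samples}
    depths: dict[str, list[int]] = {s: [] for s in samples}
    n_excluded = 0
    n_hemi_het = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_excluded += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dp_arr = var.format("DP")
        for j, s in enumerate(samples):
            alleles = [a for a in var.genotypes[j][:-1] if a >= 0]
            g: Genotype
            if not alleles:
                g = None
            elif s in hemi:
                uniq = set(alleles)
                if len(uniq) == 1:
                    g = (alleles[0],)
                else:
                    n_hemi_het += 1
                    g = None
            else:
                g = (alleles[0], alleles[0]) if len(alleles) == 1 else (alleles[0], alleles[1])
            calls[s].append(g)
            d = int(dp_arr[j][0]) if dp_arr is not None else 0
            depths[s].append(max(d, 0))
    vcf.close()
    if n_excluded:
        log.info("excluded %d multiallelic/non-SNP records", n_excluded)
    if n_hemi_het:
        log.warning("nulled %d heterozygous calls in hemizygous samples", n_hemi_het)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return SnpTable(
        sites=sites,
        calls=calls,
        depths={s: np.asarray(d, dtype=np.int64) for s, d in depths.items()},
        roles=full_roles,
    )


def apply_region_depth_filter(
    table: SnpTable, locus: TargetLocus, min_depth: int = 10
) -> SnpTable:
    """Restrict to the analysis window and depth-usable sites.

    A site is kept iff its position lies in the closed window
    [gene_start - flank, gene_end + flank] and the father, mother and
    reference each have depth strictly greater than ``min_depth`` there.
    Embryo depth is deliberately not gated here: a drop-out in one embryo
    must not discard the marker for the others; embryo usability is applied
    per call downstream.
    """
    if min_depth < 0:
        raise ConfigError(f"min_depth must be >= 0, got {min_depth}")
    lo, hi = locus.window
    pos = table.sites["pos"].to_numpy()
    in_window = (pos >= lo) & (pos <= hi) & (table.sites["chrom"] == locus.chrom).to_numpy()
    deep = (
        (table.depths[table.father] > min_depth)
        & (table.depths[table.mother] > min_depth)
        & (table.depths[table.reference] > min_depth)
    )
    mask = in_window & deep
    log.info(
        "region/depth filter: %d sites in, %d outside window, %d shallow, %d kept",
        table.n_sites,
        int((~in_window).sum()),
        int((in_window & ~deep).sum()),
        int(mask.sum()),
    )
    if not mask.any():
        log.warning("no usable sites after filtering; downstream calls will be Undetermined")
    return table.subset(mask)
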