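"""Core data containers shared across the pipeline.

Genotypes are stored as tuples of allele indices into (ref, alt):
``(0,)`` is a hemizygous reference call, ``(0, 1)`` a heterozygote,
``None`` a no-call.  Allele order within a tuple is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Genotype = tuple[int, ...] | None

ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_REFERENCE = "reference"
ROLE_EMBRYO = "embryo"

_REQUIRED_ROLES = (ROLE_FATHER, ROLE_MOTHER, ROLE_REFERENCE)


class ConfigError(ValueError):
    """A configuration (roles, parameters) is invalid."""


@dataclass(frozen=True)
class TargetLocus:
    """The disease locus and the marker window flanking it on chrX.

    Coordinates are 1-based inclusive (VCF convention).  ``reference_status``
    is the disease status of the phase-reference sample: an affected proband
    anchors the mutant-linked haplotype directly, an unaffected reference
    (e.g. chorionic villus from a normal conceptus) anchors the normal one.
    """

    chrom: str
    gene_start: int
    gene_end: int
    mutation_pos: int
    mutation_ref: str
    mutation_alt: str
    window_flank: int = 1_000_000
    reference_status: str = "affected"

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ConfigError("gene_start must be <= gene_end")
        lo, hi = self.window
        if not (lo <= self.mutation_pos <= hi):
            raise ConfigError("mutation_pos must lie inside the analysis window")
        if self.reference_status not in ("affected", "unaffected"):
            raise ConfigError(
                "reference_status must be 'affected' or 'unaffected', got "
                f"{self.reference_status!r}"
            )

    @property
    def window(self) -> tuple[int, int]:
        """Closed analysis interval [gene_start - flank, gene_end + flank]."""
        return self.gene_start - self.window_flank, self.gene_end + self.window_flank


@dataclass
class SnpTable:
    """Biallelic SNP calls and depths for one family on chrX.

    ``sites`` has columns chrom/pos/ref/alt with strictly increasing pos.
    ``calls[sample][i]`` and ``depths[sample][i]`` refer to ``sites`` row i.
    """

    sites: pd.DataFrame
    calls: dict[str, list[Genotype]]
    depths: dict[str, np.ndarray]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        pos = self.sites["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("site positions must be strictly increasing")
        for sample in self.calls:
            if len(self.calls[sample]) != self.n_sites:
                raise ValueError(f"call vector length mismatch for {sample!r}")
        for role in _REQUIRED_ROLES:
            n = sum(1 for r in self.roles.values() if r == role)
            if n != 1:
                raise ConfigError(f"exactly one {role} required, found {n}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def samples(self) -> list[str]:
        return list(self.calls)

    def _by_role(self, role: str) -> str:
        return next(s for s, r in self.roles.items() if r == role)

    @property
    def father(self) -> str:
        return self._by_role(ROLE_FATHER)

    @property
    def mother(self) -> str:
        return self._by_role(ROLE_MOTHER)

    @property
    def reference(self) -> str:
        return self._by_role(ROLE_REFERENCE)

    @property
    def embryos(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == ROLE_EMBRYO]

    def subset(self, mask: np.ndarray) -> "SnpTable":
        """New table restricted to sites where ``mask`` is True."""
        idx = np.flatnonzero(mask)
        return SnpTable(
            sites=self.sites.iloc[idx],
            calls={s: [g[i] for i in idx] for s, g in self.calls.items()},
            depths={s: d[idx].copy() for s, d in self.depths.items()},
            roles=dict(self.roles),
        )

    def equals(self, other: "SnpTable") -> bool:
        """Value equality (used by round-trip tests)."""
        if not self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True)):
            return False
        if self.roles != other.roles or set(self.calls) != set(other.calls):
            return False
        for s in self.calls:
            a = [None if g is None else tuple(sorted(g)) for g in self.calls[s]]
            b = [None if g is None else tuple(sorted(g)) for g in other.calls[s]]
            if a != b or not np.array_equal(self.depths[s], other.depths[s]):
                return False
        return True
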