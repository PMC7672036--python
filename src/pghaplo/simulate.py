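"""Synthetic X-linked families with known ground truth.

Generates the inputs the haplotyping pipeline consumes: biallelic SNPs in a
window around the disease gene, a heterozygous mother, hemizygous father and
phase-reference sample, and embryo biopsies whose maternal X is a recombinant
mosaic of the two maternal haplotypes.  Embryo genotypes are corrupted by the
artifacts of single-cell whole-genome amplification: per-allele drop-out
(ADO), per-site allele drop-in (ADI), and whole-sample amplification failure.

Ground truth (transmitted haplotype per site, crossover positions, corrupted
sites, true dispositions) is recorded so that recovery can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

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

_BASES = np.array(list("ACGT"))

# hg19-like coordinates for SH2D1A on Xq25; only relative geometry matters.
_GENE_START = 123_480_000
_GENE_END = 123_507_000
_MUTATION_OFFSET = 8_000  # mutation position inside the gene


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic family.

    Defaults emulate a clinical PGH workup: ~150 maternal heterozygous
    markers within +-1 Mb of the gene, capture sequencing at ~30x with a
    >10x usability threshold, single-digit-percent ADO, rare drop-in, and
    a realistic fraction of embryo WGA samples yielding nothing.
    """

    n_snps: int = 300
    window_span: int = 2_000_000
    maternal_het_fraction: float = 0.5
    paternal_discord_rate: float = 0.02
    ado_rate: float = 0.05
    adi_rate: float = 0.005
    sample_fail_rate: float = 0.2
    recomb_rate_per_mb: float = 0.013
    depth_mean: float = 30.0
    depth_min_usable: int = 10
    n_embryos: int = 10
    embryo_sex_prob_female: float = 0.5
    reference_status: str = "affected"
    hemizygous_dialect: str = "haploid"  # "haploid" -> GT "0"; "diploid" -> "0/0"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "maternal_het_fraction",
            "paternal_discord_rate",
            "ado_rate",
            "adi_rate",
            "sample_fail_rate",
            "embryo_sex_prob_female",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 1:
            raise ConfigError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.window_span <= 0:
            raise ConfigError(f"window_span must be > 0, got {self.window_span}")
        if self.n_embryos < 0:
            raise ConfigError(f"n_embryos must be >= 0, got {self.n_embryos}")
        if self.recomb_rate_per_mb < 0:
            raise ConfigError(f"recomb_rate_per_mb must be >= 0, got {self.recomb_rate_per_mb}")
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean must be > 0, got {self.depth_mean}")
        if self.reference_status not in ("affected", "unaffected"):
            raise ConfigError(f"reference_status invalid: {self.reference_status!r}")
        if self.hemizygous_dialect not in ("haploid", "diploid"):
            raise ConfigError(f"hemizygous_dialect invalid: {self.hemizygous_dialect!r}")


@dataclass
class EmbryoTruth:
    """Per-embryo ground truth."""

    sex: str  # "F" | "M"
    crossovers: list[int]  # bp positions, strictly inside the window
    transmitted: list[str]  # per site: "X1" | "X2" (X1 := reference's haplotype)
    transmitted_at_mutation: str  # "X1" | "X2"
    disposition: str  # "N" | "A" | "C"
    failed: bool = False
    ado_sites: list[list[int]] = field(default_factory=list)  # [site_idx, hap_slot]
    adi_sites: list[int] = field(default_factory=list)  # site indices


@dataclass
class GroundTruth:
    """Full simulation truth, serialisable to a JSON sidecar."""

    mutant_linked: str  # "X1" | "X2"
    hap_x1: list[int]  # maternal allele (0/1) per site on the reference-carried hap
    hap_x2: list[int]
    father_alleles: list[int]
    embryos: dict[str, EmbryoTruth]

    def to_json(self, path) -> None:
        obj = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        obj["embryos"] = {k: EmbryoTruth(**v) for k, v in obj["embryos"].items()}
        return cls(**obj)


def _draw_sites(rng: np.random.Generator, cfg: SimulationConfig, lo: int, hi: int) -> pd.DataFrame:
    pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=cfg.n_snps, replace=False))
    ref_idx = rng.integers(0, 4, size=cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_snps)) % 4
    return pd.DataFrame(
        {
            "chrom": "chrX",
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def _gamete(
    rng: np.random.Generator, cfg: SimulationConfig, lo: int, hi: int, positions: np.ndarray
) -> tuple[np.ndarray, list[int], int]:
    """Which maternal chromatid (0 = mutant-bearing) each site is drawn from.

    Haldane model: crossover count ~ Poisson(rate x window length), positions
    uniform, no interference.  Returns (per-site chromatid, crossover bp,
    starting chromatid).
    """
    span_mb = (hi - lo) / 1e6
    n_xo = rng.poisson(cfg.recomb_rate_per_mb * span_mb)
    # strictly inside the window
    xo = np.sort(rng.integers(lo + 1, hi, size=n_xo))
    start = int(rng.integers(0, 2))
    n_switches = np.searchsorted(xo, positions, side="right")
    return (start + n_switches) % 2, [int(x) for x in xo], start


def simulate_family(config: SimulationConfig) -> tuple[SnpTable, TargetLocus, GroundTruth]:
    """Simulate one family: parents, phase reference, and embryo biopsies.

    Returns the observed genotype table (already corrupted by WGA artifacts
    for embryo samples), the target locus, and the generation ground truth.
    X1 denotes the maternal haplotype carried by the reference sample; with
    an affected reference X1 is mutant-linked, with an unaffected one X2 is.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    flank = max((cfg.window_span - (_GENE_END - _GENE_START)) // 2, 1)
    locus = TargetLocus(
        chrom="chrX",
        gene_start=_GENE_START,
        gene_end=_GENE_END,
        mutation_pos=_GENE_START + _MUTATION_OFFSET,
        mutation_ref="G",
        mutation_alt="A",
        window_flank=flank,
        reference_status=cfg.reference_status,
    )
    lo, hi = locus.window
    sites = _draw_sites(rng, cfg, lo, hi)
    n = cfg.n_snps
    positions = sites["pos"].to_numpy()

    # Maternal haplotypes: hap M carries the pathogenic variant, hap N does not.
    het = rng.random(n) < cfg.maternal_het_fraction
    hap_m = np.where(het, rng.integers(0, 2, size=n), rng.integers(0, 2, size=n))
    hap_n = np.where(het, 1 - hap_m, hap_m)

    # Father: uniform allele at maternal-het sites; at maternal-homozygous
    # sites he usually shares the population allele, rarely discordant --
    # discordant sites are the paternal-informative markers.
    father = np.where(
        het,
        rng.integers(0, 2, size=n),
        np.where(rng.random(n) < cfg.paternal_discord_rate, 1 - hap_m, hap_m),
    )

    # Reference sample is hemizygous for one maternal haplotype; X1 := that one.
    ref_hap = hap_m if cfg.reference_status == "affected" else hap_n
    other_hap = hap_n if cfg.reference_status == "affected" else hap_m
    mutant_linked = "X1" if cfg.reference_status == "affected" else "X2"
    # label helper: chromatid index c (0 = hap M) -> "X1"/"X2"
    if cfg.reference_status == "affected":
        chromatid_label = {0: "X1", 1: "X2"}
    else:
        chromatid_label = {0: "X2", 1: "X1"}

    calls: dict[str, list[Genotype]] = {}
    depths: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}

    def draw_depth() -> np.ndarray:
        return rng.poisson(cfg.depth_mean, size=n).astype(np.int64)

    calls["father"] = [(int(a),) for a in father]
    calls["mother"] = [(int(a), int(b)) for a, b in zip(hap_m, hap_n)]
    calls["reference"] = [(int(a),) for a in ref_hap]
    for s, role in (("father", ROLE_FATHER), ("mother", ROLE_MOTHER), ("reference", ROLE_REFERENCE)):
        depths[s] = draw_depth()
        roles[s] = role

    embryos: dict[str, EmbryoTruth] = {}
    for e in range(1, cfg.n_embryos + 1):
        name = f"Embryo{e}"
        sex = "F" if rng.random() < cfg.embryo_sex_prob_female else "M"
        chromatid, xo, start = _gamete(rng, cfg, lo, hi, positions)  # 0 = hap M
        maternal = np.where(chromatid == 0, hap_m, hap_n)
        n_sw = int(np.searchsorted(np.array(xo), locus.mutation_pos, side="right"))
        chromatid_at_mut = (start + n_sw) % 2
        transmitted = [chromatid_label[int(c)] for c in chromatid]
        at_mut = chromatid_label[int(chromatid_at_mut)]
        carries_mutation = chromatid_at_mut == 0
        if not carries_mutation:
            disposition = "N"
        else:
            disposition = "A" if sex == "M" else "C"

        truth = EmbryoTruth(
            sex=sex,
            crossovers=xo,
            transmitted=transmitted,
            transmitted_at_mutation=at_mut,
            disposition=disposition,
        )

        failed = rng.random() < cfg.sample_fail_rate
        truth.failed = bool(failed)
        obs: list[Genotype] = []
        if failed:
            obs = [None] * n
            depths[name] = np.zeros(n, dtype=np.int64)
        else:
            for i in range(n):
                alleles = [int(maternal[i])]
                if sex == "F":
                    alleles.append(int(father[i]))
                kept = []
                for slot, a in enumerate(alleles):
                    if rng.random() < cfg.ado_rate:
                        truth.ado_sites.append([i, slot])
                    else:
                        kept.append(a)
                present = set(kept)
                if rng.random() < cfg.adi_rate:
                    spurious = {0, 1} - present
                    if spurious:
                        present.add(spurious.pop())
                        truth.adi_sites.append(i)
                if not present:
                    obs.append(None)
                elif len(present) == 1:
                    a = present.pop()
                    obs.append((a, a))  # diploid-style call: sex unknown to the caller
                else:
                    obs.append((0, 1))
            depths[name] = draw_depth()
        calls[name] = obs
        roles[name] = ROLE_EMBRYO
        embryos[name] = truth

    table = SnpTable(sites=sites, calls=calls, depths=depths, roles=roles)
    gt = GroundTruth(
        mutant_linked=mutant_linked,
        hap_x1=[int(a) for a in ref_hap],
        hap_x2=[int(a) for a in other_hap],
        father_alleles=[int(a) for a in father],
        embryos=embryos,
    )
    return table, locus, gt


def write_family_vcf(table: SnpTable, path, hemizygous_dialect: str = "haploid") -> None:
    """Write the table as a minimal multi-sample VCF 4.2 file.

    Father and reference single-allele calls are encoded per the chosen
    dialect: ``"haploid"`` writes ``0``, ``"diploid"`` writes ``0/0``.
    """
    if table.n_sites == 0:
        raise ValueError("refusing to write an empty SnpTable")
    if hemizygous_dialect not in ("haploid", "diploid"):
        raise ConfigError(f"hemizygous_dialect invalid: {hemizygous_dialect!r}")
    samples = table.samples
    hemi = {table.father, table.reference}

    def fmt(sample: str, g: Genotype, dp: int) -> str:
        if g is None:
            gt = "." if (sample in hemi and hemizygous_dialect == "haploid") else "./."
        elif len(g) == 1:
            gt = str(g[0]) if hemizygous_dialect == "haploid" else f"{g[0]}/{g[0]}"
        else:
            gt = f"{min(g)}/{max(g)}"
        return f"{gt}:{dp}"

    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrX,length=156040895>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, row in table.sites.iterrows():
        cols = [
            str(row["chrom"]),
            str(int(row["pos"])),
            ".",
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        cols += [fmt(s, table.calls[s][i], int(table.depths[s][i])) for s in samples]
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
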