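"""End-to-end orchestration: filter, phase, count, call, report, evaluate.

The final report mirrors the clinical summary table: one row per embryo
with columns Sample ID, Gene, CHR, Gender, F(X), M(X1), M(X2), Haplotype,
Results, plus extended columns (recombination flag, breakpoint interval,
undetermined reason).  All thresholds and filter counts are logged so every
reported number is traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .calling import (
    CallParams,
    DISP_UNDETERMINED,
    EmbryoCall,
    call_embryo,
    count_support,
    detect_recombination,
    infer_sex,
    mutation_segment_unsafe,
)
from .model import SnpTable, TargetLocus
from .phasing import MarkerSummary, PhasedMaternalHaplotypes, classify_sites
from .simulate import GroundTruth
from .variant_io import apply_region_depth_filter, load_vcf

log = logging.getLogger(__name__)


@dataclass
class HaplotypeResult:
    """Everything the haplotyping stage produced."""

    report: pd.DataFrame
    phase: PhasedMaternalHaplotypes
    summary: MarkerSummary
    calls: dict[str, EmbryoCall]


def run_haplotype_analysis(
    table: SnpTable,
    locus: TargetLocus,
    params: CallParams = CallParams(),
    gene_name: str = "GENE",
) -> HaplotypeResult:
    """Run the full linkage analysis on an already-loaded genotype table."""
    filtered = apply_region_depth_filter(table, locus, params.min_depth)
    phase, summary = classify_sites(filtered, locus)
    log.info(
        "markers: %d paternal-informative, %d X1-detecting, %d X2-detecting",
        summary.n_paternal_informative,
        summary.n_x1_informative,
        summary.n_x2_informative,
    )
    calls: dict[str, EmbryoCall] = {}
    rows = []
    for embryo in filtered.embryos:
        sex = infer_sex(filtered, embryo, phase, params)
        counts = count_support(filtered, embryo, phase, sex, params.min_depth)
        call = call_embryo(counts, sex, phase.mutant_linked, params)
        call.embryo = embryo
        call.breakpoints = detect_recombination(counts.per_site, params)
        call.recombinant = bool(call.breakpoints)
        if call.recombinant and mutation_segment_unsafe(
            counts.per_site, call.breakpoints, locus.mutation_pos, params
        ):
            call.haplotype = None
            call.disposition = DISP_UNDETERMINED
            call.undetermined_reason = "recombination_near_mutation"
        calls[embryo] = call
        rows.append(
            {
                "Sample ID": embryo,
                "Gene": gene_name,
                "CHR": locus.chrom,
                "Gender": call.sex if call.sex != "unknown" else "-",
                "F(X)": counts.f_x,
                "M(X1)": counts.m_x1,
                "M(X2)": counts.m_x2,
                "Haplotype": f"M({call.haplotype})" if call.haplotype else "-",
                "Results": call.disposition,
                "Recombinant": call.recombinant,
                "Breakpoints": ";".join(f"{a}-{b}" for a, b in call.breakpoints),
                "Reason": call.undetermined_reason or "",
            }
        )
    report = pd.DataFrame(rows)
    return HaplotypeResult(report=report, phase=phase, summary=summary, calls=calls)


def run_haplotype_from_vcf(
    vcf_path,
    roles: dict[str, str],
    locus: TargetLocus,
    params: CallParams = CallParams(),
    gene_name: str = "GENE",
) -> HaplotypeResult:
    table = load_vcf(vcf_path, roles)
    return run_haplotype_analysis(table, locus, params, gene_name)


def write_report(result: HaplotypeResult, out_dir, params: CallParams) -> dict[str, Path]:
    """Write report TSV + JSON and the marker classification TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report_tsv": out / "report.tsv",
        "report_json": out / "report.json",
        "markers_tsv": out / "markers.tsv",
    }
    result.report.to_csv(paths["report_tsv"], sep="\t", index=False)
    result.phase.to_frame().to_csv(paths["markers_tsv"], sep="\t", index=False)
    payload = {
        "params": asdict(params),
        "mutant_linked": result.phase.mutant_linked,
        "marker_summary": asdict(result.summary),
        "embryos": result.report.to_dict(orient="records"),
    }
    with open(paths["report_json"], "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
    return paths


@dataclass
class Evaluation:
    """Pipeline-vs-truth comparison on simulated data."""

    confusion: pd.DataFrame  # true disposition x called disposition counts
    n_embryos: int
    n_called: int
    n_correct_called: int
    accuracy_overall: float  # correct (incl. Undetermined counted wrong) / all
    call_rate: float
    recomb_true: int = 0
    recomb_detected: int = 0
    recomb_localised: int = 0
    notes: list[str] = field(default_factory=list)


def evaluate_against_truth(result: HaplotypeResult, truth: GroundTruth) -> Evaluation:
    """Confusion matrix and recombination sensitivity against ground truth."""
    missing = set(result.calls) ^ set(truth.embryos)
    if missing:
        raise ValueError(f"embryo id mismatch between report and truth: {sorted(missing)}")
    records = []
    n_called = n_correct = 0
    recomb_true = recomb_detected = recomb_localised = 0
    for embryo, call in result.calls.items():
        et = truth.embryos[embryo]
        records.append((et.disposition, call.disposition))
        if call.disposition != DISP_UNDETERMINED:
            n_called += 1
            if call.disposition == et.disposition:
                n_correct += 1
        xo_in = [x for x in et.crossovers]
        if xo_in and not et.failed:
            recomb_true += 1
            if call.breakpoints:
                recomb_detected += 1
                if any(lo <= x <= hi for x in xo_in for lo, hi in call.breakpoints):
                    recomb_localised += 1
    confusion = (
        pd.DataFrame(records, columns=["truth", "called"])
        .value_counts()
        .unstack(fill_value=0)
    )
    n = len(records)
    return Evaluation(
        confusion=confusion,
        n_embryos=n,
        n_called=n_called,
        n_correct_called=n_correct,
        accuracy_overall=n_correct / n if n else float("nan"),
        call_rate=n_called / n if n else float("nan"),
        recomb_true=recomb_true,
        recomb_detected=recomb_detected,
        recomb_localised=recomb_localised,
    )
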