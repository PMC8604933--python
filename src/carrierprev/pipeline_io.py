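"""End-to-end orchestration: VCF in, analysis report out.

Stages run in order filter -> enrichment -> prevalence -> founder
haplotype.  The haplotype stage degrades gracefully: a failure there is
recorded as a warning and the report is still produced.  The report
contains only derived state — every number in it is regenerable from the
inputs plus the echoed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation_filter import AnnotatedVariant, FilterCriteria, filter_cohort, decisions_to_tsv
from .enrichment_stats import EnrichmentResult, enrich_all
from .founder_haplotype import HaplotypeSegment, segment_table, shared_segment
from .prevalence_model import (
    cumulative_pathogenic_frequency,
    hwe_prevalence,
    scenario_prevalence,
)
from .synthetic_cohort import GenotypeMatrix

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "PipelineError",
    "read_cohort_vcf",
    "read_reference_summary",
    "apply_reference_summary",
    "run_pipeline",
    "plot_af_comparison",
]

log = logging.getLogger("carrierprev")

#: default mapping from variant fields to VCF INFO keys (remappable)
DEFAULT_INFO_MAP = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "hgvs_p": "HGVSP",
    "cadd_phred": "CADD",
    "sift": "SIFT",
    "polyphen2": "PP2",
    "gerp": "GERP",
    "phastcons": "PHC",
    "reference_af": "REF_AF",
    "reference_n_individuals": "REF_N",
    "known_pathogenic": "KNOWN_PATHOGENIC",
}


class PipelineError(RuntimeError):
    """A hard failure with a user-actionable diagnostic."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    vcf_path: str
    reference_summary_path: Optional[str] = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    births_per_year: int = 84_200
    confidence_level: float = 0.95
    haplotype_region: Optional[str] = None  # "chrom:start-end"
    out_dir: Optional[str] = None
    include_filter_passing_vus: bool = False
    bonferroni: bool = False
    scenario_years: tuple = (1.0, 2.0, 3.0, 4.0)
    info_map: Optional[dict] = None
    haplotype_mode: str = "unphased"

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["criteria"]["allowed_consequences"] = sorted(
            self.criteria.allowed_consequences
        )
        return out


@dataclass
class AnalysisReport:
    """Derived state of one run; serialisable as deterministic JSON."""

    version: str
    config: dict
    n_variants: int
    n_pass: int
    filter_tally: dict
    enrichment: list
    prevalence: Optional[dict]
    scenarios: list
    segments: list
    warnings: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serialisable: {x!r}")


# ---------------------------------------------------------------------------
# input


def _parse_region(spec: str) -> tuple[str, int, int]:
    try:
        chrom, span = spec.rsplit(":", 1)
        start, end = span.replace(",", "").split("-")
        return chrom, int(start), int(end)
    except Exception as exc:
        raise PipelineError(f"malformed region {spec!r}; expected chrom:start-end") from exc


def read_cohort_vcf(
    path,
    info_map: Optional[dict] = None,
    region: Optional[str] = None,
) -> tuple[GenotypeMatrix, list[AnnotatedVariant]]:
    """Read a cohort VCF into a genotype matrix plus annotated variants.

    INFO keys are looked up through ``info_map`` (defaults to
    :data:`DEFAULT_INFO_MAP`).  Phased GT separators ("|") are honoured:
    haplotypes are retained only when every genotype is phased.
    ``region`` restricts sites to ``chrom:start-end`` (1-based inclusive).
    """
    import pysam

    keys = dict(DEFAULT_INFO_MAP, **(info_map or {}))
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"input VCF not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise PipelineError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    positions: list[int] = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    variants: list[AnnotatedVariant] = []
    all_phased = True
    chrom = None
    sel = _parse_region(region) if region else None

    with vf:
        for rec in vf:
            if sel and not (rec.chrom == sel[0] and sel[1] <= rec.pos <= sel[2]):
                continue
            if chrom is None:
                chrom = rec.chrom
            elif rec.chrom != chrom:
                raise PipelineError(
                    f"multi-chromosome VCF not supported (saw {chrom} and {rec.chrom})"
                )
            if rec.alts is None or len(rec.alts) != 1:
                raise PipelineError(f"site {rec.chrom}:{rec.pos} is not biallelic")

            col = np.zeros(len(samples), dtype=np.int8)
            hap = np.zeros(2 * len(samples), dtype=np.int8)
            for s, sample in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT") or (0, 0)
                alleles = [0 if a in (0, None) else 1 for a in gt]
                if len(alleles) == 1:
                    alleles = alleles * 2
                col[s] = sum(alleles)
                hap[2 * s], hap[2 * s + 1] = alleles
                if not call.phased:
                    all_phased = False

            def info(field_key, cast=float):
                raw = rec.info.get(keys[field_key])
                if raw is None:
                    return None
                if isinstance(raw, tuple):
                    raw = raw[0]
                return cast(raw)

            positions.append(rec.pos)
            geno_cols.append(col)
            hap_cols.append(hap)
            variants.append(AnnotatedVariant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                gene=info("gene", str) or "",
                consequence=info("consequence", str) or "other",
                hgvs_p=info("hgvs_p", str) or "",
                cadd_phred=info("cadd_phred"),
                sift=info("sift"),
                polyphen2=info("polyphen2"),
                gerp=info("gerp"),
                phastcons=info("phastcons"),
                cohort_ac=int(col.sum()),
                cohort_an=2 * len(samples),
                reference_af=info("reference_af"),
                reference_n_individuals=info("reference_n_individuals", int),
                known_pathogenic=bool(rec.info.get(keys["known_pathogenic"], False)),
            ))

    geno = (np.stack(geno_cols, axis=1) if geno_cols
            else np.zeros((len(samples), 0), dtype=np.int8))
    haps = (np.stack(hap_cols, axis=1) if hap_cols else None)
    gm = GenotypeMatrix(
        individual_ids=samples,
        site_positions=np.asarray(positions, dtype=np.int64),
        genotypes=geno,
        phased_haplotypes=haps if (all_phased and haps is not None) else None,
        chrom=chrom or "?",
    )
    return gm, variants


def read_reference_summary(path) -> pd.DataFrame:
    """Reference-population TSV: variant_id, reference_af, reference_n_individuals."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "reference_af", "reference_n_individuals"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"reference summary lacks columns: {sorted(missing)}")
    return df


def apply_reference_summary(
    variants: Sequence[AnnotatedVariant], summary: pd.DataFrame
) -> list[AnnotatedVariant]:
    """Override per-variant reference fields from the summary table."""
    lookup = summary.set_index("variant_id")
    out = []
    for v in variants:
        if v.variant_id in lookup.index:
            row = lookup.loc[v.variant_id]
            v = dataclasses.replace(
                v,
                reference_af=float(row["reference_af"]),
                reference_n_individuals=int(row["reference_n_individuals"]),
            )
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Execute filter -> enrichment -> prevalence -> haplotype.

    Haplotype-stage failures degrade to a report without segments; hard
    failures (unreadable input, malformed VCF, inconsistent allele
    numbers) raise :class:`PipelineError`.
    """
    warnings_out: list[str] = []
    t0 = time.perf_counter()
    gm, variants = read_cohort_vcf(cfg.vcf_path, info_map=cfg.info_map)
    log.info("read %d variants x %d individuals in %.2fs",
             len(variants), gm.n_individuals, time.perf_counter() - t0)

    if cfg.reference_summary_path:
        variants = apply_reference_summary(
            variants, read_reference_summary(cfg.reference_summary_path)
        )

    t0 = time.perf_counter()
    passing, tally, decisions = filter_cohort(variants, cfg.criteria)
    log.info("filter: %d/%d pass in %.2fs", len(passing), len(variants),
             time.perf_counter() - t0)

    results = enrich_all(passing)
    if cfg.bonferroni and results:
        m = len(results)
        results = [
            dataclasses.replace(r, p_one_sided=min(1.0, r.p_one_sided * m))
            if r.p_one_sided is not None else r
            for r in results
        ]

    pathogenic = [
        v for v in passing
        if v.known_pathogenic or cfg.include_filter_passing_vus
    ]
    prevalence = None
    if pathogenic:
        ans = {v.cohort_an for v in pathogenic}
        if len(ans) != 1:
            raise PipelineError(f"inconsistent cohort allele numbers: {sorted(ans)}")
        total_ac = sum(v.cohort_ac for v in pathogenic)
        (total_an,) = ans
        q = cumulative_pathogenic_frequency(pathogenic)
        prevalence = hwe_prevalence(
            q, cfg.births_per_year,
            total_ac=total_ac, total_an=total_an, level=cfg.confidence_level,
        ).report()
    else:
        warnings_out.append("no filter-passing pathogenic variants; prevalence not estimated")

    scenarios = [
        {"years_per_case": k,
         "prevalence_per_100k": scenario_prevalence(k, cfg.births_per_year).prevalence_per_100k,
         "prevalence_per_100k_2dp": scenario_prevalence(k, cfg.births_per_year).prevalence_per_100k_2dp}
        for k in cfg.scenario_years
    ]

    segments: list[dict] = []
    for v in pathogenic:
        carriers = [
            gm.individual_ids[i]
            for i in np.flatnonzero(gm.genotypes[:, gm.site_index(v.pos)] > 0)
        ]
        if not carriers:
            continue
        try:
            seg = shared_segment(gm, carriers, v.pos, mode=cfg.haplotype_mode)
            segments.append(json.loads(seg.to_json()))
        except (ValueError, KeyError) as exc:
            warnings_out.append(f"haplotype scan failed for {v.variant_id}: {exc}")

    report = AnalysisReport(
        version=__version__,
        config=cfg.echo(),
        n_variants=len(variants),
        n_pass=len(passing),
        filter_tally=dict(sorted(tally.items())),
        enrichment=[dataclasses.asdict(r) for r in results],
        prevalence=prevalence,
        scenarios=scenarios,
        segments=segments,
        warnings=warnings_out,
    )
    if not variants:
        report.warnings.append("input VCF contains no variant records")

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "filter_decisions.tsv").write_text(decisions_to_tsv(decisions))
        pd.DataFrame(report.enrichment).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# plotting


def plot_af_comparison(results: Sequence[EnrichmentResult], output_path) -> None:
    """Scatter of cohort AF against reference AF with the identity line.

    Points above the identity line are enriched in the cohort.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = [r for r in results if r.error is None]
    if not results:
        raise ValueError("no enrichment results to plot")
    x = np.array([r.reference_af for r in results], dtype=float)
    y = np.array([r.cohort_af for r in results], dtype=float)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=40, zorder=3)
    lo = min(x.min(), y.min()) * 0.5 or 1e-6
    hi = max(x.max(), y.max()) * 2.0
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("reference allele frequency")
    ax.set_ylabel("cohort allele frequency")
    ax.legend(frameon=False)
    for r in results:
        label = r.variant_id.split(":")[1] if ":" in r.variant_id else r.variant_id
        ax.annotate(label, (r.reference_af, r.cohort_af),
                    textcoords="offset points", xytext=(4, 4), fontsize=7)
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
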