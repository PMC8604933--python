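"""Synthetic diploid cohorts with planted rare pathogenic variants.

The generator emulates the study design the pipeline targets: a cohort of
1,016 diploid individuals (2,032 alleles) typed over a dense panel of
common background markers, carrying a handful of rare heterozygous
pathogenic variants.  A planted variant either has a fixed number of
carriers, or (for estimator-recovery experiments) a true allele frequency
from which carriers are drawn binomially.  A founder variant additionally
places all of its carriers on one shared haplotype over a contiguous
segment (default geometry: symmetric around the focal position, truncated
at the region boundary), emulating identity by descent from a recent
common ancestor.

Background markers are in linkage equilibrium and Hardy-Weinberg
proportions; the only linkage in the simulation is the planted founder
sharing.  Annotation scores are drawn uniformly strictly inside the filter
pass-region for a ``pathogenic`` profile and strictly outside it (CADD
below threshold) for a ``benign`` profile, so filter behaviour on planted
variants is deterministic by construction.  Genotypes are error-free.

Everything is driven by one :class:`numpy.random.Generator` seeded from
the config: identical seed and config give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .annotation_filter import AnnotatedVariant

__all__ = [
    "Region",
    "PlantedVariantSpec",
    "CohortSimConfig",
    "GenotypeMatrix",
    "PlantedTruth",
    "SimulationTruth",
    "simulate_cohort",
    "write_cohort_vcf",
    "write_truth_json",
    "config_from_yaml",
]


@dataclass(frozen=True)
class Region:
    """Half-closed genomic interval [start_bp, end_bp], 1-based, inclusive."""

    chrom: str = "18"
    start_bp: int = 12_000_000
    end_bp: int = 30_000_000

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError("region start_bp must be < end_bp")

    def contains(self, pos: int) -> bool:
        return self.start_bp <= pos <= self.end_bp


@dataclass(frozen=True)
class PlantedVariantSpec:
    """One variant to plant in the cohort.

    Exactly one of ``n_carrier_individuals`` (fixed carrier count) or
    ``true_af`` (carriers drawn binomially with heterozygote probability
    ``2 * true_af``) must be given.  All carriers are heterozygous.
    """

    pos_bp: int
    n_carrier_individuals: Optional[int] = None
    true_af: Optional[float] = None
    founder: bool = False
    founder_segment_mb: Optional[float] = None
    annotation_profile: str = "pathogenic"
    reference_af: float = 1e-5
    reference_n_individuals: int = 55_852
    gene: str = "NPC1"
    hgvs_p: str = ""
    ref: str = "C"
    alt: str = "T"

    def __post_init__(self) -> None:
        if (self.n_carrier_individuals is None) == (self.true_af is None):
            raise ValueError("give exactly one of n_carrier_individuals or true_af")
        if self.true_af is not None and not 0.0 <= self.true_af <= 0.5:
            raise ValueError("true_af must lie in [0, 0.5]")
        if self.founder and not (self.founder_segment_mb and self.founder_segment_mb > 0):
            raise ValueError("founder variants need founder_segment_mb > 0")
        if self.annotation_profile not in ("pathogenic", "benign"):
            raise ValueError(f"unknown annotation_profile {self.annotation_profile!r}")


def _default_planted() -> tuple:
    # two rare pathogenic NPC1 missense variants: a 3-carrier founder
    # variant on a 9.4 Mb shared haplotype and a 2-carrier independent one
    return (
        PlantedVariantSpec(
            pos_bp=21_120_000, n_carrier_individuals=3, founder=True,
            founder_segment_mb=9.4, reference_af=1.79e-5,
            hgvs_p="p.Pro543Leu", ref="C", alt="T",
        ),
        PlantedVariantSpec(
            pos_bp=21_137_000, n_carrier_individuals=2, founder=False,
            reference_af=3.94e-4, hgvs_p="p.Ile1061Thr", ref="T", alt="C",
        ),
    )


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for one simulated cohort."""

    seed: int
    n_individuals: int = 1016
    region: Region = field(default_factory=Region)
    n_markers: int = 1800
    marker_af_range: tuple[float, float] = (0.2, 0.5)
    planted_variants: tuple = field(default_factory=_default_planted)
    births_per_year: int = 84_200

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        lo, hi = self.marker_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("marker AFs must lie strictly inside (0,1)")
        object.__setattr__(self, "planted_variants", tuple(self.planted_variants))
        for spec in self.planted_variants:
            if not self.region.contains(spec.pos_bp):
                raise ValueError(f"planted pos {spec.pos_bp} outside region")
            if (spec.n_carrier_individuals is not None
                    and spec.n_carrier_individuals > self.n_individuals):
                raise ValueError("n_carrier_individuals exceeds n_individuals")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (0/1/2 alt-allele dosage) over ordered sites.

    ``phased_haplotypes`` rows ``2i`` and ``2i+1`` are the two chromosomes
    of individual ``i``; when present, their column sums equal
    ``genotypes``.
    """

    individual_ids: list
    site_positions: np.ndarray
    genotypes: np.ndarray
    phased_haplotypes: Optional[np.ndarray] = None
    chrom: str = "18"

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        n, s = self.genotypes.shape
        if n != len(self.individual_ids) or s != self.site_positions.size:
            raise ValueError("genotype matrix shape mismatch")
        if self.genotypes.min(initial=0) < 0 or self.genotypes.max(initial=0) > 2:
            raise ValueError("genotype values must lie in {0,1,2}")
        if self.phased_haplotypes is not None:
            h = np.asarray(self.phased_haplotypes)
            if h.shape != (2 * n, s):
                raise ValueError("phased haplotype shape mismatch")
            if not np.array_equal(h[0::2] + h[1::2], self.genotypes):
                raise ValueError("haplotypes do not sum to genotypes")
            self.phased_haplotypes = h

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def site_index(self, pos: int) -> int:
        idx = np.flatnonzero(self.site_positions == pos)
        if idx.size == 0:
            raise KeyError(f"position {pos} not typed")
        return int(idx[0])


@dataclass(frozen=True)
class PlantedTruth:
    """Generation-time record of one planted variant.

    ``founder_segment`` is the planted interval in bp;
    ``founder_marker_span`` is the same interval snapped to the outermost
    typed sites inside it — the tightest segment any marker-based scan can
    report.
    """

    pos_bp: int
    variant_id: str
    carrier_ids: tuple
    annotation_profile: str
    founder_segment: Optional[tuple[int, int]] = None
    founder_marker_span: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class SimulationTruth:
    planted: tuple
    true_q: float

    def for_pos(self, pos_bp: int) -> PlantedTruth:
        for t in self.planted:
            if t.pos_bp == pos_bp:
                return t
        raise KeyError(f"no planted variant at {pos_bp}")


# score ranges for the two annotation profiles; the pathogenic profile is
# uniform strictly inside the pass region of every clause, the benign one
# fails the CADD clause with certainty and looks unremarkable elsewhere
_PATHOGENIC = dict(cadd=(15.0, 50.0), sift=(0.0, 0.25), polyphen2=(0.75, 1.0),
                   gerp=(5.0, 6.18), phastcons=(500.0, 1000.0))
_BENIGN = dict(cadd=(0.0, 15.0), sift=(0.3, 1.0), polyphen2=(0.0, 0.6),
               gerp=(-3.0, 4.0), phastcons=(0.0, 450.0))


def _marker_positions(cfg: CohortSimConfig) -> np.ndarray:
    span = cfg.region.end_bp - cfg.region.start_bp
    pos = cfg.region.start_bp + np.round(
        (np.arange(cfg.n_markers) + 1) * span / (cfg.n_markers + 1)
    ).astype(np.int64)
    planted = {s.pos_bp for s in cfg.planted_variants}
    # nudge the rare marker that collides with a planted position
    while True:
        clash = np.isin(pos, list(planted))
        if not clash.any():
            break
        pos[clash] += 1
    return pos


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[GenotypeMatrix, list[AnnotatedVariant], SimulationTruth]:
    """Generate one cohort: genotypes, annotated variants, and the truth.

    Planted carriers are heterozygous; founder carriers share one
    haplotype, identical over the founder segment and free outside it.
    Background genotypes are drawn per site from Hardy-Weinberg
    proportions via two independent haplotypes.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    ids = [f"I{i:04d}" for i in range(n)]

    marker_pos = _marker_positions(cfg)
    lo, hi = cfg.marker_af_range
    marker_afs = rng.uniform(lo, hi, cfg.n_markers)
    haps_markers = (rng.random((2 * n, cfg.n_markers)) < marker_afs).astype(np.int8)

    planted_cols = np.zeros((2 * n, len(cfg.planted_variants)), dtype=np.int8)
    truths: list[PlantedTruth] = []
    true_q = 0.0
    # founder haplotypes are reserved so that an unrelated planted allele on
    # the same individual lands on the other chromosome and cannot interrupt
    # the shared segment the truth promises
    reserved: list[tuple[int, int, int, int]] = []  # (individual, hap, seg_start, seg_end)
    planted_on: dict[tuple[int, int], list[int]] = {}
    for j, spec in enumerate(cfg.planted_variants):
        if spec.true_af is not None:
            k = int(rng.binomial(n, min(1.0, 2.0 * spec.true_af)))
            if spec.annotation_profile == "pathogenic":
                true_q += spec.true_af
        else:
            k = spec.n_carrier_individuals
            if spec.annotation_profile == "pathogenic":
                true_q += k / (2 * n)
        carriers = np.sort(rng.choice(n, size=k, replace=False)) if k else np.array([], dtype=int)
        which_hap = rng.integers(0, 2, size=k)

        segment = None
        if spec.founder:
            half = int(round(spec.founder_segment_mb * 1e6 / 2))
            segment = (max(cfg.region.start_bp, spec.pos_bp - half),
                       min(cfg.region.end_bp, spec.pos_bp + half))
            for i, (c, h) in enumerate(zip(carriers, which_hap)):
                if any(segment[0] <= p <= segment[1]
                       for p in planted_on.get((c, h), [])):
                    which_hap[i] = 1 - h
            template = (rng.random(cfg.n_markers) < marker_afs).astype(np.int8)
            in_seg = (marker_pos >= segment[0]) & (marker_pos <= segment[1])
            for c, h in zip(carriers, which_hap):
                haps_markers[2 * c + h, in_seg] = template[in_seg]
                reserved.append((c, h, segment[0], segment[1]))
        else:
            for i, (c, h) in enumerate(zip(carriers, which_hap)):
                if any(c == rc and h == rh and s0 <= spec.pos_bp <= s1
                       for rc, rh, s0, s1 in reserved):
                    which_hap[i] = 1 - h

        planted_cols[2 * carriers + which_hap, j] = 1
        for c, h in zip(carriers, which_hap):
            planted_on.setdefault((int(c), int(h)), []).append(spec.pos_bp)

        truths.append(PlantedTruth(
            pos_bp=spec.pos_bp,
            variant_id=f"{cfg.region.chrom}:{spec.pos_bp}:{spec.ref}>{spec.alt}",
            carrier_ids=tuple(ids[c] for c in carriers),
            annotation_profile=spec.annotation_profile,
            founder_segment=segment,
        ))

    # merge markers and planted variants into one position-sorted panel
    all_pos = np.concatenate([marker_pos, [s.pos_bp for s in cfg.planted_variants]])
    order = np.argsort(all_pos, kind="stable")
    for j, t in enumerate(truths):
        if t.founder_segment is not None:
            s0, s1 = t.founder_segment
            inside = all_pos[(all_pos >= s0) & (all_pos <= s1)]
            truths[j] = dataclasses.replace(
                t, founder_marker_span=(int(inside.min()), int(inside.max()))
            )
    haps = np.concatenate([haps_markers, planted_cols], axis=1)[:, order]
    positions = all_pos[order]
    gm = GenotypeMatrix(
        individual_ids=ids, site_positions=positions,
        genotypes=haps[0::2] + haps[1::2], phased_haplotypes=haps,
        chrom=cfg.region.chrom,
    )

    variants = _annotate_sites(cfg, rng, gm, marker_pos, marker_afs, order)
    return gm, variants, SimulationTruth(planted=tuple(truths), true_q=true_q)


def _annotate_sites(cfg, rng, gm, marker_pos, marker_afs, order) -> list[AnnotatedVariant]:
    n_sites = gm.site_positions.size
    ac = gm.genotypes.sum(axis=0).astype(int)
    an = 2 * gm.n_individuals

    # annotation lookup in pre-sort column order: markers then planted
    kind = np.concatenate([np.zeros(marker_pos.size, dtype=int),
                           np.arange(1, len(cfg.planted_variants) + 1)])[order]
    marker_af_by_pos = dict(zip(marker_pos.tolist(), marker_afs.tolist()))

    variants: list[AnnotatedVariant] = []
    for i in range(n_sites):
        pos = int(gm.site_positions[i])
        if kind[i] == 0:
            variants.append(AnnotatedVariant(
                chrom=cfg.region.chrom, pos=pos, ref="A", alt="G",
                gene="", consequence="other",
                cadd_phred=float(rng.uniform(0, 10)),
                gerp=float(rng.uniform(-3, 3)),
                phastcons=float(rng.uniform(0, 300)),
                cohort_ac=int(ac[i]), cohort_an=an,
                reference_af=float(marker_af_by_pos[pos]),
                reference_n_individuals=55_852,
                known_pathogenic=False,
            ))
        else:
            spec = cfg.planted_variants[kind[i] - 1]
            ranges = _PATHOGENIC if spec.annotation_profile == "pathogenic" else _BENIGN
            draw = {name: float(rng.uniform(*bounds)) for name, bounds in ranges.items()}
            variants.append(AnnotatedVariant(
                chrom=cfg.region.chrom, pos=pos, ref=spec.ref, alt=spec.alt,
                gene=spec.gene, consequence="missense", hgvs_p=spec.hgvs_p,
                cadd_phred=draw["cadd"], sift=draw["sift"],
                polyphen2=draw["polyphen2"], gerp=draw["gerp"],
                phastcons=draw["phastcons"],
                cohort_ac=int(ac[i]), cohort_an=an,
                reference_af=spec.reference_af,
                reference_n_individuals=spec.reference_n_individuals,
                known_pathogenic=(spec.annotation_profile == "pathogenic"),
            ))
    return variants


# ---------------------------------------------------------------------------
# persistence

_INFO_FIELDS = [
    ("GENE", "String", "Gene symbol"),
    ("CSQ_CLASS", "String", "Consequence class: missense/indel/other"),
    ("HGVSP", "String", "Protein-level HGVS"),
    ("CADD", "Float", "CADD PHRED score"),
    ("SIFT", "Float", "SIFT score (damaging when low)"),
    ("PP2", "Float", "PolyPhen2 score (damaging when high)"),
    ("GERP", "Float", "GERP conservation score"),
    ("PHC", "Float", "phastCons element score (0-1000)"),
    ("REF_AF", "Float", "Reference-population allele frequency"),
    ("REF_N", "Integer", "Reference-population sequenced individuals"),
    ("KNOWN_PATHOGENIC", "Flag", "Curated pathogenic variant"),
]


def write_cohort_vcf(path, gm: GenotypeMatrix, variants: Sequence[AnnotatedVariant]) -> None:
    """Write the cohort as an uncompressed VCF 4.2 with GT and INFO annotations."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={gm.chrom},length={int(gm.site_positions.max()) + 10_000}>")
    for name, typ, desc in _INFO_FIELDS:
        number = "0" if typ == "Flag" else "1"
        header.add_line(f'##INFO=<ID={name},Number={number},Type={typ},Description="{desc}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sample in gm.individual_ids:
        header.add_sample(sample)

    phased = gm.phased_haplotypes is not None
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(variants):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, stop=v.pos,
                                 alleles=(v.ref, v.alt))
            info = {"CSQ_CLASS": v.consequence, "REF_AF": v.reference_af,
                    "REF_N": v.reference_n_individuals, "GENE": v.gene or None,
                    "HGVSP": v.hgvs_p or None, "CADD": v.cadd_phred,
                    "SIFT": v.sift, "PP2": v.polyphen2, "GERP": v.gerp,
                    "PHC": v.phastcons}
            for key, val in info.items():
                if val is not None and val != "":
                    rec.info[key] = val
            if v.known_pathogenic:
                rec.info["KNOWN_PATHOGENIC"] = True
            for s, sample in enumerate(gm.individual_ids):
                if phased:
                    gt = (int(gm.phased_haplotypes[2 * s, i]),
                          int(gm.phased_haplotypes[2 * s + 1, i]))
                else:
                    g = int(gm.genotypes[s, i])
                    gt = (0, 0) if g == 0 else (0, 1) if g == 1 else (1, 1)
                rec.samples[sample]["GT"] = gt
                rec.samples[sample].phased = phased
            out.write(rec)


def write_truth_json(path, truth: SimulationTruth) -> None:
    payload = {
        "true_q": truth.true_q,
        "planted": [dataclasses.asdict(t) for t in truth.planted],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def config_from_yaml(path) -> CohortSimConfig:
    """Load a :class:`CohortSimConfig` from a YAML (or flat key:value) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    if "seed" not in raw:
        raise ValueError("config file must set an explicit seed")
    kwargs = dict(raw)
    if "region" in kwargs:
        kwargs["region"] = Region(**kwargs["region"])
    if "marker_af_range" in kwargs:
        kwargs["marker_af_range"] = tuple(kwargs["marker_af_range"])
    if "planted_variants" in kwargs:
        kwargs["planted_variants"] = tuple(
            PlantedVariantSpec(**spec) for spec in kwargs["planted_variants"]
        )
    return CohortSimConfig(**kwargs)
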