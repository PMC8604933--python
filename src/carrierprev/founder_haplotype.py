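"""Shared-haplotype segment detection around a focal variant.

Supports the founder-variant argument: carriers of a variant inherited
from a recent common ancestor share a long stretch of chromosome around
it.  Given carrier genotypes over a marker panel, the scan finds the
maximal contiguous interval containing the focal position over which all
carriers *can* share one haplotype.

Unphased mode (the default for real cohort data, where parental genotypes
are unavailable and phasing is not possible) uses a per-marker
compatibility rule: a marker is compatible when some single allele could
sit on a shared haplotype of every carrier — the alternate allele qualifies
unless a carrier is homozygous reference, the reference allele unless a
carrier is homozygous alternate.  The scan extends marker by marker from
the focal position and stops before the first incompatible marker on each
side; boundaries are the outermost compatible markers.

Phased mode (available when haplotypes are known, e.g. from simulation)
demands an explicit choice of one haplotype per carrier, identical across
carriers over the whole segment; it is never more permissive than the
unphased rule.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .prevalence_model import round_half_up
from .synthetic_cohort import GenotypeMatrix

__all__ = ["HaplotypeSegment", "shared_segment", "segment_table"]


@dataclass(frozen=True)
class HaplotypeSegment:
    """Maximal interval over which all carriers can share one haplotype.

    ``shared_alleles`` maps marker position to "ref"/"alt" where the shared
    allele is uniquely determined, ``None`` where ambiguous.
    """

    chrom: str
    start_bp: int
    end_bp: int
    focal_pos: int
    carrier_ids: tuple
    shared_alleles: dict
    mode: str = "unphased"

    def __post_init__(self) -> None:
        if not self.start_bp <= self.focal_pos <= self.end_bp:
            raise ValueError("focal position must lie inside the segment")

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6

    @property
    def length_mb_1dp(self) -> float:
        return round_half_up(self.length_mb, 1)

    def to_json(self, **kwargs) -> str:
        payload = {
            "chrom": self.chrom, "start_bp": self.start_bp, "end_bp": self.end_bp,
            "length_mb": self.length_mb, "length_mb_1dp": self.length_mb_1dp,
            "focal_pos": self.focal_pos, "carrier_ids": list(self.carrier_ids),
            "mode": self.mode,
            "shared_alleles": {str(k): v for k, v in self.shared_alleles.items()},
        }
        return json.dumps(payload, **kwargs)


def _extent(compatible: np.ndarray, focal_idx: int, max_mismatch: int) -> tuple[int, int]:
    """Outermost compatible indices around focal, skipping up to
    ``max_mismatch`` incompatible markers per side."""
    left = focal_idx
    budget = max_mismatch
    i = focal_idx - 1
    while i >= 0:
        if compatible[i]:
            left = i
        else:
            if budget == 0:
                break
            budget -= 1
        i -= 1
    right = focal_idx
    budget = max_mismatch
    i = focal_idx + 1
    while i < compatible.size:
        if compatible[i]:
            right = i
        else:
            if budget == 0:
                break
            budget -= 1
        i += 1
    return left, right


def shared_segment(
    gm: GenotypeMatrix,
    carrier_ids: Sequence[str],
    focal_pos: int,
    mode: str = "auto",
    max_mismatch: int = 0,
) -> HaplotypeSegment:
    """Maximal segment around ``focal_pos`` compatible with one shared haplotype.

    ``mode`` is ``"unphased"``, ``"phased"`` or ``"auto"`` (phased when the
    matrix carries haplotypes).  ``max_mismatch`` incompatible markers per
    side are tolerated (default 0); boundaries remain the outermost
    compatible markers.
    """
    if not carrier_ids:
        raise ValueError("need at least one carrier")
    if mode == "auto":
        mode = "phased" if gm.phased_haplotypes is not None else "unphased"
    if mode == "phased" and gm.phased_haplotypes is None:
        raise ValueError("phased mode requested but no haplotypes present")

    focal_idx = gm.site_index(focal_pos)
    rows = []
    for cid in carrier_ids:
        try:
            rows.append(gm.individual_ids.index(cid))
        except ValueError:
            raise KeyError(f"unknown individual {cid!r}") from None
    geno = gm.genotypes[rows, :]
    if (geno[:, focal_idx] < 1).any():
        lacking = [carrier_ids[k] for k in np.flatnonzero(geno[:, focal_idx] < 1)]
        raise ValueError(f"carriers lack the focal alternate allele: {lacking}")

    if mode == "unphased":
        alt_ok = (geno != 0).all(axis=0)  # no carrier homozygous reference
        ref_ok = (geno != 2).all(axis=0)  # no carrier homozygous alternate
        left, right = _extent(alt_ok | ref_ok, focal_idx, max_mismatch)
        shared = {}
        for i in range(left, right + 1):
            pos = int(gm.site_positions[i])
            if alt_ok[i] and not ref_ok[i]:
                shared[pos] = "alt"
            elif ref_ok[i] and not alt_ok[i]:
                shared[pos] = "ref"
            else:
                shared[pos] = None
    else:
        left, right, shared = _phased_scan(gm, rows, focal_idx, max_mismatch)

    return HaplotypeSegment(
        chrom=gm.chrom,
        start_bp=int(gm.site_positions[left]),
        end_bp=int(gm.site_positions[right]),
        focal_pos=focal_pos,
        carrier_ids=tuple(carrier_ids),
        shared_alleles=shared,
        mode=mode,
    )


def _phased_scan(gm: GenotypeMatrix, rows: list, focal_idx: int, max_mismatch: int):
    """Best segment over explicit choices of one haplotype per carrier."""
    haps = gm.phased_haplotypes
    candidates = []
    for r in rows:
        own = [h for h in (0, 1) if haps[2 * r + h, focal_idx] == 1]
        candidates.append(own)

    best = None
    for choice in itertools.product(*candidates):
        mat = np.stack([haps[2 * r + h, :] for r, h in zip(rows, choice)])
        compatible = (mat == mat[0]).all(axis=0)
        left, right = _extent(compatible, focal_idx, max_mismatch)
        span = gm.site_positions[right] - gm.site_positions[left]
        if best is None or span > best[0]:
            shared = {
                int(gm.site_positions[i]): ("alt" if mat[0, i] else "ref")
                for i in range(left, right + 1)
            }
            best = (span, left, right, shared)
    _, left, right, shared = best
    return left, right, shared


def segment_table(seg: HaplotypeSegment, gm: GenotypeMatrix) -> pd.DataFrame:
    """Markers-by-carriers genotype table over the segment.

    Rows are marker positions inside the segment; columns are carrier
    genotypes (alt-allele dosage) plus the shared allele where determined.
    Round-trips losslessly through ``DataFrame.to_csv(sep="\\t")``.
    """
    mask = (gm.site_positions >= seg.start_bp) & (gm.site_positions <= seg.end_bp)
    idx = np.flatnonzero(mask)
    rows = [gm.individual_ids.index(c) for c in seg.carrier_ids]
    data = {
        cid: gm.genotypes[r, idx].astype(int)
        for cid, r in zip(seg.carrier_ids, rows)
    }
    table = pd.DataFrame(data, index=[int(p) for p in gm.site_positions[idx]])
    table.index.name = "pos_bp"
    table["shared_allele"] = [
        seg.shared_alleles.get(p) or "." for p in table.index
    ]
    return table
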