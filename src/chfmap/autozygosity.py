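"""Run-of-homozygosity detection and shared-autozygosity interval mapping.

Under a recessive model with inbred cases descending from one founder, all
cases are autozygous (identical by descent) for the causal haplotype.  The
causal variant must therefore lie inside the region where every case is
homozygous for the *same* allele, and the critical interval is bounded by
the closest flanking markers at which any case is heterozygous or the
cases' homozygous alleles disagree.

ROH detection here uses direct run-scan semantics: a segment is a maximal
stretch of non-missing homozygous calls permitting at most ``max_het``
heterozygous calls, and must satisfy the minimum SNP-count and kb-length
thresholds.  Missing calls neither break a run nor count toward its SNP or
het tallies.  The thresholds map 1:1 to the common PLINK parameters
(--homozyg-kb / -snp / -het / -match); the sliding-window machinery of that
tool is deliberately not reproduced, since it is an approximation device,
not part of the segment definition.  Qualification thresholds apply to each
individual's segments; the cross-case consensus is a separate object and
carries no thresholds of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, MarkerMap


@dataclass
class RohParams:
    """Segment qualification thresholds (PLINK-style)."""

    min_length_kb: float = 500.0
    min_snps: int = 25
    max_het: int = 1
    match_frac: float = 0.95

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if not 0.0 < self.match_frac <= 1.0:
            raise ValueError("match_frac must be in (0,1]")
        if self.max_het < 0:
            raise ValueError("max_het must be >= 0")


@dataclass
class RohSegment:
    sample_id: str
    chromosome: str
    first_marker: int  # global marker index
    last_marker: int
    start_bp: int
    end_bp: int
    n_snps: int  # non-missing homozygous calls inside the run
    n_het_inside: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class CriticalInterval:
    """Cross-case shared autozygous block with flanking-heterozygote bounds.

    ``left_bound_bp``/``right_bound_bp`` are the positions of the closest
    markers outside the shared block at which at least one case is
    heterozygous or allele-discordant (closed interval, matching how such
    intervals are reported from array data).
    """

    chromosome: str
    left_bound_bp: int
    right_bound_bp: int
    n_shared_snps: int
    first_marker: int  # global index of first shared marker
    last_marker: int

    @property
    def length_bp(self) -> int:
        return self.right_bound_bp - self.left_bound_bp

    @property
    def length_kb_rounded(self) -> int:
        return interval_length(self)[1]


def interval_length(ci: CriticalInterval) -> tuple[int, int]:
    """Interval length in bp and in kb rounded half-up."""
    if ci.left_bound_bp >= ci.right_bound_bp:
        raise ValueError("inverted interval bounds")
    bp = ci.right_bound_bp - ci.left_bound_bp
    return bp, int(floor(bp / 1000.0 + 0.5))


def _maximal_windows(het_idx: np.ndarray, n: int, max_het: int) -> list[tuple[int, int]]:
    """Maximal index windows [lo, hi] containing at most ``max_het`` hets."""
    t = len(het_idx)
    if t <= max_het:
        return [(0, n - 1)] if n > 0 else []
    ext = np.concatenate([[-1], het_idx, [n] * (max_het + 1)])
    windows = []
    prev = None
    for i in range(t + 1):
        lo = int(ext[i]) + 1
        hi = int(ext[i + max_het + 1]) - 1
        if lo > hi:
            continue
        if prev is not None and lo >= prev[0] and hi <= prev[1]:
            continue
        windows.append((lo, hi))
        prev = (lo, hi)
    return windows


def detect_roh(
    calls: np.ndarray,
    mm: MarkerMap,
    params: RohParams | None = None,
    sample_id: str = "",
) -> list[RohSegment]:
    """Detect qualifying runs of homozygosity for one sample.

    ``calls`` is the sample's genotype vector aligned to ``mm`` (which is
    validated as position-sorted on construction).
    """
    if params is None:
        params = RohParams()
    calls = np.asarray(calls)
    if calls.shape != (mm.n_markers,):
        raise ValueError("calls length must match the marker map")

    positions = mm.positions()
    segments: list[RohSegment] = []
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        sub = calls[idx]
        hom = (sub == HOM_REF) | (sub == HOM_ALT)
        het = sub == HET
        hom_idx = np.flatnonzero(hom)
        if hom_idx.size == 0:
            continue
        het_idx = np.flatnonzero(het)
        het_cum = np.concatenate([[0], np.cumsum(het)])
        hom_cum = np.concatenate([[0], np.cumsum(hom)])
        seen: set[tuple[int, int]] = set()
        for lo, hi in _maximal_windows(het_idx, len(sub), params.max_het):
            # trim window ends to homozygous calls
            a = np.searchsorted(hom_idx, lo, side="left")
            b = np.searchsorted(hom_idx, hi, side="right") - 1
            if a > b:
                continue
            lo2, hi2 = int(hom_idx[a]), int(hom_idx[b])
            if (lo2, hi2) in seen:
                continue
            seen.add((lo2, hi2))
            n_snps = int(hom_cum[hi2 + 1] - hom_cum[lo2])
            n_het = int(het_cum[hi2 + 1] - het_cum[lo2])
            g0, g1 = int(idx[lo2]), int(idx[hi2])
            length = int(positions[g1] - positions[g0])
            if n_snps < params.min_snps or length < params.min_length_kb * 1000.0:
                continue
            segments.append(
                RohSegment(
                    sample_id=sample_id,
                    chromosome=chrom,
                    first_marker=g0,
                    last_marker=g1,
                    start_bp=int(positions[g0]),
                    end_bp=int(positions[g1]),
                    n_snps=n_snps,
                    n_het_inside=n_het,
                )
            )
    return segments


def _pairs(k: np.ndarray) -> np.ndarray:
    return k * (k - 1) // 2


def shared_autozygous_segment(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    case_ids: Sequence[str],
    params: RohParams | None = None,
) -> CriticalInterval | None:
    """Longest genome-wide block shared homozygous-identical across all cases.

    Each case's qualifying ROH are intersected; within the intersection a
    marker keeps the run alive only if no case is heterozygous there and the
    homozygous alleles agree in at least ``match_frac`` of the pairwise
    case comparisons (pairs with a missing call are not compared and a
    missing call never breaks sharing).  The longest surviving run is
    returned with bounds extended outward to the nearest heterozygous or
    allele-discordant marker on either side; ``None`` when no block exists.
    Output is independent of case ordering.
    """
    if params is None:
        params = RohParams()
    if len(case_ids) < 2:
        raise ValueError("shared_autozygous_segment requires at least 2 cases")
    rows = np.stack([gm.row(s) for s in case_ids])  # (k, m)
    m = gm.n_markers

    covered = np.zeros((len(case_ids), m), dtype=bool)
    for i, sid in enumerate(case_ids):
        for seg in detect_roh(rows[i], mm, params, sample_id=sid):
            covered[i, seg.first_marker : seg.last_marker + 1] = True
    inter = covered.all(axis=0)

    any_het = (rows == HET).any(axis=0)
    c0 = (rows == HOM_REF).sum(axis=0)
    c2 = (rows == HOM_ALT).sum(axis=0)
    pairs_total = _pairs(c0 + c2)
    pairs_match = _pairs(c0) + _pairs(c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pairs_total > 0, pairs_match / np.maximum(pairs_total, 1), 1.0)
    breaking = any_het | ((pairs_total > 0) & (frac < params.match_frac))
    all_identical = ((c0 == len(case_ids)) | (c2 == len(case_ids)))

    positions = mm.positions()
    best: CriticalInterval | None = None
    best_key: tuple | None = None
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        ok = inter[idx] & ~breaking[idx]
        if not ok.any():
            continue
        # maximal runs of ok
        padded = np.concatenate([[False], ok, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        brk = breaking[idx]
        for s, e in zip(starts, ends):
            n_shared = int(all_identical[idx[s : e + 1]].sum())
            if n_shared == 0:
                continue
            g0, g1 = int(idx[s]), int(idx[e])
            # flanking bounds: nearest het/discordant marker outside the run
            left_brk = np.flatnonzero(brk[:s])
            right_brk = np.flatnonzero(brk[e + 1 :])
            lb = int(idx[left_brk[-1]]) if left_brk.size else g0
            rb = int(idx[e + 1 + right_brk[0]]) if right_brk.size else g1
            length = int(positions[rb] - positions[lb])
            key = (length, n_shared, -positions[g0])
            if best_key is None or key > best_key:
                best_key = key
                best = CriticalInterval(
                    chromosome=chrom,
                    left_bound_bp=int(positions[lb]),
                    right_bound_bp=int(positions[rb]),
                    n_shared_snps=n_shared,
                    first_marker=g0,
                    last_marker=g1,
                )
    return best


def write_bed(segments: Sequence[RohSegment], path: str | Path) -> None:
    """Emit ROH segments as BED (the one 0-based half-open boundary in the
    package: start = start_bp - 1, end = end_bp)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chromosome}\t{seg.start_bp - 1}\t{seg.end_bp}\t"
                f"{seg.sample_id}\t{seg.n_snps}\n"
            )
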