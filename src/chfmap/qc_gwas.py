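"""Marker QC and case/control allelic association with permutation significance.

The association statistic is the Pearson chi-square on the 2x2 allele-count
table (2N alleles for N diploid individuals), df = 1, *without* Yates
continuity correction: with 5 cases and 12 controls a completely separating
marker gives chi2 = 34 and an upper-tail p of 5.5e-9, the textbook allelic
test.  Genome-wide significance comes from max-T label permutation: the
observed statistic at each marker is compared with the distribution of the
per-permutation genome-wide maximum, and the empirical p uses the add-one
estimator (r+1)/(R+1), with ties counted as exceedances.

Marker QC removes markers by call rate, then minor allele frequency, then
Hardy-Weinberg disequilibrium (exact test, probability-ordering two-sided
convention), attributing each removed marker to the first failing rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, MarkerMap

# chi-square(1) distribution median, denominator of the genomic inflation factor
CHI2_DF1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

# smallest positive double: keeps p-values in (0, 1] even when sf underflows
_TINY = 5e-324


@dataclass
class QcThresholds:
    """Marker retention thresholds: call rate, MAF, HWE exact-test p."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    min_hwe_p: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QcReport:
    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_retained: int
    reasons: pd.DataFrame = field(repr=False)  # marker_id, reason

    @property
    def m(self) -> int:
        """Retained marker count (Bonferroni denominator)."""
        return self.n_retained


@dataclass
class PermConfig:
    """Label-permutation settings for genome-wide empirical significance."""

    n_perm: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Probability-ordering convention: sums the probabilities of all
    heterozygote counts (given the observed allele counts) whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic markers return 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # unnormalised probabilities over het counts h (parity of n_rare), via the
    # standard two-direction recurrence from the modal het count
    h_obs = n_het
    hs = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {h: 0.0 for h in hs}
    # start near the mode
    h_mid = int(round(n_rare * (2 * n - n_rare) / (2 * n)))
    if (h_mid % 2) != (n_rare % 2):
        h_mid += 1
    h_mid = min(max(h_mid, hs[0]), hs[-1])
    probs[h_mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((hr+1)(ha+1)*4) with hr,ha homs at h
    h = h_mid
    while h - 2 >= hs[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = h_mid
    while h + 2 <= hs[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[h_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-10)) / total
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# allelic association
# ---------------------------------------------------------------------------


def allelic_test(
    case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on allele counts.

    Returns ``(chi2, p_raw)`` with upper-tail p.  Degenerate tables (a zero
    row or column total) give ``(0.0, 1.0)``.
    """
    if min(case_alt, case_ref, ctrl_alt, ctrl_ref) < 0:
        raise ValueError("allele counts must be non-negative")
    a, b, c, d = (float(x) for x in (case_alt, case_ref, ctrl_alt, ctrl_ref))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = max(float(stats.chi2.sf(chi2, 1)), _TINY)
    return float(chi2), p


def _chi2_from_counts(a, b, c, d):
    """Vectorised allelic chi-square; zero where a marginal vanishes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return chi2


def _allele_counts(calls: np.ndarray, mask: np.ndarray):
    """Alt/ref allele counts per marker for the samples selected by ``mask``."""
    nonmiss = calls != MISSING
    altmat = np.where(nonmiss, calls, 0).astype(np.int64)
    alt = altmat[mask].sum(axis=0)
    nn = nonmiss[mask].sum(axis=0)
    return alt, 2 * nn - alt


def genomic_inflation(chi2_values) -> float:
    """Genomic inflation factor: median observed chi2 over the null median."""
    arr = np.asarray(list(chi2_values), dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("genomic_inflation requires at least one finite statistic")
    return float(np.median(arr) / CHI2_DF1_MEDIAN)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, m * p_raw))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def qc_filter(
    gm: GenotypeMatrix, mm: MarkerMap, th: QcThresholds | None = None
) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Remove markers failing call-rate, MAF or HWE thresholds (in that order).

    Each removed marker is attributed to the first failing rule.  The HWE
    check is applied to all samples jointly.  Removing every marker is a
    warning condition, not an error: an empty matrix is returned.
    """
    if th is None:
        th = QcThresholds()
    if gm.n_samples < 1:
        raise ValueError("qc_filter requires at least one sample")
    if gm.n_markers != mm.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")

    calls = gm.calls
    n = gm.n_samples
    call_rate = (calls != MISSING).sum(axis=0) / n

    nonmiss = (calls != MISSING).sum(axis=0)
    alt = np.where(calls != MISSING, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(nonmiss > 0, alt / np.maximum(2 * nonmiss, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    reasons = np.full(gm.n_markers, "", dtype=object)
    fail_cr = call_rate < th.min_call_rate
    reasons[fail_cr] = "call_rate"
    fail_maf = (maf < th.min_maf) & ~fail_cr
    reasons[fail_maf] = "maf"

    candidates = np.flatnonzero(~fail_cr & ~fail_maf)
    fail_hwe = np.zeros(gm.n_markers, dtype=bool)
    for j in candidates:
        col = calls[:, j]
        p = hwe_exact_p(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        if p <= th.min_hwe_p:
            fail_hwe[j] = True
            reasons[j] = "hwe"

    keep = reasons == ""
    report = QcReport(
        n_input=gm.n_markers,
        removed_call_rate=int(fail_cr.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
        reasons=pd.DataFrame(
            {"marker_id": mm.df["marker_id"], "reason": reasons}
        ).query("reason != ''").reset_index(drop=True),
    )
    return gm.subset_markers(keep), mm.subset(keep), report


# ---------------------------------------------------------------------------
# association scan and max-T permutation
# ---------------------------------------------------------------------------


def allelic_scan(gm: GenotypeMatrix, mm: MarkerMap, case_mask: np.ndarray) -> pd.DataFrame:
    """Single-marker allelic association over all markers.

    Returns a DataFrame with allele counts, chi2, p_raw and p_bonf
    (m = number of markers scanned).
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    if case_mask.shape != (gm.n_samples,):
        raise ValueError("case_mask length must equal the sample count")
    ca, cr = _allele_counts(gm.calls, case_mask)
    ta, tr = _allele_counts(gm.calls, ~case_mask)
    chi2 = _chi2_from_counts(ca, cr, ta, tr)
    p_raw = np.maximum(stats.chi2.sf(chi2, 1), _TINY)
    m = gm.n_markers
    return pd.DataFrame(
        {
            "marker_id": mm.df["marker_id"],
            "chromosome": mm.df["chromosome"],
            "position_bp": mm.df["position_bp"],
            "case_alt": ca,
            "case_ref": cr,
            "ctrl_alt": ta,
            "ctrl_ref": tr,
            "chi2": chi2,
            "p_raw": p_raw,
            "p_bonf": np.minimum(1.0, m * p_raw),
        }
    )


def maxT_permutation(
    gm: GenotypeMatrix,
    case_mask: np.ndarray,
    perm: PermConfig | None = None,
    exhaustive: bool = False,
    chunk: int = 2048,
) -> np.ndarray:
    """Genome-wide empirical p-values by max-T phenotype permutation.

    Case/control labels are shuffled with the case count fixed.  For each
    marker, p_emp = (r+1)/(R+1) where r counts permutations whose
    genome-wide maximum chi2 is >= the observed chi2 at that marker (ties
    count as exceedances).  With ``exhaustive=True`` every distinct case
    subset is enumerated once and the exact fraction r/R is returned.

    Allele counts are accumulated with integer matrix products, so permuted
    statistics are bit-identical to the observed ones computed from the same
    counts - exceedance ties are exact, not float-fuzzy.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    n = gm.n_samples
    k = int(case_mask.sum())
    if k == 0 or k == n:
        raise ValueError("permutation requires both cases and controls")

    calls = gm.calls
    nonmiss = (calls != MISSING).astype(np.int64)
    altmat = np.where(calls != MISSING, calls, 0).astype(np.int64)
    tot_alt = altmat.sum(axis=0)
    tot_nn = nonmiss.sum(axis=0)

    def chi2_for(ind: np.ndarray) -> np.ndarray:
        """Rows of ``ind`` are 0/1 case-indicator vectors."""
        ca = ind @ altmat
        cn = ind @ nonmiss
        cr = 2 * cn - ca
        ta = tot_alt - ca
        tr = 2 * (tot_nn - cn) - ta
        return _chi2_from_counts(ca, cr, ta, tr)

    obs = chi2_for(case_mask.astype(np.int64)[None, :])[0]

    maxima: list[np.ndarray] = []
    if exhaustive:
        combos = list(itertools.combinations(range(n), k))
        R = len(combos)
        for lo in range(0, R, chunk):
            sub = combos[lo : lo + chunk]
            ind = np.zeros((len(sub), n), dtype=np.int64)
            for i, combo in enumerate(sub):
                ind[i, list(combo)] = 1
            maxima.append(chi2_for(ind).max(axis=1))
    else:
        if perm is None:
            perm = PermConfig()
        rng = np.random.default_rng(perm.seed)
        R = perm.n_perm
        done = 0
        while done < R:
            b = min(chunk, R - done)
            order = rng.random((b, n)).argsort(axis=1)
            ind = (order < k).astype(np.int64)
            maxima.append(chi2_for(ind).max(axis=1))
            done += b
    all_max = np.sort(np.concatenate(maxima))
    r = R - np.searchsorted(all_max, obs, side="left")
    if exhaustive:
        return r / R
    return (r + 1) / (R + 1)
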