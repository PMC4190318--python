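"""Gene-drop simulator emulating a recessive-disease mapping study design.

The emulated design: a handful of affected, inbred foals whose sire and
dam lines both trace back (over 3-7 generations) to a single founder
carrying a recessive lethal on one haplotype; a dozen same-breed controls;
whole-genome variant tables for one sequenced case, one obligate-carrier
sire and a mixed-breed control panel; and allele-count observations for an
allele-specific expression check on a carrier.

Descent is simulated by gene dropping founder haplotypes through explicit
meioses.  Recombination follows the Haldane model at a fixed 1 cM/Mb:
crossover counts are Poisson(L x 1e-8) per chromosome per meiosis with
uniform breakpoint placement and no interference.  Haplotypes are stored
as ancestry segment lists (founder-haplotype id per interval), so identity
by descent is known exactly and every study sample's genotypes derive
mechanically from founder alleles - Mendelian consistency is structural,
not sampled.

Marker allele frequencies are drawn uniformly (0.05-0.5 by default,
matching a post-QC informative array); a single pseudo-autosomal genome is
simulated since the mapped locus is autosomal.  One integer seed drives
every random draw.

What the simulator does *not* reproduce: linkage disequilibrium beyond
descent from the founder pool, genotyping error, the tangled loop
structure of a real studbook pedigree, or sequencing-error models.  It
guarantees exactly the analytic properties the downstream modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ase_quant import AseObservation
from .io_formats import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    SampleTable,
    VariantRecord,
)

CM_PER_MB = 1.0  # fixed recombination rate, Haldane model
_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Infeasible simulation configuration."""


@dataclass
class WgsClassCounts:
    """Planted whole-genome variant classes inside the autozygous segment.

    ``shared_hom_in_controls``: case hom-alt, carrier also hom-alt, hom-alt
    in at least one control (a common variant; dies at the carrier-het
    stage of the cascade).  ``het_only_in_controls``: case hom-alt, carrier
    het, hom-alt in at least one cross-breed control (dies at control
    exclusion).  ``breed_private_nested``: case hom-alt, carrier het, never
    homozygous in any control; exactly one of these - the planted causal -
    additionally has its alt allele absent from every non-target-breed
    sample, while the remaining decoys are het in one cross-breed control.
    ``outside_region`` variants fall outside the mapped interval and are
    removed by the region stage.
    """

    shared_hom_in_controls: int = 40
    het_only_in_controls: int = 15
    breed_private_nested: int = 8  # includes the planted causal
    outside_region: int = 12

    def __post_init__(self) -> None:
        if self.breed_private_nested < 1:
            raise ValueError("breed_private_nested must include the causal (>= 1)")
        for name in ("shared_hom_in_controls", "het_only_in_controls", "outside_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimConfig:
    """Study-design parameters; defaults emulate the 5-case/12-control array
    design with a 46-genome control panel (28 same-breed, 18 other-breed)."""

    n_cases: int = 5
    n_controls: int = 12
    n_markers: int = 5_000
    n_chromosomes: int = 31
    chromosome_length_bp: int = 50_000_000
    founder_pool_size: int = 30
    generations_min: int = 3
    generations_max: int = 7
    causal_chromosome: str = "chr20"
    causal_position_bp: int = 25_000_000
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    maf_min: float = 0.05
    maf_max: float = 0.5
    missing_rate: float = 0.01
    carrier_control_fraction: float = 0.25
    wgs_variant_counts: WgsClassCounts = field(default_factory=WgsClassCounts)
    n_wgs_target_controls: int = 28
    n_wgs_other_controls: int = 18
    target_breed: str = "FranchesMontagnes"
    other_breeds: tuple[str, ...] = (
        "Thoroughbred",
        "Warmblood",
        "Arabian",
        "Icelandic",
        "NewForestPony",
        "Shetland",
    )
    adversarial_causal_hom_in_control: bool = False
    ase_depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "penetrance",
            "phenocopy_rate",
            "maf_min",
            "maf_max",
            "missing_rate",
            "carrier_control_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not self.penetrance > 0:
            raise ValueError("penetrance must be in (0,1]")
        if not 0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")
        if not 1 <= self.generations_min <= self.generations_max:
            raise ValueError("generation range must satisfy 1 <= min <= max")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.founder_pool_size < 3:
            raise ValueError("founder pool too small")
        chroms = [f"chr{i + 1}" for i in range(self.n_chromosomes)]
        if self.causal_chromosome not in chroms:
            raise ValueError(
                f"causal chromosome {self.causal_chromosome} not among {len(chroms)} simulated"
            )
        if not 1 <= self.causal_position_bp <= self.chromosome_length_bp:
            raise ValueError("causal position outside the simulated chromosome")
        if self.ase_depth < 1:
            raise ValueError("ase_depth must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        """Load a flat key-value (TOML) configuration file; keys mirror the
        field names (``wgs_variant_counts`` as a sub-table)."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "wgs_variant_counts" in data:
            data["wgs_variant_counts"] = WgsClassCounts(**data["wgs_variant_counts"])
        if "other_breeds" in data:
            data["other_breeds"] = tuple(data["other_breeds"])
        return cls(**data)


@dataclass
class GroundTruth:
    causal_chromosome: str
    causal_position_bp: int
    causal_variant_id: str | None
    case_ibd_segments: dict[str, tuple[int, int]]
    causal_genotypes: dict[str, int]
    # maximal identical-homozygous marker run around the causal position,
    # computed from the clean (pre-missingness) case genotypes
    shared_run_first_marker: int | None
    shared_run_last_marker: int | None


@dataclass
class SimulatedStudy:
    config: SimConfig
    pedigree: pd.DataFrame  # individual, sire, dam, generation
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    samples: SampleTable
    ground_truth: GroundTruth
    wgs_case_id: str | None = None
    wgs_carrier_id: str | None = None
    wgs_control_ids: list[str] = field(default_factory=list)
    wgs_variants: list[VariantRecord] = field(default_factory=list)
    ase_observations: list[AseObservation] = field(default_factory=list)
    # internals for invariant checking (ancestry-tracked haplotypes)
    haplotypes: dict[str, tuple[dict, dict]] = field(default_factory=dict, repr=False)
    founder_alleles: np.ndarray | None = field(default=None, repr=False)
    clean_calls: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------


def _single_hap(chroms: Sequence[str], hap_id: int) -> dict:
    return {c: (np.array([1], dtype=np.int64), np.array([hap_id], dtype=np.int64)) for c in chroms}


def _splice(
    segA: tuple[np.ndarray, np.ndarray],
    segB: tuple[np.ndarray, np.ndarray],
    breakpoints: np.ndarray,
    first: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate between two segment lists at the given breakpoints."""
    sources = (segA, segB)
    bounds = np.concatenate([[1], breakpoints])
    starts: list[int] = []
    ids: list[int] = []
    cur = first
    for i, b in enumerate(bounds):
        src_starts, src_ids = sources[cur]
        hi = bounds[i + 1] if i + 1 < len(bounds) else None
        j = np.searchsorted(src_starts, b, side="right") - 1
        while j < len(src_starts):
            s = max(int(src_starts[j]), int(b))
            if hi is not None and s >= hi:
                break
            if not starts or ids[-1] != int(src_ids[j]):
                starts.append(s)
                ids.append(int(src_ids[j]))
            j += 1
        cur = 1 - cur
    return np.array(starts, dtype=np.int64), np.array(ids, dtype=np.int64)


def _gamete(hap1: dict, hap2: dict, rng: np.random.Generator, chrom_len: int) -> dict:
    """One meiosis: recombine the two parental haplotypes per chromosome."""
    out = {}
    for chrom in hap1:
        n_xo = rng.poisson(chrom_len * CM_PER_MB * 1e-8)
        first = int(rng.integers(2))
        if n_xo == 0:
            src = (hap1, hap2)[first][chrom]
            out[chrom] = (src[0].copy(), src[1].copy())
        else:
            xo = np.sort(rng.integers(2, chrom_len, size=n_xo))
            out[chrom] = _splice(hap1[chrom], hap2[chrom], xo, first)
    return out


def _ancestry_at(hap: dict, chrom: str, pos: int) -> int:
    starts, ids = hap[chrom]
    return int(ids[np.searchsorted(starts, pos, side="right") - 1])


def _ibd_interval(hap: dict, chrom: str, pos: int, chrom_len: int) -> tuple[int, int]:
    """Extent of the ancestry segment covering ``pos``."""
    starts, _ = hap[chrom]
    j = np.searchsorted(starts, pos, side="right") - 1
    start = int(starts[j])
    end = int(starts[j + 1] - 1) if j + 1 < len(starts) else chrom_len
    return start, end


# ---------------------------------------------------------------------------
# genome and pedigree construction
# ---------------------------------------------------------------------------


def _build_map(cfg: SimConfig, rng: np.random.Generator) -> tuple[MarkerMap, np.ndarray]:
    chroms = cfg.chromosomes
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes, dtype=int)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    rows = []
    mafs = []
    k = 0
    for ci, chrom in enumerate(chroms):
        n = int(per[ci])
        if n == 0:
            continue
        grid = (np.arange(n) + 0.5) * cfg.chromosome_length_bp / n
        jitter = rng.uniform(-0.3, 0.3, n) * cfg.chromosome_length_bp / n
        pos = np.clip(np.round(grid + jitter), 1, cfg.chromosome_length_bp).astype(np.int64)
        last = 0
        for i in range(n):
            p = max(int(pos[i]), last + 1)
            pos[i] = p
            last = p
        maf = rng.uniform(cfg.maf_min, cfg.maf_max, n)
        for i in range(n):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                (f"M{k:06d}", chrom, int(pos[i]), str(_BASES[ref]), str(_BASES[alt]))
            )
            k += 1
        mafs.append(maf)
    mm = MarkerMap(
        pd.DataFrame(
            rows,
            columns=["marker_id", "chromosome", "position_bp", "ref_allele", "alt_allele"],
        )
    )
    return mm, np.concatenate(mafs)


def _genotypes_of(
    hap_pair: tuple[dict, dict], mm: MarkerMap, founder_alleles: np.ndarray
) -> np.ndarray:
    """Alt-allele dose per marker (0/1/2) for one individual."""
    m = mm.n_markers
    out = np.zeros(m, dtype=np.int8)
    positions = mm.positions()
    for chrom in mm.chromosomes:
        idx = mm.chrom_indices(chrom)
        pos = positions[idx]
        for hap in hap_pair:
            starts, ids = hap[chrom]
            seg = np.searchsorted(starts, pos, side="right") - 1
            out[idx] += founder_alleles[ids[seg], idx]
    return out


def simulate_pedigree_genotypes(config: SimConfig) -> SimulatedStudy:
    """Gene-drop the study cohort and genotype it on the simulated array.

    Every case is the offspring of a sire line and a dam line that both
    descend from the carrier founder and both transmit the causal founder
    haplotype; controls never carry two copies of it.  Phenotypes are
    assigned from the causal genotype with the configured penetrance and
    phenocopy rate.  Deterministic given ``config.seed``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_founder, rng_drop, rng_geno = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    mm, mafs = _build_map(cfg, rng_map)
    n_haps = 2 * cfg.founder_pool_size
    founder_alleles = (
        rng_founder.random((n_haps, cfg.n_markers)) < mafs[None, :]
    ).astype(np.int8)

    chroms = cfg.chromosomes
    L = cfg.chromosome_length_bp
    causal_chrom, causal_pos = cfg.causal_chromosome, cfg.causal_position_bp

    founder_h = (_single_hap(chroms, 0), _single_hap(chroms, 1))  # hap 0 carries causal
    ped_rows: list[tuple[str, str, str, int]] = [("FOUNDER", "0", "0", 0)]
    haplotypes: dict[str, tuple[dict, dict]] = {"FOUNDER": founder_h}
    counter = {"n": 0}

    def new_id(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix}{counter['n']:04d}"

    def pool_individual() -> tuple[str, tuple[dict, dict]]:
        ids = rng_drop.choice(np.arange(2, n_haps), size=2, replace=False)
        name = new_id("POP")
        haps = (_single_hap(chroms, int(ids[0])), _single_hap(chroms, int(ids[1])))
        haplotypes[name] = haps
        ped_rows.append((name, "0", "0", 0))
        return name, haps

    def carrier_gamete(haps: tuple[dict, dict]) -> dict:
        for _ in range(200):
            g = _gamete(haps[0], haps[1], rng_drop, L)
            if _ancestry_at(g, causal_chrom, causal_pos) == 0:
                return g
        raise SimulationError(
            "could not transmit the causal haplotype within the retry budget"
        )

    def descend(generations: int) -> tuple[str, tuple[dict, dict]]:
        cur_id, cur_haps = "FOUNDER", founder_h
        for gen in range(1, generations + 1):
            mate_id, mate_haps = pool_individual()
            child_id = new_id("ANC") if gen < generations else new_id("PAR")
            child_haps = (
                carrier_gamete(cur_haps),
                _gamete(mate_haps[0], mate_haps[1], rng_drop, L),
            )
            haplotypes[child_id] = child_haps
            ped_rows.append((child_id, cur_id, mate_id, gen))
            cur_id, cur_haps = child_id, child_haps
        return cur_id, cur_haps

    case_ids = []
    case_parents: dict[str, tuple[str, str]] = {}
    for i in range(cfg.n_cases):
        g_s = int(rng_drop.integers(cfg.generations_min, cfg.generations_max + 1))
        g_d = int(rng_drop.integers(cfg.generations_min, cfg.generations_max + 1))
        sire_id, sire_haps = descend(g_s)
        dam_id, dam_haps = descend(g_d)
        cid = f"CASE{i + 1:02d}"
        haps = (carrier_gamete(sire_haps), carrier_gamete(dam_haps))
        haplotypes[cid] = haps
        ped_rows.append((cid, sire_id, dam_id, max(g_s, g_d) + 1))
        case_ids.append(cid)
        case_parents[cid] = (sire_id, dam_id)

    control_ids = []
    for j in range(cfg.n_controls):
        cid = f"CTRL{j + 1:02d}"
        if rng_drop.random() < cfg.carrier_control_fraction:
            sire_id, sire_haps = "FOUNDER", founder_h
            h1 = carrier_gamete(sire_haps)
        else:
            sire_id, sire_haps = pool_individual()
            h1 = _gamete(sire_haps[0], sire_haps[1], rng_drop, L)
        dam_id, dam_haps = pool_individual()
        h2 = _gamete(dam_haps[0], dam_haps[1], rng_drop, L)
        haplotypes[cid] = (h1, h2)
        ped_rows.append((cid, sire_id, dam_id, 1))
        control_ids.append(cid)

    study_ids = case_ids + control_ids
    clean = np.stack(
        [_genotypes_of(haplotypes[s], mm, founder_alleles) for s in study_ids]
    )
    calls = clean.copy()
    if cfg.missing_rate > 0:
        mask = rng_geno.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    gm = GenotypeMatrix(study_ids, calls)

    causal_genotypes = {}
    for s in study_ids:
        h1, h2 = haplotypes[s]
        causal_genotypes[s] = int(_ancestry_at(h1, causal_chrom, causal_pos) == 0) + int(
            _ancestry_at(h2, causal_chrom, causal_pos) == 0
        )

    phenos = {}
    for s in study_ids:
        if causal_genotypes[s] == 2:
            affected = rng_geno.random() < cfg.penetrance
        else:
            affected = rng_geno.random() < cfg.phenocopy_rate
        phenos[s] = "affected" if affected else "unaffected"

    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": study_ids,
                "phenotype": [phenos[s] for s in study_ids],
                "breed": [cfg.target_breed] * len(study_ids),
                "role": ["case"] * len(case_ids) + ["control"] * len(control_ids),
            }
        )
    )

    ibd = {}
    for s in case_ids:
        h1, h2 = haplotypes[s]
        s1, e1 = _ibd_interval(h1, causal_chrom, causal_pos, L)
        s2, e2 = _ibd_interval(h2, causal_chrom, causal_pos, L)
        ibd[s] = (max(s1, s2), min(e1, e2))

    first, last = _shared_identical_run(clean[: len(case_ids)], mm, causal_chrom, causal_pos)

    truth = GroundTruth(
        causal_chromosome=causal_chrom,
        causal_position_bp=causal_pos,
        causal_variant_id=None,
        case_ibd_segments=ibd,
        causal_genotypes=causal_genotypes,
        shared_run_first_marker=first,
        shared_run_last_marker=last,
    )
    study = SimulatedStudy(
        config=cfg,
        pedigree=pd.DataFrame(
            ped_rows, columns=["individual", "sire", "dam", "generation"]
        ),
        genotypes=gm,
        marker_map=mm,
        samples=st,
        ground_truth=truth,
        haplotypes=haplotypes,
        founder_alleles=founder_alleles,
        clean_calls=clean,
    )
    study.wgs_case_id = case_ids[0]
    study.wgs_carrier_id = case_parents[case_ids[0]][0]
    return study


def _shared_identical_run(
    case_clean: np.ndarray, mm: MarkerMap, chrom: str, pos: int
) -> tuple[int | None, int | None]:
    """Maximal run of markers around ``pos`` where all cases are homozygous
    for the same allele (global marker indices); (None, None) if the markers
    adjacent to the causal position are not identical-homozygous."""
    idx = mm.chrom_indices(chrom)
    sub = case_clean[:, idx]
    k = case_clean.shape[0]
    identical = ((sub == 0).sum(axis=0) == k) | ((sub == 2).sum(axis=0) == k)
    positions = mm.positions()[idx]
    j = int(np.searchsorted(positions, pos))
    candidates = [jj for jj in (j - 1, j) if 0 <= jj < len(idx) and identical[jj]]
    if not candidates:
        return None, None
    a = b = candidates[0]
    while a - 1 >= 0 and identical[a - 1]:
        a -= 1
    while b + 1 < len(idx) and identical[b + 1]:
        b += 1
    return int(idx[a]), int(idx[b])


# ---------------------------------------------------------------------------
# whole-genome variant table
# ---------------------------------------------------------------------------


def simulate_wgs_variants(config: SimConfig, study: SimulatedStudy) -> list[VariantRecord]:
    """Plant the whole-genome variant classes of the filter cascade.

    Positions fall inside the sequenced case's autozygous segment (the
    mapped region), except for the ``outside_region`` class.  Exactly one
    variant - the planted causal at the configured causal position - is
    absent from every non-target-breed sample and never homozygous in a
    control.  See :class:`WgsClassCounts` for the class definitions.
    The generated records are stored on ``study`` and returned.
    """
    cfg = config
    counts = cfg.wgs_variant_counts
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])

    case_id = study.wgs_case_id
    carrier_id = study.wgs_carrier_id
    if case_id is None or carrier_id is None:
        raise SimulationError("study has no sequenced case/carrier")
    fm_controls = [f"WGS_FM{i + 1:02d}" for i in range(cfg.n_wgs_target_controls)]
    ob_controls = [f"WGS_OB{i + 1:02d}" for i in range(cfg.n_wgs_other_controls)]
    ob_breeds = {
        s: cfg.other_breeds[i % len(cfg.other_breeds)] for i, s in enumerate(ob_controls)
    }
    study.wgs_control_ids = fm_controls + ob_controls

    chrom = study.ground_truth.causal_chromosome
    causal_pos = study.ground_truth.causal_position_bp
    seg_start, seg_end = study.ground_truth.case_ibd_segments[case_id]
    n_inside = counts.shared_hom_in_controls + counts.het_only_in_controls + (
        counts.breed_private_nested - 1
    )
    avail = (seg_end - seg_start + 1) - 1  # minus the causal position itself
    if n_inside > avail:
        raise SimulationError(
            f"{n_inside} planted variants do not fit in the {avail + 1} bp segment"
        )

    inside = set()
    while len(inside) < n_inside:
        draw = rng.integers(seg_start, seg_end + 1, size=n_inside - len(inside))
        inside.update(int(p) for p in draw if int(p) != causal_pos)
    inside_pos = np.array(sorted(inside), dtype=np.int64)
    rng.shuffle(inside_pos)
    inside_pos = [int(p) for p in inside_pos]

    outside = set()
    L = cfg.chromosome_length_bp
    while len(outside) < counts.outside_region:
        p = int(rng.integers(1, L + 1))
        if not seg_start <= p <= seg_end:
            outside.add(p)

    def alleles() -> tuple[str, str]:
        r, a = rng.choice(4, size=2, replace=False)
        return str(_BASES[r]), str(_BASES[a])

    def base_genotypes() -> dict[str, int]:
        g = {s: 0 for s in [case_id, carrier_id] + fm_controls + ob_controls}
        return g

    records: list[VariantRecord] = []
    it = iter(inside_pos)

    for _ in range(counts.shared_hom_in_controls):
        g = base_genotypes()
        g[case_id] = 2
        g[carrier_id] = 2
        for s in rng.choice(fm_controls + ob_controls, size=3, replace=False):
            g[str(s)] = 2
        for s in rng.choice(fm_controls + ob_controls, size=4, replace=False):
            if g[str(s)] == 0:
                g[str(s)] = 1
        ref, alt = alleles()
        records.append(VariantRecord(chrom, next(it), ref, alt, g))

    for _ in range(counts.het_only_in_controls):
        g = base_genotypes()
        g[case_id] = 2
        g[carrier_id] = 1
        g[str(rng.choice(ob_controls))] = 2
        for s in rng.choice(fm_controls, size=2, replace=False):
            g[str(s)] = 1
        ref, alt = alleles()
        records.append(VariantRecord(chrom, next(it), ref, alt, g))

    for _ in range(counts.breed_private_nested - 1):
        g = base_genotypes()
        g[case_id] = 2
        g[carrier_id] = 1
        g[str(rng.choice(ob_controls))] = 1  # alt seen cross-breed, never hom
        ref, alt = alleles()
        records.append(VariantRecord(chrom, next(it), ref, alt, g))

    # the planted causal: breed-private, never homozygous in a control
    g = base_genotypes()
    g[case_id] = 2
    g[carrier_id] = 1
    for s in rng.choice(fm_controls, size=2, replace=False):
        g[str(s)] = 1
    if cfg.adversarial_causal_hom_in_control:
        g[str(rng.choice(fm_controls))] = 2
    ref, alt = alleles()
    causal = VariantRecord(chrom, causal_pos, ref, alt, g)
    records.append(causal)

    for p in sorted(outside):
        g = base_genotypes()
        g[case_id] = 2
        g[carrier_id] = int(rng.integers(0, 3))
        ref, alt = alleles()
        records.append(VariantRecord(chrom, p, ref, alt, g))

    records.sort(key=lambda r: (r.chromosome, r.position_bp, r.alt_allele))
    study.wgs_variants = records
    study.ground_truth.causal_variant_id = causal.variant_id

    # extend the sample table so every WGS sample is resolvable
    extra_ids = [carrier_id] + fm_controls + ob_controls
    extra = pd.DataFrame(
        {
            "sample_id": extra_ids,
            "phenotype": ["unaffected"] * len(extra_ids),
            "breed": [cfg.target_breed] * (1 + len(fm_controls))
            + [ob_breeds[s] for s in ob_controls],
            "role": ["obligate_carrier"] + ["population"] * (len(extra_ids) - 1),
        }
    )
    known = set(study.samples.df["sample_id"])
    extra = extra[~extra["sample_id"].isin(known)]
    study.samples = SampleTable(
        pd.concat([study.samples.df, extra], ignore_index=True)
    )
    return records


def wgs_breed_labels(config: SimConfig, study: SimulatedStudy) -> dict[str, str]:
    """Breed label for every WGS-panel sample (from the sample table)."""
    return dict(zip(study.samples.df["sample_id"], study.samples.df["breed"]))


# ---------------------------------------------------------------------------
# allele-specific expression counts
# ---------------------------------------------------------------------------


def simulate_ase_counts(
    n_sites: int, depth: int, skew: float, seed: int
) -> list[AseObservation]:
    """Binomial allele-count draws: gDNA at ratio 0.5, cDNA at ``skew``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < skew < 1.0:
        raise ValueError("skew must be in (0,1)")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    g_alt = rng.binomial(depth, 0.5, size=n_sites)
    c_alt = rng.binomial(depth, skew, size=n_sites)
    return [
        AseObservation(
            gdna_ref=int(depth - ga),
            gdna_alt=int(ga),
            cdna_ref=int(depth - ca),
            cdna_alt=int(ca),
        )
        for ga, ca in zip(g_alt, c_alt)
    ]


# ---------------------------------------------------------------------------
# convenience: full study bundle and a null cohort
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Pedigree + array genotypes + WGS variant table + ASE counts."""
    study = simulate_pedigree_genotypes(config)
    simulate_wgs_variants(config, study)
    ase_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    study.ase_observations = simulate_ase_counts(
        n_sites=3, depth=config.ase_depth, skew=0.5, seed=ase_seed
    )
    return study


def simulate_null_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, MarkerMap, SampleTable]:
    """Unrelated outbred cohort with arbitrary phenotype labels (no causal
    variant): genotypes are Hardy-Weinberg draws at each marker's MAF."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_geno = (np.random.default_rng(c) for c in ss.spawn(2))
    mm, mafs = _build_map(cfg, rng_map)
    n = cfg.n_cases + cfg.n_controls
    calls = rng_geno.binomial(2, mafs[None, :], size=(n, cfg.n_markers)).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng_geno.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    ids = [f"S{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(ids, calls)
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "phenotype": ["affected"] * cfg.n_cases
                + ["unaffected"] * cfg.n_controls,
                "breed": [cfg.target_breed] * n,
                "role": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
            }
        )
    )
    return gm, mm, st
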