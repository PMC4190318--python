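"""Core data types and file formats shared by every stage of the pipeline.

Genotype calls are encoded as small integers everywhere downstream:
``0`` = homozygous reference, ``1`` = heterozygous, ``2`` = homozygous
alternate, ``-1`` = missing.  Allele symbols live in :class:`MarkerMap`
(array markers) or on each :class:`VariantRecord` (sequence variants).

Coordinates are 1-based inclusive throughout, the native convention of
PED/MAP and VCF.  The only half-open conversion in the package happens at
the BED export boundary in :mod:`chfmap.autozygosity`.

For SNP-array data read from PED/MAP the "alt" allele of each marker is
the minor allele computed over the full cohort at load time (ties broken
lexicographically, the later symbol becoming alt).  Association results
are orientation-invariant, so this choice only fixes the sign of allele
counts, never a p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

VALID_PED_ALLELES = frozenset("ACGT0")
PHENOTYPES = ("affected", "unaffected", "unknown")
ROLES = ("case", "obligate_carrier", "control", "population")


class FormatError(ValueError):
    """Malformed input file (parse errors name the offending line)."""


class StructureError(ValueError):
    """Structurally inconsistent inputs (e.g. sample/marker count mismatch)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered marker annotation: id, chromosome, 1-based bp position, alleles.

    Markers must be position-sorted within each chromosome and ids unique.
    ``ref_allele``/``alt_allele`` are single-character symbols; ``.`` marks
    an unobserved alternate allele at a monomorphic marker.
    """

    df: pd.DataFrame  # columns: marker_id, chromosome, position_bp, ref_allele, alt_allele

    REQUIRED = ("marker_id", "chromosome", "position_bp", "ref_allele", "alt_allele")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise StructureError(f"MarkerMap missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["marker_id"].duplicated().any():
            dup = self.df.loc[self.df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise StructureError(f"duplicate marker_id {dup!r}")
        for chrom, sub in self.df.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise StructureError(
                    f"marker positions not strictly increasing on {chrom}"
                )
            if np.any(pos < 1):
                raise StructureError(f"non-positive position on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.df["chromosome"]))

    def positions(self) -> np.ndarray:
        return self.df["position_bp"].to_numpy()

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Global marker indices belonging to one chromosome."""
        return np.flatnonzero((self.df["chromosome"] == chrom).to_numpy())

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix in {0, 1, 2, -1}."""

    sample_ids: list[str]
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.sample_ids):
            raise StructureError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise StructureError("genotype codes must be in {0,1,2,-1}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StructureError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls (denominator: all samples)."""
        return (self.calls != MISSING).mean(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), self.calls[:, keep])


@dataclass
class SampleTable:
    """Sample metadata: phenotype, breed and study role for every sample."""

    df: pd.DataFrame  # columns: sample_id, phenotype, breed, role

    REQUIRED = ("sample_id", "phenotype", "breed", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise StructureError(f"SampleTable missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["sample_id"].duplicated().any():
            raise StructureError("duplicate sample_id in sample table")
        bad_ph = set(self.df["phenotype"]) - set(PHENOTYPES)
        if bad_ph:
            raise StructureError(f"unknown phenotype labels {sorted(bad_ph)}")
        bad_role = set(self.df["role"]) - set(ROLES)
        if bad_role:
            raise StructureError(f"unknown role labels {sorted(bad_role)}")

    def phenotype_of(self, sample_id: str) -> str:
        sub = self.df.loc[self.df["sample_id"] == sample_id, "phenotype"]
        if sub.empty:
            raise KeyError(sample_id)
        return sub.iloc[0]

    def breed_of(self, sample_id: str) -> str:
        sub = self.df.loc[self.df["sample_id"] == sample_id, "breed"]
        if sub.empty:
            raise KeyError(sample_id)
        return sub.iloc[0]

    def ids_with_role(self, role: str) -> list[str]:
        return list(self.df.loc[self.df["role"] == role, "sample_id"])

    def case_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over ``sample_ids``: phenotype == affected."""
        status = dict(zip(self.df["sample_id"], self.df["phenotype"]))
        unknown = [s for s in sample_ids if s not in status]
        if unknown:
            raise StructureError(f"samples absent from sample table: {unknown[:5]}")
        return np.array([status[s] == "affected" for s in sample_ids], dtype=bool)


@dataclass
class VariantRecord:
    """One biallelic SNV with per-sample genotype codes."""

    chromosome: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise StructureError("only single-nucleotide alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise StructureError("ref and alt alleles must differ")
        if self.position_bp < 1:
            raise StructureError("positions are 1-based (>= 1)")

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position_bp}:{self.ref_allele}>{self.alt_allele}"

    def genotype(self, sample_id: str) -> int:
        return self.genotypes.get(sample_id, MISSING)

    def carriers(self) -> list[str]:
        """Samples carrying at least one alt allele."""
        return [s for s, g in self.genotypes.items() if g in (HET, HOM_ALT)]


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_PED_PHENO = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}


def read_ped_map(ped_path: str | Path, map_path: str | Path):
    """Read a plink text PED/MAP pair.

    Returns ``(GenotypeMatrix, MarkerMap, SampleTable)``.  Genotypes are
    re-oriented so that the alt allele is the cohort minor allele; ``0 0``
    allele pairs become missing.  Parse errors name the offending line.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{map_path} line {lineno}: expected 4 fields")
            chrom, marker_id, _cm, pos = parts[:4]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(
                    f"{map_path} line {lineno}: bad position {pos!r}"
                ) from exc
            map_rows.append((marker_id, chrom, pos_i))
    m = len(map_rows)

    sample_ids: list[str] = []
    phenos: list[str] = []
    a1_rows: list[np.ndarray] = []
    a2_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} markers, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            alleles = np.array(parts[6:], dtype="U1")
            bad = ~np.isin(alleles, list(VALID_PED_ALLELES))
            if bad.any():
                sym = alleles[bad][0]
                raise FormatError(
                    f"{ped_path} line {lineno}: invalid allele symbol {sym!r}"
                )
            a1, a2 = alleles[0::2], alleles[1::2]
            half = (a1 == "0") != (a2 == "0")
            if half.any():
                j = int(np.flatnonzero(half)[0])
                raise FormatError(
                    f"{ped_path} line {lineno}: half-missing genotype at marker {j + 1}"
                )
            sample_ids.append(iid)
            phenos.append(_PED_PHENO.get(pheno, "unknown"))
            a1_rows.append(a1)
            a2_rows.append(a2)

    if len(set(sample_ids)) != len(sample_ids):
        raise StructureError(f"{ped_path}: duplicate sample ids")

    a1m = np.array(a1_rows)  # (n, m)
    a2m = np.array(a2_rows)
    n = len(sample_ids)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    refs: list[str] = []
    alts: list[str] = []
    for j in range(m):
        col = np.concatenate([a1m[:, j], a2m[:, j]])
        col = col[col != "0"]
        syms, counts = np.unique(col, return_counts=True)
        if len(syms) == 0:
            refs.append(".")
            alts.append(".")
            continue
        if len(syms) == 1:
            ref, alt = str(syms[0]), "."
        elif len(syms) == 2:
            # major allele is ref; tie -> lexicographically later symbol is alt
            order = np.lexsort((syms, -counts))
            ref, alt = str(syms[order[0]]), str(syms[order[1]])
        else:
            raise StructureError(
                f"marker {map_rows[j][0]}: more than two alleles observed"
            )
        refs.append(ref)
        alts.append(alt)
        obs = a1m[:, j] != "0"
        calls[obs, j] = (a1m[obs, j] == alt).astype(np.int8) + (
            a2m[obs, j] == alt
        ).astype(np.int8)

    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [r[0] for r in map_rows],
                "chromosome": [r[1] for r in map_rows],
                "position_bp": [r[2] for r in map_rows],
                "ref_allele": refs,
                "alt_allele": alts,
            }
        )
    )
    gm = GenotypeMatrix(sample_ids, calls)
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "phenotype": phenos,
                "breed": [""] * n,
                "role": ["case" if p == "affected" else "control" for p in phenos],
            }
        )
    )
    return gm, mm, st


def write_ped_map(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    st: SampleTable | None,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write a plink text PED/MAP pair (inverse of :func:`read_ped_map`)."""
    if gm.n_markers != mm.n_markers:
        raise StructureError("genotype matrix and marker map disagree on marker count")
    with open(map_path, "w") as fh:
        for row in mm.df.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    pheno_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    refs = mm.df["ref_allele"].to_numpy()
    alts = mm.df["alt_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            ph = st.phenotype_of(sid) if st is not None else "unknown"
            fields = [sid, sid, "0", "0", "0", pheno_code[ph]]
            row = gm.calls[i]
            pair = np.empty((gm.n_markers, 2), dtype="U1")
            pair[:, :] = "0"
            pair[row == HOM_REF] = np.stack([refs, refs], axis=1)[row == HOM_REF]
            pair[row == HET] = np.stack([refs, alts], axis=1)[row == HET]
            pair[row == HOM_ALT] = np.stack([alts, alts], axis=1)[row == HOM_ALT]
            fields.extend(pair.ravel())
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, sample_filter: Iterable[str] | None = None
) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF 4.x file.

    Multi-allelic and non-SNV rows are skipped (a count is logged).  Phased
    and unphased genotypes are treated identically; any genotype with a
    missing allele becomes ``MISSING``.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: no GT field defined in FORMAT header")
    file_samples = list(vf.header.samples)
    if sample_filter is not None:
        wanted = list(sample_filter)
        unknown = [s for s in wanted if s not in file_samples]
        if unknown:
            raise StructureError(f"{path}: unknown samples in filter: {unknown}")
        samples = [s for s in file_samples if s in set(wanted)]
    else:
        samples = file_samples

    records: list[VariantRecord] = []
    skipped = 0
    for rec in vf:
        alts = rec.alts
        if alts is None or len(alts) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            skipped += 1
            continue
        genos: dict[str, int] = {}
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                genos[s] = MISSING
            else:
                genos[s] = int(gt[0] != 0) + int(gt[1] != 0)
        records.append(
            VariantRecord(
                chromosome=rec.chrom,
                position_bp=rec.pos,
                ref_allele=ref,
                alt_allele=alt,
                genotypes=genos,
            )
        )
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNV rows", path, skipped)
    vf.close()
    return records


def write_vcf(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> None:
    """Write records as a GT-only VCF 4.2 file.

    Records must already be sorted by (chromosome, position); unsorted input
    raises (no silent sorting).  Duplicate positions with distinct alleles
    are allowed.
    """
    seen: list[str] = []
    last_pos: dict[str, int] = {}
    for r in records:
        if r.chromosome in last_pos:
            if seen[-1] != r.chromosome:
                raise StructureError(
                    f"records not sorted: chromosome {r.chromosome} reappears"
                )
            if r.position_bp < last_pos[r.chromosome]:
                raise StructureError(
                    f"records not sorted at {r.chromosome}:{r.position_bp}"
                )
        else:
            seen.append(r.chromosome)
        last_pos[r.chromosome] = r.position_bp

    header = pysam.VariantHeader()
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", "GT"),
            ("Number", "1"),
            ("Type", "String"),
            ("Description", "Genotype"),
        ],
    )
    for chrom in seen:
        header.add_meta("contig", items=[("ID", chrom)])
    for s in samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}
    for r in records:
        rec = out.new_record(
            contig=r.chromosome,
            start=r.position_bp - 1,
            alleles=(r.ref_allele, r.alt_allele),
        )
        for s in samples:
            code = r.genotype(s)
            rec.samples[s]["GT"] = gt_map.get(code, (None, None))
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# sample metadata table
# ---------------------------------------------------------------------------


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.df.to_csv(path, sep="\t", index=False)
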