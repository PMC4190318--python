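"""Transcript-aware coordinate arithmetic and coding-effect classification.

HGVS-style conventions: c.1 is the A of the initiator ATG, protein residue
``r`` is encoded by cDNA positions ``3(r-1)+1 .. 3r``, and on a minus-strand
gene the cDNA numbering decreases as the genomic position increases.  All
alleles stored on :class:`~chfmap.io_formats.VariantRecord` are
genomic-strand; reverse complementation happens only at this annotation
boundary.

A transcript model is an input here (an exon table with strand and the CDS
start offset); exon discovery from RNA-seq is out of scope and the tests
use hand-built toy models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

EFFECTS = ("missense", "synonymous", "nonsense", "assembly_error_flag")


def complement(base: str) -> str:
    if base not in COMPLEMENT:
        raise ValueError(f"invalid base {base!r}")
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


# ---------------------------------------------------------------------------
# cDNA / protein arithmetic
# ---------------------------------------------------------------------------


def cdna_to_protein(cdna_pos: int) -> tuple[int, int]:
    """Residue index and codon offset for a coding-sequence position.

    residue = ceil(pos/3); offset in {1,2,3} with 3*(residue-1)+offset = pos.
    """
    if cdna_pos < 1:
        raise ValueError("cDNA positions are 1-based (c.1 = first base of ATG)")
    residue = -(-cdna_pos // 3)
    offset = cdna_pos - 3 * (residue - 1)
    return residue, offset


@dataclass
class CdnaCoord:
    """A cDNA coordinate: exonic (offset 0) or intronic (anchor +/- offset)."""

    pos: int  # coding coordinate of the position itself, or of the anchor exon base
    offset: int = 0  # 0 exonic; >0 downstream of anchor (c.N+k); <0 upstream (c.N-k)

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    def __str__(self) -> str:
        if self.offset == 0:
            return f"c.{self.pos}"
        sign = "+" if self.offset > 0 else "-"
        return f"c.{self.pos}{sign}{abs(self.offset)}"


@dataclass
class TranscriptModel:
    """Exon table with strand and CDS start offset.

    ``exons`` are (start_bp, end_bp) 1-based inclusive, non-overlapping and
    sorted by genomic position.  ``cds_offset`` is the number of spliced
    bases preceding c.1 in transcript orientation (0 when the transcript
    starts at the ATG).
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("at least one exon required")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if a > b or a < 1:
                raise ValueError(f"bad exon ({a},{b})")
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise ValueError("exons overlap")
        self.exons = exons
        if self.spliced_length < 3:
            raise ValueError("spliced transcript shorter than one codon")
        if not 0 <= self.cds_offset < self.spliced_length:
            raise ValueError("cds_offset outside the spliced transcript")

    @property
    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def _tx_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def _tx_pos(self, g: int) -> int | None:
        """1-based spliced-transcript coordinate of an exonic genomic position."""
        cum = 0
        for a, b in self._tx_exons():
            if a <= g <= b:
                within = (g - a + 1) if self.strand == "+" else (b - g + 1)
                return cum + within
            cum += b - a + 1
        return None


def _cdna_from_tx(tpos: int, cds_offset: int) -> int:
    """Spliced-transcript coordinate to cDNA coordinate (c.-k for 5' UTR)."""
    c = tpos - cds_offset
    return c if c > 0 else c - 1  # HGVS has no c.0


def genomic_to_cdna(position_bp: int, tm: TranscriptModel) -> CdnaCoord:
    """Map a genomic position inside the transcript span to cDNA coordinates.

    Exonic positions return an exact coding coordinate; intronic positions
    return nearest-exon offset notation (anchor exon-boundary coordinate
    plus a signed genomic distance, ties to the preceding exon).  Positions
    outside the transcript span raise.
    """
    lo, hi = tm.span
    if not lo <= position_bp <= hi:
        raise ValueError(f"position {position_bp} outside transcript span {lo}-{hi}")
    tpos = tm._tx_pos(position_bp)
    if tpos is not None:
        return CdnaCoord(_cdna_from_tx(tpos, tm.cds_offset), 0)

    # intronic: neighbouring exons in genomic order
    prev_exon = max((e for e in tm.exons if e[1] < position_bp), key=lambda e: e[1])
    next_exon = min((e for e in tm.exons if e[0] > position_bp), key=lambda e: e[0])
    dist_prev = position_bp - prev_exon[1]
    dist_next = next_exon[0] - position_bp
    if tm.strand == "+":
        donor_base, donor_dist = prev_exon[1], dist_prev
        acceptor_base, acceptor_dist = next_exon[0], dist_next
    else:
        donor_base, donor_dist = next_exon[0], dist_next
        acceptor_base, acceptor_dist = prev_exon[1], dist_prev
    if donor_dist <= acceptor_dist:  # tie goes to the transcript-upstream exon
        anchor = tm._tx_pos(donor_base)
        return CdnaCoord(_cdna_from_tx(anchor, tm.cds_offset), donor_dist)
    anchor = tm._tx_pos(acceptor_base)
    return CdnaCoord(_cdna_from_tx(anchor, tm.cds_offset), -acceptor_dist)


def cdna_to_genomic(cdna_pos: int, tm: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cdna` for exonic coding positions."""
    if cdna_pos < 1:
        raise ValueError("only coding positions (c.>=1) are invertible here")
    tpos = cdna_pos + tm.cds_offset
    if tpos > tm.spliced_length:
        raise ValueError("position beyond the spliced transcript")
    cum = 0
    for a, b in tm._tx_exons():
        ln = b - a + 1
        if tpos <= cum + ln:
            within = tpos - cum
            return a + within - 1 if tm.strand == "+" else b - within + 1
        cum += ln
    raise AssertionError("unreachable")


def infer_strand(pairs: list[tuple[int, int]]) -> str:
    """Infer transcript strand from (genomic_pos, cdna_pos) pairs.

    Strictly co-monotone pairs give '+', strictly anti-monotone '-';
    anything else is inconsistent and raises.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (genomic, cdna) pairs")
    s = sorted(pairs)
    cd = [c for _, c in s]
    if all(x < y for x, y in zip(cd, cd[1:])):
        return "+"
    if all(x > y for x, y in zip(cd, cd[1:])):
        return "-"
    raise ValueError("inconsistent (genomic, cdna) pairs: mixed monotonicity")


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------


def classify_effect(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """Classify a codon substitution; returns (effect, ref_aa, alt_aa)."""
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return effect, ref_aa, alt_aa


@dataclass
class ProteinChange:
    residue_index: int
    ref_aa: str
    alt_aa: str
    codon_offset: int
    effect: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue index is 1-based")
        if self.codon_offset not in (1, 2, 3):
            raise ValueError("codon offset must be 1, 2 or 3")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


def count_by_effect(records) -> dict[str, int]:
    """Tally effect classes; assembly-error flags are reported separately.

    Each record needs an ``effect`` attribute or key (one of
    ``missense/synonymous/nonsense``) or an ``assembly_error_flag``.
    """
    counts = {e: 0 for e in EFFECTS}
    for rec in records:
        eff = rec.get("effect") if isinstance(rec, dict) else getattr(rec, "effect")
        if eff not in counts:
            raise ValueError(f"unknown effect {eff!r}")
        counts[eff] += 1
    return counts


# ---------------------------------------------------------------------------
# published PKHD1 variant table (printed study data, bundled as input)
# ---------------------------------------------------------------------------

_CDNA_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_PROT_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


def parse_cdna_notation(text: str) -> tuple[int, str, str]:
    m = _CDNA_RE.match(text)
    if not m:
        raise ValueError(f"unparseable cDNA notation {text!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def parse_protein_notation(text: str) -> tuple[int, str, str]:
    m = _PROT_RE.match(text)
    if not m:
        raise ValueError(f"unparseable protein notation {text!r}")
    return int(m.group(2)), m.group(1), m.group(3)


def load_pkhd1_variant_table() -> pd.DataFrame:
    """Published non-synonymous variant table for the equine PKHD1 critical
    interval (14 PKHD1 missense rows plus 2 reference-assembly-error rows),
    bundled as package data."""
    path = resources.files("chfmap") / "data" / "pkhd1_coding_variants.tsv"
    return pd.read_csv(Path(str(path)), sep="\t")


def read_transcript_model(path: str | Path) -> tuple[str, TranscriptModel]:
    """Read a minimal exon-table TSV: columns gene_id, chromosome, strand,
    start_bp, end_bp and an optional cds_offset (taken from the first row).
    Returns ``(chromosome, TranscriptModel)``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "strand", "start_bp", "end_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].nunique() != 1 or df["chromosome"].nunique() != 1:
        raise ValueError(f"{path}: expected exactly one gene on one chromosome")
    cds_offset = int(df["cds_offset"].iloc[0]) if "cds_offset" in df.columns else 0
    tm = TranscriptModel(
        gene_id=str(df["gene_id"].iloc[0]),
        strand=str(df["strand"].iloc[0]),
        exons=[(int(r.start_bp), int(r.end_bp)) for r in df.itertuples()],
        cds_offset=cds_offset,
    )
    return str(df["chromosome"].iloc[0]), tm


def effect_from_protein_notation(text: str) -> str:
    residue, ref_aa, alt_aa = parse_protein_notation(text)
    del residue
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"
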