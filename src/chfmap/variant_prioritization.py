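"""Recessive segregation filter cascade and cohort concordance scoring.

The cascade mirrors the classic homozygosity-mapping follow-up on whole
genome sequence: restrict to the critical interval, keep variants
homozygous-alternate in the sequenced case, keep those heterozygous in the
obligate carrier, drop those homozygous-alternate in any control genome,
and finally keep only variants whose alternate allele is private to the
target breed.  Stage order is fixed so that the stage survivor counts form
a reproducible, monotone non-increasing cascade; individual stages can be
skipped for reuse.

Missing genotypes never remove a variant: a variant whose deciding sample
is missing survives the stage and is flagged for follow-up genotyping,
mirroring how ambiguous calls are resolved by targeted re-sequencing in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import HET, HOM_ALT, MISSING, VariantRecord

STAGE_ORDER = ("region", "case_hom_alt", "carrier_het", "control_exclusion", "breed_private")


@dataclass
class FilterStage:
    name: str
    input_count: int
    surviving_count: int
    surviving_ids: list[str]


@dataclass
class FilterReport:
    stages: list[FilterStage]
    final: list[VariantRecord]
    flagged: dict[str, list[str]] = field(default_factory=dict)

    def stage_counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.input_count, s.surviving_count) for s in self.stages]


@dataclass
class GenotypeCountTable:
    """Genotype-class counts for one variant in one cohort (missing excluded)."""

    variant_id: str
    cohort: str
    phenotype: str  # "affected" | "unaffected"
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype class counts must be non-negative")
        if self.phenotype not in ("affected", "unaffected"):
            raise ValueError(f"phenotype must be affected/unaffected, got {self.phenotype!r}")


@dataclass
class DiscordanceResult:
    variant_id: str
    cohort: str
    n_discordant: int
    rule: str


def segregation_filter(
    variants: Sequence[VariantRecord],
    case_id: str,
    carrier_id: str,
    control_ids: Sequence[str],
    region: tuple[str, int, int] | None = None,
    skip_stages: Iterable[str] = (),
) -> FilterReport:
    """Run the recessive filter cascade; see the module docstring.

    ``region`` is (chromosome, start_bp, end_bp), 1-based inclusive; ``None``
    skips the region restriction.  An empty region yields an empty (not
    erroneous) report.  The breed-private stage is separate
    (:func:`breed_private`) because it needs breed labels.
    """
    if case_id == carrier_id:
        raise ValueError("case and carrier must be distinct samples")
    skip = set(skip_stages)
    unknown = skip - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    stages: list[FilterStage] = []
    flagged: dict[str, list[str]] = {}
    current = list(variants)

    def run_stage(name: str, keep_fn, flag_fn=None) -> None:
        nonlocal current
        if name in skip:
            return
        survivors = []
        flags = []
        for v in current:
            if keep_fn(v):
                survivors.append(v)
                if flag_fn is not None and flag_fn(v):
                    flags.append(v.variant_id)
        stages.append(
            FilterStage(
                name=name,
                input_count=len(current),
                surviving_count=len(survivors),
                surviving_ids=[v.variant_id for v in survivors],
            )
        )
        if flags:
            flagged[name] = flags
        current = survivors

    if region is not None:
        chrom, start, end = region
        run_stage(
            "region",
            lambda v: v.chromosome == chrom and start <= v.position_bp <= end,
        )
    run_stage(
        "case_hom_alt",
        lambda v: v.genotype(case_id) in (HOM_ALT, MISSING),
        lambda v: v.genotype(case_id) == MISSING,
    )
    run_stage(
        "carrier_het",
        lambda v: v.genotype(carrier_id) in (HET, MISSING),
        lambda v: v.genotype(carrier_id) == MISSING,
    )
    run_stage(
        "control_exclusion",
        lambda v: not any(v.genotype(c) == HOM_ALT for c in control_ids),
    )
    return FilterReport(stages=stages, final=current, flagged=flagged)


def breed_private(
    variants: Sequence[VariantRecord],
    breeds: Mapping[str, str],
    target_breed: str,
) -> list[VariantRecord]:
    """Keep variants whose alt allele occurs only in target-breed samples.

    Both heterozygous and homozygous alt carriers count as "present".  A
    carrier without a breed label is an error.
    """
    kept = []
    for v in variants:
        private = True
        for s in v.carriers():
            if s not in breeds or not breeds[s]:
                raise KeyError(f"no breed label for alt-allele carrier {s!r}")
            if breeds[s] != target_breed:
                private = False
        if private:
            kept.append(v)
    return kept


def genotype_concordance(
    table: GenotypeCountTable, model: str = "recessive"
) -> DiscordanceResult:
    """Count animals discordant with a recessive model in one cohort.

    Affected animals are expected homozygous-alternate, so hets and
    homozygous-reference animals are discordant; unaffected animals are
    expected anything *but* homozygous-alternate.
    """
    if model != "recessive":
        raise ValueError("only the recessive model is implemented")
    if table.phenotype == "affected":
        n = table.n_het + table.n_hom_ref
        rule = "affected_not_hom_alt"
    else:
        n = table.n_hom_alt
        rule = "unaffected_hom_alt"
    return DiscordanceResult(
        variant_id=table.variant_id, cohort=table.cohort, n_discordant=n, rule=rule
    )


def count_table_from_records(
    variant: VariantRecord,
    sample_ids: Sequence[str],
    cohort: str,
    phenotype: str,
) -> GenotypeCountTable:
    """Tally genotype classes of one variant over a cohort (missing excluded)."""
    counts = {0: 0, 1: 0, 2: 0}
    for s in sample_ids:
        g = variant.genotype(s)
        if g != MISSING:
            counts[g] += 1
    return GenotypeCountTable(
        variant_id=variant.variant_id,
        cohort=cohort,
        phenotype=phenotype,
        n_hom_ref=counts[0],
        n_het=counts[1],
        n_hom_alt=counts[2],
    )
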