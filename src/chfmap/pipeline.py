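"""End-to-end study orchestration: simulate/load -> QC -> GWAS -> shared
autozygosity -> segregation cascade -> concordance -> allele balance.

``run_study`` is a pure function of (inputs, config, seed): running it
twice with the same configuration produces byte-identical reports.  Every
intermediate artifact is written in a standard format that the
corresponding module can read back (PED/MAP, VCF, BED, TSV), and one
structured log line per stage records input/output cardinalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autozygosity as az
from . import io_formats as io
from . import qc_gwas as qg
from . import variant_prioritization as vp
from .ase_quant import allele_balance_test
from .synthetic_data import SimConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    samples_path: str | None = None
    vcf_path: str | None = None
    qc: qg.QcThresholds = field(default_factory=qg.QcThresholds)
    roh: az.RohParams = field(default_factory=az.RohParams)
    n_perm: int = 10_000  # max-T permutations; 0 disables the permutation pass
    run_cascade: bool = True
    target_breed: str | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.ped_path is None or self.map_path is None):
            raise ValueError("either a SimConfig or PED/MAP paths are required")


@dataclass
class StudyReport:
    qc: dict
    gwas: dict
    interval: dict
    candidates: dict
    concordance: dict
    ase: dict

    def to_json(self) -> str:
        payload = {
            "qc": self.qc,
            "gwas": self.gwas,
            "interval": self.interval,
            "candidates": self.candidates,
            "concordance": self.concordance,
            "ase": self.ase,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)


def _stage(name: str, n_in, n_out) -> None:
    logger.info("stage=%s in=%s out=%s", name, n_in, n_out)


def run_study(cfg: PipelineConfig) -> StudyReport:
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ data
    study = None
    if cfg.sim is not None:
        sim_cfg = cfg.sim
        if sim_cfg.seed != cfg.seed:
            sim_cfg = SimConfig(**{**sim_cfg.__dict__, "seed": cfg.seed})
        study = simulate_study(sim_cfg)
        gm, mm, st = study.genotypes, study.marker_map, study.samples
        variants = study.wgs_variants
        if out_dir:
            io.write_ped_map(gm, mm, st, out_dir / "study.ped", out_dir / "study.map")
            io.write_sample_table(st, out_dir / "samples.tsv")
            wgs_samples = [study.wgs_case_id, study.wgs_carrier_id] + study.wgs_control_ids
            io.write_vcf(variants, wgs_samples, out_dir / "wgs.vcf")
    else:
        gm, mm, st = io.read_ped_map(cfg.ped_path, cfg.map_path)
        if cfg.samples_path:
            st = io.read_sample_table(cfg.samples_path)
        variants = io.read_vcf(cfg.vcf_path) if cfg.vcf_path else []
    _stage("load", f"{gm.n_samples}x{gm.n_markers}", "-")

    case_mask = st.case_mask(gm.sample_ids)
    case_ids = [s for s, c in zip(gm.sample_ids, case_mask) if c]
    if study is not None:
        # analysis case set = designed cases (role), robust to reduced penetrance
        case_ids = st.ids_with_role("case")
        case_mask = np.array([s in set(case_ids) for s in gm.sample_ids])

    # -------------------------------------------------------------------- QC
    gm_f, mm_f, qc_report = qg.qc_filter(gm, mm, cfg.qc)
    _stage("qc", gm.n_markers, qc_report.m)
    qc_section = {
        "n_input_markers": qc_report.n_input,
        "removed_call_rate": qc_report.removed_call_rate,
        "removed_maf": qc_report.removed_maf,
        "removed_hwe": qc_report.removed_hwe,
        "m_retained": qc_report.m,
    }

    # ------------------------------------------------------------------ GWAS
    gwas_section: dict = {}
    if qc_report.m > 0 and case_mask.any() and (~case_mask).any():
        assoc = qg.allelic_scan(gm_f, mm_f, case_mask)
        lam = qg.genomic_inflation(assoc["chi2"])
        if cfg.n_perm > 0:
            p_emp = qg.maxT_permutation(
                gm_f, case_mask, qg.PermConfig(n_perm=cfg.n_perm, seed=cfg.seed)
            )
            assoc["p_emp"] = p_emp
        top = assoc.loc[assoc["chi2"].idxmax()]
        gwas_section = {
            "lambda": round(float(lam), 6),
            "top_marker": str(top["marker_id"]),
            "top_chromosome": str(top["chromosome"]),
            "top_position_bp": int(top["position_bp"]),
            "top_chi2": round(float(top["chi2"]), 6),
            "top_p_raw": float(top["p_raw"]),
            "top_p_bonf": float(top["p_bonf"]),
        }
        if "p_emp" in assoc:
            gwas_section["top_p_emp"] = float(top["p_emp"])
        if out_dir:
            assoc.to_csv(out_dir / "association.tsv", sep="\t", index=False)
    _stage("gwas", qc_report.m, len(gwas_section))

    # ------------------------------------------------- shared autozygosity
    interval_section: dict = {}
    ci = None
    if len(case_ids) >= 2 and qc_report.m > 0:
        ci = az.shared_autozygous_segment(gm_f, mm_f, case_ids, cfg.roh)
        if ci is not None:
            bp, kb = az.interval_length(ci)
            interval_section = {
                "chromosome": ci.chromosome,
                "left_bound_bp": ci.left_bound_bp,
                "right_bound_bp": ci.right_bound_bp,
                "n_shared_snps": ci.n_shared_snps,
                "length_bp": bp,
                "length_kb": kb,
            }
            if out_dir:
                segs = []
                for sid in case_ids:
                    segs.extend(az.detect_roh(gm_f.row(sid), mm_f, cfg.roh, sid))
                az.write_bed(segs, out_dir / "roh.bed")
    _stage("interval", len(case_ids), interval_section.get("n_shared_snps", 0))

    # ------------------------------------------------------------- cascade
    candidates_section: dict = {}
    final = []
    if cfg.run_cascade and variants and study is not None:
        region = None
        if ci is not None:
            region = (ci.chromosome, ci.left_bound_bp, ci.right_bound_bp)
        elif study is not None:
            gt = study.ground_truth
            seg = gt.case_ibd_segments[study.wgs_case_id]
            region = (gt.causal_chromosome, seg[0], seg[1])
        report = vp.segregation_filter(
            variants,
            case_id=study.wgs_case_id,
            carrier_id=study.wgs_carrier_id,
            control_ids=study.wgs_control_ids,
            region=region,
        )
        breeds = dict(zip(st.df["sample_id"], st.df["breed"]))
        target = cfg.target_breed or study.config.target_breed
        final = vp.breed_private(report.final, breeds, target)
        candidates_section = {
            "stages": [
                {"name": n, "input": i, "surviving": s}
                for n, i, s in report.stage_counts()
            ]
            + [
                {
                    "name": "breed_private",
                    "input": len(report.final),
                    "surviving": len(final),
                }
            ],
            "final_variants": [v.variant_id for v in final],
        }
        if out_dir and final:
            samples = [study.wgs_case_id, study.wgs_carrier_id] + study.wgs_control_ids
            io.write_vcf(final, samples, out_dir / "candidates.vcf")
    _stage("cascade", len(variants), len(final))

    # --------------------------------------------------------- concordance
    concordance_section: dict = {}
    if study is not None:
        truth = study.ground_truth
        affected = [s for s in gm.sample_ids if st.phenotype_of(s) == "affected"]
        unaffected = [s for s in gm.sample_ids if st.phenotype_of(s) == "unaffected"]

        def tally(ids):
            c = {0: 0, 1: 0, 2: 0}
            for s in ids:
                c[truth.causal_genotypes[s]] += 1
            return c

        ca, cu = tally(affected), tally(unaffected)
        d_aff = vp.genotype_concordance(
            vp.GenotypeCountTable(
                variant_id=truth.causal_variant_id or "causal",
                cohort="affected",
                phenotype="affected",
                n_hom_ref=ca[0],
                n_het=ca[1],
                n_hom_alt=ca[2],
            )
        )
        d_un = vp.genotype_concordance(
            vp.GenotypeCountTable(
                variant_id=truth.causal_variant_id or "causal",
                cohort="unaffected",
                phenotype="unaffected",
                n_hom_ref=cu[0],
                n_het=cu[1],
                n_hom_alt=cu[2],
            )
        )
        concordance_section = {
            "variant": truth.causal_variant_id,
            "affected_discordant": d_aff.n_discordant,
            "unaffected_discordant": d_un.n_discordant,
            "perfect_association": d_aff.n_discordant == 0 and d_un.n_discordant == 0,
        }
    _stage("concordance", gm.n_samples, len(concordance_section))

    # ------------------------------------------------------------------ ASE
    ase_section: dict = {}
    if study is not None and study.ase_observations:
        results = [allele_balance_test(o) for o in study.ase_observations]
        ase_section = {
            "n_sites": len(results),
            "verdicts": [r.verdict for r in results],
            "p_values": [round(r.p, 6) for r in results],
        }
    _stage("ase", len(ase_section.get("verdicts", [])), "-")

    report_obj = StudyReport(
        qc=qc_section,
        gwas=gwas_section,
        interval=interval_section,
        candidates=candidates_section,
        concordance=concordance_section,
        ase=ase_section,
    )
    if out_dir:
        (out_dir / "report.json").write_text(report_obj.to_json() + "\n")
    return report_obj
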