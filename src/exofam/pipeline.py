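"""End-to-end orchestration: inputs -> filter -> aggregate -> enrich -> segregate.

A run either simulates a synthetic cohort or consumes real inputs (VCF +
PED + GMT).  Every stage is a pure function of its inputs and the seed, so
a rerun with the same configuration produces identical outputs; the run
manifest records the seed, a configuration hash, and per-stage row counts
for auditability.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .aggregate import (
    GeneSharingTable,
    build_sharing_table,
    sharing_census,
    summarize,
    write_retained_tsv,
)
from .cascade import FilterConfig, run_cascade
from .cohort import (
    AnnotatedVariant,
    Family,
    Genotype,
    VariantKey,
    VcfDialect,
    DEFAULT_DIALECT,
    read_pedigree,
    read_term_sets,
    read_variants,
)
from .enrichment import EnrichmentInput, enrich
from .segregation import classify_segregation
from .simulate import SimulatedCohort, SimulationParams, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode applies: ``simulate=True`` generates a synthetic
    cohort from ``sim_params`` and ``seed``; otherwise ``vcf``, ``ped`` and
    ``gmt`` must point at real inputs.
    """

    out_dir: str | Path = "exofam_run"
    seed: int = 0
    simulate: bool = True
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    vcf: str | None = None
    ped: str | None = None
    gmt: str | None = None
    followup_vcf: str | None = None
    dialect: VcfDialect = DEFAULT_DIALECT
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    ease: bool = True
    min_count: int = 2
    adjust: str = "BH"
    #: classify co-segregation for variants in genes shared by >= this many
    #: families (0 disables the stage).
    segregate_min_families: int = 2

    def validate(self) -> None:
        if self.simulate:
            return
        for name in ("vcf", "ped", "gmt"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"input mode requires --{name}")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name} input not found: {value}")

    def digest(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, (frozenset, set)):
                return sorted(str(x) for x in obj)
            return str(obj)

        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # analytic config only, not output location
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _segregation_stage(
    families: list[Family],
    per_family_retained: Mapping[str, list[AnnotatedVariant]],
    table: GeneSharingTable,
    followup_by_key: Mapping[VariantKey, Mapping[str, Genotype]],
    min_families: int,
    discovery: Mapping[str, frozenset[str]],
) -> list[dict]:
    """Classify co-segregation for retained variants in multi-family genes."""
    by_id = {f.family_id: f for f in families}
    rows = []
    for fid, variants in per_family_retained.items():
        family = by_id[fid]
        for v in variants:
            if table.n_families(v.gene) < min_families:
                continue
            genos = followup_by_key.get(v.key)
            if genos is None:
                continue
            result = classify_segregation(
                v.key,
                family,
                genos,
                gene=v.gene,
                discovery_samples=discovery.get(fid, frozenset()),
            )
            rows.append(
                {
                    "family_id": fid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "n_affected_genotyped": result.n_affected_genotyped,
                    "n_affected_carriers": result.n_affected_carriers,
                    "n_unaffected_genotyped": result.n_unaffected_genotyped,
                    "n_unaffected_carriers": result.n_unaffected_carriers,
                    "call": result.call,
                    "low_information": int(result.low_information),
                }
            )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort: SimulatedCohort | None = None
    if config.simulate:
        log.info("simulating cohort (seed=%d)", config.seed)
        cohort = simulate_cohort(config.sim_params, config.seed)
        cohort.write(out / "sim", dialect=config.dialect)
        families = cohort.families
        per_family_variants = cohort.variants_by_family
        term_sets = cohort.term_sets
        followup_by_key: dict[VariantKey, Mapping[str, Genotype]] = {}
        for fid, by_key in cohort.followup_genotypes.items():
            followup_by_key.update(by_key)
    else:
        families = read_pedigree(config.ped)
        known = {
            m.individual_id for fam in families for m in fam.members
        }
        all_variants = read_variants(
            config.vcf, dialect=config.dialect, known_samples=known
        )
        term_sets = read_term_sets(config.gmt)
        per_family_variants = {
            fam.family_id: all_variants for fam in families
        }
        followup_by_key = {}
        if config.followup_vcf:
            for v in read_variants(config.followup_vcf, config.dialect):
                followup_by_key[v.key] = v.genotypes

    # per-family filter cascade
    per_family_retained: dict[str, list[AnnotatedVariant]] = {}
    funnel_rows = []
    for family in families:
        retained, funnel = run_cascade(
            per_family_variants[family.family_id], family, config.filter_config
        )
        per_family_retained[family.family_id] = retained
        for stage, n_in, n_out in funnel.stages:
            funnel_rows.append(
                {
                    "family_id": family.family_id,
                    "stage": stage,
                    "n_in": n_in,
                    "n_out": n_out,
                }
            )
    write_retained_tsv(per_family_retained, out / "retained.tsv")
    pd.DataFrame(funnel_rows).to_csv(out / "funnel.tsv", sep="\t", index=False)

    # cross-family aggregation
    table = build_sharing_table(per_family_retained)
    sharing_rows = [
        {
            "gene": gene,
            "n_families": len(fams),
            "families": ",".join(sorted(fams)),
            "identical_variant": int(table.identical_variant[gene]),
        }
        for gene, fams in sorted(
            table.families_by_gene.items(),
            key=lambda item: (-len(item[1]), item[0]),
        )
    ]
    pd.DataFrame(sharing_rows).to_csv(
        out / "sharing.tsv", sep="\t", index=False
    )
    census = sharing_census(table)
    pd.DataFrame(
        [{"min_families": t, "n_genes": n} for t, n in census.items()]
    ).to_csv(out / "census.tsv", sep="\t", index=False)

    summary = summarize(per_family_retained)
    summary_rows = []
    for c, n in sorted(
        summary.consequence_counts.items(), key=lambda kv: -kv[1]
    ):
        summary_rows.append(
            {
                "section": "consequence",
                "key": c.value,
                "count": n,
                "pct": summary.consequence_pct[c],
            }
        )
    for b, n in summary.maf_bin_counts.items():
        summary_rows.append(
            {
                "section": "maf_bin",
                "key": b,
                "count": n,
                "pct": summary.maf_bin_pct[b],
            }
        )
    for chrom, n in sorted(summary.chrom_counts.items()):
        summary_rows.append(
            {"section": "chromosome", "key": chrom, "count": n, "pct": ""}
        )
    for fid, n in sorted(summary.per_family_counts.items()):
        summary_rows.append(
            {"section": "per_family", "key": fid, "count": n, "pct": ""}
        )
    for key, value in (
        ("total_variants", summary.total_variants),
        ("total_genes", summary.total_genes),
        ("private_genes", summary.private_genes),
        ("median_per_family", summary.median_per_family),
    ):
        summary_rows.append(
            {"section": "totals", "key": key, "count": value, "pct": ""}
        )
    summary_rows.append(
        {
            "section": "totals",
            "key": "private_gene_pct",
            "count": "",
            "pct": summary.private_gene_pct,
        }
    )
    pd.DataFrame(summary_rows).to_csv(
        out / "summary.tsv", sep="\t", index=False
    )

    # enrichment of the combined retained gene list
    gene_list = frozenset(
        v.gene for variants in per_family_retained.values() for v in variants
    )
    enrichment_rows = []
    results = []
    if gene_list:
        results = enrich(
            EnrichmentInput(
                gene_list=gene_list,
                term_sets=term_sets,
                ease=config.ease,
                min_count=config.min_count,
                adjust=config.adjust,
            )
        )
        enrichment_rows = [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "count": r.k,
                "pct": r.pct,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "fold_enrichment": round(r.fold, 4),
                "genes": ",".join(r.genes),
            }
            for r in results
        ]
    pd.DataFrame(
        enrichment_rows,
        columns=[
            "term_id",
            "term_name",
            "count",
            "pct",
            "p_raw",
            "p_adjusted",
            "fold_enrichment",
            "genes",
        ],
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # co-segregation of variants in multi-family genes
    seg_rows = []
    if config.segregate_min_families > 0 and followup_by_key:
        discovery = {
            fam.family_id: frozenset(
                m.individual_id for m in fam.sequenced_members
            )
            for fam in families
        }
        seg_rows = _segregation_stage(
            list(families),
            per_family_retained,
            table,
            followup_by_key,
            config.segregate_min_families,
            discovery,
        )
        pd.DataFrame(seg_rows).to_csv(out / "seg.tsv", sep="\t", index=False)

    manifest = {
        "exofam_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "simulated": config.simulate,
        "n_families": len(families),
        "n_input_variants": sum(
            len(v) for v in per_family_variants.values()
        ),
        "n_retained_variants": summary.total_variants,
        "n_retained_genes": summary.total_genes,
        "median_retained_per_family": summary.median_per_family,
        "sharing_census": {str(t): n for t, n in census.items()},
        "n_enriched_terms": len(results),
        "top_term": results[0].term_id if results else None,
        "n_segregation_calls": len(seg_rows),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
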