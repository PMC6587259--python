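"""End-to-end orchestration: variants -> epitopes -> binding ->
expression -> prioritization, with optional ELISpot and signature
stages, and a machine-readable cohort report.

Default thresholds encode the published procedure: <150 nM mutant
affinity, mutant/wild-type ratio <0.9, >=100 nM affinity difference
(CGC-exempt); >=2 mutant RNA reads with the tiered VAF minimum and no
strand bias; ELISpot positivity at >=25 spots per 5x10^4 cells and
>=2-fold over wild type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import binding, elispot, expression, prioritize, signatures, stats, variants
from .errors import ConfigError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """File paths, stage toggles and thresholds for one cohort run."""

    mutations: str = ""
    affinities: str = ""
    rna_evidence: str = ""
    rpkm: str = ""
    elispot_wells: str = ""
    expression_matrix: str = ""
    groups: str = ""
    survival: str = ""
    gene_sets: str = ""
    outdir: str = "neoprior_out"
    mutation_dialect: str = "maf-tsv"
    run_filters: bool = True
    run_elispot: bool = True
    run_signatures: bool = True
    render_clp: bool = True
    panel_size: int = 0  # 0 disables panel selection
    nonexpressed_quota: int = 0
    binding_thresholds: dict = field(default_factory=dict)
    filter_thresholds: dict = field(default_factory=dict)
    elispot_config: dict = field(default_factory=dict)
    deg_method: str = "moderated"
    deg_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = [("mutations", self.mutations), ("affinities", self.affinities)]
        if self.run_elispot and self.elispot_wells:
            required.append(("elispot_wells", self.elispot_wells))
        if self.run_signatures and self.expression_matrix:
            required.append(("expression_matrix", self.expression_matrix))
        for name, path in required:
            if not path:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages, writing per-stage artifacts.

    Returns the report dict (also written to ``<outdir>/report.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    mutations = variants.read_mutation_table(config.mutations,
                                             config.mutation_dialect)
    if config.run_filters:
        mutations = variants.filter_mutations(mutations,
                                              config.filter_thresholds)
        n_fail = int((~mutations["filter_pass"]).sum())
        logger.info("post-call filters removed %d of %d mutations",
                    n_fail, len(mutations))
        mutations.to_csv(out / "mutations_filtered.tsv", sep="\t", index=False)
        mutations = mutations[mutations["filter_pass"]]
    recurrence = variants.recurrence_matrix(mutations)
    recurrence.to_csv(out / "recurrence_matrix.tsv", sep="\t")

    affinities = binding.read_affinity_table(config.affinities)
    affinities = affinities[affinities["mutation_id"].isin(
        mutations["mutation_id"])]
    called = binding.call_neoepitopes(affinities, mutations,
                                      config.binding_thresholds)
    candidates = binding.collapse_neoantigens(called, mutations)

    if config.rna_evidence and config.rpkm:
        rna = expression.read_rna_evidence(config.rna_evidence)
        rpkm = expression.read_rpkm_table(config.rpkm)
        candidates = expression.annotate_candidates(candidates, rna, rpkm)
    else:
        candidates["expressed"] = False
        candidates["expression_reason"] = "no-data"
        candidates["gene_rpkm"] = float("nan")
        candidates["weakly_expressed"] = False

    ranked = prioritize.rank_candidates(candidates)
    ranked.to_csv(out / "candidates_ranked.tsv", sep="\t", index=False)
    classification = binding.classify_cohort(ranked)

    panel = None
    if config.panel_size and len(ranked):
        size = min(config.panel_size, len(ranked))
        panel = prioritize.select_panel(ranked, size,
                                        min(config.nonexpressed_quota, size))
        panel.to_csv(out / "panel.tsv", sep="\t", index=False)
    if config.render_clp and len(ranked):
        label_ids = set(panel["mutation_id"]) if panel is not None else set()
        prioritize.render_clp(ranked, str(out / "clp.svg"),
                              label_ids=label_ids)

    response_summary = None
    if config.run_elispot and config.elispot_wells:
        wells = elispot.read_wells(config.elispot_wells)
        calls = elispot.pair_and_call(wells, config.elispot_config)
        if calls:
            response_summary = elispot.summarize_cohort(
                calls, n_patients=wells["patient"].nunique())
            response_summary["validation_rate_percent"] = \
                elispot.validation_rate(response_summary)
            pd.DataFrame([c.__dict__ for c in calls]).to_csv(
                out / "response_calls.tsv", sep="\t", index=False)

    signature_results = None
    if config.run_signatures and config.expression_matrix:
        matrix = signatures.read_expression_matrix(config.expression_matrix)
        sig_block: dict = {}
        if config.groups and config.gene_sets:
            groups = pd.read_csv(config.groups, sep="\t", index_col=0)["group"]
            deg = signatures.differential_expression(matrix, groups,
                                                     method=config.deg_method)
            deg.to_csv(out / "deg_table.tsv", sep="\t")
            sets = signatures.read_gmt(config.gene_sets)
            sig_genes = signatures.derive_appm_signature(deg, sets,
                                                         config.deg_alpha)
            pd.Series(sig_genes, name="gene").to_csv(
                out / "signature_genes.tsv", sep="\t", index=False)
            sig_block["n_signature_genes"] = len(sig_genes)
        else:
            sig_genes = list(matrix.index)
        if config.survival and sig_genes:
            scores = signatures.signature_score(matrix, sig_genes)
            scores.rename("score").to_csv(out / "signature_scores.tsv", sep="\t")
            surv_df = pd.read_csv(config.survival, sep="\t")
            records = [stats.SurvivalRecord(str(r.sample), float(r.time),
                                            int(r.event))
                       for r in surv_df.itertuples()]
            surv = signatures.survival_by_signature(scores, records)
            surv["tertiles"].rename("tertile").to_csv(out / "tertiles.tsv",
                                                      sep="\t")
            for label in ("high", "low"):
                pd.DataFrame({k: v for k, v in surv["km"][label].items()}
                             ).to_csv(out / f"km_{label}.tsv", sep="\t",
                                      index=False)
            sig_block.update({
                "logrank_p": surv["logrank_p"],
                "cox_p": surv["cox"]["p"],
                "cox_hazard_ratio": surv["cox"]["hazard_ratio"],
            })
        signature_results = sig_block or None

    report = write_report(
        out / "report.json",
        mutation_counts={
            "total": int(len(mutations)),
            "patients": int(mutations["patient"].nunique()),
            "missense": int((mutations["mutation_class"] == "missense").sum()),
        },
        classification=classification,
        response_summary=response_summary,
        signature_results=signature_results,
    )
    return report


def write_report(path, mutation_counts=None, classification=None,
                 response_summary=None, signature_results=None) -> dict:
    """Assemble and write the versioned JSON cohort report."""
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "mutations": mutation_counts or {},
        "neoantigen_classification": classification or {},
        "response_summary": response_summary or {},
        "signature": signature_results or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
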