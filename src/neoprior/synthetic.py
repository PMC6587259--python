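"""Synthetic cohort generation for the full pipeline.

The generator emits every table the pipeline reads -- somatic mutations
with read evidence, protein contexts, peptide-HLA affinities, RNA site
evidence, gene RPKM, ELISpot wells, a gene-expression matrix and a
survival table -- together with truth labels for each planted effect
(strong specific binders, immunogenic peptides, differentially
expressed signature genes).

Defaults mirror an advanced epithelial ovarian cancer cohort: 20
patients, per-patient nonsynonymous mutation counts drawn from a
negative binomial with mean 62 truncated to the observed 9-183 range,
median overall survival near 31 months.  The affinity model is a
deterministic hash of (peptide, allele) mapped log-uniformly onto the
weak-binding range, so unplanted peptides essentially never satisfy the
<150 nM criterion, while planted binders are placed near 50 nM and pass
all three binding criteria by construction.

One global seed expands into per-component child seeds through
``numpy.random.SeedSequence`` so each stage is individually
reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import epitopes
from .errors import FormatError, ParameterError
from .variants import MUTATION_COLUMNS

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

UNPLANTED_NM_RANGE = (500.0, 50000.0)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort, with cohort-scale defaults."""

    n_patients: int = 20
    mutations_per_patient_mean: float = 62.0
    mutations_per_patient_dispersion: float = 8.0
    mutation_count_range: tuple[int, int] = (9, 183)
    missense_fraction: float = 0.8
    cgc_fraction: float = 0.10
    hla_class1: tuple[str, ...] = ("HLA-A*02:01", "HLA-B*07:02")
    hla_class2: tuple[str, ...] = ("HLA-DRB1*04:01",)
    planted_binder_fraction: float = 0.10
    planted_affinity_nm: float = 50.0
    dna_depth: float = 80.0
    rna_depth: float = 40.0
    rna_expressed_fraction: float = 0.55
    strand_bias_prob: float = 0.05
    elispot_background_mean: float = 2.0
    elispot_effect_mean: float = 60.0
    elispot_cells_plated: int = 50000
    elispot_immunogenic_fraction: float = 0.2
    n_expression_genes: int = 1000
    n_expression_samples: int = 300
    n_signature_genes: int = 31
    signature_effect: float = 2.0
    hazard_ratio: float = 2.5
    n_gene_universe: int = 400
    protein_length_range: tuple[int, int] = (120, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missense_fraction", "cgc_fraction",
                     "planted_binder_fraction", "rna_expressed_fraction",
                     "strand_bias_prob", "elispot_immunogenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must lie in [0, 1]")
        for name in ("dna_depth", "rna_depth"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.hazard_ratio <= 0:
            raise ParameterError("hazard_ratio must be positive")
        if self.mutations_per_patient_mean <= 0:
            raise ParameterError("mutations_per_patient_mean must be positive")
        lo, hi = self.mutation_count_range
        if not 1 <= lo <= hi:
            raise ParameterError("mutation_count_range must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticCohort:
    """Every table the pipeline consumes plus the planted truth labels."""

    config: SimulationConfig
    mutations: pd.DataFrame
    proteins: dict[str, str]
    affinities: pd.DataFrame
    rna_evidence: pd.DataFrame
    rpkm: pd.DataFrame
    elispot_wells: pd.DataFrame
    expression: pd.DataFrame
    survival: pd.DataFrame
    groups: pd.Series
    truth_binders: pd.DataFrame
    truth_immunogenic: pd.DataFrame
    truth_degs: pd.DataFrame

    def write(self, outdir: str) -> None:
        """Serialize every table as TSV/FASTA under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
        with open(out / "proteins.fasta", "w") as fh:
            for gene in sorted(self.proteins):
                fh.write(f">{gene}\n{self.proteins[gene]}\n")
        self.affinities.to_csv(out / "affinities.tsv", sep="\t", index=False)
        self.rna_evidence.to_csv(out / "rna_evidence.tsv", sep="\t", index=False)
        self.rpkm.to_csv(out / "rpkm.tsv", sep="\t", index=False)
        self.elispot_wells.to_csv(out / "elispot_wells.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
        self.groups.rename("group").to_csv(out / "groups.tsv", sep="\t")
        self.truth_binders.to_csv(out / "truth_binders.tsv", sep="\t", index=False)
        self.truth_immunogenic.to_csv(out / "truth_immunogenic.tsv", sep="\t",
                                      index=False)
        self.truth_degs.to_csv(out / "truth_degs.tsv", sep="\t", index=False)


def _hash_unit(*parts: str) -> float:
    """Deterministic uniform-(0,1) value from a string tuple."""
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


def toy_affinity_model(
    peptide: str,
    allele: str,
    planted: dict | None = None,
    planted_nm: float = 50.0,
) -> float:
    """Deterministic pseudo-predictor of peptide-HLA IC50 (nM).

    Unplanted (peptide, allele) pairs map log-uniformly onto the
    500-50000 nM non-binder range via a hash; pairs listed in
    ``planted`` return a value near ``planted_nm`` (within ~25%), which
    keeps every planted mutant a strong, specific binder against any
    unplanted wild-type partner.
    """
    if not allele:
        raise ParameterError("empty allele name")
    if not epitopes.MIN_LENGTH <= len(peptide) <= epitopes.MAX_LENGTH:
        raise FormatError(
            f"peptide length {len(peptide)} outside "
            f"[{epitopes.MIN_LENGTH}, {epitopes.MAX_LENGTH}]"
        )
    bad = set(peptide) - epitopes.STANDARD_AA
    if bad:
        raise FormatError(f"invalid amino-acid letter(s) {sorted(bad)} in {peptide}")
    u = _hash_unit(peptide, allele)
    if planted and (peptide, allele) in planted:
        return planted_nm * 10.0 ** (0.2 * (u - 0.5))  # within [-10%, +12%] in log10
    lo, hi = UNPLANTED_NM_RANGE
    return lo * (hi / lo) ** u


def simulate_read_evidence(
    true_vaf: float,
    depth: float,
    strand_bias: bool,
    rng: np.random.Generator,
) -> dict:
    """Binomial read support at one site: (alt, total, alt_fwd, alt_rev)."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ParameterError(f"true_vaf={true_vaf} outside [0, 1]")
    if depth <= 0:
        raise ParameterError("depth must be positive")
    total = int(max(rng.poisson(depth), 1))
    alt = int(rng.binomial(total, true_vaf)) if true_vaf > 0 else 0
    if strand_bias:
        fwd = alt if rng.random() < 0.5 else 0
    else:
        fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    return {"alt": alt, "total": total, "alt_fwd": fwd, "alt_rev": alt - fwd}


def simulate_elispot(
    immunogenic: bool,
    background_mean: float,
    effect_mean: float,
    cells_plated: int,
    rng: np.random.Generator,
    ref_cells: float = 5e4,
) -> tuple[int, int, int]:
    """Poisson spot counts for (mutant, wild-type, no-peptide) wells.

    Means are spot rates per ``ref_cells`` and scale linearly with the
    number of plated cells.  Immunogenic wells add ``effect_mean`` to
    the mutant-well rate only.
    """
    if background_mean < 0 or effect_mean < 0:
        raise ParameterError("spot-rate means must be >= 0")
    if cells_plated <= 0:
        raise ParameterError("cells_plated must be positive")
    scale = cells_plated / ref_cells
    mut_mean = background_mean + (effect_mean if immunogenic else 0.0)
    mut = int(rng.poisson(mut_mean * scale))
    wt = int(rng.poisson(background_mean * scale))
    none = int(rng.poisson(background_mean * scale))
    return mut, wt, none


def simulate_expression_survival(
    n_genes: int,
    n_samples: int,
    signature_genes: list[str],
    effect: float,
    hazard_ratio: float,
    seed: int | np.random.Generator,
    gene_names: list[str] | None = None,
    n_group1: int | None = None,
    median_survival_months: float = 31.0,
    censor_horizon_months: float = 120.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expression matrix with a planted group signature linked to survival.

    Genes are iid standard normal (log-scale expression).  The signature
    genes are shifted upward by ``effect`` standard deviations in group
    1 (the responder-like group, the first ``n_group1`` samples, half by
    default).  Survival times are exponential with log-hazard
    -log(hazard_ratio) x z, where z is the standardized per-sample mean
    over signature genes, so high-signature samples live longer;
    censoring is administrative at ``censor_horizon_months``.

    Returns (matrix genes x samples, survival table, group labels).
    """
    if hazard_ratio <= 0:
        raise ParameterError("hazard_ratio must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if gene_names is None:
        gene_names = [f"G{i:05d}" for i in range(n_genes)]
    unknown = set(signature_genes) - set(gene_names)
    if unknown:
        raise ParameterError(f"signature genes outside universe: {sorted(unknown)}")
    samples = [f"S{i:04d}" for i in range(n_samples)]
    n_group1 = n_samples // 2 if n_group1 is None else n_group1
    values = rng.normal(size=(n_genes, n_samples))
    matrix = pd.DataFrame(values, index=gene_names, columns=samples)
    matrix.loc[signature_genes, samples[:n_group1]] += effect
    groups = pd.Series(
        ["responder"] * n_group1 + ["non-responder"] * (n_samples - n_group1),
        index=samples, name="group",
    )
    score = matrix.loc[signature_genes].mean(axis=0) if signature_genes \
        else pd.Series(0.0, index=samples)
    z = ((score - score.mean()) / score.std(ddof=0)
         if score.std(ddof=0) > 0 else score * 0.0)
    lam0 = np.log(2.0) / median_survival_months
    lam = lam0 * np.exp(-np.log(hazard_ratio) * z.to_numpy())
    times = rng.exponential(1.0 / lam)
    event = (times <= censor_horizon_months).astype(int)
    times = np.minimum(times, censor_horizon_months)
    survival = pd.DataFrame({
        "sample": samples,
        "time": np.round(times, 3),
        "event": event,
    })
    return matrix, survival, groups


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully self-contained synthetic cohort.

    Deterministic for a fixed config (including seed): rerunning and
    serializing yields byte-identical files.
    """
    children = np.random.SeedSequence(config.seed).spawn(6)
    rng_mut, rng_rna, rng_eli, rng_expr, rng_prot, rng_misc = (
        np.random.default_rng(s) for s in children
    )

    # --- gene universe and proteins -------------------------------------
    n_cgc = max(int(round(config.n_gene_universe * config.cgc_fraction)), 1)
    cgc_genes = [f"CGC{i:03d}" for i in range(n_cgc)]
    other_genes = [f"GENE{i:04d}" for i in range(config.n_gene_universe - n_cgc)]
    universe = cgc_genes + other_genes
    lo, hi = config.protein_length_range
    proteins = {
        g: _random_protein(rng_prot, int(rng_prot.integers(lo, hi + 1)))
        for g in universe
    }

    # --- somatic mutations with DNA read evidence -----------------------
    lo_c, hi_c = config.mutation_count_range
    mean = config.mutations_per_patient_mean
    r = config.mutations_per_patient_dispersion
    p_nb = r / (r + mean)
    rows = []
    for i in range(config.n_patients):
        patient = f"P{i + 1:02d}"
        count = int(np.clip(rng_mut.negative_binomial(r, p_nb), lo_c, hi_c))
        genes = rng_mut.choice(universe, size=count, replace=False) \
            if count <= len(universe) else rng_mut.choice(universe, size=count)
        for j, gene in enumerate(genes):
            is_cgc = gene in cgc_genes
            mutation_id = f"{patient}_M{j + 1:04d}"
            u = rng_mut.random()
            if u < config.missense_fraction:
                mclass = "missense"
            elif u < config.missense_fraction + 0.1:
                mclass = "nonsense"
            elif u < config.missense_fraction + 0.15:
                mclass = "frameshift"
            else:
                mclass = "in-frame"
            seq = proteins[gene]
            ppos = int(rng_mut.integers(1, len(seq) + 1))
            ref_aa = seq[ppos - 1]
            alt_aa = rng_mut.choice([a for a in AA_ALPHABET if a != ref_aa])
            vaf = float(np.clip(rng_mut.beta(2.0, 4.0), 0.02, 0.98))
            ev = simulate_read_evidence(vaf, config.dna_depth,
                                        rng_mut.random() < config.strand_bias_prob,
                                        rng_mut)
            rows.append({
                "mutation_id": mutation_id, "patient": patient,
                "chrom": f"chr{int(rng_mut.integers(1, 23))}",
                "pos": int(rng_mut.integers(1, 2_000_000)),
                "ref": str(rng_mut.choice(list("ACGT"))),
                "alt": str(rng_mut.choice(list("ACGT"))),
                "gene": gene, "mutation_class": mclass,
                "protein_pos": ppos, "ref_aa": ref_aa, "alt_aa": alt_aa,
                "vaf": round(vaf, 4),
                "t_alt": ev["alt"], "t_ref": ev["total"] - ev["alt"],
                "n_alt": 0, "n_ref": int(rng_mut.poisson(config.dna_depth)),
                "alt_fwd": ev["alt_fwd"], "alt_rev": ev["alt_rev"],
                "baseq_site": round(float(rng_mut.normal(35, 1)), 2),
                "baseq_flank": round(float(rng_mut.normal(35, 1)), 2),
                "mapq_alt": round(float(rng_mut.normal(58, 2)), 2),
                "is_cgc": is_cgc,
            })
    mutations = pd.DataFrame(rows, columns=MUTATION_COLUMNS)

    # --- peptide pairs and affinities with planted binders --------------
    missense = mutations[mutations["mutation_class"] == "missense"]
    planted: dict[tuple[str, str], str] = {}
    truth_binder_rows = []
    aff_rows = []
    for row in missense.itertuples():
        ctx = epitopes.ProteinContext(
            gene=row.gene, sequence=proteins[row.gene],
            position=int(row.protein_pos), ref_aa=row.ref_aa,
            alt_aa=row.alt_aa, mutation_id=row.mutation_id,
        )
        pairs_i = epitopes.enumerate_peptide_pairs(ctx, epitopes.CLASS_I_LENGTHS)
        pairs_ii = epitopes.enumerate_peptide_pairs(ctx, epitopes.CLASS_II_LENGTHS)
        plant_here = rng_misc.random() < config.planted_binder_fraction
        u_cls = rng_misc.random()
        # class I / class II / both, echoing the observed class mix
        plant_classes = {"I"} if u_cls < 0.35 else (
            {"II"} if u_cls < 0.75 else {"I", "II"})
        for mhc_class, pairs, alleles in (
            ("I", pairs_i, config.hla_class1),
            ("II", pairs_ii, config.hla_class2),
        ):
            if plant_here and pairs and mhc_class in plant_classes:
                k = int(rng_misc.integers(0, len(pairs)))
                a = str(rng_misc.choice(list(alleles)))
                planted[(pairs[k].mutant, a)] = row.mutation_id
                truth_binder_rows.append({
                    "mutation_id": row.mutation_id,
                    "peptide": pairs[k].mutant,
                    "allele": a, "mhc_class": mhc_class,
                })
            for pair in pairs:
                for allele in alleles:
                    aff_rows.append({
                        "mutation_id": row.mutation_id,
                        "mut_peptide": pair.mutant,
                        "wt_peptide": pair.wildtype,
                        "allele": allele, "mhc_class": mhc_class,
                        "mut_nm": round(toy_affinity_model(
                            pair.mutant, allele, planted,
                            config.planted_affinity_nm), 2),
                        "wt_nm": round(toy_affinity_model(
                            pair.wildtype, allele, planted,
                            config.planted_affinity_nm), 2),
                    })
    affinities = pd.DataFrame(
        aff_rows, columns=["mutation_id", "mut_peptide", "wt_peptide",
                           "allele", "mhc_class", "mut_nm", "wt_nm"])
    truth_binders = pd.DataFrame(
        truth_binder_rows,
        columns=["mutation_id", "peptide", "allele", "mhc_class"])

    # --- RNA site evidence and gene RPKM --------------------------------
    rna_rows = []
    rpkm_rows = []
    gene_rpkm_base = {
        g: float(np.round(rng_rna.lognormal(mean=1.0, sigma=1.5), 3))
        for g in universe
    }
    for row in mutations.itertuples():
        expressed_site = rng_rna.random() < config.rna_expressed_fraction
        site_vaf = row.vaf if expressed_site else 0.0
        ev = simulate_read_evidence(
            site_vaf, config.rna_depth,
            rng_rna.random() < config.strand_bias_prob, rng_rna)
        rna_rows.append({"mutation_id": row.mutation_id, **ev})
        rpkm_rows.append({
            "patient": row.patient, "gene": row.gene,
            "rpkm": round(gene_rpkm_base[row.gene]
                          * float(rng_rna.lognormal(0.0, 0.3)), 3),
        })
    rna_evidence = pd.DataFrame(
        rna_rows, columns=["mutation_id", "alt", "total", "alt_fwd", "alt_rev"])
    rpkm = pd.DataFrame(rpkm_rows, columns=["patient", "gene", "rpkm"])

    # --- ELISpot wells with planted immunogenic peptides ----------------
    eli_rows = []
    truth_imm_rows = []
    screened_patients = [f"P{i + 1:02d}"
                         for i in range(min(10, config.n_patients))]
    panel = missense[missense["patient"].isin(screened_patients)]
    for patient in screened_patients:
        pep_ids = panel[panel["patient"] == patient]["mutation_id"].head(8)
        for pep in pep_ids:
            immunogenic = rng_eli.random() < config.elispot_immunogenic_fraction
            if immunogenic:
                truth_imm_rows.append({"patient": patient, "target": pep})
            subset = "CD4" if rng_eli.random() < 0.5 else "CD8"
            for compartment in ("TIL", "PBMC"):
                mut, wt, none = simulate_elispot(
                    immunogenic, config.elispot_background_mean,
                    config.elispot_effect_mean, config.elispot_cells_plated,
                    rng_eli)
                for kind, spots in (("mutant", mut), ("wildtype", wt),
                                    ("none", none)):
                    eli_rows.append({
                        "patient": patient, "target": pep, "kind": kind,
                        "compartment": compartment, "subset": subset,
                        "spots": spots, "cells": config.elispot_cells_plated,
                    })
    elispot_wells = pd.DataFrame(
        eli_rows, columns=["patient", "target", "kind", "compartment",
                           "subset", "spots", "cells"])
    truth_immunogenic = pd.DataFrame(truth_imm_rows,
                                     columns=["patient", "target"])

    # --- expression matrix + survival with planted signature ------------
    expr_genes = [f"EXPR{i:05d}" for i in range(config.n_expression_genes)]
    signature_genes = expr_genes[: config.n_signature_genes]
    expression, survival, groups = simulate_expression_survival(
        n_genes=config.n_expression_genes,
        n_samples=config.n_expression_samples,
        signature_genes=signature_genes,
        effect=config.signature_effect,
        hazard_ratio=config.hazard_ratio,
        seed=rng_expr,
        gene_names=expr_genes,
    )
    truth_degs = pd.DataFrame({"gene": signature_genes})

    return SyntheticCohort(
        config=config,
        mutations=mutations,
        proteins=proteins,
        affinities=affinities,
        rna_evidence=rna_evidence,
        rpkm=rpkm,
        elispot_wells=elispot_wells,
        expression=expression,
        survival=survival,
        groups=groups,
        truth_binders=truth_binders,
        truth_immunogenic=truth_immunogenic,
        truth_degs=truth_degs,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict, naming bad fields."""
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
    d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()}
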