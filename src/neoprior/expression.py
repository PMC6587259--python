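"""Mutant-allele RNA expression evidence and gene-level RPKM annotation.

A predicted neoantigen is called "robustly expressed" when the mutant
allele itself is visible in tumor RNA-seq:

1. at least two reads support the mutant allele;
2. the RNA variant allele fraction is at least 4% when three or more
   reads support it, or at least 20% when exactly two do;
3. the alt reads show no significant strand bias (exact two-sided
   binomial test against a 0.5 split, p >= 0.05).

Gene-level expression is carried as RPKM; genes under 1 RPKM are
flagged weakly expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .errors import EvidenceError, FormatError, ParameterError

RPKM_WEAK_THRESHOLD = 1.0


@dataclass(frozen=True)
class RnaSiteEvidence:
    """RNA-seq read support for the mutant allele at one site."""

    mutation_id: str
    alt: int
    total: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if self.alt > self.total:
            raise EvidenceError(f"{self.mutation_id}: alt > total")
        if self.alt_fwd + self.alt_rev != self.alt:
            raise EvidenceError(f"{self.mutation_id}: strand counts != alt")
        if min(self.alt, self.total, self.alt_fwd, self.alt_rev) < 0:
            raise EvidenceError(f"{self.mutation_id}: negative counts")


def mutant_allele_expressed(ev: RnaSiteEvidence, alpha: float = 0.05) -> bool:
    """Apply the three mutant-allele expression criteria."""
    if ev.total == 0:
        raise EvidenceError(f"{ev.mutation_id}: zero RNA depth at site")
    if ev.alt < 2:
        return False
    vaf = ev.alt / ev.total
    min_vaf = 0.20 if ev.alt == 2 else 0.04
    if vaf < min_vaf:
        return False
    if stats.binomial_two_sided(ev.alt_fwd, ev.alt, 0.5) < alpha:
        return False
    return True


def compute_rpkm(count: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise ParameterError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ParameterError("total mapped reads must be positive")
    return 1e9 * count / (gene_length_bp * total_mapped_reads)


def read_rna_evidence(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str})
    required = ["mutation_id", "alt", "total", "alt_fwd", "alt_rev"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_rpkm_table(path: str, total_mapped_reads: float | None = None) -> pd.DataFrame:
    """RPKM TSV keyed by (patient, gene); recompute RPKM when absent.

    Columns: patient, gene, plus either an ``rpkm`` column or the
    (count, length_bp) pair with ``total_mapped_reads`` supplied.
    """
    df = pd.read_csv(path, sep="\t")
    if "rpkm" not in df.columns:
        if not {"count", "length_bp"} <= set(df.columns) or total_mapped_reads is None:
            raise FormatError(
                f"{path}: need an rpkm column, or count/length_bp plus "
                "total_mapped_reads"
            )
        df["rpkm"] = [
            compute_rpkm(c, l, total_mapped_reads)
            for c, l in zip(df["count"], df["length_bp"])
        ]
    return df


def annotate_candidates(
    candidates: pd.DataFrame,
    rna_evidence: pd.DataFrame,
    rpkm: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach expressed / weakly_expressed flags and gene RPKM.

    Candidates with no RNA evidence row are marked not expressed with
    reason "no-data".  Gene RPKM is looked up per (patient, gene) when a
    patient column is present in the RPKM table, else per gene.
    """
    ev_by_id = rna_evidence.set_index("mutation_id")
    if "patient" in rpkm.columns and "patient" in candidates.columns:
        rpkm_idx = rpkm.set_index(["patient", "gene"])["rpkm"]
        lookup = lambda row: rpkm_idx.get((row.patient, row.gene), np.nan)
    else:
        rpkm_idx = rpkm.set_index("gene")["rpkm"]
        lookup = lambda row: rpkm_idx.get(row.gene, np.nan)

    expressed, reasons, rpkms = [], [], []
    for row in candidates.itertuples():
        if row.mutation_id in ev_by_id.index:
            e = ev_by_id.loc[row.mutation_id]
            site = RnaSiteEvidence(
                mutation_id=row.mutation_id,
                alt=int(e["alt"]), total=int(e["total"]),
                alt_fwd=int(e["alt_fwd"]), alt_rev=int(e["alt_rev"]),
            )
            ok = site.total > 0 and mutant_allele_expressed(site, alpha=alpha)
            expressed.append(ok)
            reasons.append("" if ok else "criteria-failed")
        else:
            expressed.append(False)
            reasons.append("no-data")
        rpkms.append(lookup(row))
    out = candidates.copy()
    out["expressed"] = expressed
    out["expression_reason"] = reasons
    out["gene_rpkm"] = rpkms
    out["weakly_expressed"] = out["gene_rpkm"] < RPKM_WEAK_THRESHOLD
    return out
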