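"""Somatic mutation ingestion, post-call filtering and cohort summaries.

Calls are consumed as tables (MAF-like TSV or a minimal VCF dialect)
rather than re-derived from alignments.  The post-call filters recast
the standard false-call screens onto tabulated read evidence:

1. normal contamination -- the alternative allele is present in the
   matched normal and the tumor/normal contingency is not significant
   (one-sided Fisher exact, tumor-enriched);
2. strand bias -- alt reads sit on a single strand and the exact
   binomial test against a 0.5 strand split is significant;
3. base-quality drop -- mean base quality at the site is well below the
   flanking positions;
4. mapping quality -- alt-supporting reads map poorly on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .errors import EvidenceError, FormatError, InsufficientDataError, ParameterError

MUTATION_CLASSES = ("missense", "nonsense", "frameshift", "in-frame")
TRUNCATING = ("nonsense", "frameshift")

#: columns of the MAF-like TSV dialect
MUTATION_COLUMNS = [
    "mutation_id", "patient", "chrom", "pos", "ref", "alt", "gene",
    "mutation_class", "protein_pos", "ref_aa", "alt_aa", "vaf",
    "t_alt", "t_ref", "n_alt", "n_ref", "alt_fwd", "alt_rev",
    "baseq_site", "baseq_flank", "mapq_alt", "is_cgc",
]

DEFAULT_FILTER_THRESHOLDS = {"alpha": 0.05, "baseq_drop": 10.0, "min_mapq": 30.0}


@dataclass(frozen=True)
class ReadEvidence:
    """Site-level read support for one called variant."""

    t_alt: int
    t_ref: int
    n_alt: int
    n_ref: int
    alt_fwd: int
    alt_rev: int
    baseq_site: float
    baseq_flank: float
    mapq_alt: float

    def __post_init__(self) -> None:
        counts = (self.t_alt, self.t_ref, self.n_alt, self.n_ref,
                  self.alt_fwd, self.alt_rev)
        if any(c < 0 for c in counts):
            raise EvidenceError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev != self.t_alt:
            raise EvidenceError(
                f"strand counts {self.alt_fwd}+{self.alt_rev} != tumor alt {self.t_alt}"
            )


@dataclass(frozen=True)
class SomaticMutation:
    """One called coding variant with annotation and read evidence."""

    mutation_id: str
    patient: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    mutation_class: str
    protein_pos: int | None
    ref_aa: str
    alt_aa: str
    vaf: float
    is_cgc: bool = False
    evidence: ReadEvidence | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ParameterError(
                f"{self.mutation_id}: VAF {self.vaf} outside [0, 1]"
            )
        if self.mutation_class not in MUTATION_CLASSES:
            raise FormatError(
                f"{self.mutation_id}: unknown mutation class {self.mutation_class!r}"
            )
        if self.mutation_class == "missense":
            if self.protein_pos is None:
                raise FormatError(f"{self.mutation_id}: missense without protein_pos")
            if self.ref_aa == self.alt_aa:
                raise FormatError(f"{self.mutation_id}: missense with ref_aa == alt_aa")


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the four post-call filters for one variant."""

    passes: bool
    failed_criteria: tuple[str, ...] = field(default_factory=tuple)


def read_mutation_table(path: str, dialect: str = "maf-tsv") -> pd.DataFrame:
    """Read somatic mutations from a MAF-like TSV or minimal VCF.

    Returns a DataFrame with MUTATION_COLUMNS; 1-based positions are
    preserved.  Unknown genes are kept (flagged by an empty symbol).
    """
    if dialect == "maf-tsv":
        return _read_maf_tsv(path)
    if dialect == "vcf-minimal":
        return _read_vcf_minimal(path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def _read_maf_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "patient": str,
                                            "chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    bad = df.index[vaf.isna() | (vaf < 0) | (vaf > 1)]
    if len(bad):
        raise FormatError(
            f"{path}: row {bad[0] + 2}: malformed VAF {df.loc[bad[0], 'vaf']!r}"
        )
    df["vaf"] = vaf
    df["is_cgc"] = df["is_cgc"].astype(bool)
    return df


def _read_vcf_minimal(path: str) -> pd.DataFrame:
    """Minimal VCF: INFO keys GENE,CLASS,PPOS,RAA,AAA,VAF,CGC; tumor/normal AD."""
    import pysam

    def _info(info, key, default):
        try:
            return info[key]
        except KeyError:
            return default

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf):
            if rec.filter.keys() and "PASS" not in rec.filter.keys():
                continue
            info = rec.info
            t_ad = rec.samples[samples[0]]["AD"] if samples else (0, 0)
            n_ad = rec.samples[samples[1]]["AD"] if len(samples) > 1 else (0, 0)
            rows.append({
                "mutation_id": rec.id or f"var{i + 1}",
                "patient": samples[0] if samples else "",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
                "gene": _info(info, "GENE", ""),
                "mutation_class": _info(info, "CLASS", "missense"),
                "protein_pos": int(_info(info, "PPOS", 0)) or None,
                "ref_aa": _info(info, "RAA", ""),
                "alt_aa": _info(info, "AAA", ""),
                "vaf": float(_info(info, "VAF", t_ad[1] / max(sum(t_ad), 1))),
                "t_alt": int(t_ad[1]),
                "t_ref": int(t_ad[0]),
                "n_alt": int(n_ad[1]),
                "n_ref": int(n_ad[0]),
                "alt_fwd": int(_info(info, "SAF", t_ad[1])),
                "alt_rev": int(_info(info, "SAR", 0)),
                "baseq_site": float(_info(info, "BQS", 35.0)),
                "baseq_flank": float(_info(info, "BQF", 35.0)),
                "mapq_alt": float(_info(info, "MQA", 60.0)),
                "is_cgc": bool(int(_info(info, "CGC", 0))),
            })
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    bad = df.index[(df["vaf"] < 0) | (df["vaf"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: record {bad[0] + 1}: malformed VAF")
    return df


def write_mutation_table(df: pd.DataFrame, path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def evidence_from_row(row) -> ReadEvidence:
    """Build ReadEvidence from one mutation-table row."""
    return ReadEvidence(
        t_alt=int(row.t_alt), t_ref=int(row.t_ref),
        n_alt=int(row.n_alt), n_ref=int(row.n_ref),
        alt_fwd=int(row.alt_fwd), alt_rev=int(row.alt_rev),
        baseq_site=float(row.baseq_site), baseq_flank=float(row.baseq_flank),
        mapq_alt=float(row.mapq_alt),
    )


def apply_call_filters(
    ev: ReadEvidence, thresholds: dict | None = None
) -> FilterDecision:
    """Run the four post-call false-positive screens on read evidence."""
    th = dict(DEFAULT_FILTER_THRESHOLDS, **(thresholds or {}))
    alpha = th["alpha"]
    if ev.t_alt + ev.t_ref == 0:
        raise EvidenceError("zero tumor reads at the site")
    failed = []
    if ev.n_alt > 0:
        p = stats.fisher_exact_2x2(ev.t_alt, ev.t_ref, ev.n_alt, ev.n_ref,
                                   side="greater")
        if p >= alpha:
            failed.append("normal-contamination")
    if ev.t_alt > 0 and (ev.alt_fwd == 0 or ev.alt_rev == 0):
        p = stats.binomial_two_sided(ev.alt_fwd, ev.t_alt, 0.5)
        if p < alpha:
            failed.append("strand-bias")
    if ev.baseq_site < ev.baseq_flank - th["baseq_drop"]:
        failed.append("base-quality-drop")
    if ev.mapq_alt < th["min_mapq"]:
        failed.append("mapping-quality")
    return FilterDecision(passes=not failed, failed_criteria=tuple(failed))


def filter_mutations(
    mutations: pd.DataFrame,
    thresholds: dict | None = None,
    exclusion_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the post-call filters to every row of a mutation table.

    ``exclusion_genes`` stands in for germline-database subtraction.
    Adds ``filter_pass`` and ``filter_failed`` columns.
    """
    passes, failures = [], []
    for row in mutations.itertuples():
        if exclusion_genes and row.gene in exclusion_genes:
            passes.append(False)
            failures.append("exclusion-list")
            continue
        decision = apply_call_filters(evidence_from_row(row), thresholds)
        passes.append(decision.passes)
        failures.append(",".join(decision.failed_criteria))
    out = mutations.copy()
    out["filter_pass"] = passes
    out["filter_failed"] = failures
    return out


def recurrence_matrix(mutations: pd.DataFrame) -> pd.DataFrame:
    """Gene x patient matrix of mutation classes, ordered by recurrence.

    Cell values: "truncating" (nonsense SNV or frameshift indel),
    "altering" (missense or in-frame) or "" (no mutation).  Truncating
    takes precedence when a patient carries both classes in one gene.
    Genes are ordered by descending patient recurrence, ties by name.
    """
    if mutations.empty:
        return pd.DataFrame()
    sev = mutations.assign(
        _trunc=mutations["mutation_class"].isin(TRUNCATING)
    )
    cell = (
        sev.groupby(["gene", "patient"])["_trunc"]
        .max()
        .map({True: "truncating", False: "altering"})
        .unstack(fill_value="")
    )
    recurrence = (cell != "").sum(axis=1)
    order = sorted(cell.index, key=lambda g: (-recurrence[g], g))
    return cell.loc[order]


def vaf_concordance(pairs: pd.DataFrame):
    """Pearson concordance of matched primary/invasive tumor VAFs.

    ``pairs`` columns: mutation_id, vaf_primary, vaf_invasive; NaN marks
    a mutation private to the other tumor.  Returns (r, table) where the
    table lists shared mutations and private ones with VAF 0 imputed.
    """
    for col in ("mutation_id", "vaf_primary", "vaf_invasive"):
        if col not in pairs.columns:
            raise FormatError(f"pairs table missing column {col}")
    shared = pairs.dropna(subset=["vaf_primary", "vaf_invasive"])
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared mutations, got {len(shared)}"
        )
    x = shared["vaf_primary"].to_numpy(float)
    y = shared["vaf_invasive"].to_numpy(float)
    if np.var(x) == 0 and np.var(y) == 0 and np.allclose(x, y):
        r = 1.0  # identical constant vectors: perfectly concordant
    else:
        r, _ = stats.pearson(x, y)
    table = pairs.copy()
    table["shared"] = ~table[["vaf_primary", "vaf_invasive"]].isna().any(axis=1)
    table[["vaf_primary", "vaf_invasive"]] = table[
        ["vaf_primary", "vaf_invasive"]
    ].fillna(0.0)
    return float(r), table
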