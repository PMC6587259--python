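"""Neoepitope calling from peptide-HLA binding-affinity predictions.

Affinities are predicted IC50 values in nM (NetMHCpan convention; lower
is stronger).  A mutant peptide qualifies as a neoepitope when

1. its predicted affinity is below 150 nM (strong binder),
2. the mutant/wild-type affinity ratio is below 0.9, and
3. the wild-type minus mutant affinity difference is at least 100 nM
   -- except for peptides from Cancer Gene Census genes, which are
   exempt from the difference criterion.

Criteria 2-3 select *specific* binders: mutant peptides predicted to
bind appreciably more strongly than their wild-type counterpart, for
which T-cell precursors are less likely to have been deleted by central
tolerance.  A mutation generating several passing neoepitopes counts as
a single neoantigen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: default thresholds for the three neoepitope criteria
DEFAULT_THRESHOLDS = {"aff": 150.0, "ratio": 0.9, "diff": 100.0}

AFFINITY_COLUMNS = [
    "mutation_id",
    "mut_peptide",
    "wt_peptide",
    "allele",
    "mhc_class",
    "mut_nm",
    "wt_nm",
]


@dataclass(frozen=True)
class NeoepitopeCall:
    """Outcome of the three binding criteria for one peptide/allele."""

    passes: bool
    criteria_failed: tuple[str, ...] = field(default_factory=tuple)


def read_affinity_table(path: str) -> pd.DataFrame:
    """Read a NetMHCpan-style affinity TSV.

    Required columns: mutation_id, mut_peptide, wt_peptide, allele,
    mhc_class (I|II), mut_nm, wt_nm.  Rows with a missing wild-type
    affinity or a non-positive nM value are rejected with the offending
    row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str})
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("mut_nm", "wt_nm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(
                f"{path}: row {bad[0] + 2}: missing or non-numeric {col}"
            )
        df[col] = df[col].astype(float)
        nonpos = df.index[df[col] <= 0]
        if len(nonpos):
            raise FormatError(f"{path}: row {nonpos[0] + 2}: non-positive {col}")
    bad_class = df.index[~df["mhc_class"].isin(["I", "II"])]
    if len(bad_class):
        raise FormatError(f"{path}: row {bad_class[0] + 2}: mhc_class must be I or II")
    return df


def call_neoepitope(
    mut_nm: float,
    wt_nm: float,
    is_cgc: bool = False,
    thresholds: dict | None = None,
) -> NeoepitopeCall:
    """Apply the three binding criteria to one mutant/wild-type pair."""
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    if mut_nm <= 0 or wt_nm <= 0:
        raise ParameterError("affinities must be positive nM values")
    failed = []
    if not mut_nm < th["aff"]:
        failed.append("affinity")
    if not mut_nm / wt_nm < th["ratio"]:
        failed.append("ratio")
    if not (wt_nm - mut_nm >= th["diff"] or is_cgc):
        failed.append("difference")
    return NeoepitopeCall(passes=not failed, criteria_failed=tuple(failed))


def call_neoepitopes(
    affinities: pd.DataFrame,
    mutations: pd.DataFrame,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Vectorized criteria over an affinity table.

    ``mutations`` supplies the per-mutation CGC flag (columns
    mutation_id, is_cgc).  Returns the affinity frame with added
    boolean ``passes`` and string ``criteria_failed`` columns.
    """
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    df = affinities.merge(
        mutations[["mutation_id", "is_cgc"]], on="mutation_id", how="left"
    )
    df["is_cgc"] = df["is_cgc"].fillna(False).astype(bool)
    mut = df["mut_nm"].to_numpy()
    wt = df["wt_nm"].to_numpy()
    cgc = df["is_cgc"].to_numpy()
    fail_aff = ~(mut < th["aff"])
    fail_ratio = ~(mut / wt < th["ratio"])
    fail_diff = ~((wt - mut >= th["diff"]) | cgc)
    df["passes"] = ~(fail_aff | fail_ratio | fail_diff)
    df["criteria_failed"] = [
        ",".join(
            name
            for name, f in (("affinity", fa), ("ratio", fr), ("difference", fd))
            if f
        )
        for fa, fr, fd in zip(fail_aff, fail_ratio, fail_diff)
    ]
    return df


def collapse_neoantigens(
    called: pd.DataFrame, mutations: pd.DataFrame
) -> pd.DataFrame:
    """Collapse passing neoepitope calls into one candidate per mutation.

    The best call per MHC class is the passing call with minimal mutant
    nM; ties break by (nM, peptide length, allele name).  The class
    label is "both" when passing calls exist in both classes, otherwise
    "I-only" / "II-only".  Mutations without a passing call are absent
    from the output.
    """
    passing = called[called["passes"]].copy()
    if passing.empty:
        return _empty_candidates()
    passing["length"] = passing["mut_peptide"].str.len()
    passing = passing.sort_values(
        ["mutation_id", "mut_nm", "length", "allele"], kind="stable"
    )
    rows = []
    mut_info = mutations.set_index("mutation_id")
    for mutation_id, grp in passing.groupby("mutation_id", sort=True):
        best = {}
        for cls in ("I", "II"):
            sub = grp[grp["mhc_class"] == cls]
            if not sub.empty:
                best[cls] = sub.iloc[0]
        label = (
            "both"
            if len(best) == 2
            else ("I-only" if "I" in best else "II-only")
        )
        info = mut_info.loc[mutation_id]
        row = {
            "mutation_id": mutation_id,
            "patient": info.get("patient", ""),
            "gene": info.get("gene", ""),
            "is_cgc": bool(info.get("is_cgc", False)),
            "vaf": float(info.get("vaf", np.nan)),
            "class_label": label,
        }
        for cls, prefix in (("I", "i"), ("II", "ii")):
            if cls in best:
                b = best[cls]
                row[f"best_{prefix}_nm"] = float(b["mut_nm"])
                row[f"best_{prefix}_wt_nm"] = float(b["wt_nm"])
                row[f"best_{prefix}_peptide"] = b["mut_peptide"]
                row[f"best_{prefix}_allele"] = b["allele"]
            else:
                row[f"best_{prefix}_nm"] = np.nan
                row[f"best_{prefix}_wt_nm"] = np.nan
                row[f"best_{prefix}_peptide"] = ""
                row[f"best_{prefix}_allele"] = ""
        row["best_nm"] = np.nanmin([row["best_i_nm"], row["best_ii_nm"]])
        row["best_diff"] = np.nanmax(
            [
                row["best_i_wt_nm"] - row["best_i_nm"],
                row["best_ii_wt_nm"] - row["best_ii_nm"],
            ]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _empty_candidates() -> pd.DataFrame:
    cols = [
        "mutation_id", "patient", "gene", "is_cgc", "vaf", "class_label",
        "best_i_nm", "best_i_wt_nm", "best_i_peptide", "best_i_allele",
        "best_ii_nm", "best_ii_wt_nm", "best_ii_peptide", "best_ii_allele",
        "best_nm", "best_diff",
    ]
    return pd.DataFrame(columns=cols)


def classify_cohort(candidates: pd.DataFrame) -> dict:
    """Cohort counts by MHC class label and expression status.

    Returns exclusive category counts (I-only / II-only / both), the
    derived class-containing totals and, when an ``expressed`` column is
    present, the expressed / not-expressed split.
    """
    counts = {
        label: int((candidates.get("class_label", pd.Series(dtype=str)) == label).sum())
        for label in ("I-only", "II-only", "both")
    }
    total = sum(counts.values())
    out = {
        "I-only": counts["I-only"],
        "II-only": counts["II-only"],
        "both": counts["both"],
        "total": total,
        "class_I_containing": counts["I-only"] + counts["both"],
        "class_II_containing": counts["II-only"] + counts["both"],
    }
    if "expressed" in candidates.columns and total:
        expressed = candidates["expressed"].fillna(False).astype(bool)
        out["expressed"] = int(expressed.sum())
        out["not_expressed"] = int((~expressed).sum())
        for label in ("I-only", "II-only", "both"):
            mask = candidates["class_label"] == label
            out[f"{label}_expressed"] = int((mask & expressed).sum())
            out[f"{label}_not_expressed"] = int((mask & ~expressed).sum())
    return out
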