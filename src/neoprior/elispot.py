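"""IFN-gamma ELISpot response calling and cohort immunogenicity summary.

A neoepitope-specific T-cell response is positive when the mutant
peptide elicits at least 25 spot-forming cells per 5x10^4 plated cells
and at least two-fold the spot count of the matched wild-type peptide.
Spot counts are rescaled linearly to the 5x10^4-cell reference before
comparison; the mutant-vs-wild-type rule uses no background (no-peptide
well) subtraction by default.

A "response" is one positive (patient, target, subset, compartment)
combination, so the same peptide can contribute one TIL and one PBMC
response; an "immunogenic target" is a distinct (patient, target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, PairingError, ParameterError

DEFAULT_CONFIG = {"min_spots": 25.0, "fold": 2.0, "ref_cells": 5e4}

WELL_COLUMNS = ["patient", "target", "kind", "compartment", "subset",
                "spots", "cells"]
KINDS = ("mutant", "wildtype", "none", "pool")


@dataclass(frozen=True)
class ElispotWell:
    """Spot count for one peptide/compartment/subset well."""

    patient: str
    target: str
    kind: str  # mutant | wildtype | none
    compartment: str  # TIL | PBMC
    subset: str  # CD4 | CD8
    spots: float
    cells_plated: float
    is_pool: bool = False

    def __post_init__(self) -> None:
        if self.spots < 0:
            raise ParameterError("negative spot count")
        if self.cells_plated <= 0:
            raise ParameterError("cells_plated must be positive")
        if self.kind not in ("mutant", "wildtype", "none"):
            raise FormatError(f"unknown well kind {self.kind!r}")


@dataclass(frozen=True)
class ResponseCall:
    """Positivity decision for one mutant/wild-type well pair."""

    patient: str
    target: str
    subset: str
    compartment: str
    mut_spots_ref: float  # per reference cell count
    wt_spots_ref: float
    positive: bool
    fold: float
    is_pool: bool = False


def call_response(mut_well: ElispotWell, wt_well: ElispotWell,
                  config: dict | None = None,
                  background_well: ElispotWell | None = None) -> ResponseCall:
    """Positivity rule for one mutant/wild-type well pair.

    Counts are scaled to ``ref_cells``; positive iff scaled mutant
    spots >= ``min_spots`` and >= ``fold`` x scaled wild-type spots.
    When ``background_well`` is given, its scaled count is subtracted
    from both sides (off by default: the stated rule is mutant vs
    wild-type only).
    """
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    same_context = (
        mut_well.patient == wt_well.patient
        and mut_well.target == wt_well.target
        and mut_well.subset == wt_well.subset
        and mut_well.compartment == wt_well.compartment
    )
    if not same_context:
        raise PairingError(
            f"wells not from the same assay context: {mut_well} vs {wt_well}"
        )
    if mut_well.kind != "mutant" or wt_well.kind != "wildtype":
        raise PairingError("expected a (mutant, wildtype) well pair")
    ref = cfg["ref_cells"]
    mut = mut_well.spots * ref / mut_well.cells_plated
    wt = wt_well.spots * ref / wt_well.cells_plated
    if background_well is not None:
        bg = background_well.spots * ref / background_well.cells_plated
        mut = max(mut - bg, 0.0)
        wt = max(wt - bg, 0.0)
    fold = mut / wt if wt > 0 else math.inf
    positive = mut >= cfg["min_spots"] and mut >= cfg["fold"] * wt
    return ResponseCall(
        patient=mut_well.patient, target=mut_well.target,
        subset=mut_well.subset, compartment=mut_well.compartment,
        mut_spots_ref=mut, wt_spots_ref=wt, positive=positive, fold=fold,
        is_pool=mut_well.is_pool,
    )


def read_wells(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "target": str})
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = df.index[~df["kind"].isin(KINDS)]
    if len(bad):
        raise FormatError(f"{path}: row {bad[0] + 2}: unknown kind")
    return df


def pair_and_call(wells: pd.DataFrame, config: dict | None = None) -> list[ResponseCall]:
    """Pair mutant/wild-type wells per assay context and call responses.

    The ``kind`` column uses "pool" for pooled-peptide mutant wells;
    their wild-type partner is the matching "wildtype" row for the same
    target.  Contexts lacking either well are skipped.
    """
    calls = []
    grouped = wells.groupby(["patient", "target", "subset", "compartment"],
                            sort=True)
    for (patient, target, subset, compartment), grp in grouped:
        mut_rows = grp[grp["kind"].isin(["mutant", "pool"])]
        wt_rows = grp[grp["kind"] == "wildtype"]
        if mut_rows.empty or wt_rows.empty:
            continue
        m, w = mut_rows.iloc[0], wt_rows.iloc[0]
        mut_well = ElispotWell(patient, target, "mutant", compartment, subset,
                               float(m["spots"]), float(m["cells"]),
                               is_pool=(m["kind"] == "pool"))
        wt_well = ElispotWell(patient, target, "wildtype", compartment, subset,
                              float(w["spots"]), float(w["cells"]))
        calls.append(call_response(mut_well, wt_well, config))
    return calls


def summarize_cohort(calls: list[ResponseCall], n_patients: int | None = None) -> dict:
    """Cohort-level immunogenicity summary.

    Counts positive responses split by individual peptide vs pool, CD4
    vs CD8 and TIL vs PBMC; distinct immunogenic targets; per-patient
    responder flags; and targets detected in both compartments versus
    exclusively one.
    """
    if not calls:
        raise ParameterError("no response calls to summarize")
    df = pd.DataFrame([c.__dict__ for c in calls])
    pos = df[df["positive"]]
    pos_targets = pos.groupby(["patient", "target"], sort=True)
    both, exclusive = 0, 0
    for _, grp in pos_targets:
        n_comp = grp["compartment"].nunique()
        if n_comp >= 2:
            both += 1
        else:
            exclusive += 1
    screened = df.drop_duplicates(["patient", "target"])
    responders = sorted(pos["patient"].unique())
    summary = {
        "total_responses": int(len(pos)),
        "individual_responses": int((~pos["is_pool"]).sum()),
        "pool_responses": int(pos["is_pool"].sum()),
        "responses_cd4": int((pos["subset"] == "CD4").sum()),
        "responses_cd8": int((pos["subset"] == "CD8").sum()),
        "responses_til": int((pos["compartment"] == "TIL").sum()),
        "responses_pbmc": int((pos["compartment"] == "PBMC").sum()),
        "immunogenic_peptides": int(
            pos[~pos["is_pool"]].drop_duplicates(["patient", "target"]).shape[0]
        ),
        "immunogenic_pools": int(
            pos[pos["is_pool"]].drop_duplicates(["patient", "target"]).shape[0]
        ),
        "targets_both_compartments": both,
        "targets_single_compartment": exclusive,
        "responders": responders,
        "n_responders": len(responders),
        "n_patients": int(n_patients if n_patients is not None
                          else df["patient"].nunique()),
        "screened_peptides": int((~screened["is_pool"]).sum()),
        "screened_pools": int(screened["is_pool"].sum()),
    }
    return summary


def response_rate_by_expression(panel: pd.DataFrame,
                                immunogenic: set[tuple[str, str]]) -> dict:
    """Immunogenicity fractions split by mutant-allele expression status.

    ``panel`` lists screened individual peptides with columns patient,
    target and a boolean ``expressed``; ``immunogenic`` holds the
    (patient, target) pairs that elicited a response.  Returns counts
    and percentages (nearest integer) for each stratum.
    """
    for col in ("patient", "target", "expressed"):
        if col not in panel.columns:
            raise FormatError(f"panel table missing column {col}")
    hits = panel.apply(
        lambda r: (r["patient"], r["target"]) in immunogenic, axis=1)
    out = {}
    for label, mask in (("expressed", panel["expressed"].astype(bool)),
                        ("not_expressed", ~panel["expressed"].astype(bool))):
        n = int(mask.sum())
        k = int((mask & hits).sum())
        out[f"{label}_screened"] = n
        out[f"{label}_immunogenic"] = k
        out[f"{label}_percent"] = int(round(100.0 * k / n)) if n else 0
    return out


def validation_rate(summary: dict, denominator_rule: str = "individuals") -> int:
    """Percent of screened peptides validated as immunogenic.

    Numerator: immunogenic individual peptides plus immunogenic pools.
    Denominator under "individuals" (default): screened individual
    peptides; under "all-targets": screened peptides plus pools.
    Returns the nearest integer percent.
    """
    num = summary["immunogenic_peptides"] + summary["immunogenic_pools"]
    if denominator_rule == "individuals":
        den = summary["screened_peptides"]
    elif denominator_rule == "all-targets":
        den = summary["screened_peptides"] + summary["screened_pools"]
    else:
        raise ParameterError(f"unknown denominator rule {denominator_rule!r}")
    if den == 0:
        raise ParameterError("zero screened peptides in denominator")
    return int(round(100.0 * num / den))
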