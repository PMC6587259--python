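"""Candidate ranking, the Christmas Light Plot and panel selection.

Candidates are ranked per patient by a lexicographic policy over six
criteria: CGC gene membership, mutant binding affinity, mutant/wild-type
affinity difference, DNA VAF, expression (mutant-allele flag then gene
RPKM) and MHC class type (both > I > II).  The Christmas Light Plot
(CLP) lays the ranked landscape out with VAF on x, mutant affinity on an
inverted log y (stronger binders plot higher), dot size for gene
expression, glyph shape for MHC class and a vertical bar for the
wild-type minus mutant affinity difference.  Every rendered plot emits a
TSV sidecar of the plotted values so the encoding is testable without
image comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_CRITERIA = ("cgc", "affinity", "difference", "vaf", "expression", "class_type")
CLASS_PREFERENCE = {"both": 0, "I-only": 1, "II-only": 2}

REQUIRED_ANNOTATIONS = ("best_nm", "best_diff", "vaf", "expressed", "gene_rpkm")


@dataclass(frozen=True)
class RankPolicy:
    """Ordered lexicographic ranking criteria.

    Criteria names: cgc, affinity, difference, vaf, expression,
    class_type.  The final tie-break is always mutation id.
    """

    criteria: tuple[str, ...] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        unknown = set(self.criteria) - set(DEFAULT_CRITERIA)
        if unknown:
            raise ParameterError(f"unknown ranking criteria: {sorted(unknown)}")
        if len(set(self.criteria)) != len(self.criteria):
            raise ParameterError("ranking criteria must be unique")


def _sort_columns(df: pd.DataFrame, policy: RankPolicy) -> pd.DataFrame:
    keys = pd.DataFrame(index=df.index)
    for crit in policy.criteria:
        if crit == "cgc":
            keys["k_cgc"] = (~df["is_cgc"].astype(bool)).astype(int)
        elif crit == "affinity":
            keys["k_aff"] = df["best_nm"].astype(float)  # lower nM first
        elif crit == "difference":
            keys["k_diff"] = -df["best_diff"].astype(float)
        elif crit == "vaf":
            keys["k_vaf"] = -df["vaf"].astype(float)
        elif crit == "expression":
            keys["k_expr"] = (~df["expressed"].astype(bool)).astype(int)
            keys["k_rpkm"] = -df["gene_rpkm"].fillna(0.0).astype(float)
        elif crit == "class_type":
            keys["k_class"] = df["class_label"].map(CLASS_PREFERENCE)
    keys["k_id"] = df["mutation_id"].astype(str)
    return keys


def rank_candidates(candidates: pd.DataFrame, policy: RankPolicy | None = None,
                    per_patient: bool = True) -> pd.DataFrame:
    """Order candidates by the policy and set a 1-based ``rank`` column.

    Ranking is within patient by default (matching per-patient target
    selection); the output frame is sorted patient-major, rank-minor.
    """
    policy = policy or RankPolicy()
    missing = [c for c in REQUIRED_ANNOTATIONS if c not in candidates.columns]
    if missing:
        raise AnnotationError(
            f"candidates lack annotations required for ranking: {missing}"
        )
    if candidates.empty:
        out = candidates.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    keys = _sort_columns(candidates, policy)
    df = pd.concat([candidates.reset_index(drop=True),
                    keys.reset_index(drop=True)], axis=1)
    key_cols = [c for c in keys.columns]
    if per_patient and "patient" in df.columns:
        df = df.sort_values(["patient"] + key_cols, kind="stable")
        df["rank"] = df.groupby("patient").cumcount() + 1
    else:
        df = df.sort_values(key_cols, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns=key_cols).reset_index(drop=True)


def select_panel(ranked: pd.DataFrame, panel_size: int,
                 nonexpressed_quota: int = 0) -> pd.DataFrame:
    """Select a synthesis panel: top expressed plus a non-expressed quota.

    Non-expressed candidates are deliberately included to probe the link
    between expression and T-cell response induction.  A shortfall of
    non-expressed candidates is back-filled with expressed ones.
    """
    if nonexpressed_quota > panel_size:
        raise ParameterError("nonexpressed_quota exceeds panel_size")
    if panel_size > len(ranked):
        raise ParameterError(
            f"panel_size {panel_size} exceeds candidate count {len(ranked)}"
        )
    df = ranked.sort_values("rank", kind="stable")
    expressed = df[df["expressed"].astype(bool)]
    nonexpressed = df[~df["expressed"].astype(bool)]
    take_non = nonexpressed.head(nonexpressed_quota)
    shortfall = nonexpressed_quota - len(take_non)
    if shortfall:
        logger.info("non-expressed shortfall of %d filled by expressed", shortfall)
    take_expr = expressed.head(panel_size - nonexpressed_quota + shortfall)
    # if expressed candidates run short, fall back to remaining non-expressed
    panel = pd.concat([take_expr, take_non])
    if len(panel) < panel_size:
        rest = df.loc[~df.index.isin(panel.index)].head(panel_size - len(panel))
        panel = pd.concat([panel, rest])
    return panel.sort_values("rank", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class ClpStyle:
    """Visual encoding of the Christmas Light Plot."""

    min_dot: float = 20.0
    dot_scale: float = 60.0
    shapes: dict = field(default_factory=lambda: {
        "I-only": "o", "II-only": "s", "both": "^"
    })
    stratum_colors: dict = field(default_factory=lambda: {
        "specific-expressed": "#d62728",
        "specific-not-expressed": "#ff9896",
        "nonspecific-expressed": "#1f77b4",
        "nonspecific-not-expressed": "#aec7e8",
    })
    specific_ratio: float = 0.5  # mut/wt below this counts as highly specific


def _stratum(row, style: ClpStyle) -> str:
    ratio = row.best_nm / max(row.best_nm + row.best_diff, 1e-12)
    spec = "specific" if ratio < style.specific_ratio else "nonspecific"
    expr = "expressed" if bool(row.expressed) else "not-expressed"
    return f"{spec}-{expr}"


def clp_data(candidates: pd.DataFrame, style: ClpStyle | None = None,
             label_ids: set | None = None) -> pd.DataFrame:
    """The exact values a CLP rendering displays, one row per glyph."""
    style = style or ClpStyle()
    rpkm = candidates["gene_rpkm"].fillna(0.0).astype(float)
    size = style.min_dot + style.dot_scale * np.log10(1.0 + rpkm)
    data = pd.DataFrame({
        "mutation_id": candidates["mutation_id"],
        "gene": candidates.get("gene", ""),
        "x_vaf": candidates["vaf"].astype(float),
        "y_nm": candidates["best_nm"].astype(float),
        "bar_diff_nm": candidates["best_diff"].astype(float),
        "size": size.clip(lower=style.min_dot),
        "shape": candidates["class_label"].map(style.shapes),
        "stratum": [
            _stratum(r, style) for r in candidates.itertuples()
        ],
        "labeled": candidates["mutation_id"].isin(label_ids or set()),
    })
    return data.reset_index(drop=True)


def render_clp(candidates: pd.DataFrame, path: str,
               style: ClpStyle | None = None,
               label_ids: set | None = None) -> pd.DataFrame:
    """Render the Christmas Light Plot to ``path`` (+ a ``.tsv`` sidecar).

    Returns the sidecar frame.  The y axis is log-scaled and inverted so
    that stronger binding (lower nM) plots higher.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if candidates.empty:
        raise ParameterError("cannot render a CLP with no candidates")
    style = style or ClpStyle()
    data = clp_data(candidates, style, label_ids)

    fig, ax = plt.subplots(figsize=(7, 5))
    for _, row in data.iterrows():
        # vertical bar up to the (weaker) wild-type affinity
        ax.plot([row.x_vaf, row.x_vaf], [row.y_nm, row.y_nm + row.bar_diff_nm],
                color="#888888", lw=1, zorder=1)
    for shape in sorted(data["shape"].dropna().unique()):
        sub = data[data["shape"] == shape]
        label = {v: k for k, v in style.shapes.items()}[shape]
        ax.scatter(sub["x_vaf"], sub["y_nm"], s=sub["size"], marker=shape,
                   c=[style.stratum_colors[s] for s in sub["stratum"]],
                   edgecolors="black", linewidths=0.5, zorder=2,
                   label=f"class {label}")
    for _, row in data[data["labeled"]].iterrows():
        ax.annotate(str(row.gene), (row.x_vaf, row.y_nm), fontsize=7,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_yscale("log")
    ax.invert_yaxis()  # lower nM (stronger binding) on top
    ax.set_xlabel("variant allele fraction (WES)")
    ax.set_ylabel("mutant binding affinity (nM, IC50)")
    ax.legend(fontsize=8, title="MHC binding")
    fig.tight_layout()
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out)
    plt.close(fig)
    sidecar = out.with_suffix(out.suffix + ".tsv")
    data.to_csv(sidecar, sep="\t", index=False)
    return data
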