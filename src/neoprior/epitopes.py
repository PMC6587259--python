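"""Mutant/wild-type peptide enumeration around missense variants.

For every missense substitution, all 8-15-mer windows of the protein
that contain the mutated residue are emitted as mutant/wild-type peptide
pairs.  These pairs feed MHC binding-affinity prediction: class I
predictions conventionally use the 8-11-mer subset, class II the
13-15-mer subset, both configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: residues that invalidate a peptide window for affinity prediction
AMBIGUOUS_RESIDUES = frozenset("UXBZJO*")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIN_LENGTH = 8
MAX_LENGTH = 15
CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (13, 14, 15)


@dataclass(frozen=True)
class ProteinContext:
    """A protein sequence with one missense substitution.

    ``position`` is 1-based; the sequence must carry ``ref_aa`` there.
    """

    gene: str
    sequence: str
    position: int
    ref_aa: str
    alt_aa: str
    mutation_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.sequence):
            raise ParameterError(
                f"{self.gene}: position {self.position} outside protein "
                f"of length {len(self.sequence)}"
            )
        if self.sequence[self.position - 1] != self.ref_aa:
            raise FormatError(
                f"{self.gene}: reference residue mismatch at {self.position} "
                f"(sequence has {self.sequence[self.position - 1]!r}, "
                f"expected {self.ref_aa!r})"
            )
        if self.ref_aa == self.alt_aa:
            raise ParameterError(f"{self.gene}: synonymous substitution")


@dataclass(frozen=True)
class PeptidePair:
    """Equal-length mutant/wild-type peptides differing at one offset."""

    mutant: str
    wildtype: str
    length: int
    offset: int  # 1-based position of the mutated residue in the peptide
    mutation_id: str = ""


def enumerate_peptide_pairs(
    ctx: ProteinContext,
    lengths: Iterable[int] = range(MIN_LENGTH, MAX_LENGTH + 1),
) -> list[PeptidePair]:
    """All peptide windows covering the mutated residue, per length.

    For each length L every window fully inside the protein that covers
    the mutated position is emitted left-to-right.  Windows containing
    ambiguous residues (U, X, ...) are skipped with a warning.
    """
    lengths = sorted(set(int(L) for L in lengths))
    if any(L < MIN_LENGTH or L > MAX_LENGTH for L in lengths):
        raise ParameterError(f"peptide lengths must lie in [{MIN_LENGTH}, {MAX_LENGTH}]")
    seq = ctx.sequence
    pos = ctx.position
    n = len(seq)
    pairs: list[PeptidePair] = []
    for L in lengths:
        first = max(1, pos - L + 1)
        last = min(pos, n - L + 1)
        for start in range(first, last + 1):
            wt = seq[start - 1 : start - 1 + L]
            offset = pos - start + 1
            if AMBIGUOUS_RESIDUES & set(wt) or ctx.alt_aa in AMBIGUOUS_RESIDUES:
                logger.warning(
                    "skipping window with ambiguous residue: %s (%s)", wt, ctx.gene
                )
                continue
            mut = wt[: offset - 1] + ctx.alt_aa + wt[offset:]
            pairs.append(
                PeptidePair(
                    mutant=mut,
                    wildtype=wt,
                    length=L,
                    offset=offset,
                    mutation_id=ctx.mutation_id,
                )
            )
    return pairs


def validate_pair(pair: PeptidePair) -> tuple[bool, list[str]]:
    """Check the PeptidePair invariants; returns (ok, reasons)."""
    reasons: list[str] = []
    if len(pair.mutant) != len(pair.wildtype):
        reasons.append("unequal lengths")
    else:
        if len(pair.mutant) != pair.length:
            reasons.append("stated length disagrees with peptides")
        diffs = [
            i + 1
            for i, (m, w) in enumerate(zip(pair.mutant, pair.wildtype))
            if m != w
        ]
        if diffs != [pair.offset]:
            reasons.append(
                f"peptides differ at positions {diffs}, expected [{pair.offset}]"
            )
    if not 1 <= pair.offset <= max(len(pair.mutant), 1):
        reasons.append("offset outside peptide")
    return (not reasons), reasons


def contexts_from_fasta(
    proteins_path: str, mutations: pd.DataFrame
) -> list[ProteinContext]:
    """Build ProteinContexts from a gene-keyed FASTA and a mutation table.

    Only missense rows are used; rows whose gene is absent from the
    FASTA are skipped with a warning.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(proteins_path, "fasta")}
    contexts = []
    for row in mutations.itertuples():
        if row.mutation_class != "missense":
            continue
        seq = seqs.get(row.gene)
        if seq is None:
            logger.warning("no protein sequence for gene %s; skipped", row.gene)
            continue
        contexts.append(
            ProteinContext(
                gene=row.gene,
                sequence=seq,
                position=int(row.protein_pos),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                mutation_id=row.mutation_id,
            )
        )
    return contexts


def pairs_to_frame(pairs: Sequence[PeptidePair]) -> pd.DataFrame:
    """Tabulate peptide pairs (mutation_id, length, offset, peptides)."""
    return pd.DataFrame(
        {
            "mutation_id": [p.mutation_id for p in pairs],
            "length": [p.length for p in pairs],
            "offset": [p.offset for p in pairs],
            "mut_peptide": [p.mutant for p in pairs],
            "wt_peptide": [p.wildtype for p in pairs],
        }
    )
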