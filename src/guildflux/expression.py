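"""Metatranscriptomic quantification and functional aggregation.

Per-CDS read counts are converted to TPM and rolled up through a
CDS -> gene -> enzyme complex -> reaction -> pathway hierarchy:

* complex value   = mean TPM over its subunit genes (copies of one subunit
  are summed first; declared-but-missing subunits contribute 0, flagged);
* reaction value  = sum over alternate complexes (e.g. nar + nap);
* pathway value   = mean over the pathway's reactions.

Two alignment-filter dialects are provided: the metagenomic one removes on
``<=`` at 0.90/0.97 and the metatranscriptomic one removes on ``<`` at
0.95/0.97.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CDSRecord",
    "AlignmentRecord",
    "FunctionMap",
    "ExpressionTable",
    "AggregateResult",
    "filter_alignments",
    "metagenomic_filter",
    "metatranscriptomic_filter",
    "count_reads",
    "compute_tpm",
    "complex_expression",
    "reaction_expression",
    "pathway_expression",
    "mag_expression_fraction",
    "mag_relative_abundance",
    "relativize_to_median",
]

UNBINNED = "unbinned"
NOT_ENCODED = "not encoded"
UNDETECTABLE = "undetectable"


@dataclass(frozen=True)
class CDSRecord:
    """One protein-coding sequence and its annotation."""

    cds_id: str
    genome_id: str = UNBINNED
    gene_symbol: str = ""
    complex_id: str = ""
    length: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"CDS {self.cds_id!r}: length must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.cds_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-target alignment summary."""

    read_id: str
    target_id: str
    read_length: int
    aligned_length: int
    identity: float

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"{self.read_id!r}: read_length must be > 0")
        if self.aligned_length > self.read_length:
            raise ValueError(
                f"{self.read_id!r}: aligned_length exceeds read_length"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.read_id!r}: identity must be in [0, 1]")

    @property
    def aligned_frac(self) -> float:
        return self.aligned_length / self.read_length


@dataclass(frozen=True)
class FunctionMap:
    """CDS->gene->complex->reaction->pathway aggregation hierarchy.

    ``complexes`` maps a complex id to the ordered tuple of member gene
    symbols; ``reactions`` maps a reaction id to its alternate complexes;
    ``pathways`` maps a pathway id to its member reactions.
    """

    complexes: Mapping[str, Tuple[str, ...]]
    reactions: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)
    pathways: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        complexes = {k: tuple(v) for k, v in self.complexes.items()}
        reactions = {k: tuple(v) for k, v in self.reactions.items()}
        pathways = {k: tuple(v) for k, v in self.pathways.items()}
        for name, mapping in (
            ("complex", complexes),
            ("reaction", reactions),
            ("pathway", pathways),
        ):
            for key, members in mapping.items():
                if not members:
                    raise ValueError(f"{name} {key!r} has no members")
        for rxn, cxs in reactions.items():
            for cx in cxs:
                if cx not in complexes:
                    raise ValueError(
                        f"reaction {rxn!r} references undefined complex {cx!r}"
                    )
        for pw, rxns in pathways.items():
            for rxn in rxns:
                if rxn not in reactions:
                    raise ValueError(
                        f"pathway {pw!r} references undefined reaction {rxn!r}"
                    )
        object.__setattr__(self, "complexes", complexes)
        object.__setattr__(self, "reactions", reactions)
        object.__setattr__(self, "pathways", pathways)


def filter_alignments(
    records: Sequence[AlignmentRecord],
    min_aligned_frac: float = 0.95,
    min_identity: float = 0.97,
    strict: bool = False,
) -> List[AlignmentRecord]:
    """Drop low-quality alignments, preserving input order.

    ``strict=True`` removes records with aligned fraction or identity
    less than *or equal to* the thresholds (metagenomic dialect);
    ``strict=False`` removes strictly-below records only, so equality
    survives (metatranscriptomic dialect).
    """
    for name, thr in (("min_aligned_frac", min_aligned_frac), ("min_identity", min_identity)):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    out = []
    for rec in records:
        if strict:
            removed = rec.aligned_frac <= min_aligned_frac or rec.identity <= min_identity
        else:
            removed = rec.aligned_frac < min_aligned_frac or rec.identity < min_identity
        if not removed:
            out.append(rec)
    return out


def metagenomic_filter(records: Sequence[AlignmentRecord]) -> List[AlignmentRecord]:
    """Metagenomic dialect: remove on <= at 0.90 aligned fraction / 0.97 identity."""
    return filter_alignments(records, 0.90, 0.97, strict=True)


def metatranscriptomic_filter(records: Sequence[AlignmentRecord]) -> List[AlignmentRecord]:
    """Metatranscriptomic dialect: remove on < at 0.95 aligned fraction / 0.97 identity."""
    return filter_alignments(records, 0.95, 0.97, strict=False)


def count_reads(
    records: Sequence[AlignmentRecord],
) -> Tuple[Dict[str, int], int]:
    """Assign each read to its best alignment's target and tally per target.

    Best = highest identity, then longest aligned length; remaining ties go
    to the first-listed target.  Returns (counts per target, tie count).
    """
    best: Dict[str, AlignmentRecord] = {}
    ties = 0
    for rec in records:
        cur = best.get(rec.read_id)
        if cur is None:
            best[rec.read_id] = rec
            continue
        key_new = (rec.identity, rec.aligned_length)
        key_cur = (cur.identity, cur.aligned_length)
        if key_new > key_cur:
            best[rec.read_id] = rec
        elif key_new == key_cur and rec.target_id != cur.target_id:
            ties += 1  # first-listed target kept
    counts: Dict[str, int] = {}
    for rec in best.values():
        counts[rec.target_id] = counts.get(rec.target_id, 0) + 1
    return counts, ties


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: (c_i/L_i) / sum_j(c_j/L_j) * 1e6.

    All-zero counts return all-zero TPM.
    """
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if c.shape != L.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(L <= 0):
        raise ValueError("all CDS lengths must be > 0")
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    rates = c / L
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return rates / total * 1e6


@dataclass
class ExpressionTable:
    """Per-CDS counts and TPM with genome/gene annotation.

    Backed by a DataFrame with columns ``cds_id``, ``genome_id``,
    ``gene_symbol``, ``complex_id``, ``length``, ``count``, ``tpm``.
    """

    data: pd.DataFrame

    COLUMNS = ("cds_id", "genome_id", "gene_symbol", "complex_id", "length", "count", "tpm")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        if self.data["cds_id"].duplicated().any():
            dup = self.data.loc[self.data["cds_id"].duplicated(), "cds_id"].iloc[0]
            raise ValueError(f"duplicate cds_id {dup!r}")
        if (self.data["tpm"] < 0).any():
            raise ValueError("TPM values must be >= 0")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_counts(
        cls,
        cds_records: Sequence[CDSRecord],
        counts: Mapping[str, int] | Sequence[int],
    ) -> "ExpressionTable":
        """Build a table from CDS annotations plus per-CDS counts.

        ``counts`` is either a mapping cds_id -> count (absent ids count 0)
        or a sequence aligned with ``cds_records``.  Fractional counts are
        allowed (e.g. expectation counts from the synthetic generator).
        """
        if isinstance(counts, Mapping):
            count_vec = [float(counts.get(r.cds_id, 0)) for r in cds_records]
        else:
            if len(counts) != len(cds_records):
                raise ValueError("counts sequence length mismatch")
            count_vec = [float(c) for c in counts]
        lengths = [r.length for r in cds_records]
        tpm = compute_tpm(count_vec, lengths)
        df = pd.DataFrame(
            {
                "cds_id": [r.cds_id for r in cds_records],
                "genome_id": [r.genome_id for r in cds_records],
                "gene_symbol": [r.gene_symbol for r in cds_records],
                "complex_id": [r.complex_id for r in cds_records],
                "length": lengths,
                "count": count_vec,
                "tpm": tpm,
            }
        )
        return cls(df)

    def genome(self, genome_id: str) -> pd.DataFrame:
        return self.data[self.data["genome_id"] == genome_id]

    def gene_tpm(self, genome_id: str, gene_symbol: str) -> float:
        """Summed TPM over all CDS copies of one gene in one genome."""
        sub = self.genome(genome_id)
        return float(sub.loc[sub["gene_symbol"] == gene_symbol, "tpm"].sum())


@dataclass
class AggregateResult:
    """Aggregated expression values plus per-key diagnostic flags."""

    values: Dict[str, float]
    flags: Dict[str, str] = field(default_factory=dict)


def complex_expression(
    table: ExpressionTable, function_map: FunctionMap, genome_id: str
) -> AggregateResult:
    """Per-complex expression for one genome: mean TPM over subunit genes.

    Multiple CDS copies of one subunit are summed before averaging across
    subunits.  Declared subunits with no CDS in the genome contribute 0 and
    are flagged; a complex with no resolvable member at all is omitted from
    ``values`` and flagged "not encoded".
    """
    sub = table.genome(genome_id)
    present_genes = set(sub["gene_symbol"])
    values: Dict[str, float] = {}
    flags: Dict[str, str] = {}
    for cx, members in function_map.complexes.items():
        found = [g for g in members if g in present_genes]
        if not found:
            flags[cx] = NOT_ENCODED
            continue
        member_tpm = [table.gene_tpm(genome_id, g) if g in present_genes else 0.0
                      for g in members]
        values[cx] = float(np.mean(member_tpm))
        missing = [g for g in members if g not in present_genes]
        if missing:
            flags[cx] = "missing subunits: " + ",".join(missing)
    return AggregateResult(values, flags)


def reaction_expression(
    complex_values: Mapping[str, float] | AggregateResult,
    function_map: FunctionMap,
) -> AggregateResult:
    """Per-reaction expression: sum over alternate complexes.

    Complexes absent from ``complex_values`` (not encoded) contribute 0.
    """
    if isinstance(complex_values, AggregateResult):
        complex_values = complex_values.values
    values: Dict[str, float] = {}
    flags: Dict[str, str] = {}
    for rxn, alternates in function_map.reactions.items():
        encoded = [cx for cx in alternates if cx in complex_values]
        values[rxn] = float(sum(complex_values[cx] for cx in encoded))
        if not encoded:
            flags[rxn] = NOT_ENCODED
    return AggregateResult(values, flags)


def pathway_expression(
    reaction_values: Mapping[str, float] | AggregateResult,
    function_map: FunctionMap,
) -> AggregateResult:
    """Per-pathway expression: mean over the pathway's reactions.

    Reactions absent from ``reaction_values`` count as 0 and are flagged.
    """
    if isinstance(reaction_values, AggregateResult):
        flags_in = reaction_values.flags
        reaction_values = reaction_values.values
    else:
        flags_in = {}
    values: Dict[str, float] = {}
    flags: Dict[str, str] = {}
    for pw, rxns in function_map.pathways.items():
        vals = [reaction_values.get(rxn, 0.0) for rxn in rxns]
        values[pw] = float(np.mean(vals))
        absent = [
            rxn for rxn in rxns
            if rxn not in reaction_values or flags_in.get(rxn) == NOT_ENCODED
        ]
        if len(absent) == len(rxns):
            flags[pw] = NOT_ENCODED
        elif absent:
            flags[pw] = "missing reactions: " + ",".join(absent)
    return AggregateResult(values, flags)


def mag_expression_fraction(table: ExpressionTable) -> pd.Series:
    """Percent of total TPM contributed by each genome (incl. unbinned).

    Fractions over all genomes sum to 100 whenever any TPM is nonzero.
    """
    totals = table.data.groupby("genome_id")["tpm"].sum()
    return totals / 1e6 * 100.0


def mag_relative_abundance(
    mapped_read_counts: Mapping[str, int], total_trimmed_reads: int
) -> Tuple[Dict[str, float], float]:
    """Percent of total trimmed reads mapped to each genome, plus remainder."""
    if total_trimmed_reads <= 0:
        raise ValueError("total_trimmed_reads must be > 0")
    percents = {
        g: 100.0 * c / total_trimmed_reads for g, c in mapped_read_counts.items()
    }
    mapped = sum(mapped_read_counts.values())
    if mapped > total_trimmed_reads:
        raise ValueError("mapped reads exceed total trimmed reads")
    remainder = 100.0 * (total_trimmed_reads - mapped) / total_trimmed_reads
    return percents, remainder


def relativize_to_median(table: ExpressionTable, mode: str = "log2") -> pd.DataFrame:
    """Relativize per-CDS TPM to the genome-wide median TPM.

    ``mode="log2"`` (default) returns log2(TPM/median), so a value of one
    means twice the median expression; ``mode="ratio"`` returns the plain
    TPM/median ratio.  Zero-TPM CDS are flagged undetectable (value NaN)
    rather than assigned -inf; a genome whose median is 0 has every CDS
    flagged.
    """
    if mode not in ("log2", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = []
    for genome_id, sub in table.data.groupby("genome_id", sort=False):
        med = float(sub["tpm"].median())
        values = np.full(len(sub), np.nan)
        flags = np.empty(len(sub), dtype=object)
        flags[:] = ""
        tpm = sub["tpm"].to_numpy(float)
        if med > 0:
            pos = tpm > 0
            ratio = tpm[pos] / med
            values[pos] = np.log2(ratio) if mode == "log2" else ratio
            flags[~pos] = UNDETECTABLE
        else:
            flags[:] = UNDETECTABLE
        frames.append(
            pd.DataFrame(
                {
                    "cds_id": sub["cds_id"].to_numpy(),
                    "genome_id": genome_id,
                    "value": values,
                    "flag": flags,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
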