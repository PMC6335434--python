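"""HLA class II eluted-peptide filtering and source-protein mapping.

Eluted peptides are retained when they are 12-34 residues long and their
predicted binding affinity is strictly below 500 nM IC50 (lower IC50 =
stronger predicted binding). Retained peptides are mapped back to candidate
protein sequences by exact substring search; coordinates are kept 0-based
half-open internally and reported 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, DataError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    allele: str
    predicted_ic50: float      # nM
    cell_line: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideOccurrence:
    """One exact match of a retained peptide within a protein sequence."""

    protein_id: str
    peptide: PeptideRecord
    start: int                 # 0-based, half-open internally

    @property
    def end(self) -> int:
        return self.start + self.peptide.length

    @property
    def report_position(self) -> tuple[int, int]:
        """1-based inclusive (start, end) for human-readable reports."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class EpitopeEvidence:
    """All peptide-level support for one candidate protein."""

    protein_id: str
    occurrences: tuple
    best_ic50_per_allele: Mapping[str, float]

    @property
    def n_distinct_peptides(self) -> int:
        return len({o.peptide.sequence for o in self.occurrences})


def validate_peptide(sequence: str) -> str | None:
    """Return a rejection reason for an invalid peptide, or None if valid."""
    if not sequence:
        return "empty sequence"
    bad = sorted(set(sequence.upper()) - AMINO_ACIDS)
    if bad:
        return f"invalid residue(s): {''.join(bad)}"
    return None


def filter_hla2_peptides(
    peptides: Iterable[PeptideRecord],
    min_len: int = 12,
    max_len: int = 34,
    ic50_threshold: float = 500.0,
) -> tuple[list, list]:
    """Apply the length-window and strict-IC50 filters.

    Returns ``(retained, rejected)`` where each rejected entry is a
    ``(record, reason)`` pair. The IC50 comparison is strict: a peptide at
    exactly the threshold is removed.
    """
    if min_len > max_len or min_len < 1:
        raise ConfigurationError("need 1 <= min_len <= max_len")
    if ic50_threshold <= 0:
        raise ConfigurationError("ic50_threshold must be positive")
    retained, rejected = [], []
    for rec in peptides:
        reason = validate_peptide(rec.sequence)
        if reason is None and not min_len <= rec.length <= max_len:
            reason = f"length {rec.length} outside [{min_len}, {max_len}]"
        if reason is None and not rec.predicted_ic50 < ic50_threshold:
            reason = f"predicted IC50 {rec.predicted_ic50} nM not < {ic50_threshold} nM"
        if reason is None:
            retained.append(rec)
        else:
            rejected.append((rec, reason))
    return retained, rejected


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def map_peptides_to_sources(
    peptides: Iterable[PeptideRecord],
    proteins: Mapping[str, str],
    collapse_il: bool = False,
) -> tuple[list, list]:
    """Exact-substring mapping of peptides onto protein sequences.

    Every occurrence in every protein is reported; peptides found nowhere are
    returned in the unmapped list. ``collapse_il`` treats leucine and
    isoleucine as equivalent (they are isobaric in MS), off by default.
    Returns ``(evidence_list, unmapped_peptides)``.
    """
    peptides = list(peptides)
    proteins = dict(proteins)
    if any(not seq for seq in proteins.values()):
        raise DataError("protein sequences must be non-empty")

    def canon(s: str) -> str:
        s = s.upper()
        return s.replace("I", "L") if collapse_il else s

    searchable = {pid: canon(seq) for pid, seq in proteins.items()}
    by_protein: dict[str, list] = {}
    unmapped = []
    for rec in peptides:
        target = canon(rec.sequence)
        hit = False
        for pid, seq in searchable.items():
            for start in _find_all(seq, target):
                by_protein.setdefault(pid, []).append(
                    PeptideOccurrence(protein_id=pid, peptide=rec, start=start)
                )
                hit = True
        if not hit:
            unmapped.append(rec)
    evidence = []
    for pid in sorted(by_protein):
        occs = tuple(sorted(by_protein[pid], key=lambda o: (o.start, o.peptide.sequence)))
        best: dict[str, float] = {}
        for occ in occs:
            allele = occ.peptide.allele
            ic50 = occ.peptide.predicted_ic50
            best[allele] = min(best.get(allele, float("inf")), ic50)
        evidence.append(EpitopeEvidence(
            protein_id=pid, occurrences=occs, best_ic50_per_allele=best,
        ))
    return evidence, unmapped


def read_peptide_table(path: str | Path) -> list:
    """Read a peptide TSV with columns sequence, allele, ic50_nM, cell_line."""
    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "allele", "ic50_nM", "cell_line"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"peptide table missing column(s): {sorted(missing)}")
    return [
        PeptideRecord(sequence=str(r.sequence), allele=str(r.allele),
                      predicted_ic50=float(r.ic50_nM), cell_line=str(r.cell_line))
        for r in df.itertuples()
    ]


def read_protein_fasta(path: str | Path) -> dict:
    """Protein id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def evidence_table(evidence: Iterable[EpitopeEvidence]) -> pd.DataFrame:
    """Tidy per-occurrence table with 1-based inclusive positions."""
    rows = []
    for ev in evidence:
        for occ in ev.occurrences:
            start, end = occ.report_position
            rows.append({
                "protein_id": ev.protein_id,
                "peptide": occ.peptide.sequence,
                "allele": occ.peptide.allele,
                "ic50_nM": occ.peptide.predicted_ic50,
                "cell_line": occ.peptide.cell_line,
                "start_1based": start,
                "end_1based_inclusive": end,
            })
    return pd.DataFrame(
        rows, columns=["protein_id", "peptide", "allele", "ic50_nM",
                       "cell_line", "start_1based", "end_1based_inclusive"],
    )
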