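"""Mapping epitope patterns onto antigen protein sequences.

A discovered pattern is placed on a protein wherever every one of its
fixed residues is identical to the protein residue at the aligned
position (wildcards unconstrained). Antigens matched by patterns from
two independent epitope sets (e.g. disease-specific and
treatment-specific) can be recruited by intersection, and each antigen
scored by the mean repertoire abundance of the patterns aligning to it.
Coordinates are 1-based inclusive, the protein-annotation convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import EpitopePattern, as_pattern, pattern_abundance
from .repertoire import PeptideRepertoire, CANONICAL_RESIDUES

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


class AntigenError(ValueError):
    """Invalid antigen input."""


@dataclass(frozen=True)
class AntigenRecord:
    """One antigen protein sequence."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AntigenError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise AntigenError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class LinearEpitope:
    """A linear database epitope with its parent protein accession."""

    sequence: str
    parent_accession: str
    parent_name: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AntigenError("empty epitope sequence")


@dataclass(frozen=True)
class AlignmentHit:
    """A pattern placed on an antigen; start/end are 1-based inclusive."""

    pattern: EpitopePattern
    accession: str
    start: int
    end: int


def read_fasta(path: str | Path) -> list[AntigenRecord]:
    """Read antigen records from FASTA (first header token = accession)."""
    records: list[AntigenRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        name = rec.description[len(rec.id):].strip()
        seq = str(rec.seq).upper().rstrip("*")
        if accession in seen:
            raise AntigenError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(AntigenRecord(accession=accession, name=name, sequence=seq))
    if not records:
        raise AntigenError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[AntigenRecord], path: str | Path) -> None:
    SeqIO.write(
        [
            SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
            for r in records
        ],
        str(path),
        "fasta",
    )


def read_linear_epitopes(path: str | Path) -> list[LinearEpitope]:
    """Read a linear-epitope CSV (epitope_sequence, parent_accession[, parent_name])."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"epitope_sequence", "parent_accession"}
    if not required.issubset(df.columns):
        raise AntigenError(
            f"{path}: epitope table needs columns {sorted(required)}"
        )
    return [
        LinearEpitope(
            sequence=row.epitope_sequence.upper(),
            parent_accession=row.parent_accession,
            parent_name=getattr(row, "parent_name", ""),
        )
        for row in df.itertuples(index=False)
    ]


def _pattern_regex(pattern: EpitopePattern) -> re.Pattern:
    # Residue letters and '.' are regex-safe as written; the lookahead
    # yields overlapping occurrences.
    return re.compile(f"(?=({pattern.symbols}))")


def align_pattern_to_sequence(
    pattern: EpitopePattern | str, antigen: AntigenRecord
) -> list[AlignmentHit]:
    """All placements of the pattern on the antigen (overlaps allowed).

    A placement requires every fixed residue of the pattern to be
    identical to the antigen residue at its offset; hits are sorted by
    start position.
    """
    pat = as_pattern(pattern)
    hits = [
        AlignmentHit(
            pattern=pat,
            accession=antigen.accession,
            start=m.start() + 1,
            end=m.start() + pat.span,
        )
        for m in _pattern_regex(pat).finditer(antigen.sequence)
    ]
    return hits


def match_pattern_to_linear_epitopes(
    pattern: EpitopePattern | str, epitopes: list[LinearEpitope]
) -> list[tuple[EpitopePattern, LinearEpitope]]:
    """Pairs (pattern, epitope) where the pattern occurs inside the epitope."""
    pat = as_pattern(pattern)
    rx = _pattern_regex(pat)
    return [
        (pat, epi)
        for epi in epitopes
        if len(epi.sequence) >= pat.span and rx.search(epi.sequence)
    ]


def recruit_antigens(hits_a: set[str], hits_b: set[str]) -> set[str]:
    """Antigens matched by at least one epitope from each of two sets."""
    return set(hits_a) & set(hits_b)


def antigen_abundance(
    accession: str,
    hits: list[AlignmentHit],
    rep: PeptideRepertoire,
    count_mode: str = "reads",
) -> tuple[float, float]:
    """Antigen-level antibody-response score in one sample.

    The mean, over the distinct patterns aligning to the antigen, of each
    pattern's repertoire abundance; a pattern hitting several offsets
    counts once. Returns ``(raw_mean, log10(raw_mean + 1))``; ``(0, 0)``
    when nothing aligns. The +1 keeps zero abundance defined on the log
    scale.
    """
    import math

    for h in hits:
        if h.accession != accession:
            raise AntigenError(
                f"hit on {h.accession!r} passed to antigen {accession!r}"
            )
    patterns = sorted({h.pattern.symbols for h in hits})
    if not patterns:
        return 0.0, 0.0
    raw = sum(
        pattern_abundance(p, rep, count_mode=count_mode) for p in patterns
    ) / len(patterns)
    return raw, math.log10(raw + 1.0)


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pattern": h.pattern.symbols,
                "accession": h.accession,
                "start": h.start,
                "end": h.end,
            }
            for h in hits
        ],
        columns=["pattern", "accession", "start", "end"],
    )
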