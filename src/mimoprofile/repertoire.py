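"""Peptide repertoires: data model, TSV/CSV I/O, cleaning and normalization.

A repertoire is one serum sample's IgG-bound peptide set: a map from
12-mer amino-acid sequence to read count. Raw counts are integers from
sequencing; after normalization to a common sequencing depth (3 million
reads by convention) counts are real-valued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Displayed peptide length of the phage library.
PEPTIDE_LENGTH = 12

#: Default normalization depth (reads per sample).
NORMALIZATION_TARGET = 3_000_000.0

_REL_TOL = 1e-9


class RepertoireError(ValueError):
    """Invalid repertoire content or operation."""


class ParseError(RepertoireError):
    """Malformed input table."""


@dataclass
class PeptideRepertoire:
    """One sample's peptide->count map.

    ``counts`` values are raw integer reads before normalization and
    real-valued afterwards; ``total`` always equals their sum.
    """

    sample_id: str
    counts: dict[str, float]
    total: float = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.total is None:
            self.total = float(sum(self.counts.values()))

    def validate(self, target: float = NORMALIZATION_TARGET) -> None:
        """Check the structural invariants, raising on violation."""
        for pep in self.counts:
            if len(pep) != PEPTIDE_LENGTH or not _CANONICAL_SET.issuperset(pep):
                raise RepertoireError(
                    f"{self.sample_id}: non-canonical peptide {pep!r}"
                )
        s = float(sum(self.counts.values()))
        if not math.isclose(self.total, s, rel_tol=_REL_TOL, abs_tol=1e-12):
            raise RepertoireError(
                f"{self.sample_id}: total {self.total} != sum of counts {s}"
            )
        if self.normalized and not math.isclose(self.total, target, rel_tol=_REL_TOL):
            raise RepertoireError(
                f"{self.sample_id}: normalized total {self.total} != target {target}"
            )

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class CleaningReport:
    """Per-rule removal counts from :func:`clean_repertoire`."""

    wrong_length: int = 0
    noncanonical: int = 0
    artefact: int = 0
    kept: int = 0
    empty_result: bool = False

    @property
    def removed(self) -> int:
        return self.wrong_length + self.noncanonical + self.artefact


@dataclass
class SampleMeta:
    """Sample-sheet row: study-design metadata for one sample."""

    sample_id: str
    subject_id: str
    group: str
    timepoint: str = ""
    paired_with: str | None = None
    competition_of: str | None = None


#: Group labels used in the study design (other labels are permitted).
KNOWN_GROUPS = (
    "MelVac", "MelVac-CTRL", "NSCLC", "CTRL-NSCLC", "PEM-Mel", "CTRL-Mel",
    "OTHER",
)


@dataclass
class Cohort:
    """A set of repertoires plus their sample metadata."""

    repertoires: list[PeptideRepertoire]
    meta: list[SampleMeta]

    def __post_init__(self) -> None:
        rep_ids = [r.sample_id for r in self.repertoires]
        meta_ids = [m.sample_id for m in self.meta]
        if len(set(rep_ids)) != len(rep_ids):
            raise RepertoireError("duplicate sample_id among repertoires")
        if set(rep_ids) != set(meta_ids):
            raise RepertoireError("repertoires and metadata sample_ids differ")
        by_id = {m.sample_id: m for m in self.meta}
        for m in self.meta:
            if m.paired_with is not None:
                other = by_id.get(m.paired_with)
                if other is None:
                    raise RepertoireError(
                        f"{m.sample_id}: paired_with references unknown "
                        f"sample {m.paired_with!r}"
                    )
                if other.subject_id != m.subject_id:
                    raise RepertoireError(
                        f"{m.sample_id}: paired_with {m.paired_with!r} "
                        "belongs to a different subject"
                    )
            if m.competition_of is not None:
                other = by_id.get(m.competition_of)
                if other is None:
                    raise RepertoireError(
                        f"{m.sample_id}: competition_of references unknown "
                        f"sample {m.competition_of!r}"
                    )
                if other.subject_id != m.subject_id:
                    raise RepertoireError(
                        f"{m.sample_id}: competition_of {m.competition_of!r} "
                        "belongs to a different subject"
                    )

    def repertoire(self, sample_id: str) -> PeptideRepertoire:
        for r in self.repertoires:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def metadata(self, sample_id: str) -> SampleMeta:
        for m in self.meta:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def __len__(self) -> int:
        return len(self.repertoires)


def read_repertoire(path: str | Path, sample_id: str) -> PeptideRepertoire:
    """Read a two-column (peptide, count) TSV into an un-normalized repertoire.

    A header line whose first field starts with ``peptide`` is skipped.
    Duplicate peptide rows are summed. Counts must be non-negative integers.
    """
    path = Path(path)
    counts: dict[str, float] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower().startswith("peptide"):
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            pep, cnt = fields[0].strip(), fields[1].strip()
            try:
                value = int(cnt)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: count {cnt!r} is not an integer"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative count {value}"
                )
            counts[pep] = counts.get(pep, 0.0) + value
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: empty peptide table")
    return PeptideRepertoire(sample_id=sample_id, counts=counts, normalized=False)


def write_repertoire(rep: PeptideRepertoire, path: str | Path) -> None:
    """Write a repertoire as a peptide/count TSV (counts rounded only if integral)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tcount\n")
        for pep in sorted(rep.counts):
            c = rep.counts[pep]
            if float(c).is_integer():
                fh.write(f"{pep}\t{int(c)}\n")
            else:
                fh.write(f"{pep}\t{c:.10g}\n")


def clean_repertoire(
    rep: PeptideRepertoire, artefacts: set[str] | frozenset[str] = frozenset()
) -> tuple[PeptideRepertoire, CleaningReport]:
    """Remove non-library and artefact peptides.

    Hard rules: length != 12 and any non-canonical letter (stop ``*``,
    ambiguity code ``X``, ...). The artefact set is user-supplied; the
    report records how many distinct peptides each rule removed.
    """
    report = CleaningReport()
    kept: dict[str, float] = {}
    for pep, cnt in rep.counts.items():
        if len(pep) != PEPTIDE_LENGTH:
            report.wrong_length += 1
        elif not _CANONICAL_SET.issuperset(pep):
            report.noncanonical += 1
        elif pep in artefacts:
            report.artefact += 1
        else:
            kept[pep] = cnt
    report.kept = len(kept)
    report.empty_result = not kept
    out = PeptideRepertoire(sample_id=rep.sample_id, counts=kept, normalized=False)
    return out, report


def normalize_reads(
    rep: PeptideRepertoire, target: float = NORMALIZATION_TARGET
) -> PeptideRepertoire:
    """Scale counts so they sum to ``target`` (default 3 million reads).

    Counts stay real-valued; relative composition is conserved exactly up
    to floating-point rounding. Idempotent at a fixed target.
    """
    if target <= 0:
        raise RepertoireError("normalization target must be positive")
    if rep.total <= 0:
        raise RepertoireError(f"{rep.sample_id}: empty repertoire")
    scale = target / rep.total
    counts = {pep: cnt * scale for pep, cnt in rep.counts.items()}
    out = PeptideRepertoire(
        sample_id=rep.sample_id, counts=counts, total=target, normalized=True
    )
    return out


SAMPLE_SHEET_COLUMNS = (
    "sample_id", "subject_id", "group", "timepoint",
    "paired_with", "competition_of", "file",
)


def load_cohort(
    sample_sheet: str | Path,
    data_dir: str | Path,
    artefacts: set[str] | frozenset[str] = frozenset(),
    target: float = NORMALIZATION_TARGET,
) -> Cohort:
    """Load, clean and normalize every sample listed in a sample sheet.

    The sheet is a CSV with columns ``sample_id, subject_id, group,
    timepoint, paired_with, competition_of, file``; ``file`` is a peptide
    TSV path relative to ``data_dir``. Empty strings mean "no pairing".
    """
    sheet = pd.read_csv(sample_sheet, dtype=str, keep_default_na=False)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ParseError(
            f"{sample_sheet}: sample sheet missing columns {sorted(missing)}"
        )
    data_dir = Path(data_dir)
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise RepertoireError(f"duplicate sample_id in sample sheet: {dupes}")

    reps: list[PeptideRepertoire] = []
    meta: list[SampleMeta] = []
    for row in sheet.itertuples(index=False):
        path = data_dir / row.file
        if not path.exists():
            raise RepertoireError(
                f"sample {row.sample_id}: peptide table not found: {path}"
            )
        rep = read_repertoire(path, row.sample_id)
        rep, _ = clean_repertoire(rep, artefacts)
        rep = normalize_reads(rep, target=target)
        reps.append(rep)
        meta.append(
            SampleMeta(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                group=row.group,
                timepoint=row.timepoint,
                paired_with=row.paired_with or None,
                competition_of=row.competition_of or None,
            )
        )
    return Cohort(repertoires=reps, meta=meta)


def write_sample_sheet(meta: list[SampleMeta], files: dict[str, str],
                       path: str | Path) -> None:
    """Write a sample sheet CSV; ``files`` maps sample_id -> peptide TSV name."""
    rows = [
        {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "group": m.group,
            "timepoint": m.timepoint,
            "paired_with": m.paired_with or "",
            "competition_of": m.competition_of or "",
            "file": files[m.sample_id],
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS)).to_csv(path, index=False)
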