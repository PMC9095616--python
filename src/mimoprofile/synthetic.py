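"""Synthetic phage-display cohorts with known ground truth.

Real mimotope-variation sequencing data carry patient-identifiable
material and are typically not shareable, so this module generates
cohorts with the statistical structure the analysis assumes: heavy-tailed
12-mer count repertoires, paired pre/post-treatment samples, epitope
motifs planted at configurable fold-enrichments, lysate-competition
samples with depleted motif reads, and antigen protein sequences with
embedded motif instances. Every stochastic choice flows from a single
seed, so outputs are byte-identical across runs.

What it emulates: per-sample scale (default 3e5 reads over 5e4 unique
peptides, about a tenth of a deep MVA run), Zipf-like count skew, group
structure and pairing, motif read-fractions at baseline and at
baseline*fold. What it does not: phage selection rounds, NNK codon
composition, amplification bias, or sequencing error profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discovery import EpitopePattern, as_pattern, encode_peptides, match_mask
from .repertoire import (
    CANONICAL_RESIDUES,
    NORMALIZATION_TARGET,
    PEPTIDE_LENGTH,
    Cohort,
    PeptideRepertoire,
    SampleMeta,
    clean_repertoire,
    normalize_reads,
)

_RES_BYTES = np.frombuffer(CANONICAL_RESIDUES.encode("ascii"), dtype=np.uint8)


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PlantedMotif:
    """A ground-truth epitope motif planted into generated repertoires.

    ``baseline_fraction`` is the fraction of reads matching the motif in
    the reference (pre-treatment) condition; the query (post-treatment)
    condition carries ``baseline_fraction * fold``. Only samples of
    subjects in ``target_groups`` receive the plant.
    """

    pattern: EpitopePattern
    baseline_fraction: float
    fold: float
    target_groups: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", as_pattern(self.pattern))
        object.__setattr__(self, "target_groups", frozenset(self.target_groups))
        if not (0.0 <= self.baseline_fraction <= 1.0):
            raise SyntheticConfigError("baseline_fraction must be in [0, 1]")
        if self.fold <= 0:
            raise SyntheticConfigError("fold must be positive")
        if self.baseline_fraction * self.fold > 1.0:
            raise SyntheticConfigError(
                "baseline_fraction * fold exceeds 1 (infeasible read fraction)"
            )
        if self.pattern.fixed_count < 4:
            raise SyntheticConfigError("planted motifs need >=4 fixed residues")


def _default_groups() -> dict[str, int]:
    # Study-like design at a tenth of the original cohort breadth.
    return {"MelVac": 6, "PEM-Mel": 5, "CTRL-Mel": 8, "NSCLC": 4, "CTRL-NSCLC": 4}


@dataclass
class SyntheticConfig:
    """Cohort generator settings; defaults emulate a scaled-down MVA study."""

    seed: int = 0
    n_subjects_per_group: dict[str, int] = field(default_factory=_default_groups)
    reads_per_sample: int = 300_000
    unique_peptides_per_sample: int = 50_000
    background_freqs: dict[str, float] | None = None
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    count_dispersion: float = 2.0
    paired_groups: dict[str, str] = field(
        default_factory=lambda: {"MelVac": "MelVac-CTRL"}
    )
    competition: dict[str, float] = field(default_factory=dict)
    normalization_target: float = NORMALIZATION_TARGET

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0 or self.unique_peptides_per_sample <= 0:
            raise SyntheticConfigError("sample sizes must be positive")
        if self.count_dispersion <= 1.0:
            raise SyntheticConfigError(
                "count_dispersion (power-law exponent) must exceed 1"
            )
        for g, n in self.n_subjects_per_group.items():
            if n < 0:
                raise SyntheticConfigError(f"negative subject count for {g!r}")
        for g, d in self.competition.items():
            if not (0.0 <= d <= 1.0):
                raise SyntheticConfigError(
                    f"competition depletion for {g!r} must be in [0, 1]"
                )
        _validate_freqs(self.background_freqs)
        self.planted_motifs = [
            m if isinstance(m, PlantedMotif) else PlantedMotif(**m)
            for m in self.planted_motifs
        ]


def _validate_freqs(
    freqs: dict[str, float] | None,
) -> tuple[str, np.ndarray]:
    """Return (letters, probabilities) for a residue distribution."""
    if freqs is None:
        p = np.full(len(CANONICAL_RESIDUES), 1.0 / len(CANONICAL_RESIDUES))
        return CANONICAL_RESIDUES, p
    letters = "".join(sorted(freqs))
    for c in letters:
        if c not in CANONICAL_RESIDUES:
            raise SyntheticConfigError(f"unknown residue {c!r} in background_freqs")
    p = np.array([freqs[c] for c in letters], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise SyntheticConfigError("background_freqs must sum to 1")
    return letters, p


def sample_background_peptide(
    freqs: dict[str, float] | None,
    length: int = PEPTIDE_LENGTH,
    rng: np.random.Generator | None = None,
) -> str:
    """Draw one random peptide, residues i.i.d. from ``freqs``."""
    letters, p = _validate_freqs(freqs)
    rng = rng if rng is not None else np.random.default_rng()
    idx = rng.choice(len(letters), size=length, p=p)
    return "".join(letters[i] for i in idx)


def _draw_unique_peptides(
    n: int, letters: str, probs: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` distinct peptides; error out if the support is too small."""
    letter_bytes = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
    out: list[str] = []
    seen: set[str] = set()
    stale_rounds = 0
    while len(out) < n:
        batch = max(1024, int((n - len(out)) * 1.3))
        codes = rng.choice(len(letters), size=(batch, PEPTIDE_LENGTH), p=probs)
        text = letter_bytes[codes].tobytes().decode("ascii")
        before = len(out)
        for i in range(batch):
            pep = text[i * PEPTIDE_LENGTH:(i + 1) * PEPTIDE_LENGTH]
            if pep not in seen:
                seen.add(pep)
                out.append(pep)
                if len(out) == n:
                    break
        stale_rounds = stale_rounds + 1 if len(out) == before else 0
        if stale_rounds >= 5:
            raise SyntheticConfigError(
                f"cannot draw {n} distinct peptides from this residue "
                "distribution (support too small)"
            )
    return out


def _impose_motif(peptide: str, pattern: EpitopePattern,
                  rng: np.random.Generator) -> str:
    """Rewrite a peptide so the pattern matches at a random offset."""
    offset = int(rng.integers(0, PEPTIDE_LENGTH - pattern.span + 1))
    chars = list(peptide)
    for j, c in pattern.fixed_positions():
        chars[offset + j] = c
    return "".join(chars)


def generate_repertoire(
    cfg: SyntheticConfig,
    group: str,
    condition: str = "reference",
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    raw: bool = False,
) -> PeptideRepertoire:
    """Generate one repertoire for a group/condition.

    Unique background peptides receive Zipf-distributed raw counts
    (exponent ``count_dispersion``) scaled to integer reads summing to
    approximately ``reads_per_sample``. For every planted motif targeting
    ``group``, background peptides are rewritten in place (preserving the
    unique-peptide count) until the motif's matching read fraction
    reaches ``baseline_fraction`` (reference condition) or
    ``baseline_fraction * fold`` (query). Returns the cleaned, normalized
    repertoire, or the un-normalized integer-count one when ``raw``.
    """
    if condition not in ("reference", "query"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    letters, probs = _validate_freqs(cfg.background_freqs)
    motifs = [m for m in cfg.planted_motifs if group in m.target_groups]
    total_frac = sum(
        m.baseline_fraction * (m.fold if condition == "query" else 1.0)
        for m in motifs
    )
    if total_frac > 1.0:
        raise SyntheticConfigError(
            f"planted motif read fractions sum to {total_frac:.3g} > 1"
        )

    peps = _draw_unique_peptides(
        cfg.unique_peptides_per_sample, letters, probs, rng
    )
    zipf = rng.zipf(cfg.count_dispersion,
                    size=cfg.unique_peptides_per_sample).astype(float)
    counts = np.maximum(
        1, np.rint(zipf * (cfg.reads_per_sample / zipf.sum()))
    ).astype(np.int64)
    total = int(counts.sum())
    mat = encode_peptides(peps)
    pep_set = set(peps)
    lut = np.full(128, 255, dtype=np.uint8)
    for i, c in enumerate(CANONICAL_RESIDUES):
        lut[ord(c)] = i

    for motif in motifs:
        frac = motif.baseline_fraction * (
            motif.fold if condition == "query" else 1.0
        )
        if frac <= 0:
            continue
        target = frac * total
        mask = match_mask(mat, motif.pattern)
        acc = float(counts[mask].sum())
        candidates = np.flatnonzero(~mask)
        rng.shuffle(candidates)
        for i in candidates:
            if acc >= 0.98 * target:
                break
            c = float(counts[i])
            if acc + c > 1.05 * target:
                continue
            newpep = _impose_motif(peps[i], motif.pattern, rng)
            if newpep in pep_set:
                continue
            pep_set.discard(peps[i])
            pep_set.add(newpep)
            peps[i] = newpep
            mat[i] = lut[np.frombuffer(newpep.encode("ascii"), dtype=np.uint8)]
            acc += c

    rep = PeptideRepertoire(
        sample_id=sample_id,
        counts={p: float(c) for p, c in zip(peps, counts)},
        normalized=False,
    )
    if raw:
        return rep
    rep, _ = clean_repertoire(rep)
    return normalize_reads(rep, target=cfg.normalization_target)


@dataclass
class AntigenTruthRow:
    """One planted motif instance inside a generated antigen sequence."""

    pattern: str
    accession: str
    start: int  # 1-based, inclusive


def generate_antigens(
    cfg: SyntheticConfig,
    n_antigens: int,
    length: int,
    rng: np.random.Generator | None = None,
    embed_fraction: float = 0.5,
) -> tuple[list, list[AntigenTruthRow]]:
    """Random protein sequences with planted motifs at recorded offsets.

    Each planted motif is embedded (fixed residues written) into a random
    subset of antigens at non-overlapping, recorded 1-based offsets. The
    truth table lists every (motif, accession, start) instance.
    """
    from .antigens import AntigenRecord

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    letters, probs = _validate_freqs(cfg.background_freqs)
    max_span = max((m.pattern.span for m in cfg.planted_motifs), default=1)
    if length < max_span:
        raise SyntheticConfigError("antigen length shorter than the longest motif")
    letter_bytes = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
    seqs = [
        letter_bytes[rng.choice(len(letters), size=length, p=probs)]
        .tobytes().decode("ascii")
        for _ in range(n_antigens)
    ]
    chars = [list(s) for s in seqs]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_antigens)]
    truth: list[AntigenTruthRow] = []
    for motif in cfg.planted_motifs:
        n_embed = max(1, round(embed_fraction * n_antigens)) if n_antigens else 0
        targets = rng.choice(n_antigens, size=min(n_embed, n_antigens),
                             replace=False)
        for t in sorted(int(x) for x in targets):
            placed = False
            for _ in range(100):
                o = int(rng.integers(0, length - motif.pattern.span + 1))
                span = motif.pattern.span
                if any(o < e and o + span > s for s, e in occupied[t]):
                    continue
                for j, c in motif.pattern.fixed_positions():
                    chars[t][o + j] = c
                occupied[t].append((o, o + span))
                truth.append(
                    AntigenTruthRow(
                        pattern=motif.pattern.symbols,
                        accession=f"SYN{t + 1:03d}",
                        start=o + 1,
                    )
                )
                placed = True
                break
            if not placed:  # pragma: no cover - dense packing only
                continue
    records = [
        AntigenRecord(
            accession=f"SYN{i + 1:03d}",
            name=f"synthetic antigen {i + 1}",
            sequence="".join(chars[i]),
        )
        for i in range(n_antigens)
    ]
    return records, truth


@dataclass
class CohortTruth:
    """Ground truth accompanying a generated cohort."""

    motifs: list[PlantedMotif]
    expected_fraction: dict[tuple[str, str], float]  # (sample_id, pattern) -> reads fraction
    labels: dict[str, str]  # sample_id -> group
    raw_cohort: Cohort | None = None  # un-normalized integer-count twin


def _deplete_motifs(
    rep: PeptideRepertoire,
    motifs: list[PlantedMotif],
    retained: float,
    rng: np.random.Generator,
    sample_id: str,
) -> PeptideRepertoire:
    """Competition sample: binomially thin motif-matching peptide reads.

    Each read of a matching peptide survives competition independently
    with probability ``retained`` (unbiased; ``retained=1`` reproduces
    the parent exactly). Operates on raw integer counts.
    """
    peps = list(rep.counts)
    mat = encode_peptides(peps)
    mask = np.zeros(len(peps), dtype=bool)
    for m in motifs:
        mask |= match_mask(mat, m.pattern)
    counts: dict[str, float] = {}
    for p, hit in zip(peps, mask):
        c = rep.counts[p]
        if hit and retained < 1.0:
            c = float(rng.binomial(int(round(c)), retained))
        if c > 0:
            counts[p] = float(c)
    return PeptideRepertoire(sample_id=sample_id, counts=counts,
                             normalized=False)


def generate_cohort(cfg: SyntheticConfig) -> tuple[Cohort, CohortTruth]:
    """Generate a full cohort: paired treated samples, controls, competition.

    Groups listed in ``cfg.paired_groups`` produce a pre-treatment
    (reference-condition) and post-treatment (query-condition) sample per
    subject with mutual pairing; groups listed in ``cfg.competition``
    additionally get a competition sample derived from the post sample by
    depleting planted-motif reads to the configured retained fraction.
    Other groups produce one sample each (query condition when a motif
    targets the group, reference otherwise).
    """
    root = np.random.SeedSequence(cfg.seed)
    raw_reps: list[PeptideRepertoire] = []
    meta: list[SampleMeta] = []
    truth = CohortTruth(motifs=list(cfg.planted_motifs),
                        expected_fraction={}, labels={})

    def record_truth(sample_id: str, group: str, condition: str,
                     comp_retained: float | None = None) -> None:
        for m in cfg.planted_motifs:
            if group not in m.target_groups:
                continue
            frac = m.baseline_fraction * (m.fold if condition == "query" else 1.0)
            if comp_retained is not None:
                frac *= comp_retained
            truth.expected_fraction[(sample_id, m.pattern.symbols)] = frac

    n_samples = sum(cfg.n_subjects_per_group.values()) * 3 + 8
    stream = iter(root.spawn(n_samples))
    for group in sorted(cfg.n_subjects_per_group):
        n_sub = cfg.n_subjects_per_group[group]
        for s in range(n_sub):
            subject = f"{group}-{s + 1}"
            if group in cfg.paired_groups:
                ref_group = cfg.paired_groups[group]
                pre_id, post_id = f"{subject}-pre", f"{subject}-post"
                pre = generate_repertoire(
                    cfg, group, "reference",
                    np.random.default_rng(next(stream)), pre_id, raw=True,
                )
                post = generate_repertoire(
                    cfg, group, "query",
                    np.random.default_rng(next(stream)), post_id, raw=True,
                )
                raw_reps += [pre, post]
                meta += [
                    SampleMeta(pre_id, subject, ref_group, "pre",
                               paired_with=post_id),
                    SampleMeta(post_id, subject, group, "post",
                               paired_with=pre_id),
                ]
                truth.labels[pre_id] = ref_group
                truth.labels[post_id] = group
                record_truth(pre_id, group, "reference")
                record_truth(post_id, group, "query")
                if group in cfg.competition:
                    d = cfg.competition[group]
                    comp_id = f"{subject}-comp"
                    motifs = [m for m in cfg.planted_motifs
                              if group in m.target_groups]
                    comp = _deplete_motifs(
                        post, motifs, d,
                        np.random.default_rng(next(stream)), comp_id,
                    )
                    raw_reps.append(comp)
                    meta.append(
                        SampleMeta(comp_id, subject, group, "post-competition",
                                   competition_of=post_id)
                    )
                    truth.labels[comp_id] = group
                    record_truth(comp_id, group, "query", comp_retained=d)
            else:
                condition = (
                    "query"
                    if any(group in m.target_groups for m in cfg.planted_motifs)
                    else "reference"
                )
                sid = f"{subject}-s1"
                rep = generate_repertoire(
                    cfg, group, condition,
                    np.random.default_rng(next(stream)), sid, raw=True,
                )
                raw_reps.append(rep)
                meta.append(SampleMeta(sid, subject, group, "single"))
                truth.labels[sid] = group
                record_truth(sid, group, condition)

    normalized = []
    for rep in raw_reps:
        cleaned, _ = clean_repertoire(rep)
        normalized.append(normalize_reads(cleaned, cfg.normalization_target))
    truth.raw_cohort = Cohort(repertoires=raw_reps, meta=meta)
    return Cohort(repertoires=normalized, meta=meta), truth


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write per-sample peptide TSVs plus the sample sheet; return file map.

    Pass the raw (integer-count) cohort so the tables round-trip through
    :func:`mimoprofile.repertoire.load_cohort`.
    """
    from pathlib import Path

    from .repertoire import write_repertoire, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for rep in cohort.repertoires:
        fname = f"{rep.sample_id}.tsv"
        write_repertoire(rep, outdir / fname)
        files[rep.sample_id] = fname
    write_sample_sheet(cohort.meta, files, outdir / "samples.csv")
    return files


def write_truth_table(truth: list[AntigenTruthRow], path) -> None:
    """Write the antigen motif-placement truth table as TSV."""
    import pandas as pd

    pd.DataFrame(
        [{"pattern": r.pattern, "accession": r.accession, "start": r.start}
         for r in truth],
        columns=["pattern", "accession", "start"],
    ).to_csv(path, sep="\t", index=False)
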