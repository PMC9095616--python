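"""End-to-end orchestration: simulate -> load -> discover -> map -> profile -> markers.

A single YAML config drives the whole analysis. Every stochastic stage
derives its own substream from the run seed and the stage name, so
stages are reproducible in isolation and two runs with the same config
and seed produce byte-identical outputs. The run report (JSON) records
the package version, parameters, seeds, input digests and per-stage
record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .antigens import (
    align_pattern_to_sequence,
    antigen_abundance,
    hits_to_frame,
    match_pattern_to_linear_epitopes,
    read_fasta,
    read_linear_epitopes,
    recruit_antigens,
    write_fasta,
)
from .biomarkers import (
    best_subset,
    markers_to_frame,
    rank_markers,
)
from .discovery import (
    DiscoveryParams,
    discover,
    generate_random_reference,
    pattern_abundance,
    reduce_to_core,
    results_to_frame,
)
from .profiles import (
    abundance_matrix,
    abundance_ratio,
    competition_relative_abundance,
    csi_matrix,
    top_k_epitopes,
    zscore_map,
)
from .repertoire import load_cohort
from .synthetic import (
    PlantedMotif,
    SyntheticConfig,
    generate_antigens,
    generate_cohort,
    write_cohort,
    write_truth_table,
)

logger = logging.getLogger("mimoprofile")

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``from_yaml`` for the schema)."""

    seed: int = 0
    log_level: str = "INFO"
    sample_sheet: str = ""
    data_dir: str = ""
    antigen_fasta: str = ""
    epitope_csv: str = ""
    out_dir: str = "out"
    synthetic: dict | None = None
    # discovery
    min_fixed: int = 4
    max_span: int = 12
    min_fold_discriminative: float = 2.0
    min_fold_vs_random: float = 10.0
    max_p: float = 1e-8
    min_support: int = 10
    count_mode: str = "reads"
    random_reference_unique: int = 10_000
    # profile
    top_n: int = 2500
    top_k: int = 50
    cap_percentile: float = 97.5
    # markers
    min_sens: float = 0.72
    min_spec: float = 0.67
    n_markers: int = 15
    max_subset: int = 3
    positive_groups: list[str] = field(
        default_factory=lambda: ["MelVac", "PEM-Mel", "NSCLC"]
    )

    _SECTIONS = {
        "paths": {"sample_sheet", "data_dir", "antigen_fasta", "epitope_csv",
                  "out_dir"},
        "discovery": {"min_fixed", "max_span", "min_fold_discriminative",
                      "min_fold_vs_random", "max_p", "min_support",
                      "count_mode", "random_reference_unique"},
        "profile": {"top_n", "top_k", "cap_percentile"},
        "markers": {"min_sens", "min_spec", "n_markers", "max_subset",
                    "positive_groups"},
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        top_allowed = {"seed", "log_level", "synthetic"} | set(cls._SECTIONS)
        unknown = set(raw) - top_allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "synthetic" in raw:
            kwargs["synthetic"] = raw["synthetic"]
        for section, allowed in cls._SECTIONS.items():
            sub = raw.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(bad)}"
                )
            kwargs.update(sub)
        return cls(**kwargs)

    def synthetic_config(self) -> SyntheticConfig | None:
        if self.synthetic is None:
            return None
        raw = dict(self.synthetic)
        allowed = {
            "n_subjects_per_group", "reads_per_sample",
            "unique_peptides_per_sample", "background_freqs",
            "planted_motifs", "count_dispersion", "paired_groups",
            "competition", "n_antigens", "antigen_length",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown synthetic keys: {sorted(unknown)}")
        raw.pop("n_antigens", None)
        raw.pop("antigen_length", None)
        motifs = [
            PlantedMotif(
                pattern=m["pattern"],
                baseline_fraction=float(m["baseline_fraction"]),
                fold=float(m["fold"]),
                target_groups=frozenset(m["target_groups"]),
            )
            for m in raw.pop("planted_motifs", [])
        ]
        return SyntheticConfig(
            seed=_substream_seed(self.seed, "simulate"),
            planted_motifs=motifs,
            **raw,
        )


def _substream_seed(seed: int, stage: str) -> int:
    """Stage-specific deterministic sub-seed (stays below 2**31)."""
    return (int(seed) * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the machine-readable run report.

    Any stage failure aborts with the stage name and cause; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, str(config.log_level).upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if k != "synthetic"
        },
        "stages": {},
        "outputs": {},
        "warnings": [
            "performance figures are apparent (no cross-validation)",
        ],
    }
    stage = "init"
    try:
        # ---- stage 1: simulate -------------------------------------------
        stage = "simulate"
        syn_cfg = config.synthetic_config()
        data_dir = Path(config.data_dir or out_dir / "data")
        sample_sheet = Path(config.sample_sheet or data_dir / "samples.csv")
        antigen_fasta = Path(config.antigen_fasta) if config.antigen_fasta else None
        if syn_cfg is not None and not sample_sheet.exists():
            logger.info("simulating synthetic cohort into %s", data_dir)
            cohort, truth = generate_cohort(syn_cfg)
            write_cohort(truth.raw_cohort, data_dir)
            n_ant = int((config.synthetic or {}).get("n_antigens", 12))
            ant_len = int((config.synthetic or {}).get("antigen_length", 200))
            antigens, ant_truth = generate_antigens(
                syn_cfg, n_ant, ant_len,
                np.random.default_rng(_substream_seed(config.seed, "antigens")),
            )
            antigen_fasta = antigen_fasta or data_dir / "antigens.fasta"
            write_fasta(antigens, antigen_fasta)
            write_truth_table(ant_truth, data_dir / "antigen_truth.tsv")
            report["stages"]["simulate"] = {
                "samples": len(cohort),
                "antigens": len(antigens),
                "planted_motifs": len(truth.motifs),
            }
        else:
            report["stages"]["simulate"] = {"skipped": True}

        # ---- stage 2: load -----------------------------------------------
        stage = "load"
        cohort = load_cohort(sample_sheet, data_dir)
        by_id = {m.sample_id: m for m in cohort.meta}
        reps = {r.sample_id: r for r in cohort.repertoires}
        report["stages"]["load"] = {
            "samples": len(cohort),
            "sample_sheet_sha256": _sha256(Path(sample_sheet)),
        }
        logger.info("loaded %d samples", len(cohort))

        # ---- stage 3: discover -------------------------------------------
        stage = "discover"
        disc_dir = out_dir / "epitopes"
        disc_dir.mkdir(exist_ok=True)
        discriminative_cores: dict[str, list] = {}
        vs_random_cores: dict[str, list] = {}
        n_raw_total = 0
        seen_pairs: set[frozenset] = set()
        for m in cohort.meta:
            if m.paired_with and m.competition_of is None:
                pair = frozenset({m.sample_id, m.paired_with})
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                a, b = m.sample_id, m.paired_with
                # the post-treatment sample is the query
                query_id = a if by_id[a].timepoint == "post" else b
                ref_id = b if query_id == a else a
                params = DiscoveryParams(
                    min_fixed=config.min_fixed, max_span=config.max_span,
                    min_fold=config.min_fold_discriminative,
                    max_p=config.max_p, min_support=config.min_support,
                    count_mode=config.count_mode,
                )
                results = discover(reps[query_id], reps[ref_id], params,
                                   mode="discriminative")
                n_raw_total += len(results)
                core = reduce_to_core(results, reps[query_id])
                discriminative_cores[query_id] = core
                _write_tsv(results_to_frame(core),
                           disc_dir / f"{query_id}.core.tsv")
                logger.info("discriminative %s vs %s: %d raw, %d core",
                            query_id, ref_id, len(results), len(core))
        random_ref = generate_random_reference(
            config.random_reference_unique,
            seed=_substream_seed(config.seed, "random-reference"),
        )
        for m in cohort.meta:
            if (m.paired_with is None and m.competition_of is None
                    and m.group in config.positive_groups):
                params = DiscoveryParams(
                    min_fixed=config.min_fixed, max_span=config.max_span,
                    min_fold=config.min_fold_vs_random,
                    max_p=config.max_p, min_support=config.min_support,
                    count_mode=config.count_mode,
                )
                results = discover(reps[m.sample_id], random_ref, params,
                                   mode="vs_random")
                n_raw_total += len(results)
                core = reduce_to_core(results, reps[m.sample_id])
                vs_random_cores[m.sample_id] = core
                _write_tsv(results_to_frame(core),
                           disc_dir / f"{m.sample_id}.core.tsv")
                logger.info("vs_random %s: %d raw, %d core",
                            m.sample_id, len(results), len(core))
        treatment_set = sorted(
            {r.pattern.symbols for core in discriminative_cores.values()
             for r in core}
        )
        disease_set = sorted(
            {r.pattern.symbols for core in vs_random_cores.values()
             for r in core}
        )
        all_patterns = sorted(set(treatment_set) | set(disease_set))
        report["stages"]["discover"] = {
            "raw_epitopes": n_raw_total,
            "treatment_core_epitopes": len(treatment_set),
            "disease_core_epitopes": len(disease_set),
            "unique_core_epitopes": len(all_patterns),
        }

        # ---- stage 4: map -------------------------------------------------
        stage = "map"
        hits = []
        aligned_patterns: list[str] = list(all_patterns)
        recruited: list[str] = []
        if antigen_fasta and Path(antigen_fasta).exists():
            antigens = read_fasta(antigen_fasta)
            for pat in all_patterns:
                for ant in antigens:
                    hits.extend(align_pattern_to_sequence(pat, ant))
            _write_tsv(hits_to_frame(hits), out_dir / "alignment_hits.tsv")
            if config.epitope_csv and Path(config.epitope_csv).exists():
                linear = read_linear_epitopes(config.epitope_csv)
                acc_a = {
                    e.parent_accession
                    for p in treatment_set
                    for _, e in match_pattern_to_linear_epitopes(p, linear)
                }
                acc_b = {
                    e.parent_accession
                    for p in disease_set
                    for _, e in match_pattern_to_linear_epitopes(p, linear)
                }
                recruited = sorted(recruit_antigens(acc_a, acc_b))
            aligned_patterns = sorted({h.pattern.symbols for h in hits})
            # antigen-score matrix: antigens x samples, log10(mean+1)
            score_rows = {}
            for ant in antigens:
                ant_hits = [h for h in hits if h.accession == ant.accession]
                score_rows[ant.accession] = {
                    sid: antigen_abundance(ant.accession, ant_hits, rep)[1]
                    for sid, rep in reps.items()
                }
            scores = pd.DataFrame(score_rows).T.sort_index()
            _write_tsv(scores, out_dir / "antigen_scores.tsv", index=True)
        report["stages"]["map"] = {
            "alignment_hits": len(hits),
            "aligned_patterns": len(aligned_patterns),
            "recruited_antigens": len(recruited),
        }

        # ---- stage 5: profile ---------------------------------------------
        stage = "profile"
        non_comp = [r for r in cohort.repertoires
                    if by_id[r.sample_id].competition_of is None]
        csi = csi_matrix(non_comp, n=config.top_n)
        _write_tsv(csi, out_dir / "csi_matrix.tsv", index=True)
        ratio_rows = []
        n_zmaps = 0
        for query_id, core in sorted(discriminative_cores.items()):
            meta_q = by_id[query_id]
            ref_id = meta_q.paired_with
            patterns = [r.pattern for r in core]
            if not patterns:
                continue
            top = top_k_epitopes(patterns, [reps[query_id], reps[ref_id]],
                                 k=config.top_k, count_mode=config.count_mode)
            top_patterns = [p for p, _ in top]
            mat = abundance_matrix(top_patterns, [reps[ref_id], reps[query_id]],
                                   count_mode=config.count_mode)
            try:
                z = zscore_map(mat, cap_percentile=config.cap_percentile)
                _write_tsv(z, out_dir / f"zscores_{meta_q.subject_id}.tsv",
                           index=True)
                n_zmaps += 1
            except ValueError:
                logger.warning("constant abundance matrix for %s; z-map skipped",
                               meta_q.subject_id)
            for pat in top_patterns:
                post_a = mat.loc[pat.symbols, query_id]
                pre_a = mat.loc[pat.symbols, ref_id]
                ratio_rows.append({
                    "marker": pat.symbols,
                    "subject": meta_q.subject_id,
                    "log10_ratio": abundance_ratio(post_a, pre_a),
                })
        if ratio_rows:
            _write_tsv(pd.DataFrame(ratio_rows), out_dir / "abundance_ratios.tsv")
        comp_rows = []
        for m in cohort.meta:
            if m.competition_of is None:
                continue
            parent = reps[m.competition_of]
            comp = reps[m.sample_id]
            core = discriminative_cores.get(m.competition_of, [])
            for r in core:
                unc = r.k_query
                if unc <= 0:
                    continue
                comp_rows.append({
                    "marker": r.pattern.symbols,
                    "subject": m.subject_id,
                    "relative_abundance": competition_relative_abundance(
                        pattern_abundance(r.pattern, comp,
                                          count_mode=config.count_mode),
                        pattern_abundance(r.pattern, parent,
                                          count_mode=config.count_mode),
                    ),
                })
        if comp_rows:
            _write_tsv(pd.DataFrame(comp_rows),
                       out_dir / "competition_relative_abundance.tsv")
        report["stages"]["profile"] = {
            "csi_pairs": int(len(csi) * (len(csi) - 1) // 2),
            "zscore_maps": n_zmaps,
            "ratio_rows": len(ratio_rows),
            "competition_rows": len(comp_rows),
        }

        # ---- stage 6: markers ----------------------------------------------
        stage = "markers"
        marker_report: dict = {"markers": 0}
        if aligned_patterns:
            marker_samples = [r for r in non_comp]
            mat = abundance_matrix(aligned_patterns, marker_samples,
                                   count_mode=config.count_mode)
            labels = {
                r.sample_id: int(by_id[r.sample_id].group
                                 in config.positive_groups)
                for r in marker_samples
            }
            if len(set(labels.values())) == 2:
                ranked = rank_markers(
                    mat, labels, min_sens=config.min_sens,
                    min_spec=config.min_spec, k=config.n_markers,
                )
                _write_tsv(markers_to_frame(ranked), out_dir / "markers.tsv")
                marker_report["markers"] = len(ranked)
                if ranked:
                    candidates = [m.pattern.symbols for m in ranked][:15]
                    model = best_subset(mat, labels, candidates,
                                        max_size=config.max_subset)
                    model_json = {
                        "markers": model.markers,
                        "coefficients": [float(c) for c in model.coefficients],
                        "auc": model.auc,
                        "sensitivity": model.sensitivity,
                        "specificity": model.specificity,
                        "converged": model.converged,
                        "transform": "log10p1",
                        "warnings": model.warnings
                        + ["apparent performance; no cross-validation"],
                    }
                    with open(out_dir / "combined_model.json", "w") as fh:
                        json.dump(model_json, fh, indent=2, sort_keys=True)
                    marker_report["combined_auc"] = model.auc
            else:
                logger.warning("single-class labels; marker stage skipped")
        report["stages"]["markers"] = marker_report

        # ---- finalize -------------------------------------------------------
        stage = "report"
        for f in sorted(out_dir.rglob("*.tsv")) + sorted(out_dir.glob("*.json")):
            if f.name == "report.json":
                continue
            report["outputs"][str(f.relative_to(out_dir))] = _sha256(f)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
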