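"""End-to-end peptide design runs.

One run goes: corpus (read or synthesised) -> curation (length band +
identity deduplication) -> LSTM training -> sequence generation ->
exact-duplicate removal -> physicochemical screening -> similarity
ranking against the reference peptide -> report + artifacts.

All stage randomness derives from one global seed: the synthetic
corpus uses the seed itself, model training uses the generator
config's own seed if set (else the global seed), and generation uses
seed + 1.  Identical config + seed therefore reproduces a run
byte-for-byte, including every artifact file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus import CurationReport, PeptideRecord, curate, read_fasta, write_fasta
from .lstm import GeneratorConfig, PeptideLSTM, generate
from .properties import FilterCriteria, passes_filters, profiles_to_tsv
from .similarity import RankedCandidate, rank_candidates, ranking_to_tsv
from .synthetic import QK_SEQUENCE, CorpusSpec, sample_corpus

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    """Everything a design run needs.

    ``corpus_fasta`` (a file of training peptides) takes precedence
    over ``corpus_spec`` (a synthetic corpus specification).
    """

    corpus_fasta: str | None = None
    corpus_spec: CorpusSpec = field(default_factory=CorpusSpec)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    min_len: int = 8
    max_len: int = 20
    identity_threshold: float = 0.30
    reference: str = QK_SEQUENCE
    n_generate: int = 500
    top_k: int = 6
    seed: int = 42

    def validate(self) -> None:
        if not 1 <= self.top_k <= self.n_generate:
            raise ValueError("need n_generate >= top_k >= 1")
        if not self.reference:
            raise ValueError("reference peptide must be non-empty")
        self.generator.validate()
        self.corpus_spec.validate()

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "corpus_spec" in data and isinstance(data["corpus_spec"], dict):
            data["corpus_spec"] = CorpusSpec(**data["corpus_spec"])
        if "generator" in data and isinstance(data["generator"], dict):
            data["generator"] = GeneratorConfig(**data["generator"])
        if "criteria" in data and isinstance(data["criteria"], dict):
            crit = data["criteria"]
            crit["charge_range"] = tuple(crit.get("charge_range", (-2, 2)))
            crit["gravy_range"] = tuple(crit.get("gravy_range", (-1.0, 1.0)))
            data["criteria"] = FilterCriteria(**crit)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class DesignReport:
    """Counts, rankings and provenance of one design run."""

    config: dict
    config_hash: str
    version: str
    curation: CurationReport
    n_corpus: int
    final_train_loss: float
    final_train_accuracy: float
    final_holdout_loss: float | None
    final_holdout_accuracy: float | None
    n_generated: int
    n_unique: int
    n_passing_filters: int
    top_candidates: list[RankedCandidate]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "version": self.version,
            "curation": dataclasses.asdict(self.curation),
            "n_corpus": self.n_corpus,
            "final_train_loss": self.final_train_loss,
            "final_train_accuracy": self.final_train_accuracy,
            "final_holdout_loss": self.final_holdout_loss,
            "final_holdout_accuracy": self.final_holdout_accuracy,
            "n_generated": self.n_generated,
            "n_unique": self.n_unique,
            "n_passing_filters": self.n_passing_filters,
            "top_candidates": [
                dataclasses.asdict(rc) for rc in self.top_candidates
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_design(config: PipelineConfig,
               outdir: str | Path | None = None) -> DesignReport:
    """Execute the full design pipeline; optionally write artifacts.

    Artifacts (when ``outdir`` is given): curated corpus FASTA,
    generated candidates FASTA, screening TSV, ranking TSV, training
    trace JSON/TSV, model JSON, report JSON.  On a stage failure the
    partial artifacts are retained next to a ``FAILED`` marker naming
    the stage.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    logger.info("design run: seed=%d config_hash=%s", config.seed, chash)

    stage = "corpus"
    try:
        if config.corpus_fasta:
            raw = read_fasta(config.corpus_fasta)
        else:
            spec = dataclasses.replace(config.corpus_spec, seed=config.seed)
            raw = sample_corpus(spec)
        logger.info("corpus: %d records", len(raw))

        stage = "curation"
        corpus, report = curate(
            raw, config.min_len, config.max_len, config.identity_threshold
        )
        logger.info(
            "curation: %d -> %d (length band) -> %d (identity < %.2f)",
            report.n_input, report.n_after_length, report.n_after_identity,
            config.identity_threshold,
        )
        if out is not None:
            write_fasta(corpus, out / "curated_corpus.fasta")
            report.to_tsv(out / "curation_report.tsv")

        stage = "training"
        gen_cfg = dataclasses.replace(config.generator)
        est = PeptideLSTM(**gen_cfg.__dict__)
        est.fit(corpus)
        trace = est.trace_
        logger.info(
            "training: final loss %.4f, accuracy %.4f",
            trace.train_loss[-1], trace.train_accuracy[-1],
        )
        if out is not None:
            trace.to_json(out / "training_trace.json")
            trace.to_tsv(out / "training_trace.tsv")
            est.model_.save(out / "model.json")

        stage = "generation"
        gen_seed = (config.seed + 1) % _SEED_MOD
        sequences = generate(
            est.model_, "", config.n_generate, gen_cfg, rng_seed=gen_seed
        )
        sequences = [s for s in sequences if s]
        unique = list(dict.fromkeys(sequences))
        logger.info("generation: %d sequences, %d unique",
                    len(sequences), len(unique))
        if out is not None:
            write_fasta(
                [PeptideRecord(id=f"gen{k + 1:04d}", sequence=s,
                               source="generated")
                 for k, s in enumerate(unique)],
                out / "generated.fasta",
            )

        stage = "screening"
        profiles = [passes_filters(s, config.criteria) for s in unique]
        passing = [p for p in profiles if p.passes]
        logger.info("screening: %d/%d pass", len(passing), len(unique))
        if out is not None:
            profiles_to_tsv(
                [(f"gen{k + 1:04d}", p) for k, p in enumerate(profiles)],
                out / "properties.tsv",
            )

        stage = "ranking"
        ranked = rank_candidates(profiles, config.reference)
        top = ranked[: config.top_k]
        if out is not None:
            ranking_to_tsv(ranked, out / "ranking.tsv")
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report_obj = DesignReport(
        config=config.to_dict(),
        config_hash=chash,
        version=__version__,
        curation=report,
        n_corpus=len(corpus),
        final_train_loss=trace.train_loss[-1],
        final_train_accuracy=trace.train_accuracy[-1],
        final_holdout_loss=trace.holdout_loss[-1] if trace.holdout_loss else None,
        final_holdout_accuracy=(
            trace.holdout_accuracy[-1] if trace.holdout_accuracy else None
        ),
        n_generated=len(sequences),
        n_unique=len(unique),
        n_passing_filters=len(passing),
        top_candidates=top,
    )
    if out is not None:
        (out / "report.json").write_text(report_obj.to_json())
    return report_obj


def wound_closure_percent(area_initial: float, area_t: float) -> float:
    """Scratch-wound closure percentage, 100 * (A0 - At) / A0.

    ``A0`` is the wound area at 0 h and ``At`` the area at the later
    time point.  A negative value (wound expansion) is permitted but
    logged as a warning.
    """
    if area_initial <= 0:
        raise ValueError("initial wound area must be positive")
    if area_t < 0:
        raise ValueError("wound area cannot be negative")
    closure = 100.0 * (area_initial - area_t) / area_initial
    if closure < 0:
        logger.warning(
            "wound expanded: area %.3g -> %.3g (closure %.1f%%)",
            area_initial, area_t, closure,
        )
    return closure
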