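"""End-to-end orchestration: simulate/read inputs, build the space,
embed, predict accuracy, score constructs, run the keyword analysis,
and write a summary table plus a reproducibility manifest.

The manifest records the package version, every parameter, the seeds,
per-fold selected dimensions, and SHA-256 checksums of all written
outputs; it contains no timestamps or absolute paths, so a rerun with
the same config and seed produces a byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy_model import DEFAULT_DIMENSION_GRID, AccuracyPredictions, run_accuracy_model
from .corpus_io import (
    ConstructWordList,
    RatingList,
    StatementRecord,
    make_tokenizer,
    read_ngram_corpus,
    read_rating_list,
    read_statements,
    read_word_list,
    write_ngram_corpus,
    write_rating_list,
    write_statements,
    write_word_list,
)
from .construct_scoring import (
    build_construct_representation,
    score_statements_against_constructs,
    train_rating_model,
)
from .errors import InputFormatError
from .group_stats import (
    GroupComparison,
    keyword_chisq,
    pool_datasets,
    render_results_table,
    two_group_test,
    write_results_table,
)
from .semantic_space import build_space
from .statement_embedding import embed_all, write_embeddings
from .synthetic_data import SimulationConfig, simulate_bundle

__all__ = ["RunConfig", "ResultsBundle", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable).

    Either ``simulation`` is set (inputs are generated into the output
    directory) or ``corpus`` and ``statements`` point at existing files.
    Multiple statement tables trigger mega-analysis pooling with
    dataset-prefixed ids and themes.
    """

    out_dir: str = "witsem_run"
    seed: int = 0
    corpus: str | None = None
    statements: list[str] = field(default_factory=list)
    rating_lists: dict[str, dict] = field(default_factory=dict)
    word_lists: dict[str, str] = field(default_factory=dict)
    ngram_length: int = 5
    row_vocab: int = 50_000
    col_vocab: int = 120_000
    dimensions: int = 300
    grid: tuple[int, ...] = DEFAULT_DIMENSION_GRID
    alpha: float = 0.05
    keyword_coding: str = "tokens"
    keyword_min_count: int = 5
    lowercase: bool = True
    language: str = "syn"
    study_label: str = "1"
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            sim.setdefault("seed", raw.get("seed", 0))
            if "theme_base_rates" in sim and sim["theme_base_rates"] is not None:
                sim["theme_base_rates"] = tuple(sim["theme_base_rates"])
            if "rating_scale" in sim:
                sim["rating_scale"] = tuple(sim["rating_scale"])
            raw["simulation"] = SimulationConfig(**sim)
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grid"] = list(self.grid)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["rating_scale"] = list(self.simulation.rating_scale)
            if self.simulation.theme_base_rates is not None:
                sim["theme_base_rates"] = list(self.simulation.theme_base_rates)
            out["simulation"] = sim
        return out


@dataclass
class ResultsBundle:
    """In-memory results of a full run, mirroring the files on disk."""

    config: RunConfig
    statements: list[StatementRecord]
    comparisons: list[GroupComparison]
    accuracy: AccuracyPredictions
    construct_scores: pd.DataFrame
    keywords: list
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _materialise_simulation(config: RunConfig, out_dir: Path) -> RunConfig:
    """Generate synthetic inputs into ``out_dir/inputs`` and point at them."""
    assert config.simulation is not None
    bundle = simulate_bundle(config.simulation)
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_ngram_corpus(bundle.corpus, inputs / "corpus.tsv")
    write_statements(bundle.statements, inputs / "statements.csv")
    write_rating_list(bundle.rating_list, inputs / f"{bundle.rating_list.name}.tsv")
    word_lists: dict[str, str] = {}
    for name, wl in bundle.construct_lists.items():
        path = inputs / f"{name}.txt"
        write_word_list(wl, path)
        word_lists[name] = str(path)
    manifest = {
        "simulation": config.to_dict()["simulation"],
        "n_statements": len(bundle.statements),
        "accuracy_rate": float(
            np.mean([s.accuracy for s in bundle.statements])
        ),
    }
    with (inputs / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return dataclasses.replace(
        config,
        corpus=str(inputs / "corpus.tsv"),
        statements=[str(inputs / "statements.csv")],
        rating_lists={
            bundle.rating_list.name: {
                "path": str(inputs / f"{bundle.rating_list.name}.tsv"),
                "scale_min": bundle.rating_list.scale_min,
                "scale_max": bundle.rating_list.scale_max,
            }
        },
        word_lists=word_lists,
        ngram_length=config.simulation.ngram_length,
    )


def run_full_analysis(config: RunConfig) -> ResultsBundle:
    """Execute the pipeline stages end to end and write all outputs.

    Stage order: (simulate) -> build-space -> embed -> predict-accuracy
    -> score-constructs -> keywords -> report.  Any stage failure
    propagates with its cause; rating lists and word lists are optional
    and simply skipped when absent.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        config = _materialise_simulation(config, out_dir)
    if config.corpus is None or not config.statements:
        raise InputFormatError("config must provide a corpus and statement table(s)")

    tokenizer = make_tokenizer(lowercase=config.lowercase)

    # --- inputs -----------------------------------------------------------
    corpus = read_ngram_corpus(config.corpus, n=config.ngram_length)
    tables = [(Path(p).stem, read_statements(p)) for p in config.statements]
    if len(tables) == 1:
        statements = list(tables[0][1])
    else:
        statements = pool_datasets(tables)
        logger.info("mega-analysis: pooled %d statements from %d tables",
                    len(statements), len(tables))

    # --- semantic space ---------------------------------------------------
    space = build_space(
        corpus, R=config.row_vocab, C=config.col_vocab, d=config.dimensions
    )
    space.save(out_dir / "space.tsv")

    # --- statement embeddings --------------------------------------------
    matrix, mask, embeddings = embed_all(statements, space, tokenizer)
    write_embeddings(embeddings, out_dir / "embeddings.tsv")

    # --- accuracy model ---------------------------------------------------
    accuracy, acc_comparison, valid_idx = run_accuracy_model(
        statements, matrix, mask, grid=config.grid,
        measure="Accuracy (LSA)", language=config.language,
    )
    kept = [statements[i] for i in valid_idx]
    pred_table = pd.DataFrame(
        {
            "statement_id": [s.statement_id for s in kept],
            "theme": [s.theme for s in kept],
            "accuracy": [s.accuracy for s in kept],
            "predicted": accuracy.predictions,
        }
    )
    pred_table.to_csv(out_dir / "predictions.tsv", sep="\t", index=False,
                      lineterminator="\n")
    comparisons = [acc_comparison]

    # --- construct scoring ------------------------------------------------
    constructs = []
    for name, path in sorted(config.word_lists.items()):
        wl = read_word_list(path, name=name)
        constructs.append(build_construct_representation(wl, space))
    models = []
    for name, spec_ in sorted(config.rating_lists.items()):
        ratings = read_rating_list(
            spec_["path"], spec_["scale_min"], spec_["scale_max"], name=name
        )
        models.append(
            train_rating_model(
                ratings, space, grid=config.grid, seed=config.seed
            )
        )
    scores = None
    if constructs or models:
        ids = [s.statement_id for s in statements]
        scores = score_statements_against_constructs(
            ids, matrix, mask, constructs, models
        )
        scores.to_csv(out_dir / "construct_scores.tsv", sep="\t",
                      lineterminator="\n")
        labels = np.array([s.accuracy for s in statements])
        for col in scores.columns:
            col_values = scores[col].to_numpy()
            ok = ~np.isnan(col_values)
            comparisons.append(
                two_group_test(
                    col_values[ok], labels[ok], measure=col,
                    language=config.language,
                )
            )
    else:
        scores = pd.DataFrame(index=[s.statement_id for s in statements])

    # --- keyword analysis -------------------------------------------------
    keywords = keyword_chisq(
        statements,
        alpha=config.alpha,
        coding=config.keyword_coding,
        min_count=config.keyword_min_count,
        tokenizer=tokenizer,
    )
    kw_table = pd.DataFrame(
        {
            "word": [k.word for k in keywords],
            "count_incorrect": [k.count_incorrect for k in keywords],
            "count_correct": [k.count_correct for k in keywords],
            "chi2": [k.chi2 for k in keywords],
            "p": [k.p for k in keywords],
            "signed": [k.signed for k in keywords],
            "significant": [k.significant for k in keywords],
        }
    )
    kw_table.to_csv(out_dir / "keywords.tsv", sep="\t", index=False,
                    lineterminator="\n")

    # --- report -----------------------------------------------------------
    table = render_results_table(
        comparisons, studies=[config.study_label] * len(comparisons)
    )
    write_results_table(table, out_dir / "summary.tsv")

    outputs = [
        "space.tsv", "embeddings.tsv", "predictions.tsv",
        "construct_scores.tsv", "keywords.tsv", "summary.tsv",
    ]
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_statements": len(statements),
        "n_valid": int(mask.sum()),
        "space_words": len(space),
        "space_d": space.d,
        "chosen_dimensions": {str(k): v for k, v in accuracy.chosen_dims.items()},
        "mean_dimensions": accuracy.mean_dims,
        "rating_models": {
            m.name: {"k": m.k, "cv_r": m.cv_r, "n_words": m.n_words} for m in models
        },
        "checksums": {
            name: _sha256(out_dir / name)
            for name in outputs
            if (out_dir / name).exists()
        },
    }
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ResultsBundle(
        config=config,
        statements=statements,
        comparisons=comparisons,
        accuracy=accuracy,
        construct_scores=scores,
        keywords=keywords,
        manifest=manifest,
        out_dir=out_dir,
    )
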