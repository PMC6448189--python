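"""End-to-end orchestration: configuration, stages, artifacts, manifests.

Each stage reads its inputs from files, writes its outputs atomically
(temp file, then rename) into the configured output directory, and drops
a JSON manifest alongside (stage name, config hash, root seed, input
digests, package version) so every artifact is reproducible from its
manifest.  One root seed governs all stages; stage seeds are derived
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .cooccurrence import read_cooccurrence_db, write_cooccurrence_db
from .corpus import (aggregate_settings, filter_to_allowlist, read_allowlist,
                     read_corpus, read_setting_map, sample_per_setting,
                     write_corpus)
from .errors import DataError
from .evaluate import (LDAConfig, cross_validate, evaluate_holdout,
                       metrics_to_json_dict, write_rankings_tsv)
from .filtering import (FilterConfig, concept_frequency_table,
                        representative_concepts, write_enrichment_tsv,
                        write_representative_tsv, write_scores_tsv)
from .lda import (fit_lda, load_model, save_model, select_num_topics,
                  term_topic_probabilities)
from .profiles import (cluster_image_map, pearson_matrix, setting_profile,
                       write_profiles_tsv, write_similarity_tsv)
from .simulate import (SyntheticConfig, generate_cooccurrence_db,
                       generate_corpus, write_ground_truth)

__all__ = ["PipelineConfig", "Pipeline", "run_all"]

logger = logging.getLogger(__name__)


def _build(cls, d: Mapping[str, Any], path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(d) - known
    if bad:
        raise DataError(f"invalid config key(s) under {path!r}: "
                        + ", ".join(sorted(bad)))
    return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; mirrors the YAML config file."""

    output_dir: str = "settinglink_out"
    seed: int = 0
    corpus_path: str | None = None        # None → simulate
    corpus_format: str | None = None
    setting_map_path: str | None = None
    cooccurrence_path: str | None = None  # None → simulated database
    allowlist_path: str | None = None
    unmapped_policy: str = "error"
    sample_n: int | None = 1000           # notes sampled per setting
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    lda: LDAConfig = field(default_factory=LDAConfig)
    folds: int = 5
    ks: tuple[int, ...] = (2, 4, 6, 8, 10)
    holdout_n: int | None = None          # fixed-holdout mode instead of CV
    top_n_frequency: int = 10
    cim_linkage: str = "average"
    cim_bins: int = 10

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "synthetic": SyntheticConfig,
            "filter": FilterConfig,
            "lda": LDAConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, sub_cls in nested.items():
            if key in d:
                kwargs[key] = _build(sub_cls, d.pop(key) or {}, key)
        if "ks" in d:
            d["ks"] = tuple(int(k) for k in d["ks"])
        if "lda" in kwargs and kwargs["lda"].grid is not None:
            kwargs["lda"] = dataclasses.replace(
                kwargs["lda"], grid=tuple(kwargs["lda"].grid))
        return _build(cls, {**d, **kwargs}, "<root>")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Pipeline:
    """Stage runner bound to one config and output directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- artifact paths -----------------------------------------------------
    def path(self, name: str) -> Path:
        return self.out / name

    def _manifest(self, stage: str, inputs: Sequence[Path],
                  outputs: Sequence[Path]) -> None:
        manifest = {
            "stage": stage,
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
            "outputs": [str(p) for p in outputs],
            "version": __version__,
        }
        _atomic_write(
            self.path(f"manifest_{stage}.json"),
            lambda tmp: tmp.write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"))

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise DataError(
                f"missing artifact {path}; run the {producer!r} stage first")
        return path

    # -- stage: simulate ----------------------------------------------------
    def simulate(self) -> dict[str, Path]:
        """Generate the synthetic corpus, ground truth and pair database."""
        syn = dataclasses.replace(self.cfg.synthetic,
                                  seed=derive_seed(self.cfg.seed, "simulate"))
        corpus, truth = generate_corpus(syn)
        db = generate_cooccurrence_db(truth, syn)
        paths = {
            "corpus": self.path("corpus.jsonl"),
            "truth": self.path("ground_truth.tsv"),
            "cooccurrence": self.path("cooccurrence.tsv"),
        }
        _atomic_write(paths["corpus"], lambda p: write_corpus(corpus, p, "jsonl"))
        _atomic_write(paths["truth"], lambda p: write_ground_truth(truth, p))
        _atomic_write(paths["cooccurrence"], lambda p: write_cooccurrence_db(db, p))
        logger.info("simulated %d documents in %d settings; %d stored pairs",
                    len(corpus), len(corpus.settings), len(db))
        self._manifest("simulate", [], list(paths.values()))
        return paths

    # -- corpus loading / preparation ----------------------------------------
    def _raw_corpus_path(self) -> Path:
        if self.cfg.corpus_path:
            return Path(self.cfg.corpus_path)
        return self._require(self.path("corpus.jsonl"), "simulate")

    def _db_path(self) -> Path:
        if self.cfg.cooccurrence_path:
            return Path(self.cfg.cooccurrence_path)
        return self._require(self.path("cooccurrence.tsv"), "simulate")

    def aggregate(self) -> Path:
        """Map raw settings to aggregated settings (needs a mapping table)."""
        src = self._raw_corpus_path()
        corpus = read_corpus(src, self.cfg.corpus_format)
        if self.cfg.setting_map_path is None:
            raise DataError("aggregate stage requires setting_map_path")
        smap = read_setting_map(self.cfg.setting_map_path)
        corpus = aggregate_settings(corpus, smap, self.cfg.unmapped_policy)
        dest = self.path("corpus_aggregated.jsonl")
        _atomic_write(dest, lambda p: write_corpus(corpus, p, "jsonl"))
        self._manifest("aggregate", [src], [dest])
        return dest

    def prepare(self) -> Path:
        """Aggregate (if mapped), allow-list filter, per-setting sampling."""
        src = self._raw_corpus_path()
        corpus = read_corpus(src, self.cfg.corpus_format)
        logger.info("loaded %d documents, %d settings", len(corpus),
                    len(corpus.settings))
        if self.cfg.setting_map_path:
            smap = read_setting_map(self.cfg.setting_map_path)
            corpus = aggregate_settings(corpus, smap, self.cfg.unmapped_policy)
            logger.info("after aggregation: %d settings", len(corpus.settings))
        if self.cfg.allowlist_path:
            allowed = read_allowlist(self.cfg.allowlist_path)
            corpus = filter_to_allowlist(corpus, allowed, drop_empty=True)
            logger.info("after allow-list: %d documents", len(corpus))
        if self.cfg.sample_n:
            corpus = sample_per_setting(
                corpus, self.cfg.sample_n, derive_seed(self.cfg.seed, "sample"))
            logger.info("after per-setting sampling (n=%d): %d documents",
                        self.cfg.sample_n, len(corpus))
        dest = self.path("corpus_prepared.jsonl")
        _atomic_write(dest, lambda p: write_corpus(corpus, p, "jsonl"))
        self._manifest("prepare", [src], [dest])
        return dest

    def _prepared_corpus(self):
        return read_corpus(self._require(self.path("corpus_prepared.jsonl"),
                                         "prepare"), "jsonl")

    # -- stage: filter-concepts ----------------------------------------------
    def filter_concepts(self) -> dict[str, Path]:
        corpus = self._prepared_corpus()
        db = read_cooccurrence_db(self._db_path())
        outcome = representative_concepts(corpus, db, self.cfg.filter)
        paths = {
            "representative": self.path("representative.tsv"),
            "enrichment": self.path("enrichment.tsv"),
            "scores": self.path("scores.tsv"),
            "frequency": self.path("frequency_top.tsv"),
        }
        _atomic_write(paths["representative"],
                      lambda p: write_representative_tsv(outcome, p))
        _atomic_write(paths["enrichment"],
                      lambda p: write_enrichment_tsv(outcome.enrichment, p))
        _atomic_write(paths["scores"],
                      lambda p: write_scores_tsv(outcome.scores, p))
        _atomic_write(paths["frequency"], lambda p: concept_frequency_table(
            corpus, self.cfg.top_n_frequency).to_csv(p, sep="\t", index=False))
        self._manifest("filter-concepts",
                       [self.path("corpus_prepared.jsonl"), self._db_path()],
                       list(paths.values()))
        return paths

    def _representative(self) -> dict[str, set[str]]:
        path = self._require(self.path("representative.tsv"), "filter-concepts")
        df = pd.read_csv(path, sep="\t")
        rep: dict[str, set[str]] = {}
        for setting, group in df.groupby("setting"):
            rep[str(setting)] = set(group["concept"].astype(str))
        return rep

    def _restricted_docs(self, corpus, vocab: set[str]):
        docs = []
        for d in corpus:
            kept = tuple(c for c in d.concepts if c in vocab)
            if kept:
                docs.append((d.doc_id, kept))
        return docs

    def _resolve_n_topics(self, corpus) -> int:
        if self.cfg.lda.n_topics is not None:
            return self.cfg.lda.n_topics
        sel = self.path("k_selection.tsv")
        if sel.exists():
            table = pd.read_csv(sel, sep="\t")
            return int(table.loc[table["loglik"].idxmax(), "K"])
        if self.cfg.lda.grid is not None:
            return self.choose_k()[0]
        # Default for a corpus with S planted themes: K = S.
        return len(corpus.settings)

    # -- stage: choose-k -----------------------------------------------------
    def choose_k(self) -> tuple[int, Path]:
        corpus = self._prepared_corpus()
        rep = self._representative()
        vocab = set().union(*rep.values())
        docs = [tokens for _, tokens in self._restricted_docs(corpus, vocab)]
        best, table = select_num_topics(
            docs, grid=self.cfg.lda.grid,
            seed=derive_seed(self.cfg.seed, "choose_k"),
            alpha=self.cfg.lda.alpha, beta=self.cfg.lda.beta,
            iterations=self.cfg.lda.iterations, burnin=self.cfg.lda.burnin)
        dest = self.path("k_selection.tsv")
        _atomic_write(dest, lambda p: table.to_csv(p, sep="\t", index=False))
        self._manifest("choose-k", [self.path("corpus_prepared.jsonl")], [dest])
        logger.info("selected K=%d by log-likelihood", best)
        return best, dest

    # -- stage: fit ----------------------------------------------------------
    def fit(self) -> Path:
        corpus = self._prepared_corpus()
        rep = self._representative()
        vocab = set().union(*rep.values())
        docs = [tokens for _, tokens in self._restricted_docs(corpus, vocab)]
        n_topics = self._resolve_n_topics(corpus)
        model = fit_lda(
            docs, n_topics, alpha=self.cfg.lda.alpha, beta=self.cfg.lda.beta,
            iterations=self.cfg.lda.iterations, burnin=self.cfg.lda.burnin,
            seed=derive_seed(self.cfg.seed, "fit"), vocabulary=sorted(vocab))
        dest = self.path("model")
        save_model(model, dest)
        self._manifest("fit", [self.path("corpus_prepared.jsonl"),
                               self.path("representative.tsv")], [dest])
        return dest

    # -- stage: profile ------------------------------------------------------
    def profile(self) -> Path:
        model = load_model(self._require(self.path("model"), "fit"))
        rep = self._representative()
        profiles = setting_profile(term_topic_probabilities(model), rep)
        dest = self.path("profiles.tsv")
        _atomic_write(dest, lambda p: write_profiles_tsv(profiles, p))
        self._manifest("profile", [self.path("representative.tsv")], [dest])
        return dest

    def _profiles(self):
        from .profiles import SettingProfile
        path = self._require(self.path("profiles.tsv"), "profile")
        df = pd.read_csv(path, sep="\t")
        return [
            SettingProfile(str(row["setting"]),
                           row.iloc[1:].to_numpy(dtype=float), 1)
            for _, row in df.iterrows()
        ]

    # -- stage: similarity / cim ---------------------------------------------
    def similarity(self) -> Path:
        sim = pearson_matrix(self._profiles())
        dest = self.path("similarity.tsv")
        _atomic_write(dest, lambda p: write_similarity_tsv(sim, p))
        self._manifest("similarity", [self.path("profiles.tsv")], [dest])
        return dest

    def cim(self, png: bool = False) -> dict[str, Path]:
        sim = pearson_matrix(self._profiles())
        result = cluster_image_map(sim, self.cfg.cim_linkage, self.cfg.cim_bins)
        paths = {"order": self.path("cim_order.tsv"),
                 "binned": self.path("cim_binned.tsv")}
        _atomic_write(paths["order"], lambda p: pd.DataFrame(
            {"position": range(len(result.order)), "setting": result.order}
        ).to_csv(p, sep="\t", index=False))
        _atomic_write(paths["binned"], lambda p: pd.DataFrame(
            result.binned_matrix, index=result.order, columns=result.order
        ).to_csv(p, sep="\t"))
        if png:
            from .profiles import plot_cim
            paths["png"] = self.path("cim.png")
            plot_cim(result, paths["png"])
        self._manifest("cim", [self.path("profiles.tsv")], list(paths.values()))
        return paths

    # -- stage: evaluate -----------------------------------------------------
    def evaluate(self) -> dict[str, Path]:
        """Cross-validated (or fixed-holdout) setting prediction metrics.

        Self-contained: filtering and topic models are re-fit inside each
        training split; no previously fitted artifacts are required.
        """
        corpus = self._prepared_corpus()
        db = read_cooccurrence_db(self._db_path())
        ks = tuple(k for k in self.cfg.ks if k <= len(corpus.settings))
        if len(ks) < len(self.cfg.ks):
            logger.warning(
                "dropping cutoffs %s: k cannot exceed the %d candidate settings",
                sorted(set(self.cfg.ks) - set(ks)), len(corpus.settings))
        if not ks:
            raise DataError("no usable k cutoffs for this corpus")
        lda_cfg = self.cfg.lda
        if lda_cfg.n_topics is None and lda_cfg.grid is None:
            lda_cfg = dataclasses.replace(lda_cfg,
                                          n_topics=len(corpus.settings))
        if self.cfg.holdout_n:
            result = evaluate_holdout(
                corpus, db, self.cfg.holdout_n, self.cfg.filter, lda_cfg,
                ks=ks, seed=derive_seed(self.cfg.seed, "evaluate"))
        else:
            result = cross_validate(
                corpus, db, self.cfg.filter, lda_cfg, folds=self.cfg.folds,
                ks=ks, seed=derive_seed(self.cfg.seed, "evaluate"))
        paths = {"metrics": self.path("metrics.json"),
                 "rankings": self.path("rankings.tsv")}
        payload = json.dumps(metrics_to_json_dict(result), indent=2,
                             sort_keys=True) + "\n"
        _atomic_write(paths["metrics"], lambda p: p.write_text(payload))
        _atomic_write(paths["rankings"],
                      lambda p: write_rankings_tsv(result.rankings, p))
        self._manifest("evaluate",
                       [self.path("corpus_prepared.jsonl"), self._db_path()],
                       list(paths.values()))
        return paths

    # -- everything ----------------------------------------------------------
    def run_all(self) -> dict[str, Path]:
        artifacts: dict[str, Path] = {}
        if self.cfg.corpus_path is None:
            artifacts.update(self.simulate())
        artifacts["prepared"] = self.prepare()
        artifacts.update(self.filter_concepts())
        artifacts["model"] = self.fit()
        artifacts["profiles"] = self.profile()
        artifacts["similarity"] = self.similarity()
        artifacts.update(self.cim())
        artifacts.update(self.evaluate())
        return artifacts


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Convenience wrapper: run every stage under one config."""
    return Pipeline(cfg).run_all()
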