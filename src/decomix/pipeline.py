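"""End-to-end pipeline: preprocess → (K guidance) → deconvolve → interpret.

A :class:`RunConfig` captures every choice of a run (paths, modality,
engine, K, seed, preprocessing, enrichment parameters) and round-trips
through YAML; :func:`run_pipeline` executes the configured run and writes
the full downloadable artifact set:

``preprocessed.csv``, ``<prefix>.A.csv`` (proportions), ``<prefix>.T.csv``
(profiles), ``<prefix>.diagnostics.json``, ``top100_genes.csv``,
``enrichment.csv`` (when gene sets are given), ``resolved_config.yaml`` and
``run.log``.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .data import read_matrix_csv, write_matrix_csv
from .interpretation import enrichment_to_frame, read_gmt
from .model import DeconvolutionModel
from .preprocess import normalize_median_of_ratios, normalize_rpm, select_features_by_cv, transform
from .rank import scree

logger = logging.getLogger("decomix")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_cpg_map_csv"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run; YAML round-trippable."""

    input_path: str
    modality: str = "expression"
    engine: str = "nmf"
    k: int | None = None  # None: take the scree suggestion
    seed: int = 0
    normalize: str = "none"  # rpm | mor | none
    transform: str = "none"  # log2 | pseudolog | none
    top_features: int | None = None
    gmt_path: str | None = None
    cpg_map_path: str | None = None
    n_perm: int = 1000
    top_n_genes: int = 100
    out_dir: str = "decomix_run"
    prefix: str = "run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_cpg_map_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping CpG id → gene id."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("cpg map CSV needs two columns: cpg, gene")
    return dict(
        zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str))
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a configured run; returns the written files keyed by role."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written: dict[str, Path] = {"log": log_path}
    try:
        logger.info("resolved config: %s", dataclasses.asdict(config))
        config.to_yaml(out_dir / "resolved_config.yaml")
        written["config"] = out_dir / "resolved_config.yaml"

        m = _stage("load")(read_matrix_csv)(config.input_path, config.modality)
        logger.info("loaded %d features x %d samples", m.n_features, m.n_samples)

        m = _run_preprocess(config, m)
        pre_path = out_dir / "preprocessed.csv"
        write_matrix_csv(m, pre_path)
        written["preprocessed"] = pre_path

        k = config.k
        if k is None:
            sr = _stage("estimate-k")(scree)(m, simplex_mixture=True)
            k = sr.suggested_k
            logger.info("scree suggested K = %d", k)

        res = _stage("deconvolve")(
            lambda: DeconvolutionModel(m, k=k, engine=config.engine).fit(
                seed=config.seed
            )
        )()
        for p in res.save(out_dir / config.prefix):
            written[p.name.split(".", 1)[1]] = p
        logger.info("deconvolution done: %s", res.summary().replace("\n", " | "))

        written["top_genes"] = _write_top_genes(config, res, out_dir)

        if config.gmt_path:
            written["enrichment"] = _run_enrichment(config, res, out_dir)
        return written
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_preprocess(config: RunConfig, m):
    run = _stage("preprocess")
    if config.modality == "expression":
        if config.normalize == "rpm":
            m = run(normalize_rpm)(m)
        elif config.normalize == "mor":
            m = run(normalize_median_of_ratios)(m).matrix
        elif config.normalize != "none":
            raise PipelineError(
                "preprocess", f"unknown normalize option {config.normalize!r}"
            )
        if config.transform != "none":
            m = run(transform)(m, kind=config.transform)
    if config.top_features:
        m = run(select_features_by_cv)(m, config.top_features)
    return m


def _write_top_genes(config: RunConfig, res, out_dir: Path) -> Path:
    run = _stage("top-genes")
    if res.modality == "methylation" and config.cpg_map_path:
        from .interpretation import RankedGeneList, aggregate_cpg_to_gene

        cpg_map = read_cpg_map_csv(config.cpg_map_path)
        T = res.profiles

        def ranked_for(comp):
            scores = dict(zip(T.index.astype(str), T.iloc[:, comp - 1]))
            return RankedGeneList.from_scores(
                aggregate_cpg_to_gene(scores, cpg_map)
            )

    else:
        ranked_for = res.rank_genes
    rows = []
    for comp in range(1, res.k + 1):
        ranked = run(ranked_for)(comp).head(config.top_n_genes)
        for rank_idx, (gene, score) in enumerate(
            zip(ranked.gene_ids, ranked.scores), start=1
        ):
            rows.append(
                {
                    "component": f"C{comp}",
                    "rank": rank_idx,
                    "gene": gene,
                    "score": score,
                }
            )
    path = out_dir / "top100_genes.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _run_enrichment(config: RunConfig, res, out_dir: Path) -> Path:
    run = _stage("interpret")
    sets = run(read_gmt)(config.gmt_path)
    cpg_map = None
    if res.modality == "methylation":
        if not config.cpg_map_path:
            raise PipelineError(
                "interpret", "methylation input requires cpg_map_path"
            )
        cpg_map = read_cpg_map_csv(config.cpg_map_path)
    enriched = run(res.interpret)(
        sets, cpg_map=cpg_map, n_perm=config.n_perm, seed=config.seed
    )
    path = out_dir / "enrichment.csv"
    enrichment_to_frame(enriched).to_csv(path, index=False)
    return path
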