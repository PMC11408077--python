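"""End-to-end pipeline: load -> score -> select -> evaluate -> write.

One call produces the three output families (score table, selections,
error report) plus a run manifest that records the configuration, seed
and package versions needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .evaluation import CLASSIFIERS, EvalConfig, error_grid
from .scores import METHODS, ScoreConfig, score_all
from .selection import DEFAULT_KS, selection_grid

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("mdselect")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end run."""

    input: str
    output_dir: str
    label_column: str = io.DEFAULT_LABEL_COLUMN
    orientation: str = "samples"
    delimiter: str | None = None
    methods: tuple[str, ...] = METHODS
    ks: tuple[int, ...] = DEFAULT_KS
    classifiers: tuple[str, ...] = CLASSIFIERS
    score: ScoreConfig = field(default_factory=ScoreConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    force: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(
                f"[config] unknown method(s) {unknown}; valid: {list(METHODS)}"
            )
        unknown = [c for c in self.classifiers if c not in CLASSIFIERS]
        if unknown:
            raise ValueError(
                f"[config] unknown classifier(s) {unknown}; valid: {list(CLASSIFIERS)}"
            )
        if not self.methods or not self.ks or not self.classifiers:
            raise ValueError("[config] methods, ks and classifiers must be non-empty")
        if any(k < 1 for k in self.ks):
            raise ValueError("[config] every k must be >= 1")


def _setup_logging(level: str) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level.upper())


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all artifacts to ``output_dir``.

    Returns a name -> path map of the written files.  Configuration is
    validated before any data is touched; stage failures are re-raised
    with the stage name attached.  Existing outputs are never overwritten
    unless ``force`` is set.
    """
    _setup_logging(config.log_level)
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": outdir / "scores.csv",
        "selections": outdir / "selections.csv",
        "errors": outdir / "errors.csv",
        "manifest": outdir / "manifest.json",
    }
    if not config.force:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"[config] outputs already exist (use force to overwrite): {existing}"
            )

    try:
        log.info("loading %s", config.input)
        data = io.load_dataset(
            config.input,
            label_column=config.label_column,
            orientation=config.orientation,
            delimiter=config.delimiter,
        )
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    try:
        log.info("scoring %d genes x %d samples", data.n_genes, data.n_samples)
        table = score_all(data, config.score)
        io.write_score_table(table, paths["scores"])
    except Exception as exc:
        raise RuntimeError(f"[score] {exc}") from exc

    try:
        selections = selection_grid(table, config.methods, config.ks)
        io.write_selections(selections, paths["selections"], genelist_dir=outdir / "genelists")
    except Exception as exc:
        raise RuntimeError(f"[select] {exc}") from exc

    try:
        log.info("evaluating %d selections x %s", len(selections), list(config.classifiers))
        report = error_grid(data, selections, config.eval, config.classifiers)
        io.write_error_report(report, paths["errors"])
    except Exception as exc:
        raise RuntimeError(f"[evaluate] {exc}") from exc

    manifest = {
        "mdselect_version": __version__,
        "python": sys.version.split()[0],
        "config": _jsonable(config),
        "n_samples": data.n_samples,
        "n_genes": data.n_genes,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %s", outdir)
    return paths


def _jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
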