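"""End-to-end wiring: fixtures/accessions -> context -> rules -> LLM -> table.

This is the library-level entry point the command line wraps: it resolves
each run's inputs through a fetcher, builds and (if needed) summarizes the
context, applies the deterministic rule stage, completes the remaining
classes through the configured backend, resolves rule vs model values
under the chosen policy, propagates and normalizes, and returns final
annotation rows ready for export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import schema
from .context import build_context, summarize
from .lexicons import LexiconSet, load_default_lexicons
from .llm import Backend, MockBackend, infer_run, write_prediction_file
from .resolve import post_propagate, resolve_row
from .rules import AnnotationRow, run_rule_stage
from .sra_io import Fetcher, FixtureFetcher, fetch_record

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    token_budget: int = 2000
    resolution_policy: str = "locked"
    backend: str = "mock"
    seed: int = 0
    mock_substitution_rate: float = 0.0
    mock_abstention_rate: float = 0.0
    adapter_map: dict = field(default_factory=dict)
    prediction_dir: Optional[Path] = None


def make_backend(config: PipelineConfig) -> Backend:
    if config.backend == "mock":
        return MockBackend(
            substitution_rate=config.mock_substitution_rate,
            abstention_rate=config.mock_abstention_rate,
            seed=config.seed,
        )
    raise ValueError(
        f"backend {config.backend!r} is not available in this installation; "
        "use 'mock' or register a local runner behind the Backend contract"
    )


def annotate_run(
    fetcher: Fetcher,
    accession: str,
    lexicons: LexiconSet,
    backend: Backend,
    config: PipelineConfig,
    registry: Optional[schema.ClassRegistry] = None,
) -> AnnotationRow:
    """Run the full hybrid pipeline for one accession."""
    registry = registry or schema.registry()
    record = fetch_record(fetcher, accession)
    bundle = summarize(build_context(record), budget=config.token_budget)
    curated = run_rule_stage(record, bundle, lexicons, registry)
    predictions = infer_run(backend, bundle, registry)
    if config.prediction_dir is not None:
        config.prediction_dir.mkdir(parents=True, exist_ok=True)
        write_prediction_file(
            accession, predictions,
            config.prediction_dir / f"{accession}.predictions.json", registry,
        )
    resolved = resolve_row(curated, predictions, config.resolution_policy, registry)
    return post_propagate(resolved, lexicons)


def annotate_fixtures(
    fixture_dir: str | Path,
    config: Optional[PipelineConfig] = None,
    accessions: Optional[Sequence[str]] = None,
    lexicons: Optional[LexiconSet] = None,
) -> list[AnnotationRow]:
    """Annotate every run in a fixture directory (offline mode)."""
    config = config or PipelineConfig()
    lexicons = lexicons or load_default_lexicons()
    fetcher = FixtureFetcher(fixture_dir)
    backend = make_backend(config)
    registry = schema.registry()
    rows = []
    for accession in accessions or fetcher.run_accessions():
        try:
            rows.append(
                annotate_run(fetcher, accession, lexicons, backend, config, registry)
            )
        except Exception as exc:
            log.error("run %s failed: %s", accession, exc)
    return rows


def write_fixture_dir(samples, directory: str | Path) -> Path:
    """Materialize synthetic samples as an offline fixture directory."""
    import csv
    import re

    from .synthetic import render_fixture_xml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    api_rows = []
    truth_rows = []
    for sample in samples:
        run_xml, biosample_xml, api_row = render_fixture_xml(sample)
        run_acc = api_row["run_accession"]
        (directory / f"{run_acc}.run.xml").write_text(run_xml, encoding="utf-8")
        samn_id = re.search(r"SAMN\d+", biosample_xml).group(0)
        (directory / f"{samn_id}.biosample.xml").write_text(
            biosample_xml, encoding="utf-8"
        )
        api_rows.append(api_row)
        truth = {"run_accession": run_acc, "sample_id": sample.sample_id,
                 "split": sample.split or ""}
        for name, values in sample.truth.items():
            truth[name] = ";".join(values)
        truth_rows.append(truth)
    with open(directory / "api.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(api_rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(api_rows)
    with open(directory / "truth.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(truth_rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(truth_rows)
    return directory
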