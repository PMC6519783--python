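"""End-to-end run: ingest -> lexicon -> search -> reports -> ranking.

A run is configured by :class:`RunConfig` (loadable from YAML; every CLI flag
overrides its config key), writes all artifacts into one output directory and
records a manifest with input digests, parameters and per-stage counts, so
that identical inputs and configuration provably yield identical outputs.
On any stage failure partial outputs are removed and a :class:`PipelineError`
naming the stage is raised.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, Field

from . import corpus_io, lexicon as lexicon_mod, matcher, reporting
from .errors import PipelineError

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger("suppsignal")


class RunConfig(BaseModel):
    corpus: Path
    products: Path
    effects_vocab: Path
    effects_rules: Path
    out_dir: Path
    include_unspecified: bool = True
    category_filter: Optional[List[str]] = None
    min_hits: int = Field(0, ge=0)
    log_level: str = "INFO"

    def input_paths(self) -> Dict[str, Path]:
        return {
            "corpus": self.corpus,
            "products": self.products,
            "effects_vocab": self.effects_vocab,
            "effects_rules": self.effects_rules,
        }


def load_run_config(path: Path, **overrides) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to out_dir)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for name, path in cfg.input_paths().items():
        if not Path(path).is_file():
            raise PipelineError("config", FileNotFoundError(f"{name}: {path}"))

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        posts = corpus_io.parse_corpus(cfg.corpus)
        n_paragraphs = sum(len(p.paragraphs) for p in posts)
        logger.info("ingest: %d posts, %d paragraphs", len(posts), n_paragraphs)

        stage = "lexicon"
        products = lexicon_mod.load_products(cfg.products)
        effects = lexicon_mod.load_effects(cfg.effects_vocab, cfg.effects_rules)
        effective = lexicon_mod.effective_lexicon(effects, cfg.include_unspecified)
        logger.info(
            "lexicon: %d product entries, %d vocab items, %d rules (effective)",
            len(products), len(effective.vocab), len(effective.rules),
        )

        stage = "search"
        hits = matcher.search_corpus(posts, products, effective)
        if cfg.category_filter:
            hits = reporting.filter_by_category(
                hits, set(cfg.category_filter), known_labels=effective.labels
            )
        logger.info("search: %d hits", len(hits))
        hits_path = out_dir / "hits.tsv"
        matcher.write_hits(hits, hits_path)
        written.append(hits_path)

        stage = "reports"
        type_rows = reporting.effect_type_report(hits)
        detail_rows = reporting.effect_details_report(hits)
        annotated = reporting.paragraph_report(hits, posts, products)
        type_path = out_dir / "report_type.tsv"
        details_path = out_dir / "report_details.tsv"
        paragraphs_path = out_dir / "report_paragraphs.html"
        reporting.write_type_report(type_rows, type_path)
        reporting.write_details_report(detail_rows, details_path)
        paragraphs_path.write_text(
            reporting.render_html(annotated), encoding="utf-8"
        )
        written += [type_path, details_path, paragraphs_path]

        stage = "rank"
        ranking = reporting.rank_products(type_rows, cfg.min_hits)
        ranking_path = out_dir / "ranking.tsv"
        reporting.write_ranking(ranking, ranking_path)
        written.append(ranking_path)

        stage = "manifest"
        manifest = {
            "inputs": {
                name: _sha256(path) for name, path in cfg.input_paths().items()
            },
            "parameters": {
                "include_unspecified": cfg.include_unspecified,
                "category_filter": cfg.category_filter,
                "min_hits": cfg.min_hits,
            },
            "counts": {
                "n_posts": len(posts),
                "n_paragraphs": n_paragraphs,
                "n_product_entries": len(products),
                "n_vocab_items": len(effective.vocab),
                "n_rules": len(effective.rules),
                "n_hits": len(hits),
                "n_hit_paragraphs": len({h.paragraph_id for h in hits}),
                "n_type_rows": len(type_rows),
                "n_detail_rows": len(detail_rows),
                "n_products_ranked": len(ranking),
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(manifest_path)
        logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
        return manifest
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
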