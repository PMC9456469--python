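"""Keyword curation, method comparison and full-pipeline orchestration.

The enrichment score used throughout the reports is log1p(-log10 p) with
the natural-log log1p, so p = 1 maps to 0 and smaller p-values map to
strictly larger scores.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .dea import (
    ContrastSpec,
    QUANTILE_CONVENTION,
    preprocess,
    run_dea,
    select_tf_degs,
    volcano_table,
)
from .enrichment import EnrichmentResult, MethodRun, run_both_methods
from .matrix import write_expression
from .ontology import write_annotations, write_obo
from .semantics import build_tdm, clean_tokens, load_stopwords, top_words, word_correlations
from .synthetic import (
    RNG_ALGORITHM,
    SimConfig,
    simulate_expression,
    simulate_ontology,
    simulate_tf_catalog,
    write_tf_catalog,
)


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def enrichment_score(p: float) -> float:
    """log1p(-log10 p); 0 at p = 1, +inf (flagged by a warning) at p = 0."""
    if p > 1:
        raise ValueError(f"p-value {p} > 1")
    if p < 0:
        raise ValueError(f"p-value {p} < 0")
    if p == 0:
        warnings.warn("p = 0 gives an infinite enrichment score", stacklevel=2)
        return math.inf
    return math.log1p(-math.log10(p))


def load_default_keywords() -> list[str]:
    text = resources.files("tfenrich.data").joinpath("keywords.txt").read_text()
    return [
        line.strip().lower() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@dataclass
class CurationSelection:
    keywords: list[str]
    selected: list[EnrichmentResult]
    matched_keywords: dict[str, list[str]]  # term -> keywords hit
    enrichment_scores: dict[str, float]
    gene_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def by_keyword(self) -> dict[str, list[str]]:
        """keyword -> sorted term ids (the published tables' layout)."""
        out: dict[str, list[str]] = {k: [] for k in self.keywords}
        for r in self.selected:
            for k in self.matched_keywords[r.term]:
                out[k].append(r.term)
        return {k: sorted(v) for k, v in out.items() if v}


def select_by_keywords(
    results: list[EnrichmentResult],
    keywords,
    stopwords=None,
) -> CurationSelection:
    """Terms whose cleaned label tokens intersect the keyword list.

    Matching is case-insensitive and whole-token ("cell" never matches
    "cellular").
    """
    keywords = [k.lower() for k in keywords]
    if not keywords:
        warnings.warn("empty keyword list: nothing selected", stacklevel=2)
    if stopwords is None:
        stopwords = load_stopwords()
    kw_set = set(keywords)
    selected = []
    matched: dict[str, list[str]] = {}
    scores: dict[str, float] = {}
    for r in results:
        tokens = set(clean_tokens(r.label, stopwords))
        hits = sorted(tokens & kw_set)
        if hits:
            selected.append(r)
            matched[r.term] = hits
            scores[r.term] = enrichment_score(r.p)
    return CurationSelection(
        keywords=keywords,
        selected=selected,
        matched_keywords=matched,
        enrichment_scores=scores,
    )


def map_selection_to_genes(sel: CurationSelection, run: MethodRun) -> pd.DataFrame:
    """Bubble-plot table: one row per (TF-DEG, selected term) association."""
    rows = []
    gene_map: dict[str, frozenset[str]] = {}
    for r in sel.selected:
        genes = run.tf_degs_associated.get(r.term, frozenset())
        gene_map[r.term] = genes
        for g in sorted(genes):
            rows.append(
                {"tf_deg": g, "term": r.term, "label": r.label,
                 "enrichment_score": sel.enrichment_scores[r.term]}
            )
    sel.gene_map = gene_map
    return pd.DataFrame(rows, columns=["tf_deg", "term", "label", "enrichment_score"])


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_methods(runs: dict[tuple[int, str], MethodRun]) -> dict:
    """Per-stream overlap of the two methods' significant terms and TF-DEGs."""
    for method in (1, 2):
        for stream in ("up", "down"):
            if (method, stream) not in runs:
                raise ValueError(f"missing run for method {method}, stream {stream}")
    comparison: dict[str, dict] = {}
    for stream in ("up", "down"):
        r1, r2 = runs[(1, stream)], runs[(2, stream)]
        terms1 = {r.term for r in r1.significant}
        terms2 = {r.term for r in r2.significant}
        tf1 = set().union(*(r1.tf_degs_associated.get(r.term, frozenset()) for r in r1.significant)) if r1.significant else set()
        tf2 = set().union(*(r2.tf_degs_associated.get(r.term, frozenset()) for r in r2.significant)) if r2.significant else set()
        comparison[stream] = {
            "terms_method1": sorted(terms1),
            "terms_method2": sorted(terms2),
            "terms_common": sorted(terms1 & terms2),
            "terms_only_method1": sorted(terms1 - terms2),
            "terms_only_method2": sorted(terms2 - terms1),
            "terms_jaccard": _jaccard(terms1, terms2),
            "tf_degs_method1": sorted(tf1),
            "tf_degs_method2": sorted(tf2),
            "tf_degs_common": sorted(tf1 & tf2),
            "tf_degs_jaccard": _jaccard(tf1, tf2),
            "method2_terms_contained_in_method1": terms2 <= terms1,
            "method2_tf_degs_contained_in_method1": tf2 <= tf1,
            "method2_vacuous": not terms2,
        }
    return comparison


# ---------------------------------------------------------------------------
# orchestration


DEFAULT_CONFIG = {
    "sim": {},  # SimConfig field overrides
    "dea": {"alpha": 0.05, "lfc_threshold": 0.1, "shrinkage": True,
            "noise_filter": False, "sd_max": 0.3, "dist_min": 0.5},
    "gsea": {"min_size": 1, "alpha_term": 0.05, "alternative": "enriched"},
    "semantics": {"top_n": 100, "k": 10, "cor_min": 0.3},
    "curation": {"keywords": None},  # None -> shipped default list
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (config or {}).items():
        if section not in merged:
            raise KeyError(f"unknown config section {section!r}")
        merged[section].update(values)
    return merged


def _results_frame(run: MethodRun) -> pd.DataFrame:
    rows = [
        {
            "term": r.term,
            "label": r.label,
            "size": r.size,
            "ks_stat": r.ks_stat,
            "p": r.p,
            "order": r.order,
            "tf_degs": ";".join(sorted(run.tf_degs_associated.get(r.term, frozenset()))),
        }
        for r in run.results
    ]
    return pd.DataFrame(
        rows, columns=["term", "label", "size", "ks_stat", "p", "order", "tf_degs"]
    )


def run_all(config: dict | None = None, seed: int | None = None, outdir=None) -> dict:
    """Simulate -> preprocess -> DEA -> 4 GSEA runs -> semantics -> curation
    -> comparison; optionally writing all artifacts plus a manifest.

    Returns a bundle dict with the in-memory objects.  Deterministic for a
    fixed seed; on error, files already written are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    cfg = _merge_config(config)
    sim_kwargs = dict(cfg["sim"])
    if seed is not None:
        sim_kwargs["seed"] = seed
    sim_config = SimConfig(**sim_kwargs)
    sim_config.validate()

    outdir = Path(outdir) if outdir is not None else None
    written: list[Path] = []

    def _write(name: str, writer) -> None:
        if outdir is None:
            return
        path = outdir / name
        writer(path)
        written.append(path)

    try:
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)

        stage = "simulate"
        matrix, truth = simulate_expression(sim_config)
        dag, ann = simulate_ontology(sim_config, truth)
        catalog = simulate_tf_catalog(truth, sim_config)
        _write("expression.tsv", lambda p: write_expression(
            matrix, p, outdir / "design.tsv", outdir / "flags.tsv"))
        if outdir is not None:
            written += [outdir / "design.tsv", outdir / "flags.tsv"]
        _write("truth_genes.tsv", lambda p: truth.write(p, outdir / "truth_terms.tsv"))
        if outdir is not None:
            written.append(outdir / "truth_terms.tsv")
        _write("ontology.obo", lambda p: p.write_text(write_obo(dag)))
        _write("annotations.tsv", lambda p: write_annotations(
            {g: ts for g, ts in ann.direct.items()}, p))
        _write("tf_catalog.txt", lambda p: write_tf_catalog(catalog, p))

        stage = "preprocess"
        processed = preprocess(matrix)

        stage = "dea"
        contrast = ContrastSpec(treatment_group="treatment", control_group="control")
        d = cfg["dea"]
        if d["noise_filter"]:
            from .dea import noise_filter

            keep = noise_filter(processed, contrast, sd_max=d["sd_max"], dist_min=d["dist_min"])
            processed = processed.with_values(processed.values.loc[keep])
        stats_df = run_dea(
            processed, contrast,
            alpha=d["alpha"], lfc_threshold=d["lfc_threshold"], shrinkage=d["shrinkage"],
        )
        stats_df["is_tf"] = stats_df.index.isin(set(catalog))
        _write("gene_stats.tsv", lambda p: stats_df.drop(columns=["degenerate_variance"]).to_csv(
            p, sep="\t", index_label="gene", float_format="%.10g"))
        _write("volcano.tsv", lambda p: volcano_table(stats_df).to_csv(
            p, sep="\t", index_label="gene", float_format="%.10g"))
        tf_degs = select_tf_degs(stats_df, catalog)
        _write("tf_degs.tsv", lambda p: tf_degs.to_csv(
            p, sep="\t", index_label="gene", float_format="%.10g"))

        stage = "gsea"
        g = cfg["gsea"]
        runs = run_both_methods(
            stats_df, catalog, dag, ann,
            min_size=g["min_size"], alpha_term=g["alpha_term"],
            alternative=g["alternative"],
        )
        for (method, stream), run in runs.items():
            _write(
                f"gsea_method{method}_{stream}.tsv",
                lambda p, run=run: _results_frame(run).to_csv(
                    p, sep="\t", index=False, float_format="%.10g"),
            )

        stage = "semantics"
        s = cfg["semantics"]
        stopwords = load_stopwords()
        word_tables = {}
        association_tables = {}
        for (method, stream), run in runs.items():
            key = f"method{method}_{stream}"
            if len(run.significant) == 0:
                word_tables[key] = pd.DataFrame(columns=["word", "significance", "n_documents"])
                association_tables[key] = pd.DataFrame(
                    columns=["anchor", "word", "correlation", "anchor_significance"])
                continue
            tdm = build_tdm(run.significant, stopwords)
            counts = tdm.document_counts()
            word_tables[key] = pd.DataFrame(
                [
                    {"word": w, "significance": sig, "n_documents": counts[w]}
                    for w, sig in top_words(tdm, s["top_n"])
                ]
            )
            if tdm.n_documents >= 2:
                assoc = word_correlations(tdm, k=s["k"], cor_min=s["cor_min"])
            else:
                assoc = []
            association_tables[key] = pd.DataFrame(
                [
                    {"anchor": a.anchor, "word": a.word, "correlation": a.correlation,
                     "anchor_significance": a.anchor_significance}
                    for a in assoc
                ],
                columns=["anchor", "word", "correlation", "anchor_significance"],
            )
            _write(f"words_{key}.tsv", lambda p, k=key: word_tables[k].to_csv(
                p, sep="\t", index=False, float_format="%.10g"))
            _write(f"associations_{key}.tsv", lambda p, k=key: association_tables[k].to_csv(
                p, sep="\t", index=False, float_format="%.10g"))

        stage = "curate"
        keywords = cfg["curation"]["keywords"] or load_default_keywords()
        curations = {}
        bubbles = {}
        for (method, stream), run in runs.items():
            key = f"method{method}_{stream}"
            sel = select_by_keywords(run.significant, keywords, stopwords)
            curations[key] = sel
            bubbles[key] = map_selection_to_genes(sel, run)
            _write(f"curation_{key}.tsv", lambda p, sel=sel: pd.DataFrame(
                [
                    {"term": r.term, "label": r.label, "p": r.p, "order": r.order,
                     "keywords": ";".join(sel.matched_keywords[r.term]),
                     "enrichment_score": sel.enrichment_scores[r.term]}
                    for r in sel.selected
                ],
                columns=["term", "label", "p", "order", "keywords", "enrichment_score"],
            ).to_csv(p, sep="\t", index=False, float_format="%.10g"))
            _write(f"bubble_{key}.tsv", lambda p, k=key: bubbles[k].to_csv(
                p, sep="\t", index=False, float_format="%.10g"))

        stage = "compare"
        comparison = compare_methods(runs)
        _write("comparison.json", lambda p: p.write_text(
            json.dumps(comparison, indent=2, sort_keys=True) + "\n"))

        stage = "manifest"
        config_blob = json.dumps(cfg, sort_keys=True, default=str)
        manifest = {
            "package": "tfenrich",
            "version": __version__,
            "seed": sim_config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
            "rng_algorithm": RNG_ALGORITHM,
            "quantile_convention": QUANTILE_CONVENTION,
            "outputs": sorted(p.name for p in written),
        }
        _write("manifest.json", lambda p: p.write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"))
    except Exception as exc:  # remove partial outputs, then re-raise
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc

    return {
        "config": cfg,
        "sim_config": sim_config,
        "matrix": matrix,
        "truth": truth,
        "dag": dag,
        "annotation": ann,
        "catalog": catalog,
        "stats": stats_df,
        "runs": runs,
        "word_tables": word_tables,
        "association_tables": association_tables,
        "curations": curations,
        "bubbles": bubbles,
        "comparison": comparison,
        "manifest": manifest,
    }
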