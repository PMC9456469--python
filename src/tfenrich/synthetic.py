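"""Synthetic microarray study generator with planted ground truth.

Emulates a 4-vs-2 one-colour design: log2 intensities are
mu_g + delta_g * I[treatment] + eps with eps ~ Normal(0, sigma_g) and
sigma_g^2 drawn from a scaled inverse-chi-square prior (d0, s0^2), so the
moderated-t hyperparameters are recoverable.  A configurable fraction of
genes is differentially expressed (half up, half down); a subset of genes
is labelled transcription factors, and planted ontology terms are
annotated preferentially to the DE transcription factors of one stream.
DE transcription factors get a reduced residual variance so that planted
terms carry a detectable score signal within a stream's DEG universe.

All randomness flows through numpy's default PCG64 generator seeded from
``SimConfig.seed``; fixed seed means bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .ontology import GoAnnotation, GoDag, propagate

RNG_ALGORITHM = "numpy default_rng (PCG64)"


@dataclass
class SimConfig:
    n_probes: int = 2000
    n_control: int = 4
    n_treatment: int = 2
    de_fraction: float = 0.05
    effect_size_log2: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    d0: float = 4.0
    s0_sq: float = 0.05
    tf_fraction: float = 0.1
    n_go_terms: int = 25
    planted_term_count: int = 2
    flag_absent_rate: float = 0.02
    seed: int = 0
    # variance down-scale for DE transcription factors: the planted signal
    # that makes TF-annotated terms enrichable within a stream's DEGs
    tf_de_variance_scale: float = 0.02
    planted_pad: int = 5  # min non-TF DE genes padded into each planted term
    marginal_rate: float = 0.03

    def validate(self) -> None:
        for name in ("de_fraction", "tf_fraction", "flag_absent_rate", "marginal_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        for name in (
            "effect_size_log2", "baseline_sd", "d0", "s0_sq", "tf_de_variance_scale",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real, got {v}")
        if not np.isfinite(self.baseline_mean):
            raise ValueError("baseline_mean must be finite")
        for name in ("n_probes", "n_control", "n_treatment", "n_go_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_control + self.n_treatment < 3:
            raise ValueError("need at least 3 samples in total")
        if self.planted_term_count < 0:
            raise ValueError("planted_term_count must be non-negative")
        if self.planted_term_count > self.n_go_terms:
            raise ValueError("planted_term_count cannot exceed n_go_terms")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted ground truth: per-gene DE status and per-term planting."""

    genes: pd.DataFrame  # index gene; is_de, direction, true_log2fc, is_tf
    terms: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["is_planted", "planted_stream"]
        )
    )

    def de_genes(self, direction: str | None = None) -> list[str]:
        g = self.genes
        mask = g["is_de"]
        if direction is not None:
            mask = mask & (g["direction"] == direction)
        return list(g.index[mask])

    def tf_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_tf"]])

    def write(self, genes_path, terms_path=None) -> None:
        self.genes.to_csv(genes_path, sep="\t", index_label="gene")
        if terms_path is not None:
            self.terms.to_csv(terms_path, sep="\t", index_label="term")


def _gene_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Linear-scale intensity matrix plus the planted truth table."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_probes
    genes = _gene_ids(n)

    n_de = round(config.de_fraction * n)
    n_up = n_de // 2  # up rounded down on odd counts
    n_down = n_de - n_up
    de_idx = rng.choice(n, size=n_de, replace=False)
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]

    delta = np.zeros(n)
    delta[up_idx] = config.effect_size_log2
    delta[down_idx] = -config.effect_size_log2

    # transcription factors: stratified over up / down / non-DE so each
    # stream holds its expected share of TF-DEGs
    n_tf = round(config.tf_fraction * n)
    is_tf = np.zeros(n, dtype=bool)
    n_tf_up = min(round(config.tf_fraction * n_up), n_tf)
    n_tf_down = min(round(config.tf_fraction * n_down), n_tf - n_tf_up)
    rest_idx = np.setdiff1d(np.arange(n), de_idx)
    picks = []
    if n_tf_up:
        picks.append(rng.choice(up_idx, size=n_tf_up, replace=False))
    if n_tf_down:
        picks.append(rng.choice(down_idx, size=n_tf_down, replace=False))
    n_tf_rest = n_tf - n_tf_up - n_tf_down
    if n_tf_rest:
        picks.append(rng.choice(rest_idx, size=min(n_tf_rest, rest_idx.size), replace=False))
    if picks:
        is_tf[np.concatenate(picks)] = True

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    sigma2 = config.d0 * config.s0_sq / rng.chisquare(config.d0, size=n)
    sigma2[(delta != 0) & is_tf] *= config.tf_de_variance_scale

    n_samples = config.n_control + config.n_treatment
    treated = np.zeros(n_samples, dtype=bool)
    treated[config.n_control:] = True
    eps = rng.normal(0.0, 1.0, size=(n, n_samples)) * np.sqrt(sigma2)[:, None]
    log2_expr = mu[:, None] + np.outer(delta, treated.astype(float)) + eps
    values = np.exp2(log2_expr)

    # control sub-conditions recorded for realism (pooled as one group)
    n_ev = math.ceil(config.n_control / 2)
    sample_ids = (
        [f"ctrl_EV_{i+1}" for i in range(n_ev)]
        + [f"ctrl_D1028A_{i+1}" for i in range(config.n_control - n_ev)]
        + [f"treat_{i+1}" for i in range(config.n_treatment)]
    )
    groups = {
        s: ("treatment" if t else "control") for s, t in zip(sample_ids, treated)
    }

    u = rng.random(size=(n, n_samples))
    flags = np.full((n, n_samples), "P", dtype="U1")
    flags[u < config.flag_absent_rate + config.marginal_rate] = "M"
    flags[u < config.flag_absent_rate] = "A"

    values_df = pd.DataFrame(values, index=genes, columns=sample_ids)
    flags_df = pd.DataFrame(flags, index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(
        values=values_df,
        groups=groups,
        flags=flags_df,
        scale="linear",
        normalized=False,
        meta={"rng": RNG_ALGORITHM, "seed": config.seed},
    )

    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
    truth_genes = pd.DataFrame(
        {
            "is_de": delta != 0,
            "direction": direction,
            "true_log2fc": delta,
            "is_tf": is_tf,
            "true_sigma2": sigma2,
        },
        index=pd.Index(genes, name="gene"),
    )
    return matrix, TruthTable(genes=truth_genes)


def load_vocabulary() -> list[str]:
    text = resources.files("tfenrich.data").joinpath("vocabulary.txt").read_text()
    return [
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def simulate_ontology(
    config: SimConfig, truth: TruthTable
) -> tuple[GoDag, GoAnnotation]:
    """Rooted random is_a DAG with planted term annotations.

    Planted terms receive the DE transcription factors of their stream as
    direct annotations (plus background genes); every gene is annotated to
    at least one term.  Fills ``truth.terms`` in place.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n_terms = config.n_go_terms
    term_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    vocab = load_vocabulary()

    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(term_ids)
    terms: dict[str, tuple[str, str]] = {}
    used_labels = set()
    for i, tid in enumerate(term_ids):
        if i == 0:
            label = "biological process"
        else:
            n_parents = 1 if (i == 1 or rng.random() < 0.7) else 2
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                graph.add_edge(tid, term_ids[int(p)])
            for _ in range(100):
                k = int(rng.integers(2, 5))
                words = rng.choice(len(vocab), size=k, replace=False)
                label = " ".join(vocab[int(w)] for w in sorted(words))
                if label not in used_labels:
                    break
        used_labels.add(label)
        terms[tid] = (label, "biological_process")
    dag = GoDag(terms=terms, graph=graph)
    dag.validate()

    genes = list(truth.genes.index)
    non_root = term_ids[1:] if n_terms > 1 else term_ids

    planted_ids: list[str] = []
    streams: list[str] = []
    if config.planted_term_count:
        # plant only on leaves: an internal term inherits its descendants'
        # genes and can blanket the whole universe, becoming untestable
        leaves = [t for t in non_root if not dag.children(t)]
        candidates = leaves if len(leaves) >= config.planted_term_count else non_root
        if len(candidates) < config.planted_term_count:
            candidates = term_ids
        pick = rng.choice(
            len(candidates), size=config.planted_term_count, replace=False
        )
        planted_ids = [candidates[int(i)] for i in sorted(pick)]
        streams = ["up" if i % 2 == 0 else "down" for i in range(len(planted_ids))]

    # background annotations go to non-planted terms so the planted signal
    # is not diluted by random members
    background_terms = [t for t in non_root if t not in planted_ids] or non_root
    direct: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(
            len(background_terms), size=min(k, len(background_terms)), replace=False
        )
        direct[g] = {background_terms[int(c)] for c in chosen}

    if planted_ids:
        tf = set(truth.tf_genes())
        for tid, stream in zip(planted_ids, streams):
            stream_de = truth.de_genes(stream)
            members = {g for g in stream_de if g in tf}
            # pad with the stream's most reliable (lowest-variance) DE genes
            # so the planted term carries a clear score signal
            by_noise = sorted(
                (g for g in stream_de if g not in members),
                key=lambda g: truth.genes.at[g, "true_sigma2"],
            )
            members |= set(by_noise[: max(config.planted_pad, len(members))])
            background = rng.choice(len(genes), size=min(5, len(genes)), replace=False)
            ann_set = members | {genes[int(b)] for b in background}
            for g in ann_set:
                direct[g].add(tid)

    truth.terms = pd.DataFrame(
        {
            "is_planted": [t in planted_ids for t in term_ids],
            "planted_stream": [
                streams[planted_ids.index(t)] if t in planted_ids else "none"
                for t in term_ids
            ],
        },
        index=pd.Index(term_ids, name="term"),
    )
    return dag, propagate(dag, direct)


def simulate_tf_catalog(truth: TruthTable, config: SimConfig) -> list[str]:
    """Gene symbols flagged as transcription factors in the truth table."""
    return truth.tf_genes()


def write_tf_catalog(catalog, path) -> None:
    with open(path, "w") as fh:
        for symbol in catalog:
            fh.write(f"{symbol}\n")


def read_tf_catalog(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
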