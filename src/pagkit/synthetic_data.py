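"""Seeded synthetic-fixture generator.

Produces every input the toolkit consumes — a differential-expression table,
a GMT gene-set collection, per-tool enrichment-term lists, a citation-count
table and a ground-truth label table — with planted, recorded structure so
every analysis path can be exercised and verified offline:

* a minority of gene sets is genuinely enriched in the candidate genes;
* tool term lists are noisy paraphrases of shared underlying concepts with
  known Venn regions;
* co-citation counts are drawn from a binomial null with an odds multiplier
  for the enriched sets;
* reference adjusted p-values follow a two-normal signal model whose
  separation implies a closed-form expected AUC.

Everything is deterministic given the seed; the planted truths are written
to a JSON manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ArgumentError
from .io_formats import (
    PAG,
    ToolTermList,
    write_citation_table,
    write_gmt,
    write_term_list,
)
from .term_matching import normalize_term, string_similarity

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture", "write_fixture"]

_TOOLS = ("toolA", "toolB", "toolC")

# Venn region template (fractions of the concept pool) used to plant the
# three-tool consensus structure.
_REGION_TEMPLATE: dict[tuple[str, ...], int] = {
    ("toolA", "toolB", "toolC"): 20,
    ("toolA", "toolB"): 8,
    ("toolA", "toolC"): 6,
    ("toolB", "toolC"): 6,
    ("toolA",): 26,
    ("toolB",): 26,
    ("toolC",): 28,
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    universe_size: int = 2000
    n_pags: int = 50
    pag_size_range: tuple[int, int] = (20, 60)
    n_enriched: int = 3
    candidate_fraction_of_enriched: float = 0.8
    de_effect_log2fc: float = 2.0
    term_paraphrase_rate: float = 0.3
    citation_background: tuple[int, int] = (1_000_000, 50_000)
    enriched_cocitation_boost: float = 20.0
    truth_auc_effect: float = 2.5
    term_similarity_cutoff: float = 0.8
    n_gene_blocks: int = 5
    block_affinity: float = 0.6
    region_counts: dict = field(default_factory=lambda: dict(_REGION_TEMPLATE))

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_pags:
            raise ArgumentError("n_enriched cannot exceed n_pags")
        if min(self.universe_size, self.n_pags, self.n_enriched) < 0:
            raise ArgumentError("sizes must be non-negative")
        lo, hi = self.pag_size_range
        if not (0 < lo <= hi <= self.universe_size):
            raise ArgumentError("invalid pag_size_range")
        if not (0.0 <= self.candidate_fraction_of_enriched <= 1.0):
            raise ArgumentError("candidate_fraction_of_enriched must be in [0,1]")
        if not (0.0 <= self.term_paraphrase_rate <= 1.0):
            raise ArgumentError("term_paraphrase_rate must be in [0,1]")
        N, K = self.citation_background
        if not (0 < K <= N):
            raise ArgumentError("citation_background must satisfy 0 < K <= N")
        if not (1 <= self.n_gene_blocks <= self.universe_size):
            raise ArgumentError("n_gene_blocks must be in [1, universe_size]")
        if not (0.0 <= self.block_affinity <= 1.0):
            raise ArgumentError("block_affinity must be in [0, 1]")

    @property
    def expected_auc(self) -> float:
        """Closed-form AUC implied by the two-normal truth model."""
        return float(norm.cdf(self.truth_auc_effect / math.sqrt(2.0)))


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    de_records: list  # list[DEGeneRecord]-compatible rows (gene, fc, p)
    pags: list[PAG]
    term_lists: dict[str, ToolTermList]
    citation_counts: dict[str, tuple[int, int]]
    citation_background: tuple[int, int]
    truth_table: list[tuple[str, float, int]]  # (pag_id, reference adjusted p, overlap)
    tool_adjusted_p: dict[str, float]  # generated tool's ranking, per pag_id
    manifest: dict


def _random_word(rng: np.random.Generator, lo: int = 5, hi: int = 9) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    length = int(rng.integers(lo, hi))
    return "".join(letters[i] for i in rng.integers(0, 26, size=length))


def _concept_names(rng: np.random.Generator, count: int, cutoff: float) -> list[str]:
    """Mutually dissimilar multi-token concept names.

    Rejection-sampled so that no two names (normalized) reach ``cutoff``
    similarity — this keeps planted Venn regions exactly recoverable.
    """
    names: list[str] = []
    guard = max(0.05, cutoff - 0.2)
    attempts = 0
    while len(names) < count:
        attempts += 1
        if attempts > 200 * count:
            raise ArgumentError("could not generate dissimilar concept names")
        n_tokens = int(rng.integers(2, 4))
        cand = " ".join(_random_word(rng) for _ in range(n_tokens))
        if all(string_similarity(cand, prev) < guard for prev in names):
            names.append(cand)
    return names


def _paraphrase(
    name: str,
    rng: np.random.Generator,
    rate: float,
    cutoff: float,
    allow_shuffle: bool = True,
) -> str:
    """Noisy variant of a term exercising normalization and edit-distance.

    Operations: species-suffix insertion, identifier suffix, case
    randomization, token shuffling.  The generator guarantees the variant
    still normalizes to >= ``cutoff`` similarity with the base name (token
    shuffles that would break recoverability fall back to a suffix), so
    planted consensus regions stay recoverable.  At most one tool per
    concept may receive a shuffled variant — two independently shuffled
    variants of the same base need not be mutually similar.
    """
    if rng.random() >= rate:
        return name
    op = int(rng.integers(0, 4 if allow_shuffle else 3))
    if op == 0:
        variant = f"{name} - Homo sapiens (human)"
    elif op == 1:
        variant = f"{name} hsa{int(rng.integers(1000, 9999))}"
    elif op == 2:
        variant = "".join(
            ch.upper() if rng.random() < 0.5 else ch for ch in name
        )
    else:
        tokens = name.split()
        perm = rng.permutation(len(tokens))
        variant = " ".join(tokens[i] for i in perm)
        base_norm = normalize_term(name).normalized
        var_norm = normalize_term(variant).normalized
        if string_similarity(base_norm, var_norm) < min(1.0, cutoff + 0.05):
            variant = f"{name} - Homo sapiens (human)"
    return variant


def generate_fixture(spec: FixtureSpec | None = None) -> FixtureBundle:
    """Generate the full synthetic input bundle for one seed."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    width = len(str(spec.universe_size))
    genes = [f"G{i:0{width}d}" for i in range(1, spec.universe_size + 1)]

    # --- gene-set collection with planted enriched sets -------------------
    # Null PAGs draw ``block_affinity`` of their genes from a shared per-block
    # core, so the co-membership network has real edges and community
    # structure.  Enriched PAGs are fully random: their candidate genes must
    # not leak into null sets, keeping planted-enrichment recovery clean.
    lo, hi = spec.pag_size_range
    n_blocks = spec.n_gene_blocks
    core_size = max(1, min(30, spec.universe_size // (2 * n_blocks)))
    cores = [
        rng.choice(spec.universe_size, size=core_size, replace=False)
        for _ in range(n_blocks)
    ]
    pags: list[PAG] = []
    blocks: list[int] = []
    for i in range(spec.n_pags):
        size = int(rng.integers(lo, hi + 1))
        if i < spec.n_enriched:
            blocks.append(-1)  # no block: fully random membership
            picked = set(
                rng.choice(spec.universe_size, size=size, replace=False).tolist()
            )
        else:
            block = i % n_blocks
            blocks.append(block)
            n_core = min(int(round(spec.block_affinity * size)), core_size)
            picked = set(
                rng.choice(cores[block], size=n_core, replace=False).tolist()
            )
            while len(picked) < size:
                picked.add(int(rng.integers(0, spec.universe_size)))
        pags.append(
            PAG(
                pag_id=f"PAG{i + 1:04d}",
                name=f"PAG{i + 1:04d}",
                source="synthetic",
                genes=frozenset(genes[j] for j in sorted(picked)),
            )
        )
    enriched_ids = [p.pag_id for p in pags[: spec.n_enriched]]

    # --- DE table: candidates from enriched sets, nulls below threshold ---
    candidates: set[str] = set()
    for pag in pags[: spec.n_enriched]:
        members = sorted(pag.genes)
        take = max(1, int(round(spec.candidate_fraction_of_enriched * len(members))))
        picked = rng.choice(len(members), size=take, replace=False)
        candidates |= {members[i] for i in picked}
    de_rows: list[tuple[str, float, float]] = []
    for g in genes:
        if g in candidates:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fc = sign * (spec.de_effect_log2fc + float(rng.uniform(0.0, 0.5)))
            p = float(rng.uniform(1e-8, 0.01))
        else:
            # nulls can never pass |log2fc| >= 1 regardless of p
            fc = float(rng.uniform(-0.8, 0.8))
            p = float(rng.uniform(0.0, 1.0)) or 1e-12
        de_rows.append((g, fc, p))

    # --- tool term lists with planted Venn regions ------------------------
    region_counts = {tuple(sorted(k)): v for k, v in spec.region_counts.items()}
    n_concepts = sum(region_counts.values())
    names = _concept_names(rng, n_concepts, spec.term_similarity_cutoff)
    concept_regions: list[tuple[str, tuple[str, ...]]] = []
    idx = 0
    for region in sorted(region_counts):
        for _ in range(region_counts[region]):
            concept_regions.append((names[idx], region))
            idx += 1
    tool_entries: dict[str, list[tuple[str, float]]] = {t: [] for t in _TOOLS}
    for name, region in concept_regions:
        for pos, tool in enumerate(region):
            variant = _paraphrase(
                name,
                rng,
                spec.term_paraphrase_rate,
                spec.term_similarity_cutoff,
                allow_shuffle=(pos == 0),
            )
            tool_entries[tool].append((variant, float(rng.uniform(1e-6, 0.05))))
    term_lists = {
        tool: ToolTermList(tool_id=tool, entries=entries)
        for tool, entries in tool_entries.items()
    }

    # --- citation counts: binomial null with a boost for enriched sets ----
    N_bg, K_bg = spec.citation_background
    base_rate = K_bg / N_bg
    citation_counts: dict[str, tuple[int, int]] = {}
    for pag in pags:
        n_kw = int(rng.integers(200, 5001))
        rate = base_rate * (
            spec.enriched_cocitation_boost if pag.pag_id in enriched_ids else 1.0
        )
        k_kw = int(rng.binomial(n_kw, min(1.0, rate)))
        k_kw = min(k_kw, n_kw, K_bg)
        citation_counts[pag.pag_id] = (n_kw, k_kw)

    # --- ground truth + tool ranking under the two-normal model -----------
    truth_table: list[tuple[str, float, int]] = []
    tool_adjusted_p: dict[str, float] = {}
    for pag in pags:
        is_true = pag.pag_id in enriched_ids
        if is_true:
            ref_p = float(rng.uniform(1e-4, 0.05))
        else:
            ref_p = float(rng.uniform(0.0500001, 1.0))
        overlap = len(pag.genes & candidates)
        truth_table.append((pag.pag_id, ref_p, overlap))
        z = float(rng.normal(spec.truth_auc_effect if is_true else 0.0, 1.0))
        tool_adjusted_p[pag.pag_id] = float(min(1.0, max(1e-300, norm.cdf(-z))))

    manifest = {
        "seed": spec.seed,
        "enriched_pags": enriched_ids,
        "pag_blocks": {p.pag_id: b for p, b in zip(pags, blocks)},
        "candidates": sorted(candidates),
        "region_counts": {"|".join(k): v for k, v in region_counts.items()},
        "concept_regions": [
            {"name": n, "region": list(r)} for n, r in concept_regions
        ],
        "true_pathways": enriched_ids,
        "expected_auc": spec.expected_auc,
    }
    return FixtureBundle(
        spec=spec,
        de_records=de_rows,
        pags=pags,
        term_lists=term_lists,
        citation_counts=citation_counts,
        citation_background=(N_bg, K_bg),
        truth_table=truth_table,
        tool_adjusted_p=tool_adjusted_p,
        manifest=manifest,
    )


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to standard text formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "de_table": outdir / "de_table.tsv",
        "gmt": outdir / "collection.gmt",
        "citations": outdir / "citations.tsv",
        "truth": outdir / "truth.tsv",
        "tool_scores": outdir / "tool_scores.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["de_table"], "w", encoding="utf-8") as fh:
        fh.write("gene\tlog2fc\tpvalue\n")
        for g, fc, p in bundle.de_records:
            fh.write(f"{g}\t{fc:.6g}\t{p:.6g}\n")
    write_gmt(bundle.pags, paths["gmt"])
    write_citation_table(bundle.citation_counts, paths["citations"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tadjusted_p\toverlap\n")
        for pid, p, ov in bundle.truth_table:
            fh.write(f"{pid}\t{p:.6g}\t{ov}\n")
    with open(paths["tool_scores"], "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tadjusted_p\n")
        for pid, p in bundle.tool_adjusted_p.items():
            fh.write(f"{pid}\t{p:.6g}\n")
    for tool, tl in bundle.term_lists.items():
        path = outdir / f"terms_{tool}.tsv"
        write_term_list(tl, path)
        paths[f"terms_{tool}"] = path
    manifest = dict(bundle.manifest)
    spec_dump = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in asdict(bundle.spec).items()
    }
    spec_dump["region_counts"] = {
        "|".join(sorted(k)): v for k, v in bundle.spec.region_counts.items()
    }
    manifest["spec"] = spec_dump
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
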