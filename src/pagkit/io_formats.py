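"""Readers and writers for the file formats the toolkit touches.

All tabular formats are tab-delimited UTF-8 with a header row (except GMT,
which is the standard headerless gene-set format).  Parsing is strict: rows
that violate the documented contracts raise :class:`~pagkit.errors.InputError`
or :class:`~pagkit.errors.ConfigError` rather than being silently dropped.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError

logger = logging.getLogger("pagkit")

__all__ = [
    "DEGeneRecord",
    "PAG",
    "ToolTermList",
    "read_de_table",
    "read_gmt",
    "write_gmt",
    "read_citation_table",
    "write_citation_table",
    "read_term_list",
    "write_term_list",
    "load_run_config",
    "write_edge_list",
    "write_graphml",
]


@dataclass(frozen=True)
class DEGeneRecord:
    """One gene's differential-expression evidence."""

    gene_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise InputError(f"log2fc for {self.gene_id!r} is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise InputError(
                f"pvalue for {self.gene_id!r} must lie in (0, 1], got {self.pvalue}"
            )


@dataclass
class PAG:
    """A named gene set (pathway, annotated list, or gene signature).

    Gene symbols are upper-cased at load time for matching; the original
    spelling is retained in ``display_genes``.
    """

    pag_id: str
    name: str
    source: str
    genes: frozenset[str]
    pag_type: str = "P"
    display_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.pag_id:
            raise InputError("pag_id must be non-empty")
        if self.pag_type not in ("P", "A", "G"):
            raise InputError(f"pag_type must be one of P/A/G, got {self.pag_type!r}")
        self.genes = frozenset(g.upper() for g in self.genes)
        if not self.genes:
            raise InputError(f"PAG {self.pag_id!r} has an empty gene set")
        if not self.display_genes:
            self.display_genes = tuple(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ToolTermList:
    """Enrichment terms reported by one tool, with adjusted p-values."""

    tool_id: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.tool_id:
            raise InputError("tool_id must be non-empty")
        for term, p in self.entries:
            if not term:
                raise InputError(f"empty term in list for tool {self.tool_id!r}")
            if not (0.0 < p <= 1.0):
                raise InputError(
                    f"adjusted_p for term {term!r} must lie in (0, 1], got {p}"
                )

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.entries]


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    fc_col: str = "log2fc",
    p_col: str = "pvalue",
) -> list[DEGeneRecord]:
    """Read a tab-delimited differential-expression table.

    Only the three named columns are used; extra columns are ignored.  Rows
    with non-numeric or out-of-range values are reported by their 1-based
    data-row number.  Duplicate gene symbols keep the row with the smallest
    p-value (a warning is logged).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"DE table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"DE table is empty: {path}") from None
    if df.empty:
        raise InputError(f"DE table has no data rows: {path}")
    for col in (gene_col, fc_col, p_col):
        if col not in df.columns:
            raise ConfigError(
                f"DE table {path} is missing required column {col!r} "
                f"(found: {list(df.columns)})"
            )
    fc = pd.to_numeric(df[fc_col], errors="coerce")
    pv = pd.to_numeric(df[p_col], errors="coerce")
    bad = df.index[
        fc.isna()
        | pv.isna()
        | ~fc.apply(math.isfinite).fillna(False).astype(bool)
        | (pv <= 0)
        | (pv > 1)
    ]
    if len(bad) > 0:
        rows = ", ".join(str(i + 1) for i in bad[:20])
        raise InputError(
            f"DE table {path}: invalid log2fc/p-value in row(s) {rows}"
        )
    records: list[DEGeneRecord] = []
    best: dict[str, int] = {}
    for i, (g, f_, p_) in enumerate(zip(df[gene_col], fc, pv)):
        g = str(g).strip()
        rec = DEGeneRecord(gene_id=g, log2fc=float(f_), pvalue=float(p_))
        if g in best:
            logger.warning(
                "duplicate gene %r in DE table; keeping smallest p-value", g
            )
            if rec.pvalue < records[best[g]].pvalue:
                records[best[g]] = rec
        else:
            best[g] = len(records)
            records.append(rec)
    return records


def read_gmt(path: str | Path) -> list[PAG]:
    """Read a GMT gene-set file (name, description, gene1, gene2, ...).

    Genes are upper-cased and de-duplicated preserving first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    pags: list[PAG] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            pag_id, desc = fields[0], fields[1]
            raw_genes = [g for g in fields[2:] if g.strip()]
            if not raw_genes:
                raise InputError(f"{path}:{lineno}: GMT line has no genes")
            if pag_id in seen_ids:
                raise InputError(f"{path}:{lineno}: duplicate PAG id {pag_id!r}")
            seen_ids.add(pag_id)
            deduped = list(dict.fromkeys(g.upper() for g in raw_genes))
            pags.append(
                PAG(
                    pag_id=pag_id,
                    name=pag_id,
                    source=desc,
                    genes=frozenset(deduped),
                    display_genes=tuple(deduped),
                )
            )
    if not pags:
        raise InputError(f"GMT file has no gene sets: {path}")
    return pags


def write_gmt(pags: Iterable[PAG], path: str | Path) -> None:
    """Write gene sets in GMT format (genes in sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pag in pags:
            genes = "\t".join(sorted(pag.genes))
            fh.write(f"{pag.pag_id}\t{pag.source}\t{genes}\n")


def read_citation_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a keyword citation-count table (columns: keyword, n, k).

    ``n`` is the keyword's citation count, ``k`` the joint disease+keyword
    count; ``n >= k >= 0`` is enforced and duplicate keywords rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"citation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"keyword": str})
    for col in ("keyword", "n", "k"):
        if col not in df.columns:
            raise ConfigError(f"citation table missing column {col!r}")
    out: dict[str, tuple[int, int]] = {}
    for _, row in df.iterrows():
        kw = str(row["keyword"])
        n, k = int(row["n"]), int(row["k"])
        if kw in out:
            raise InputError(f"duplicate keyword {kw!r} in citation table")
        if n < 0 or k < 0:
            raise InputError(f"negative count for keyword {kw!r}")
        if k > n:
            raise InputError(f"keyword {kw!r}: k={k} exceeds n={n}")
        out[kw] = (n, k)
    if not out:
        raise InputError(f"citation table has no rows: {path}")
    return out


def write_citation_table(
    counts: Mapping[str, tuple[int, int]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("keyword\tn\tk\n")
        for kw, (n, k) in counts.items():
            fh.write(f"{kw}\t{n}\t{k}\n")


def read_term_list(path: str | Path, tool_id: str | None = None) -> ToolTermList:
    """Read one tool's term list (columns: tool, term, adjusted_p).

    The ``tool`` column may be omitted if ``tool_id`` is given; if present it
    must be constant within the file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"term list not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"term": str})
    for col in ("term", "adjusted_p"):
        if col not in df.columns:
            raise ConfigError(f"term list {path} missing column {col!r}")
    if "tool" in df.columns:
        tools = set(df["tool"].astype(str))
        if len(tools) != 1:
            raise InputError(f"term list {path} mixes tools: {sorted(tools)}")
        file_tool = tools.pop()
        tool_id = tool_id or file_tool
    if tool_id is None:
        tool_id = path.stem
    entries = [
        (str(t), float(p)) for t, p in zip(df["term"], df["adjusted_p"])
    ]
    return ToolTermList(tool_id=tool_id, entries=entries)


def write_term_list(term_list: ToolTermList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tool\tterm\tadjusted_p\n")
        for term, p in term_list.entries:
            fh.write(f"{term_list.tool_id}\t{term}\t{p:.6g}\n")


_DEFAULT_CONFIG = {
    "p_cutoff": 0.05,
    "abs_log2fc_cutoff": 1.0,
    "min_overlap": 2,
    "sim_cutoff": 0.0,
    "neg_log2p_cutoff": 4.32,
    "term_similarity_cutoff": 0.8,
    "edge_p_cutoff": 0.05,
    "seed": 0,
}


def load_run_config(path: str | Path | None = None) -> dict:
    """Load a JSON run configuration, merged over the shipped defaults."""
    cfg = dict(_DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = json.load(fh)
        if not isinstance(user, dict):
            raise ConfigError(f"run config {path} must be a JSON object")
        unknown = set(user) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def write_edge_list(graph, path: str | Path) -> None:
    """Write a weighted undirected graph as a 3-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")


def write_graphml(graph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(graph, path)
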