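"""Candidate-gene selection by volcano-plot thresholds."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .errors import ArgumentError
from .io_formats import DEGeneRecord

logger = logging.getLogger("pagkit")

__all__ = ["ThresholdConfig", "VolcanoClass", "PRESETS", "select_candidates"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Volcano thresholds.

    Candidates satisfy ``p <= p_cutoff`` and ``|log2fc| >= abs_log2fc_cutoff``
    (or strictly ``>`` when ``fc_strict`` is set, as in the disease-study
    presets below).
    """

    p_cutoff: float = 0.05
    abs_log2fc_cutoff: float = 1.0
    fc_strict: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ArgumentError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if self.abs_log2fc_cutoff < 0:
            raise ArgumentError("abs_log2fc_cutoff must be >= 0")


# Named threshold presets used in the shipped disease studies; these use a
# strict ">" on the fold change.
PRESETS: dict[str, ThresholdConfig] = {
    "ms": ThresholdConfig(p_cutoff=0.01, abs_log2fc_cutoff=0.5, fc_strict=True),
    "cd": ThresholdConfig(p_cutoff=0.05, abs_log2fc_cutoff=0.5, fc_strict=True),
    "uc": ThresholdConfig(p_cutoff=0.05, abs_log2fc_cutoff=0.5, fc_strict=True),
}


@dataclass(frozen=True)
class VolcanoClass:
    gene_id: str
    klass: str  # "over" | "under" | "not_significant"


def select_candidates(
    records: Iterable[DEGeneRecord], cfg: ThresholdConfig | None = None
) -> tuple[set[str], list[VolcanoClass]]:
    """Select candidate genes and classify every gene for plotting.

    Returns the candidate gene-id set and a per-gene classification list
    (``over`` / ``under`` / ``not_significant``) partitioning the input.
    An empty candidate set logs a warning but is not an error.
    """
    cfg = cfg or ThresholdConfig()
    records = list(records)
    if not records:
        raise ArgumentError("select_candidates requires a non-empty record list")

    def _passes_fc(fc: float) -> bool:
        mag = abs(fc)
        return mag > cfg.abs_log2fc_cutoff if cfg.fc_strict else mag >= cfg.abs_log2fc_cutoff

    candidates: set[str] = set()
    classes: list[VolcanoClass] = []
    for rec in records:
        if rec.pvalue <= cfg.p_cutoff and _passes_fc(rec.log2fc):
            candidates.add(rec.gene_id)
            klass = "over" if rec.log2fc > 0 else "under"
        else:
            klass = "not_significant"
        classes.append(VolcanoClass(gene_id=rec.gene_id, klass=klass))
    if not candidates:
        logger.warning("no candidate genes passed the volcano thresholds")
    return candidates, classes
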