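"""Core container for a bioset: one case-vs-control DE gene list plus metadata.

A *bioset* is the unit of analysis throughout the pipeline — the set of gene
symbols called differentially expressed in one case/control comparison,
annotated with the experiment it came from and the tissue assayed. Symbols are
normalized (uppercased, stripped, deduplicated) on construction so that
set arithmetic downstream is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol. Returns '' for blank input."""
    return symbol.strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> tuple[frozenset[str], int]:
    """Normalize a collection of symbols.

    Returns the deduplicated symbol set and the number of entries dropped as
    duplicates (blank entries are dropped silently and not counted).
    """
    seen: set[str] = set()
    n_dup = 0
    for s in symbols:
        t = normalize_symbol(s)
        if not t:
            continue
        if t in seen:
            n_dup += 1
        else:
            seen.add(t)
    return frozenset(seen), n_dup


@dataclass(frozen=True)
class Bioset:
    """One comparison's DE gene set with provenance metadata."""

    bioset_id: str
    experiment_id: str
    tissue: str
    genes: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_symbols(
        cls,
        bioset_id: str,
        experiment_id: str,
        tissue: str,
        symbols: Iterable[str],
    ) -> "Bioset":
        genes, n_dup = normalize_symbols(symbols)
        if n_dup:
            logger.info(
                "bioset %s: dropped %d duplicate symbol(s)", bioset_id, n_dup
            )
        return cls(bioset_id, experiment_id, tissue, genes)

    def __len__(self) -> int:
        return len(self.genes)


def check_unique_ids(corpus: Sequence[Bioset]) -> None:
    """Raise ValueError naming the first duplicated bioset_id, if any."""
    seen: set[str] = set()
    for b in corpus:
        if b.bioset_id in seen:
            raise ValueError(f"duplicate bioset_id: {b.bioset_id!r}")
        seen.add(b.bioset_id)
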