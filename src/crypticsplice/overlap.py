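"""Cross-cohort overlap of significant alternative-3'ss gene sets.

Two cohorts (e.g. mouse tumors and a human pan-cancer set) are intersected
at the gene level through an ortholog map, since coordinates are not
comparable across species. A gene pair is shared when both sides carry a
significant A3SS event under their cohort's own thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("crypticsplice")


@dataclass(frozen=True)
class OrthologMap:
    """Unique (cohort A gene, cohort B gene) pairs; one-to-many allowed."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("ortholog map contains duplicate pairs")
        a_counts = pd.Series([a for a, _ in self.pairs]).value_counts()
        b_counts = pd.Series([b for _, b in self.pairs]).value_counts()
        multi_a = a_counts[a_counts > 1]
        multi_b = b_counts[b_counts > 1]
        if len(multi_a) or len(multi_b):
            logger.warning(
                "ortholog map has one-to-many entries (%d A genes, %d B genes)",
                len(multi_a), len(multi_b),
            )

    def invert(self) -> "OrthologMap":
        return OrthologMap(tuple((b, a) for a, b in self.pairs))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] != 2:
            raise ValueError(f"{path}: ortholog map must have exactly two columns")
        return cls(tuple(df.itertuples(index=False, name=None)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class OverlapResult:
    """Venn counts and the deterministic shared-pair list."""

    a_only: int
    b_only: int
    shared: int
    shared_pairs: tuple[tuple[str, str], ...]

    @property
    def shared_genes_a(self) -> list[str]:
        return sorted({a for a, _ in self.shared_pairs})

    def venn_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": ["A_only", "shared", "B_only"],
                "count": [self.a_only, self.shared, self.b_only],
            }
        ).set_index("region")


def overlap_events(
    genes_a: Iterable[str], genes_b: Iterable[str], ortholog_map: OrthologMap
) -> OverlapResult:
    """Gene-level Venn of two significant-A3SS gene sets through the map.

    ``shared`` counts distinct ortholog pairs significant on both sides;
    a cohort's private count is its genes with no such pair (genes absent
    from the map are cohort-private, logged). Swapping cohorts and
    inverting the map swaps the private counts and preserves ``shared``.
    """
    set_a, set_b = set(genes_a), set(genes_b)
    shared_pairs = tuple(
        sorted((a, b) for a, b in set(ortholog_map.pairs) if a in set_a and b in set_b)
    )
    shared_a = {a for a, _ in shared_pairs}
    shared_b = {b for _, b in shared_pairs}
    mapped_a = {a for a, _ in ortholog_map.pairs}
    mapped_b = {b for _, b in ortholog_map.pairs}
    unmapped_a = set_a - mapped_a
    unmapped_b = set_b - mapped_b
    if unmapped_a or unmapped_b:
        logger.info(
            "%d cohort-A and %d cohort-B significant genes absent from the ortholog map",
            len(unmapped_a), len(unmapped_b),
        )
    return OverlapResult(
        a_only=len(set_a - shared_a),
        b_only=len(set_b - shared_b),
        shared=len(shared_pairs),
        shared_pairs=shared_pairs,
    )
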