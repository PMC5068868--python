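"""Root-signature extraction and specificity statistics.

A stable cross-experiment cluster of biosets is "rooted" by the genes its
members share: at the default ``min_support=1.0`` the root signature is the
strict intersection of the member gene lists, so every root gene is present
in every member bioset. Lower support thresholds admit genes present in at
least ``ceil(min_support * n_members)`` members, which is the appropriate
relaxation when per-bioset inclusion is itself noisy.

Specificity of a signature is assessed three ways, mirroring how one
validates a candidate cross-study signature against the wider literature:

* :func:`overlap_null` — how many signature genes appear in each pairwise
  intersection of an unrelated bioset corpus (the empirical null for
  "a signature this coherent arises between random disease comparisons").
* :func:`list_overlap` — direct intersection with a reference list such as
  housekeeping genes (broad overlap would argue the signature is generic).
* :func:`enrichment_test` — one-sided Fisher's-exact / hypergeometric
  over-representation of the signature in a reference set, with
  Benjamini–Hochberg FDR across batches of references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import Bioset, normalize_symbols


@dataclass(frozen=True)
class RootSignature:
    cluster_id: str
    member_bioset_ids: tuple[str, ...]
    genes: tuple[str, ...]  # sorted
    min_support: float = 1.0

    def __len__(self) -> int:
        return len(self.genes)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class OverlapDistribution:
    """Sizes of pairwise bioset intersections restricted to a signature."""

    pair_counts: pd.DataFrame  # bioset_a, bioset_b, n_signature_genes
    signature_size: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_counts)

    @property
    def mean(self) -> float:
        return float(self.pair_counts["n_signature_genes"].mean())

    @property
    def max(self) -> int:
        return int(self.pair_counts["n_signature_genes"].max())

    def histogram(self) -> pd.DataFrame:
        counts = np.bincount(
            self.pair_counts["n_signature_genes"].to_numpy(),
            minlength=self.signature_size + 1,
        )
        return pd.DataFrame(
            {"n_signature_genes": np.arange(len(counts)), "n_pairs": counts}
        )


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int  # k
    signature_size: int  # m
    reference_size: int  # r
    universe_size: int  # N
    p_value: float  # one-sided over-representation
    fold_enrichment: float  # (k/m) / (r/N)


def extract_root(
    corpus: Sequence[Bioset],
    cluster_members: Iterable[str],
    min_support: float = 1.0,
    cluster_id: str = "root",
) -> RootSignature:
    """Genes shared by (at least min_support of) a cluster's member biosets."""
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    members = list(cluster_members)
    by_id = {b.bioset_id: b for b in corpus}
    unknown = [m for m in members if m not in by_id]
    if unknown:
        raise ValueError(f"unknown bioset id(s): {unknown}")
    if len(members) < 2:
        raise ValueError("need at least 2 cluster members")
    need = math.ceil(min_support * len(members))
    counts: dict[str, int] = {}
    for m in members:
        for g in by_id[m].genes:
            counts[g] = counts.get(g, 0) + 1
    genes = tuple(sorted(g for g, c in counts.items() if c >= need))
    return RootSignature(
        cluster_id=cluster_id,
        member_bioset_ids=tuple(members),
        genes=genes,
        min_support=min_support,
    )


def overlap_null(
    signature: RootSignature | Iterable[str],
    corpus: Sequence[Bioset],
) -> OverlapDistribution:
    """Signature content of every pairwise corpus intersection.

    For each unordered bioset pair (i, j) counts
    ``|genes_i ∩ genes_j ∩ signature|``. Run against a corpus *excluding*
    the signature's source biosets to obtain the empirical null.
    """
    if len(corpus) < 2:
        raise ValueError("need at least 2 corpus biosets")
    sig = (
        signature.gene_set()
        if isinstance(signature, RootSignature)
        else frozenset(signature)
    )
    rows = []
    restricted = [b.genes & sig for b in corpus]
    for i in range(len(corpus)):
        for j in range(i + 1, len(corpus)):
            rows.append(
                (
                    corpus[i].bioset_id,
                    corpus[j].bioset_id,
                    len(restricted[i] & restricted[j]),
                )
            )
    frame = pd.DataFrame(
        rows, columns=["bioset_a", "bioset_b", "n_signature_genes"]
    )
    return OverlapDistribution(pair_counts=frame, signature_size=len(sig))


def list_overlap(
    signature: RootSignature | Iterable[str], reference: Iterable[str]
) -> list[str]:
    """Sorted intersection of a signature with a normalized reference list."""
    sig = (
        signature.gene_set()
        if isinstance(signature, RootSignature)
        else frozenset(signature)
    )
    ref, _ = normalize_symbols(reference)
    if not ref:
        raise ValueError("reference list is empty after normalization")
    return sorted(sig & ref)


def enrichment_test(
    overlap: int, signature_size: int, reference_size: int, universe_size: int
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    p = P(X >= overlap) for X ~ Hypergeom(N=universe, K=reference,
    n=signature) — the upper tail of Fisher's exact test. Fold enrichment is
    the observed overlap fraction of the signature over its expectation
    under random draws, (k/m)/(r/N).
    """
    k, m, r, n = overlap, signature_size, reference_size, universe_size
    if not (0 <= k <= min(m, r) and m <= n and r <= n and n > 0):
        raise ValueError(
            f"inconsistent counts: overlap={k}, signature={m}, "
            f"reference={r}, universe={n}"
        )
    p = float(stats.hypergeom.sf(k - 1, n, r, m))
    p = min(max(p, 0.0), 1.0)
    fold = (k / m) / (r / n) if m > 0 and r > 0 else 0.0
    return EnrichmentResult(
        overlap=k,
        signature_size=m,
        reference_size=r,
        universe_size=n,
        p_value=p,
        fold_enrichment=fold,
    )


def enrichment_table(
    signature: RootSignature | Iterable[str],
    references: dict[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Enrichment of one signature against many references, with BH-FDR.

    The universe defaults upstream to the union of all corpus genes;
    references and signature are intersected with it before testing so the
    2x2 margins are consistent.
    """
    uni, _ = normalize_symbols(universe)
    sig = (
        signature.gene_set()
        if isinstance(signature, RootSignature)
        else frozenset(signature)
    )
    sig = sig & uni
    rows = []
    for name, ref in references.items():
        ref_set, _ = normalize_symbols(ref)
        ref_set = ref_set & uni
        res = enrichment_test(
            len(sig & ref_set), len(sig), len(ref_set), len(uni)
        )
        rows.append(
            {
                "reference": name,
                "overlap": res.overlap,
                "signature_size": res.signature_size,
                "reference_size": res.reference_size,
                "universe_size": res.universe_size,
                "fold_enrichment": res.fold_enrichment,
                "p_value": res.p_value,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adjusted"] = multipletests(
            frame["p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return frame
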