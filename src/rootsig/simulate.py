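"""Synthetic corpora of DE gene lists and case/control expression biosets.

The generators emulate the structure of a multi-experiment transcriptomics
corpus: several independent experiments, each contributing a few case/control
biosets; a shared background of genes that enter any list at a low baseline
rate; experiment-specific gene blocks that make biosets from the same
experiment resemble each other (batch structure); and an optional *planted
signature* — a gene set pushed into a designated subset of biosets spanning
multiple experiments, the ground-truth analogue of a cross-study root
signature.

Membership model
----------------
Gene ``g`` enters bioset ``b`` with an independent Bernoulli draw whose
success probability is the **maximum** over all effects that apply to the
pair: the baseline probability; the experiment-share probability if ``g``
belongs to ``b``'s experiment block; the signature probability if ``g`` is a
signature gene and ``b`` is a designated signature bioset. Taking the maximum
(rather than the union of independent events) keeps expectations closed-form
and easy to test.

Both generators are bit-reproducible given ``CorpusSpec.seed`` and emit a
ground-truth manifest (gene roles per category, designated biosets, and the
background genes that collided into every designated bioset by chance), which
downstream recovery tests use as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Bioset

_TISSUE_CYCLE = ("BLOOD", "BRAIN")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic bioset corpus.

    Attributes
    ----------
    n_experiments, biosets_per_experiment
        Corpus layout; bioset ids are ``E<i>_B<j>`` (1-based, zero-padded
        experiment index), experiment ids ``E<i>``.
    universe_size
        Number of distinct gene symbols (``G0001`` ...).
    baseline_inclusion_prob
        Probability a background gene enters any one bioset's list.
    experiment_specific_genes
        Count of genes assigned to each experiment's batch block (disjoint
        across experiments and from the signature).
    experiment_share_prob
        Probability an experiment-block gene enters each bioset of that
        experiment.
    signature_size, signature_biosets, signature_inclusion_prob
        Planted cross-experiment signature: its size, the bioset ids that
        must carry it, and the per-bioset inclusion probability (near 1).
    seed
        RNG seed; all randomness flows from it.
    """

    n_experiments: int = 9
    biosets_per_experiment: int = 3
    universe_size: int = 2000
    baseline_inclusion_prob: float = 0.05
    experiment_specific_genes: int = 0
    experiment_share_prob: float = 0.0
    signature_size: int = 0
    signature_biosets: tuple[str, ...] = ()
    signature_inclusion_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_inclusion_prob",
            "experiment_share_prob",
            "signature_inclusion_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "n_experiments",
            "biosets_per_experiment",
            "universe_size",
            "experiment_specific_genes",
            "signature_size",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.signature_size > self.universe_size:
            raise ValueError("signature_size exceeds universe_size")
        reserved = (
            self.signature_size
            + self.n_experiments * self.experiment_specific_genes
        )
        if reserved > self.universe_size:
            raise ValueError(
                "signature and experiment blocks do not fit in the universe "
                f"({reserved} > {self.universe_size})"
            )
        unknown = set(self.signature_biosets) - set(self.bioset_ids())
        if unknown:
            raise ValueError(
                f"signature_biosets name unknown bioset id(s): {sorted(unknown)}"
            )
        # ensure canonical tuple form even if a list was passed
        object.__setattr__(self, "signature_biosets", tuple(self.signature_biosets))

    def experiment_ids(self) -> list[str]:
        w = len(str(self.n_experiments))
        return [f"E{i + 1:0{w}d}" for i in range(self.n_experiments)]

    def bioset_ids(self) -> list[str]:
        return [
            f"{e}_B{j + 1}"
            for e in self.experiment_ids()
            for j in range(self.biosets_per_experiment)
        ]

    def gene_universe(self) -> list[str]:
        w = max(4, len(str(self.universe_size)))
        return [f"G{i + 1:0{w}d}" for i in range(self.universe_size)]

    def tissue_of(self, experiment_id: str) -> str:
        idx = self.experiment_ids().index(experiment_id)
        return _TISSUE_CYCLE[idx % len(_TISSUE_CYCLE)]


@dataclass(frozen=True)
class ExpressionBioset:
    """A genes x samples intensity matrix with case/control labels."""

    bioset_id: str
    experiment_id: str
    tissue: str
    values: pd.DataFrame  # genes x samples, nonnegative intensities
    group_labels: tuple[str, ...]  # per-sample 'case'/'control'
    paired: bool = False

    def __post_init__(self) -> None:
        labels = list(self.group_labels)
        if labels.count("case") < 2 or labels.count("control") < 2:
            raise ValueError("need >=2 case and >=2 control samples")
        if self.paired and labels.count("case") != labels.count("control"):
            raise ValueError("paired bioset needs equal case/control counts")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")

    def case_matrix(self) -> np.ndarray:
        mask = np.array([g == "case" for g in self.group_labels])
        return self.values.to_numpy()[:, mask]

    def control_matrix(self) -> np.ndarray:
        mask = np.array([g == "control" for g in self.group_labels])
        return self.values.to_numpy()[:, mask]


def _membership_probabilities(spec: CorpusSpec, rng: np.random.Generator):
    """Assign gene roles and build the (bioset x gene) probability matrix."""
    genes = np.array(spec.gene_universe())
    bioset_ids = spec.bioset_ids()
    exp_ids = spec.experiment_ids()
    n_b, n_g = len(bioset_ids), len(genes)

    # draw disjoint role blocks: signature first, then one block per experiment
    perm = rng.permutation(n_g)
    pos = 0
    signature_idx = perm[pos : pos + spec.signature_size]
    pos += spec.signature_size
    experiment_idx: dict[str, np.ndarray] = {}
    for e in exp_ids:
        experiment_idx[e] = perm[pos : pos + spec.experiment_specific_genes]
        pos += spec.experiment_specific_genes

    probs = np.full((n_b, n_g), spec.baseline_inclusion_prob)
    for bi, bid in enumerate(bioset_ids):
        e = bid.split("_")[0]
        block = experiment_idx[e]
        probs[bi, block] = np.maximum(probs[bi, block], spec.experiment_share_prob)
        if bid in spec.signature_biosets:
            probs[bi, signature_idx] = np.maximum(
                probs[bi, signature_idx], spec.signature_inclusion_prob
            )
    roles = {
        "genes": genes,
        "signature_idx": signature_idx,
        "experiment_idx": experiment_idx,
    }
    return probs, roles


def _manifest(spec: CorpusSpec, roles: dict, member: np.ndarray) -> dict:
    genes = roles["genes"]
    bioset_ids = spec.bioset_ids()
    sig = sorted(genes[roles["signature_idx"]].tolist())
    sig_rows = [i for i, b in enumerate(bioset_ids) if b in spec.signature_biosets]
    collisions: list[str] = []
    if sig_rows:
        in_all = member[sig_rows, :].all(axis=0)
        sig_mask = np.zeros(len(genes), dtype=bool)
        sig_mask[roles["signature_idx"]] = True
        collisions = sorted(genes[in_all & ~sig_mask].tolist())
    return {
        "seed": spec.seed,
        "bioset_ids": bioset_ids,
        "signature_biosets": list(spec.signature_biosets),
        "signature_genes": sig,
        "experiment_genes": {
            e: sorted(genes[idx].tolist())
            for e, idx in roles["experiment_idx"].items()
        },
        "baseline_collisions": collisions,
        "genes_per_bioset": {
            b: sorted(genes[member[i]].tolist())
            for i, b in enumerate(bioset_ids)
        },
    }


def generate_list_corpus(spec: CorpusSpec) -> tuple[list[Bioset], dict]:
    """Draw a corpus of gene-list biosets under the Bernoulli membership model.

    Returns the biosets (one per declared id, in declaration order) and the
    ground-truth manifest. ``manifest['baseline_collisions']`` lists
    non-signature genes that happen to occur in every designated signature
    bioset — exactly the genes a strict-intersection root would pick up beyond
    the planted set.
    """
    rng = np.random.default_rng(spec.seed)
    probs, roles = _membership_probabilities(spec, rng)
    member = rng.random(probs.shape) < probs
    genes = roles["genes"]
    corpus = []
    for i, bid in enumerate(spec.bioset_ids()):
        e = bid.split("_")[0]
        corpus.append(
            Bioset(
                bioset_id=bid,
                experiment_id=e,
                tissue=spec.tissue_of(e),
                genes=frozenset(genes[member[i]].tolist()),
            )
        )
    return corpus, _manifest(spec, roles, member)


def generate_expression_corpus(
    spec: CorpusSpec,
    effect_fold: float = 1.5,
    noise_sd: float = 0.1,
    samples_per_group: int = 5,
    tissue_effect_sd: float = 0.0,
    paired: bool = False,
) -> tuple[list[ExpressionBioset], dict]:
    """Generate case/control intensity matrices with planted DE genes.

    Per gene and sample the log intensity is additive —
    gene baseline + experiment effect + tissue effect + (case indicator x
    log ``effect_fold``, for genes designated DE in that bioset) + Gaussian
    noise — then exponentiated. The designated-DE sets are drawn from the same
    Bernoulli membership model as :func:`generate_list_corpus`, so the
    manifest's role annotations carry over; ``manifest['genes_per_bioset']``
    holds each bioset's designated (true) DE genes.

    With ``noise_sd=0`` the case/control ratio of group means equals
    ``effect_fold`` exactly for every designated gene, because both groups
    share the same per-gene baseline.
    """
    if not (math.isfinite(effect_fold) and effect_fold >= 1.0):
        raise ValueError(f"effect_fold must be finite and >= 1, got {effect_fold}")
    if not (math.isfinite(noise_sd) and noise_sd >= 0.0):
        raise ValueError(f"noise_sd must be finite and >= 0, got {noise_sd}")
    if samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")

    rng = np.random.default_rng(spec.seed)
    probs, roles = _membership_probabilities(spec, rng)
    member = rng.random(probs.shape) < probs
    genes = roles["genes"]
    n_g = len(genes)
    exp_ids = spec.experiment_ids()

    gene_baseline = rng.normal(loc=6.0, scale=1.0, size=n_g)
    exp_effect = {e: rng.normal(0.0, 0.25, size=n_g) for e in exp_ids}
    tissue_effect = {
        t: rng.normal(0.0, tissue_effect_sd, size=n_g) if tissue_effect_sd > 0
        else np.zeros(n_g)
        for t in _TISSUE_CYCLE
    }

    n_s = 2 * samples_per_group
    labels = tuple(["case"] * samples_per_group + ["control"] * samples_per_group)
    case_ind = np.array([1.0 if g == "case" else 0.0 for g in labels])

    biosets = []
    for i, bid in enumerate(spec.bioset_ids()):
        e = bid.split("_")[0]
        t = spec.tissue_of(e)
        de = member[i].astype(float)
        log_x = (
            gene_baseline[:, None]
            + exp_effect[e][:, None]
            + tissue_effect[t][:, None]
            + np.outer(de * math.log(effect_fold), case_ind)
        )
        if noise_sd > 0:
            log_x = log_x + rng.normal(0.0, noise_sd, size=(n_g, n_s))
        values = pd.DataFrame(
            np.exp(log_x),
            index=pd.Index(genes, name="gene"),
            columns=[f"{bid}_S{j + 1}" for j in range(n_s)],
        )
        biosets.append(
            ExpressionBioset(
                bioset_id=bid,
                experiment_id=e,
                tissue=t,
                values=values,
                group_labels=labels,
                paired=paired,
            )
        )
    return biosets, _manifest(spec, roles, member)
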