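"""Readers and writers for the pipeline's plain-text interchange formats.

Gene lists travel as GMT (one gene set per line: id, description, members,
tab-separated — the description field carries ``experiment:tissue``) or as
one-symbol-per-line text files; expression matrices as TSV with a leading
gene-symbol column; trees as Newick; everything else as TSV/JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Bioset, check_unique_ids, normalize_symbols
from .simulate import ExpressionBioset

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> list[Bioset]:
    """Parse a GMT file into biosets.

    The description field is interpreted as ``experiment:tissue`` when it
    contains a colon; otherwise the whole field becomes the experiment id
    and the tissue is left blank. Duplicate symbols within a line are
    deduplicated with a logged count; malformed lines and duplicate bioset
    ids raise with the offending location.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty gene-list file: {path}")
    corpus: list[Bioset] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        bioset_id, desc = fields[0], fields[1]
        if ":" in desc:
            experiment_id, tissue = desc.split(":", 1)
        else:
            experiment_id, tissue = desc, ""
        genes, n_dup = normalize_symbols(fields[2:])
        if n_dup:
            logger.info("%s:%d: %d duplicate symbol(s) in %s",
                        path, lineno, n_dup, bioset_id)
        corpus.append(Bioset(bioset_id, experiment_id, tissue, genes))
    check_unique_ids(corpus)
    return corpus


def write_gmt(corpus: Sequence[Bioset], path: str | Path) -> None:
    lines = []
    for b in corpus:
        desc = f"{b.experiment_id}:{b.tissue}"
        lines.append("\t".join([b.bioset_id, desc, *sorted(b.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; normalized, deduplicated, order-stable."""
    path = Path(path)
    raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError(f"empty gene-list file: {path}")
    symbols, n_dup = normalize_symbols(raw)
    if n_dup:
        logger.info("%s: %d duplicate symbol(s)", path, n_dup)
    # preserve first-occurrence order
    seen: set[str] = set()
    out = []
    for s in raw:
        t = s.strip().upper()
        if t and t in symbols and t not in seen:
            seen.add(t)
            out.append(t)
    return out


def read_gene_lists(path: str | Path, format: str = "gmt") -> list[Bioset]:
    """Load a corpus from a GMT file or a directory of plain-text lists.

    For ``format='txt'`` with a directory, each ``*.txt`` file becomes one
    bioset named after the file stem; experiment/tissue default to the stem
    and blank unless a ``metadata.tsv`` sidecar (bioset_id, experiment_id,
    tissue) sits in the directory.
    """
    path = Path(path)
    if format == "gmt":
        return read_gmt(path)
    if format != "txt":
        raise ValueError(f"unknown gene-list format: {format!r}")
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"no .txt gene lists found under {path}")
    meta = {}
    sidecar = path / "metadata.tsv" if path.is_dir() else None
    if sidecar and sidecar.exists():
        mf = pd.read_csv(sidecar, sep="\t", dtype=str)
        meta = {
            row["bioset_id"]: (row["experiment_id"], row["tissue"])
            for _, row in mf.iterrows()
        }
    corpus = []
    for f in files:
        bid = f.stem
        exp, tissue = meta.get(bid, (bid, ""))
        corpus.append(
            Bioset.from_symbols(bid, exp, tissue, read_gene_list(f))
        )
    check_unique_ids(corpus)
    return corpus


def write_expression_tsv(
    bioset: ExpressionBioset, values_path: str | Path, groups_path: str | Path
) -> None:
    bioset.values.to_csv(values_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": bioset.values.columns, "group": list(bioset.group_labels)}
    ).to_csv(groups_path, sep="\t", index=False)


def read_expression_tsv(
    values_path: str | Path,
    groups_path: str | Path,
    bioset_id: str,
    experiment_id: str = "",
    tissue: str = "",
    paired: bool = False,
) -> ExpressionBioset:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    order = {s: g for s, g in zip(groups["sample"], groups["group"])}
    missing = [s for s in values.columns if s not in order]
    if missing:
        raise ValueError(f"samples missing from group annotation: {missing}")
    return ExpressionBioset(
        bioset_id=bioset_id,
        experiment_id=experiment_id,
        tissue=tissue,
        values=values,
        group_labels=tuple(order[s] for s in values.columns),
        paired=paired,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_signature_files(signature, gmt_path: str | Path,
                          txt_path: str | Path) -> None:
    """Write a RootSignature as a one-line GMT and a plain list."""
    desc = f"root:{','.join(signature.member_bioset_ids)}"
    line = "\t".join([signature.cluster_id, desc, *signature.genes])
    Path(gmt_path).write_text(line + "\n")
    Path(txt_path).write_text("\n".join(signature.genes) + "\n")
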