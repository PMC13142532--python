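"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket (MTX) with sample/gene index TSVs, metadata and
results as TSV, and weighted gene sets in a GMT-like text format:
``set_id <TAB> description <TAB> gene:weight <TAB> gene:weight ...``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_view_mtx(view: pd.DataFrame, prefix: str | Path) -> None:
    """Write a sample x gene count view as ``<prefix>.mtx`` plus
    ``<prefix>.samples.tsv`` and ``<prefix>.genes.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx",
                 sparse.csr_matrix(view.to_numpy()))
    pd.Series(view.index, name="sample").to_csv(
        str(prefix) + ".samples.tsv", sep="\t", index=False)
    pd.Series(view.columns, name="gene").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False)


def read_view_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t")["sample"]
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene"]
    return pd.DataFrame(mat, index=samples.tolist(), columns=genes.tolist())


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gene_sets(
    sets: dict[str, pd.Series], path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    """Write weighted gene sets in GMT-like format (one set per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "")
            pairs = "\t".join(f"{g}:{w:.6g}" for g, w in members.items())
            fh.write(f"{name}\t{desc}\t{pairs}\n")


def read_gene_sets(path: str | Path) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            genes, weights = [], []
            for pair in parts[2:]:
                g, _, w = pair.rpartition(":")
                genes.append(g)
                weights.append(float(w))
            out[name] = pd.Series(np.asarray(weights), index=genes, name=name)
    return out


def write_cytokine_dictionary(
    dictionary: dict[tuple[str, str], pd.Series], path: str | Path
) -> None:
    """Cytokine dictionary as GMT-like file keyed ``cytokine|celltype``."""
    flat = {f"{cyt}|{ct}": s for (cyt, ct), s in dictionary.items()}
    write_gene_sets(flat, path)


def read_cytokine_dictionary(path: str | Path) -> dict[tuple[str, str], pd.Series]:
    flat = read_gene_sets(path)
    out = {}
    for key, s in flat.items():
        cyt, _, ct = key.partition("|")
        out[(cyt, ct)] = s
    return out
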