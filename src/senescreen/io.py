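"""Readers and writers for the plain-text formats the pipeline touches.

Dense TSV matrices, two-column label tables, MatrixMarket (MTX) triplets
with features/barcodes sidecars, GMT gene-set files, long-format
differential-expression tables and JSON reports.  All tabular outputs use
a fixed, documented column order so downstream tooling can rely on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .consensus import MarkerPanel
from .diffexpr import DE_COLUMNS
from .errors import InputError
from .ligrec import LRPair

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_gmt",
    "write_gmt",
    "panel_to_gmt",
    "panel_from_gmt",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_de_table",
    "write_de_table",
    "read_lr_pairs",
    "write_lr_pairs",
    "write_json",
    "read_json",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Dense TSV matrix with row names in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_labels_tsv(path) -> pd.Series:
    """Two-column TSV (id, label) -> Series indexed by id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise InputError(f"label table must have exactly 2 columns, got {df.shape[1]}")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name=df.columns[1])


def write_labels_tsv(labels: pd.Series, path, id_name: str = "id", label_name: str | None = None) -> None:
    pd.DataFrame(
        {id_name: labels.index, label_name or labels.name or "label": labels.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT file -> mapping set name -> gene set (description column ignored)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"malformed GMT line (needs name, description, >=1 gene): {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        ordered = list(genes) if isinstance(genes, (list, tuple)) else sorted(genes)
        lines.append("\t".join([name, str(desc), *ordered]))
    Path(path).write_text("\n".join(lines) + "\n")


def panel_to_gmt(panel: MarkerPanel, path) -> None:
    """Serialize every non-empty panel set to one GMT file (+ provenance JSON)."""
    sets = {
        "consensus_up": sorted(panel.consensus_up),
        "consensus_down": sorted(panel.consensus_down),
        "common_up": list(panel.common_up),
        "common_down": list(panel.common_down),
        "region_up": list(panel.region_up),
        "region_down": list(panel.region_down),
        "sasp": sorted(panel.sasp),
        "ecm": sorted(panel.ecm),
        "cdki": sorted(panel.cdki),
        "mcm": sorted(panel.mcm),
        "proliferation": sorted(panel.proliferation),
    }
    write_gmt({k: v for k, v in sets.items() if v}, path)
    sidecar = Path(path).with_suffix(".provenance.json")
    write_json(panel.provenance, sidecar)


def panel_from_gmt(path) -> MarkerPanel:
    """Rebuild a :class:`MarkerPanel` from a GMT written by :func:`panel_to_gmt`.

    Order of the common/region lists follows the GMT line order, which the
    writer preserves.
    """
    ordered: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        ordered[fields[0]] = fields[2:]
    kwargs: dict = {}
    for name in ("consensus_up", "consensus_down", "sasp", "ecm", "cdki", "mcm", "proliferation"):
        if name in ordered:
            kwargs[name] = set(ordered[name])
    for name in ("common_up", "common_down", "region_up", "region_down"):
        if name in ordered:
            kwargs[name] = list(ordered[name])
    sidecar = Path(path).with_suffix(".provenance.json")
    if sidecar.exists():
        kwargs["provenance"] = read_json(sidecar)
    return MarkerPanel(**kwargs)


def write_mtx_triplet(counts: pd.DataFrame, outdir) -> None:
    """Write a cells x genes count matrix as matrix.mtx + features/barcodes.

    Follows the common single-cell convention: the MTX holds genes as rows
    and cells as columns; ``features.tsv`` lists genes, ``barcodes.tsv``
    lists cell identifiers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy().T)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    (outdir / "features.tsv").write_text("\n".join(counts.columns) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(counts.index) + "\n")


def read_mtx_triplet(indir) -> pd.DataFrame:
    """Read matrix.mtx + features.tsv + barcodes.tsv into cells x genes."""
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx")
    genes = (indir / "features.tsv").read_text().split()
    cells = (indir / "barcodes.tsv").read_text().split()
    dense = np.asarray(sparse.csr_matrix(mat).todense()).T
    if dense.shape != (len(cells), len(genes)):
        raise InputError(
            f"matrix shape {dense.shape} does not match {len(cells)} barcodes x {len(genes)} features"
        )
    return pd.DataFrame(dense, index=cells, columns=genes)


def write_de_table(table: pd.DataFrame, path) -> None:
    """Differential-expression table with fixed column order.

    Columns: gene, log2fc, t, p, p_adj, direction; ``t`` is the moderated
    statistic.
    """
    out = pd.DataFrame(
        {
            "gene": table["gene"],
            "log2fc": table["log2fc"],
            "t": table.get("t_moderated", table.get("t")),
            "p": table["p"],
            "p_adj": table["p_adj"],
            "direction": table["direction"],
        }
    )
    out.to_csv(path, sep="\t", index=False, columns=DE_COLUMNS)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"DE table missing columns: {sorted(missing)}")
    return df


def read_lr_pairs(path) -> list[LRPair]:
    """Two-column TSV (ligand, receptor); complex components comma-separated."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError("ligand-receptor table needs two columns")
    return [
        LRPair(ligand=str(lig), receptor=tuple(str(rec).split(",")))
        for lig, rec in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]


def write_lr_pairs(pairs: list[LRPair], path) -> None:
    pd.DataFrame(
        {"ligand": [p.ligand for p in pairs], "receptor": [",".join(p.receptor) for p in pairs]}
    ).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
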