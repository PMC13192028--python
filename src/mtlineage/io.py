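"""Readers and writers for the pipeline's on-disk formats.

Conventions: mtDNA positions are 1-based inclusive (variant ids like
``7161G>A``); nuclear fragments and bins are 0-based half-open (BED).
Heteroplasmy matrices are stored as MatrixMarket with an explicit coverage
mask sidecar, because 0 (covered, reference) and missing (insufficient
coverage) are semantically different.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .counts import BaseCountTensor
from .genome import BASES

# ---------------------------------------------------------------------------
# mgatk-style per-base strand counts


def write_base_counts(tensor: BaseCountTensor, out_dir: str | Path) -> None:
    """Write per-base CSVs (position, barcode, plus, minus), barcodes.tsv and
    refAllele.csv, mirroring the mgatk output dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in tensor.barcodes))
    ref = pd.DataFrame({"position": tensor.positions, "ref": tensor.ref_bases})
    ref.to_csv(out / "refAllele.csv", index=False)
    for bi, base in enumerate(BASES):
        rows = []
        for pi, pos in enumerate(tensor.positions):
            plus = tensor.counts[:, pi, bi, 0]
            minus = tensor.counts[:, pi, bi, 1]
            keep = (plus > 0) | (minus > 0)
            for ci in np.flatnonzero(keep):
                rows.append((int(pos), tensor.barcodes[ci], int(plus[ci]), int(minus[ci])))
        frame = pd.DataFrame(rows, columns=["position", "barcode", "count_fwd", "count_rev"])
        frame.to_csv(out / f"{base}.csv", index=False)


def read_base_counts(counts_dir: str | Path) -> BaseCountTensor:
    """Read the per-base CSV layout back into a :class:`BaseCountTensor`.

    Validates barcode consistency across base files and position ranges;
    errors name the offending file.
    """
    src = Path(counts_dir)
    barcodes_path = src / "barcodes.tsv"
    if not barcodes_path.exists():
        raise FileNotFoundError(f"missing {barcodes_path}")
    barcodes = barcodes_path.read_text().split()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError(f"duplicated barcode in {barcodes_path}")
    ref_path = src / "refAllele.csv"
    if not ref_path.exists():
        raise FileNotFoundError(f"missing {ref_path}")
    ref = pd.read_csv(ref_path)
    positions = ref["position"].to_numpy(dtype=np.int64)
    cell_index = {b: i for i, b in enumerate(barcodes)}
    pos_index = {int(p): i for i, p in enumerate(positions)}
    counts = np.zeros((len(barcodes), len(positions), 4, 2), dtype=np.int64)
    for bi, base in enumerate(BASES):
        path = src / f"{base}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing base file {path}")
        frame = pd.read_csv(path)
        expected = ["position", "barcode", "count_fwd", "count_rev"]
        if list(frame.columns) != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
        for line, row in enumerate(frame.itertuples(index=False), start=2):
            if row.position not in pos_index:
                raise ValueError(f"{path} line {line}: unknown position {row.position}")
            if row.barcode not in cell_index:
                raise ValueError(f"{path} line {line}: unknown barcode {row.barcode}")
            counts[cell_index[row.barcode], pos_index[row.position], bi, 0] = row.count_fwd
            counts[cell_index[row.barcode], pos_index[row.position], bi, 1] = row.count_rev
    return BaseCountTensor(
        barcodes=barcodes,
        positions=positions,
        ref_bases=ref["ref"].to_numpy(),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# heteroplasmy matrix (MTX + sidecars)


def write_heteroplasmy(het: pd.DataFrame, out_dir: str | Path, name: str = "heteroplasmy") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values = het.to_numpy(dtype=float)
    covered = ~np.isnan(values)
    dense = np.where(covered, values, 0.0)
    scipy.io.mmwrite(out / f"{name}.mtx", scipy.sparse.coo_matrix(dense))
    scipy.io.mmwrite(out / f"{name}.mask.mtx", scipy.sparse.coo_matrix(covered.astype(np.int8)))
    (out / f"{name}.rows.tsv").write_text("".join(str(i) + "\n" for i in het.index))
    (out / f"{name}.cols.tsv").write_text("".join(str(c) + "\n" for c in het.columns))


def read_heteroplasmy(src_dir: str | Path, name: str = "heteroplasmy") -> pd.DataFrame:
    src = Path(src_dir)
    values = scipy.io.mmread(src / f"{name}.mtx").toarray()
    covered = scipy.io.mmread(src / f"{name}.mask.mtx").toarray().astype(bool)
    rows = (src / f"{name}.rows.tsv").read_text().split("\n")[:-1]
    cols = (src / f"{name}.cols.tsv").read_text().split("\n")[:-1]
    data = np.where(covered, values, np.nan)
    return pd.DataFrame(data, index=pd.Index(rows, name="cell"), columns=cols)


# ---------------------------------------------------------------------------
# fragments / chrom.sizes / AIRR / newick / YAML


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    """10x-style fragments.tsv: chrom, start, end, barcode, count; no header."""
    fragments[["chrom", "start", "end", "barcode", "count"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "barcode", "count"],
        comment="#",
    )


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")
        out[chrom] = int(size)
    return out


def write_airr(repertoire: pd.DataFrame, path: str | Path) -> None:
    repertoire[["cell_id", "clone_id", "junction_aa"]].to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "clone_id"):
        if col not in frame.columns:
            raise ValueError(f"{path}: AIRR table missing column {col!r}")
    return frame


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# simple TSV tables


def write_clones(labels: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"cell": labels.index, "clone": labels.to_numpy()})
    frame.to_csv(path, sep="\t", index=False)


def read_clones(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return pd.Series(
        frame["clone"].to_numpy(), index=pd.Index(frame["cell"], name="cell"), name="clone"
    )
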