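"""Readers and writers for the formats the pipeline exchanges.

Images travel as multi-page TIFF (one page per channel) with a JSON
sidecar recording pixel size (µm) and channel names; label rasters as
16-bit TIFF; cell tables as an MTX triplet (``matrix.mtx`` genes × cells,
``genes.tsv``, ``barcodes.tsv`` — the Cell Ranger layout) or a single CSV;
tabular results as UTF-8 comma-delimited CSV with a mandatory header.

All writes are atomic: content goes to a temporary file in the target
directory which is then renamed into place.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .cell_rules import CellTable
from .morphometry import LabeledImage

log = logging.getLogger("gastruquant")

__all__ = [
    "read_image",
    "write_image",
    "read_cell_table",
    "write_cell_table",
    "write_labels",
    "atomic_write_bytes",
    "write_csv",
    "write_json",
]


def atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path, obj) -> None:
    atomic_write_bytes(Path(path), (json.dumps(obj, indent=2, sort_keys=True) + "\n").encode())


def write_csv(path, df: pd.DataFrame, index: bool = True) -> None:
    atomic_write_bytes(Path(path), df.to_csv(index=index).encode())


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_image(path) -> LabeledImage:
    """Load a multi-page TIFF plus optional JSON sidecar into a LabeledImage.

    Without a sidecar, pixel size defaults to 1 µm and channels are named
    ``ch0..chN`` (logged as a warning).
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise ValueError(f"expected 2-D pages in {path}, got array of shape {pages.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        names = meta.get("channels", [f"ch{i}" for i in range(len(pages))])
        image_id = meta.get("image_id", path.stem)
        if len(names) != len(pages):
            raise ValueError(
                f"sidecar names {len(names)} channels but TIFF has {len(pages)} pages"
            )
    else:
        log.warning("no sidecar for %s; assuming pixel_size=1 µm, channels ch0..chN", path)
        pixel_size, names, image_id = 1.0, [f"ch{i}" for i in range(len(pages))], path.stem
    return LabeledImage(
        channels={n: pages[i].astype(float) for i, n in enumerate(names)},
        pixel_size=pixel_size,
        image_id=image_id,
    )


def write_image(image: LabeledImage, path) -> None:
    """Write channels as float32 TIFF pages plus a JSON sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([np.asarray(image.channels[n], dtype=np.float32) for n in names])
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, stack)
    atomic_write_bytes(path, buf.getvalue())
    write_json(
        _sidecar_path(path),
        {"pixel_size_um": image.pixel_size, "channels": names, "image_id": image.image_id},
    )


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label raster as 16-bit TIFF."""
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, np.asarray(labels, dtype=np.uint16))
    atomic_write_bytes(Path(path), buf.getvalue())


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def _dedup(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            log.warning("duplicate gene name %r deduplicated", n)
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_cell_table(
    path_matrix=None,
    path_genes=None,
    path_barcodes=None,
    path_csv=None,
    meta: pd.DataFrame | None = None,
) -> CellTable:
    """Load counts from an MTX triplet (genes × cells) or a CSV (cells × genes)."""
    if path_csv is not None:
        df = pd.read_csv(path_csv, index_col=0)
        counts = df.to_numpy()
        genes = _dedup([str(c) for c in df.columns])
        cells = [str(i) for i in df.index]
    else:
        if not (path_matrix and path_genes and path_barcodes):
            raise ValueError("provide either path_csv or the full MTX triplet")
        mat = spio.mmread(path_matrix)
        if sparse.issparse(mat):
            mat = mat.toarray()
        counts = np.asarray(mat).T  # stored genes x cells
        genes = _dedup(
            [ln.split("\t")[0] for ln in Path(path_genes).read_text().splitlines() if ln]
        )
        cells = [ln.strip() for ln in Path(path_barcodes).read_text().splitlines() if ln]
        if counts.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix is {counts.shape[1]} genes x {counts.shape[0]} cells but "
                f"genes.tsv has {len(genes)} and barcodes.tsv has {len(cells)} entries"
            )
    return CellTable(
        counts=np.rint(counts).astype(np.int64),
        gene_names=genes,
        cell_ids=cells,
        cell_meta=meta,
    )


def write_cell_table(table: CellTable, outdir, fmt: str = "mtx") -> None:
    """Write an MTX triplet (genes × cells) or a single CSV, plus metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        import io as _io

        buf = _io.BytesIO()
        spio.mmwrite(buf, sparse.coo_matrix(table.counts.T))
        atomic_write_bytes(outdir / "matrix.mtx", buf.getvalue())
        atomic_write_bytes(outdir / "genes.tsv", ("\n".join(table.gene_names) + "\n").encode())
        atomic_write_bytes(outdir / "barcodes.tsv", ("\n".join(table.cell_ids) + "\n").encode())
    elif fmt == "csv":
        df = pd.DataFrame(table.counts, index=pd.Index(table.cell_ids), columns=table.gene_names)
        write_csv(outdir / "counts.csv", df)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    write_csv(outdir / "cell_meta.csv", table.cell_meta)
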