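"""Readers and writers for the formats shared across pipeline stages.

Tabular artifacts (TSV/CSV) carry a provenance header: comment lines with
the producing stage and a hash of the configuration that generated them
(timestamps are deliberately excluded so reruns are byte-identical).
Expression goes out as Matrix Market + gene/barcode TSVs or dense CSV;
gene sets as GMT; FISH scenes as multi-page TIFF with a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import FishScene, GeneSet, LabeledExpression


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_header(stage: str, config: dict | None = None) -> str:
    h = config_hash(config or {})
    return f"# hepatlas stage={stage} config_sha1={h}\n"


def write_table(df: pd.DataFrame, path, stage: str, config: dict | None = None,
                sep: str = "\t", index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, config))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# --- gene sets (GMT: name <tab> description <tab> gene1 <tab> ...) ---------

def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(fields[0], fields[2:]))
    return sets


def write_gmt(gene_sets: list[GeneSet] | dict[str, list[str]], path,
              description: str = "hepatlas") -> None:
    if isinstance(gene_sets, dict):
        gene_sets = [GeneSet(name, genes) for name, genes in gene_sets.items()
                     if genes]
    lines = [
        "\t".join([gs.name, description, *gs.members]) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- expression matrices ---------------------------------------------------

def write_expression_mtx(expr: LabeledExpression, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "matrix.mtx", sparse.csr_matrix(expr.counts))
    pd.Series(expr.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t",
                                    index=False, header=False)
    pd.Series(expr.cell_meta.index).to_csv(out_dir / "barcodes.tsv", sep="\t",
                                           index=False, header=False)
    expr.cell_meta.to_csv(out_dir / "cell_meta.tsv", sep="\t")


def read_expression_mtx(in_dir) -> LabeledExpression:
    in_dir = Path(in_dir)
    counts = np.asarray(spio.mmread(in_dir / "matrix.mtx").todense())
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0]
    meta = pd.read_csv(in_dir / "cell_meta.tsv", sep="\t", index_col=0)
    return LabeledExpression(counts=counts, gene_ids=pd.Index(genes), cell_meta=meta)


def write_expression_csv(expression: pd.DataFrame, path, stage: str,
                         config: dict | None = None) -> None:
    write_table(expression, path, stage=stage, config=config, sep=",")


def read_expression_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


# --- FISH scenes -----------------------------------------------------------

def write_fish_scene(scene: FishScene, tiff_path, sidecar_path=None) -> None:
    import tifffile

    tiff_path = Path(tiff_path)
    names = list(scene.channels)
    stack = np.stack([np.asarray(scene.channels[n], dtype=np.float32)
                      for n in names])
    tifffile.imwrite(tiff_path, stack)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {
            "channels": names,
            "channel_map": scene.channel_map,
            "pixel_size_um": scene.pixel_size_um,
        },
        indent=2,
    ))


def read_fish_scene(tiff_path, sidecar_path=None) -> FishScene:
    import tifffile

    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    return FishScene(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_map=dict(meta.get("channel_map", {})),
    )
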