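"""Readers and writers for the standard on-disk formats.

Counts travel as MatrixMarket (.mtx) with features.tsv / barcodes.tsv
side files; spot grids as tissue-positions CSV plus a region TSV; rasters
as single-channel 8-bit PNG or TIFF; metadata, niche annotations, DE and
rank tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .niche import EnrichmentRule
from .rasters import DensityRaster, MaskRaster

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_raster",
    "read_mask",
    "read_density",
    "load_enrichment_rules",
]


def write_counts_mtx(counts: pd.DataFrame, outdir) -> None:
    """Write a genes x units count table as matrix.mtx + features/barcodes TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_counts_mtx(indir) -> pd.DataFrame:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").tocsr().toarray()
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=features, columns=barcodes)


def write_raster(raster, path) -> None:
    """Write a mask (as 0/255) or density raster to single-channel PNG/TIFF."""
    if isinstance(raster, MaskRaster):
        img = raster.pixels.astype(np.uint8) * 255
    else:
        img = raster.pixels
    iio.imwrite(Path(path), img)


def read_mask(path, pixel_size: float) -> MaskRaster:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return MaskRaster(img > 0, pixel_size)


def read_density(path, pixel_size: float) -> DensityRaster:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    return DensityRaster(img, pixel_size)


def load_enrichment_rules(path=None) -> dict:
    """Load enrichment rules from YAML into lists of EnrichmentRule per type.

    Without a path, the packaged default rule table is used.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "enrichment_rules.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules: dict[str, list[EnrichmentRule]] = {}
    for cell_type, entries in raw.items():
        rules[cell_type] = [
            EnrichmentRule(
                cell_type=cell_type,
                allowed_regions=tuple(e["regions"]),
                mode=e.get("mode", "top_quantile"),
                q=e.get("q"),
                z=e.get("z"),
                exclude_regions=tuple(e.get("exclude", ())),
            )
            for e in entries
        ]
    return rules
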