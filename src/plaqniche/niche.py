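"""Amyloid-niche calling on the spot grid.

Maps the distance-decayed amyloid density raster onto capture spots, calls
amyloid-rich spots by a strict intensity threshold (default 183 on the
0-255 scale), grows the niche to first- and second-order hex neighbours
(center-to-center reach of 2 pitches, i.e. ~200 um at 100 um pitch),
excludes vascular-amyloid spots and their immediate neighbours, calls
cell-type-enriched spots from deconvolution abundances, and quantifies
nuclei-to-plaque distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import SpotGrid, resolve_regions
from .rasters import DensityRaster, MaskRaster

__all__ = [
    "RICH_THRESHOLD",
    "EnrichmentRule",
    "spot_signal",
    "classify_rich",
    "hex_neighbors",
    "assemble_niche",
    "enriched_spots",
    "nuclei_near_plaques",
]

#: Default amyloid-rich intensity threshold on the 0-255 density scale.
RICH_THRESHOLD = 183.0

#: Regions eligible for niche membership (cortical layers + white matter).
DEFAULT_NICHE_REGIONS = ("gray matter", "white matter")


def spot_signal(
    raster: DensityRaster,
    grid: SpotGrid,
    spot_diameter: float | None = None,
    aggregator: str = "mean",
) -> pd.Series:
    """Per-spot amyloid intensity: mean (or max) raster value over the spot disc.

    Spots flagged ``reliable_ab = False`` and spots whose disc lies entirely
    outside the raster receive NaN. Physical (x, y) coordinates are mapped to
    pixel indices by the raster's pixel size; a pixel belongs to the disc if
    its centre lies within spot_diameter / 2 of the spot centre.
    """
    if aggregator not in ("mean", "max"):
        raise ValueError("aggregator must be 'mean' or 'max'")
    d = spot_diameter if spot_diameter is not None else grid.spot_diameter
    ps = raster.pixel_size
    r_px = (d / 2.0) / ps
    n = int(np.floor(r_px))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    disc = dy**2 + dx**2 <= r_px**2
    offsets = np.stack([dy[disc], dx[disc]])  # (2, n_px)
    img = raster.pixels.astype(float)
    h, w = img.shape
    out = np.full(len(grid), np.nan)
    rows = np.round(grid.spots["y"].to_numpy() / ps).astype(int)
    cols = np.round(grid.spots["x"].to_numpy() / ps).astype(int)
    reliable = grid.spots["reliable_ab"].to_numpy(dtype=bool)
    for i, (rr, cc) in enumerate(zip(rows, cols)):
        if not reliable[i]:
            continue
        py = rr + offsets[0]
        px = cc + offsets[1]
        ok = (py >= 0) & (py < h) & (px >= 0) & (px < w)
        if not ok.any():
            continue
        vals = img[py[ok], px[ok]]
        out[i] = vals.max() if aggregator == "max" else vals.mean()
    return pd.Series(out, index=grid.spots["spot_id"].to_numpy(), name="ab_intensity")


def classify_rich(intensity, threshold: float = RICH_THRESHOLD):
    """Amyloid-rich iff intensity strictly exceeds the threshold.

    NaN intensities (unreliable staining) are never rich.
    """
    arr = np.asarray(intensity, dtype=float)
    rich = np.where(np.isnan(arr), False, arr > threshold)
    if np.isscalar(intensity) or arr.ndim == 0:
        return bool(rich)
    return rich.astype(bool)


def hex_neighbors(grid: SpotGrid, spot_id: str, order: int = 1) -> set[str]:
    """Spots at hex graph distance exactly ``order`` from ``spot_id``."""
    return grid.neighbors(spot_id, order=order)


def assemble_niche(
    grid: SpotGrid,
    rich: set[str],
    vascular: set[str] = frozenset(),
    allowed_regions=DEFAULT_NICHE_REGIONS,
    ab_intensity: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every spot as rich / neighbor / outside / excluded.

    The niche comprises amyloid-rich spots plus their first- and
    second-order hex neighbours within the allowed regions (gray and white
    matter by default). Vascular-amyloid spots and their first-order
    neighbours are excluded, as are spots with unreliable staining or an
    'excluded' region annotation; exclusion overrides richness. The four
    classes partition the spot set.
    """
    spots = grid.spots
    ids = spots["spot_id"].to_numpy()
    unknown = (set(rich) | set(vascular)) - set(ids)
    if unknown:
        raise KeyError(f"spot ids not in grid: {sorted(unknown)[:5]}")
    allowed = resolve_regions(allowed_regions) | set(allowed_regions)

    excluded = set(vascular) | grid.neighbors_of_set(vascular, order=1)
    excluded |= set(ids[~spots["reliable_ab"].to_numpy(dtype=bool)])
    excluded |= set(ids[(spots["region"] == "excluded").to_numpy()])

    rich_eff = set(rich) - excluded
    nb = grid.neighbors_of_set(rich_eff, order=1) | grid.neighbors_of_set(
        rich_eff, order=2
    )
    region_ok = spots["region"].isin(allowed).to_numpy()
    allowed_ids = set(ids[region_ok])
    neighbor = (nb & allowed_ids) - rich_eff - excluded

    cls = np.full(len(ids), "outside", dtype=object)
    for i, sid in enumerate(ids):
        if sid in excluded:
            cls[i] = "excluded"
        elif sid in rich_eff:
            cls[i] = "rich"
        elif sid in neighbor:
            cls[i] = "neighbor"
    out = pd.DataFrame(
        {
            "spot_id": ids,
            "niche_class": cls,
            "vascular_flag": [sid in vascular for sid in ids],
        }
    )
    if ab_intensity is not None:
        out["ab_intensity"] = ab_intensity.reindex(ids).to_numpy()
    return out


@dataclass(frozen=True)
class EnrichmentRule:
    """Region-restricted rule calling cell-type-enriched spots per sample.

    top_quantile mode keeps, within each allowed region group, spots whose
    abundance is at least the ceil(q*n)-th largest (ties inclusive).
    z_score mode keeps spots strictly above mean + z * sd of the pooled
    allowed-region abundances.
    """

    cell_type: str
    allowed_regions: tuple
    mode: str = "top_quantile"
    q: float | None = None
    z: float | None = None
    exclude_regions: tuple = ()

    def __post_init__(self) -> None:
        if self.mode == "top_quantile":
            if self.q is None or not 0 < self.q <= 1:
                raise ValueError("top_quantile mode needs q in (0, 1]")
        elif self.mode == "z_score":
            if self.z is None or self.z <= 0:
                raise ValueError("z_score mode needs z > 0")
        else:
            raise ValueError(f"unknown mode: {self.mode}")


def enriched_spots(
    abundance: pd.DataFrame, grid: SpotGrid, rule: EnrichmentRule
) -> set[str]:
    """Spots enriched for ``rule.cell_type``, computed per sample.

    ``abundance`` is spots x cell-types, indexed by spot id. top_quantile
    thresholds are computed separately within each allowed region group and
    the selections unioned; z-score thresholds pool the allowed regions.
    """
    if rule.cell_type not in abundance.columns:
        raise KeyError(f"cell type {rule.cell_type!r} not in abundance table")
    spots = grid.spots
    vals = abundance[rule.cell_type]
    drop = resolve_regions(rule.exclude_regions)
    selected: set[str] = set()
    for _, sample_df in spots.groupby("sample_id"):
        if rule.mode == "top_quantile":
            for group_name in rule.allowed_regions:
                labels = resolve_regions([group_name]) - drop
                sub = sample_df[sample_df["region"].isin(labels)]
                sub = sub[sub["spot_id"].isin(vals.index)]
                if sub.empty:
                    continue
                a = vals.loc[sub["spot_id"]].to_numpy(dtype=float)
                k = int(np.ceil(rule.q * len(a)))
                thr = np.sort(a)[len(a) - k]
                selected |= set(sub["spot_id"].to_numpy()[a >= thr])
        else:
            labels = resolve_regions(rule.allowed_regions) - drop
            sub = sample_df[sample_df["region"].isin(labels)]
            sub = sub[sub["spot_id"].isin(vals.index)]
            if sub.empty:
                continue
            a = vals.loc[sub["spot_id"]].to_numpy(dtype=float)
            thr = a.mean() + rule.z * a.std(ddof=1 if len(a) > 1 else 0)
            selected |= set(sub["spot_id"].to_numpy()[a > thr])
    return selected


def nuclei_near_plaques(
    nuclei: pd.DataFrame, ab_mask: MaskRaster, cutoff_um: float = 20.0
) -> pd.DataFrame:
    """Per-cell-type composition of nuclei near vs far from plaques.

    Distance is the Euclidean distance from the nucleus centre to the
    nearest plaque pixel (0 inside a plaque); a nucleus is 'near' iff its
    distance is strictly below ``cutoff_um``. For each cell type the output
    reports the near/far counts, the fraction of that type's nuclei that
    are near, the enrichment ratio (share of the near bin belonging to the
    type divided by its share of the far bin) and a two-sided chi-square
    p-value from the type x bin contingency table. With an empty mask all
    nuclei are far; an empty bin yields a missing ratio.
    """
    required = {"x", "y", "cell_type"}
    if not required <= set(nuclei.columns):
        raise ValueError(f"nuclei table needs columns {sorted(required)}")
    ps = ab_mask.pixel_size
    if ab_mask.pixels.any():
        dist_map = ndimage.distance_transform_edt(~ab_mask.pixels, sampling=ps)
        h, w = ab_mask.pixels.shape
        rows = np.clip(np.round(nuclei["y"].to_numpy() / ps).astype(int), 0, h - 1)
        cols = np.clip(np.round(nuclei["x"].to_numpy() / ps).astype(int), 0, w - 1)
        dists = dist_map[rows, cols]
    else:
        dists = np.full(len(nuclei), np.inf)
    near = dists < cutoff_um
    n_near_tot = int(near.sum())
    n_far_tot = int((~near).sum())
    records = []
    for ct, sub_idx in nuclei.groupby("cell_type").groups.items():
        is_ct = nuclei.index.isin(sub_idx)
        n_near = int((near & is_ct).sum())
        n_far = int((~near & is_ct).sum())
        frac_near = n_near / (n_near + n_far) if (n_near + n_far) else np.nan
        comp_near = n_near / n_near_tot if n_near_tot else np.nan
        comp_far = n_far / n_far_tot if n_far_tot else np.nan
        if n_near_tot and n_far_tot and comp_far and not np.isnan(comp_far):
            ratio = comp_near / comp_far
        else:
            ratio = np.nan
        table = np.array(
            [[n_near, n_far], [n_near_tot - n_near, n_far_tot - n_far]]
        )
        if table.sum() and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            p = stats.chi2_contingency(table, correction=False)[1]
        else:
            p = np.nan
        records.append(
            {
                "cell_type": ct,
                "n_near": n_near,
                "n_far": n_far,
                "frac_near": frac_near,
                "near_composition": comp_near,
                "far_composition": comp_far,
                "enrichment_ratio": ratio,
                "p_value": p,
            }
        )
    return pd.DataFrame.from_records(records).set_index("cell_type")
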