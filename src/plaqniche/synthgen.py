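"""Synthetic tissue, spot-grid, abundance and count generation.

Everything here is synthetic with known ground truth: plaque fields with
cortical and vascular classes, distance-dependent myeloid recruitment,
Dirichlet cell-type abundances with microglial enrichment near plaques,
and negative-binomial counts carrying planted niche-responsive (distance-
decayed) and group-responsive gene programs. All parameter defaults are
artifact choices emulating the statistical structure of cortical capture
arrays, not measurements; they are documented in the methods note.

All randomness flows through one numpy Generator passed explicitly (an
integer seed is accepted and promoted), so every generator is a pure
function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .grid import SpotGrid
from .rasters import MaskRaster

__all__ = [
    "SynthParams",
    "SynthTruth",
    "make_spot_grid",
    "make_tissue_raster",
    "make_abundances",
    "make_counts",
    "simulate_cohort",
]


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic cohort generator (units in field docs).

    Spatial field: ``field_size`` (um x um) rasterized at ``pixel_size``
    um/px. Plaques arrive as a Poisson field of ``plaque_rate`` per mm^2
    with log-normal radii (``plaque_radius_mu/sigma`` on the log-um scale);
    a ``vascular_fraction`` of them sit on ``vessel_count`` synthetic
    vessel polylines and are exported as vascular labels. Myeloid somata
    are retained with probability ``recruitment_near_plaque`` within one
    radius of a plaque boundary and ``recruitment_base`` elsewhere.

    Expression: ``n_genes`` genes, of which ``n_niche_genes`` carry a
    distance-decayed log2 effect (maximum ``niche_lfc_max`` at the plaque
    boundary, e-folding ``niche_decay_scale`` um) and ``n_group_genes``
    carry a constant ``group_lfc`` in treated donors. Counts are negative
    binomial with Var = mu + mu^2 / ``nb_dispersion`` and log-normal
    per-spot library sizes (``libsize_mu/sigma`` on the log scale).
    """

    seed: int = 0
    field_size: tuple = (2000.0, 2000.0)
    pixel_size: float = 5.0
    plaque_rate: float = 10.0
    plaque_radius_mu: float = float(np.log(25.0))
    plaque_radius_sigma: float = 0.3
    vessel_count: int = 2
    vascular_fraction: float = 0.15
    recruitment_base: float = 0.05
    recruitment_near_plaque: float = 0.6
    myeloid_rate: float = 150.0  # candidate somata per mm^2
    myeloid_radius: float = 5.0  # rendered soma radius, um
    n_genes: int = 2000
    n_niche_genes: int = 100
    niche_lfc_max: float = 1.5
    niche_decay_scale: float = 50.0
    n_group_genes: int = 100
    group_lfc: float = 1.5
    nb_dispersion: float = 10.0
    libsize_mu: float = float(np.log(8000.0))
    libsize_sigma: float = 0.3
    donors_per_group: int = 6
    spots_per_donor: int = 2000

    def __post_init__(self) -> None:
        for name in ("recruitment_base", "recruitment_near_plaque", "vascular_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.plaque_rate < 0 or self.myeloid_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.niche_decay_scale <= 0:
            raise ValueError("niche_decay_scale must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_niche_genes + self.n_group_genes > self.n_genes:
            raise ValueError("planted gene programs exceed n_genes")


@dataclass
class SynthTruth:
    """Ground truth of one synthetic tissue field / cohort."""

    plaque_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    plaque_class: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    niche_genes: dict = field(default_factory=dict)
    group_genes: dict = field(default_factory=dict)
    recruitment_map: pd.Series | None = None
    spot_distance: pd.Series | None = None

    def distance_to_plaque(self, x, y) -> np.ndarray:
        """Distance from point(s) to the nearest plaque boundary (0 inside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if len(self.plaque_centers) == 0:
            return np.full(x.shape, np.inf)
        cx, cy, r = self.plaque_centers.T
        d = np.hypot(x[:, None] - cx[None, :], y[:, None] - cy[None, :]) - r[None, :]
        return np.maximum(d.min(axis=1), 0.0)


def make_spot_grid(
    n_rows: int,
    n_cols: int,
    pitch: float,
    spot_diameter: float,
    region_layout=("gray matter",),
    sample_id: str = "sample1",
) -> SpotGrid:
    """Hexagonally packed spot grid with row-band region annotations."""
    return SpotGrid.from_hex_layout(
        n_rows, n_cols, pitch, spot_diameter, region_layout, sample_id
    )


def _sample_vessels(params: SynthParams, rng) -> list[np.ndarray]:
    """Random vessel polylines crossing the field."""
    w, h = params.field_size
    vessels = []
    for _ in range(params.vessel_count):
        # a gently wandering polyline from one field edge to the other
        x0 = rng.uniform(0, w)
        xs = np.clip(x0 + np.cumsum(rng.normal(0, w / 20, 9)), 0, w)
        ys = np.linspace(0, h, 9)
        if rng.random() < 0.5:
            xs, ys = ys * (w / h), xs * (h / w)
        vessels.append(np.column_stack([xs, ys]))
    return vessels


def _point_on_polyline(poly: np.ndarray, rng) -> np.ndarray:
    seg_len = np.hypot(*np.diff(poly, axis=0).T)
    total = seg_len.sum()
    t = rng.uniform(0, total)
    i = int(np.searchsorted(np.cumsum(seg_len), t))
    i = min(i, len(poly) - 2)
    frac = rng.random()
    return poly[i] + frac * (poly[i + 1] - poly[i])


def _render_discs(shape, centers_um, radii_um, pixel_size) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy), r in zip(centers_um, radii_um):
        rr, cc = skdraw.disk(
            (cy / pixel_size, cx / pixel_size), max(r / pixel_size, 1.0), shape=shape
        )
        mask[rr, cc] = True
    return mask


def make_tissue_raster(
    grid: SpotGrid, params: SynthParams, rng=None
) -> tuple[MaskRaster, MaskRaster, MaskRaster, SynthTruth]:
    """Render plaque, vascular-label and myeloid rasters with ground truth.

    Plaque count is Poisson(plaque_rate * field area); a ``vascular_fraction``
    of plaques is repositioned onto vessel polylines and labelled vascular.
    Myeloid somata are a Poisson field thinned by the recruitment
    probabilities (``recruitment_near_plaque`` within one radius of a plaque
    boundary, ``recruitment_base`` elsewhere). Also fills the per-spot
    ``recruitment_map`` (exp(-d / niche_decay_scale)) and ``spot_distance``.
    """
    if params.pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = as_rng(params.seed if rng is None else rng)
    w, h = params.field_size
    gx = grid.spots["x"].to_numpy()
    gy = grid.spots["y"].to_numpy()
    if len(gx) and (gx.max() > w or gy.max() > h):
        raise ValueError("field_size does not cover the spot grid")
    shape = (int(round(h / params.pixel_size)), int(round(w / params.pixel_size)))

    area_mm2 = (w / 1000.0) * (h / 1000.0)
    n_plaques = rng.poisson(params.plaque_rate * area_mm2)
    centers = rng.uniform([0, 0], [w, h], size=(n_plaques, 2))
    radii = rng.lognormal(params.plaque_radius_mu, params.plaque_radius_sigma, n_plaques)
    is_vasc = rng.random(n_plaques) < params.vascular_fraction
    vessels = _sample_vessels(params, rng)
    if vessels:
        for i in np.flatnonzero(is_vasc):
            poly = vessels[int(rng.integers(len(vessels)))]
            centers[i] = _point_on_polyline(poly, rng)
    else:
        is_vasc[:] = False

    ab_mask = _render_discs(shape, centers, radii, params.pixel_size)
    vasc_mask = _render_discs(shape, centers[is_vasc], radii[is_vasc], params.pixel_size)

    truth = SynthTruth(
        plaque_centers=np.column_stack([centers, radii]) if n_plaques else np.empty((0, 3)),
        plaque_class=np.where(is_vasc, "vascular", "cortical"),
    )

    # myeloid somata: Poisson field thinned by plaque-proximity recruitment
    n_my = rng.poisson(params.myeloid_rate * area_mm2)
    my_xy = rng.uniform([0, 0], [w, h], size=(n_my, 2))
    d = truth.distance_to_plaque(my_xy[:, 0], my_xy[:, 1])
    near = np.zeros(n_my, dtype=bool)
    if n_plaques:
        cx, cy, r = truth.plaque_centers.T
        dc = np.hypot(my_xy[:, 0, None] - cx, my_xy[:, 1, None] - cy)
        near = (dc <= 2 * r[None, :]).any(axis=1)  # within one radius of boundary
    p_keep = np.where(near, params.recruitment_near_plaque, params.recruitment_base)
    keep = rng.random(n_my) < p_keep
    iba1_mask = _render_discs(
        shape, my_xy[keep], np.full(int(keep.sum()), params.myeloid_radius), params.pixel_size
    )

    sd = truth.distance_to_plaque(gx, gy)
    idx = grid.spots["spot_id"].to_numpy()
    truth.spot_distance = pd.Series(sd, index=idx, name="plaque_distance")
    with np.errstate(over="ignore"):
        truth.recruitment_map = pd.Series(
            np.exp(-sd / params.niche_decay_scale), index=idx, name="recruitment"
        )
    ps = params.pixel_size
    return (
        MaskRaster(ab_mask, ps),
        MaskRaster(vasc_mask, ps),
        MaskRaster(iba1_mask, ps),
        truth,
    )


def make_abundances(
    grid: SpotGrid,
    truth: SynthTruth,
    base_dirichlet: pd.Series,
    microglia_boost: float,
    rng=0,
    microglia_name: str = "microglia",
    mean_cells: float = 7.0,
) -> pd.DataFrame:
    """Spots x cell-types abundance table with plaque-proximal microgliosis.

    Per spot, cell-type fractions are Dirichlet with the base concentration
    vector, except the microglia concentration is multiplied by
    (1 + microglia_boost * recruitment); fractions are scaled by a Poisson
    total-cells draw. Emulates the output of a deconvolution step.
    """
    rng = as_rng(rng)
    conc = pd.Series(base_dirichlet, dtype=float)
    if (conc <= 0).any():
        raise ValueError("Dirichlet concentrations must be positive")
    if microglia_name not in conc.index:
        raise ValueError(f"{microglia_name!r} must be among the cell types")
    if truth.recruitment_map is None:
        raise ValueError("truth.recruitment_map is unset; run make_tissue_raster")
    ids = grid.spots["spot_id"].to_numpy()
    rec = truth.recruitment_map.reindex(ids).fillna(0.0).to_numpy()
    n, k = len(ids), len(conc)
    alpha = np.tile(conc.to_numpy(), (n, 1))
    mg_col = conc.index.get_loc(microglia_name)
    alpha[:, mg_col] *= 1.0 + microglia_boost * rec
    # Dirichlet via normalized gammas (vectorized over spots)
    g = rng.gamma(alpha)
    frac = g / g.sum(axis=1, keepdims=True)
    total = rng.poisson(mean_cells, size=n)
    return pd.DataFrame(frac * total[:, None], index=ids, columns=conc.index)


def _donor_covariates(donors, groups, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": donors,
            "group": groups,
            "sex": rng.choice(["m", "f"], size=len(donors)),
            "age": np.round(rng.normal(75, 8, len(donors)), 1),
            "gdna_pct": np.round(np.clip(rng.normal(10, 3, len(donors)), 0.5, None), 2),
        }
    ).set_index("sample")


def make_counts(
    grid: SpotGrid,
    truth: SynthTruth,
    params: SynthParams,
    group_label: dict,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a genes x spots count matrix plus per-spot metadata.

    Donors are the grid's sample_id values; every donor must appear in
    ``group_label`` (donor -> group, the second group level is 'treated'
    unless only one level is present). Counts are NB with mean
    libsize * baseline_g * 2^effects and Var = mu + mu^2 / dispersion.
    Niche genes decay as lfc_max * exp(-d / decay scale) with d the spot's
    distance to the nearest plaque boundary; group genes apply group_lfc in
    the treated (second) group. Metadata carries sample, group, sex, age,
    gDNA %, region and the cellular detection rate (CDR, fraction of genes
    with non-zero count).
    """
    rng = as_rng(params.seed if rng is None else rng)
    spots = grid.spots
    donors = spots["sample_id"].to_numpy()
    missing = set(donors) - set(group_label)
    if missing:
        raise ValueError(f"donors missing from group_label: {sorted(missing)}")
    levels = sorted(set(group_label.values()))
    if len(levels) > 2:
        raise ValueError("group_label must have at most two levels")
    treated_level = levels[-1] if len(levels) == 2 else None

    genes = np.array([f"G{i:05d}" for i in range(params.n_genes)])
    # planted programs occupy the head of the gene list
    niche_ids = genes[: params.n_niche_genes]
    group_ids = genes[params.n_niche_genes : params.n_niche_genes + params.n_group_genes]
    niche_lfc = rng.uniform(0.5, 1.0, params.n_niche_genes) * params.niche_lfc_max
    group_sign = rng.choice([-1.0, 1.0], params.n_group_genes)
    truth.niche_genes = dict(zip(niche_ids, niche_lfc))
    truth.group_genes = dict(zip(group_ids, group_sign * params.group_lfc))

    baseline = rng.lognormal(0.0, 1.0, params.n_genes)
    baseline /= baseline.sum()
    libsize = rng.lognormal(params.libsize_mu, params.libsize_sigma, len(spots))

    if truth.spot_distance is not None:
        d = truth.spot_distance.reindex(spots["spot_id"]).to_numpy()
    else:
        d = truth.distance_to_plaque(spots["x"].to_numpy(), spots["y"].to_numpy())
    decay = np.exp(-np.where(np.isinf(d), np.inf, d) / params.niche_decay_scale)
    is_treated = np.array([group_label[s] == treated_level for s in donors])

    theta = params.nb_dispersion
    counts = np.empty((params.n_genes, len(spots)), dtype=np.int32)
    # chunk over spots to bound the float temporaries
    step = 4000
    for start in range(0, len(spots), step):
        sl = slice(start, min(start + step, len(spots)))
        eff = np.zeros((params.n_genes, sl.stop - sl.start), dtype=np.float32)
        if params.n_niche_genes:
            eff[: params.n_niche_genes] = (
                niche_lfc[:, None] * decay[None, sl]
            ).astype(np.float32)
        if params.n_group_genes and treated_level is not None:
            gslice = slice(
                params.n_niche_genes, params.n_niche_genes + params.n_group_genes
            )
            eff[gslice] += (
                (group_sign * params.group_lfc)[:, None]
                * is_treated[None, sl].astype(np.float32)
            )
        mu = (
            libsize[None, sl].astype(np.float32)
            * baseline[:, None].astype(np.float32)
            * np.exp2(eff)
        )
        p = theta / (theta + mu)
        counts[:, sl] = rng.negative_binomial(theta, p)
        del eff, mu, p

    count_df = pd.DataFrame(counts, index=genes, columns=spots["spot_id"].to_numpy())
    donor_meta = _donor_covariates(
        sorted(set(donors)), [group_label[s] for s in sorted(set(donors))], rng
    )
    meta = pd.DataFrame(
        {
            "unit": spots["spot_id"].to_numpy(),
            "sample": donors,
            "group": [group_label[s] for s in donors],
            "region": spots["region"].to_numpy(),
        }
    ).set_index("unit")
    for col in ("sex", "age", "gdna_pct"):
        meta[col] = donor_meta.loc[meta["sample"], col].to_numpy()
    meta["cdr"] = (counts > 0).mean(axis=0)
    meta["libsize"] = counts.sum(axis=0)
    return count_df, meta


def simulate_cohort(
    params: SynthParams,
    seed=None,
    groups=("control", "treated"),
    with_rasters: bool = False,
    grid_shape: tuple | None = None,
):
    """End-to-end synthetic cohort: per-donor plaque fields and counts.

    Builds one hex grid per donor (same geometry), samples an independent
    plaque field per donor, and draws counts with the planted niche and
    group programs shared across donors. Returns a dict with keys
    ``grid`` (all donors concatenated), ``counts``, ``meta``, ``truth``
    (gene programs plus per-donor plaque truths under ``per_donor``), and,
    when ``with_rasters`` is set, per-donor raster tuples under ``rasters``.
    """
    rng = as_rng(params.seed if seed is None else seed)
    if grid_shape is None:
        n_cols = int(np.ceil(np.sqrt(params.spots_per_donor)))
        n_rows = int(np.ceil(params.spots_per_donor / n_cols))
    else:
        n_rows, n_cols = grid_shape
    pitch, diam = 100.0, 55.0
    field = (
        max((n_cols - 1) * pitch + pitch, 1.0),
        max((n_rows - 1) * pitch * np.sqrt(3) / 2 + pitch, 1.0),
    )
    params_d = SynthParams(
        **{**params.__dict__, "field_size": field}
    )

    all_spots = []
    per_donor_truth = {}
    rasters = {}
    donors = []
    group_label = {}
    for gi, gname in enumerate(groups):
        for di in range(params.donors_per_group):
            donor = f"{gname}{di + 1}"
            donors.append(donor)
            group_label[donor] = gname
    for donor in donors:
        g = make_spot_grid(
            n_rows, n_cols, pitch, diam, ("gray matter",), sample_id=donor
        )
        sub = g.spots.iloc[: params.spots_per_donor].reset_index(drop=True)
        g = SpotGrid(sub, pitch=pitch, spot_diameter=diam)
        if with_rasters:
            ab, vasc, iba1, tr = make_tissue_raster(g, params_d, rng)
            rasters[donor] = (ab, vasc, iba1)
        else:
            tr = _plaques_only(g, params_d, rng)
        per_donor_truth[donor] = tr
        all_spots.append(g.spots)
    spots = pd.concat(all_spots, ignore_index=True)
    grid = SpotGrid(spots, pitch=pitch, spot_diameter=diam)

    truth = SynthTruth()
    truth.spot_distance = pd.concat(
        [t.spot_distance for t in per_donor_truth.values()]
    )
    truth.recruitment_map = pd.concat(
        [t.recruitment_map for t in per_donor_truth.values()]
    )
    counts, meta = make_counts(grid, truth, params_d, group_label, rng)
    out = {
        "grid": grid,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "per_donor": per_donor_truth,
        "group_label": group_label,
    }
    if with_rasters:
        out["rasters"] = rasters
    return out


def _plaques_only(grid: SpotGrid, params: SynthParams, rng) -> SynthTruth:
    """Plaque field and per-spot distances without rendering rasters."""
    w, h = params.field_size
    area_mm2 = (w / 1000.0) * (h / 1000.0)
    n = rng.poisson(params.plaque_rate * area_mm2)
    centers = rng.uniform([0, 0], [w, h], size=(n, 2))
    radii = rng.lognormal(params.plaque_radius_mu, params.plaque_radius_sigma, n)
    truth = SynthTruth(
        plaque_centers=np.column_stack([centers, radii]) if n else np.empty((0, 3)),
        plaque_class=np.full(n, "cortical", dtype=object),
    )
    gx = grid.spots["x"].to_numpy()
    gy = grid.spots["y"].to_numpy()
    d = truth.distance_to_plaque(gx, gy)
    idx = grid.spots["spot_id"].to_numpy()
    truth.spot_distance = pd.Series(d, index=idx, name="plaque_distance")
    rec = np.exp(-np.where(np.isinf(d), np.inf, d) / params.niche_decay_scale)
    truth.recruitment_map = pd.Series(rec, index=idx, name="recruitment")
    return truth
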