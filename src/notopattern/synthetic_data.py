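"""Seeded synthetic inputs with known ground truth.

Every generator is a pure function of its parameters and seed, and returns
the generated data together with a truth object, so the simulation,
imaging, and scoring pipelines can be validated end to end without any
external download.

* 1-D lattice expression profiles with homogeneous, alternating, or
  Bernoulli positivity patterns;
* two-channel microscopy mosaics: a row of abutting coin-shaped (elliptical
  cross-section) cells inside an organ band, with a sparse mosaic subset
  filling the cell channel and carrying a planted signal enrichment;
* negative-binomial UMI count matrices with planted group-enriched genes
  and log-normally varying sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticImageTruth",
    "SyntheticCountTruth",
    "synth_lattice_pattern",
    "synth_microscopy",
    "synth_counts",
]

HIGH_LEVEL = 1.0
LOW_LEVEL = 0.05


@dataclass(frozen=True)
class SyntheticImageTruth:
    """Two-channel mosaic image with ground-truth cell masks."""

    cell_channel: np.ndarray      # mosaic cells filled (GFP-like)
    signal_channel: np.ndarray    # baseline plus planted enrichment
    organ_mask: np.ndarray
    cell_masks: np.ndarray        # labeled ground-truth cells, 1..n
    positive_ids: tuple           # labels of cells carrying the mosaic fill
    enrichment: float
    seed: int


@dataclass(frozen=True)
class SyntheticCountTruth:
    counts: np.ndarray            # cells x genes integer UMIs
    group: np.ndarray             # per-cell boolean, True = in-group
    gene_ids: tuple
    planted_genes: dict           # gene id -> planted in-group fold change
    nb_dispersion: float
    seed: int


def synth_lattice_pattern(
    n_cells: int,
    pattern: str = "alternating",
    noise_sd: float = 0.0,
    seed: int = 0,
    p: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell intensities with a known positivity pattern.

    Base levels are 1.0 (high) and 0.05 (low); Gaussian noise of the given
    standard deviation is added and truncated at zero.  Returns
    ``(intensities, truth_labels)``.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(seed)
    if pattern == "homogeneous":
        truth = np.ones(n_cells, dtype=bool)
    elif pattern == "alternating":
        truth = (np.arange(n_cells) % 2) == 0
    elif pattern == "random":
        truth = rng.random(n_cells) < p
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    base = np.where(truth, HIGH_LEVEL, LOW_LEVEL)
    intensities = np.clip(base + rng.normal(0.0, noise_sd, n_cells), 0.0, None)
    return intensities, truth


def _ellipse_mask(shape, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _choose_sparse_subset(rng, n_cells: int, n_pos: int, max_tries: int = 200) -> np.ndarray:
    """Mosaic subset with no two chosen cells adjacent (sparse mosaics do
    not usually label neighboring cells); falls back to an evenly spaced
    pick when the rejection sampling budget runs out."""
    if n_pos == 0:
        return np.array([], dtype=int)
    for _ in range(max_tries):
        pick = np.sort(rng.choice(n_cells, size=n_pos, replace=False))
        if n_pos == 1 or np.all(np.diff(pick) > 1):
            return pick
    return np.round(np.linspace(0, n_cells - 1, n_pos)).astype(int)


def synth_microscopy(
    n_cells: int = 7,
    image_size: tuple = (220, 640),
    mosaic_fraction: float = 0.35,
    enrichment: float = 3.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    baseline: float = 0.2,
    semi_width: float = 40.0,
    semi_height: float = 70.0,
) -> SyntheticImageTruth:
    """Row of abutting coin-shaped cells with a mosaic overexpression subset.

    Cells are ellipses (semi-axes jittered around ``semi_width`` x
    ``semi_height`` px) centered on the axis of a horizontal organ band.  A
    seeded sparse subset of cells fills the cell channel at intensity 1;
    the signal channel carries ``baseline`` everywhere in the organ and
    ``baseline * enrichment`` inside the mosaic cells.  Additive Gaussian
    noise (sd ``noise_sd``) is applied to both channels and truncated at 0.
    """
    if not 0 <= mosaic_fraction <= 1:
        raise ValueError("mosaic_fraction must be in [0, 1]")
    h, w = image_size
    rng = np.random.default_rng(seed)
    margin_x = 20
    pitch = 2 * semi_width + 2  # 2-px gap between neighboring cells
    if n_cells * pitch + 2 * margin_x > w or 2 * semi_height + 40 > h:
        raise ValueError(f"{n_cells} cells of {semi_width}x{semi_height} px do not fit in {image_size}")
    if np.pi * (semi_width - 3) * (semi_height - 3) < 5000:
        raise ValueError("cells must be plantable at >= 5000 px^2")

    cy = h / 2
    band_half = semi_height + 15
    organ = np.zeros((h, w), dtype=bool)
    organ[int(cy - band_half) : int(cy + band_half), margin_x // 2 : w - margin_x // 2] = True

    cell_masks = np.zeros((h, w), dtype=np.int32)
    for i in range(n_cells):
        cx = margin_x + pitch * (i + 0.5)
        ry = semi_height + rng.uniform(-3, 3)
        rx = semi_width + rng.uniform(-2, 2)
        cell_masks[_ellipse_mask((h, w), cy, cx, ry, rx)] = i + 1

    n_pos = int(round(mosaic_fraction * n_cells))
    pos_idx = _choose_sparse_subset(rng, n_cells, n_pos)
    positive_ids = tuple(int(i) + 1 for i in pos_idx)

    pos_mask = np.isin(cell_masks, positive_ids)
    ch_cell = np.zeros((h, w))
    ch_cell[pos_mask] = 1.0
    ch_signal = np.zeros((h, w))
    ch_signal[organ] = baseline
    ch_signal[pos_mask] = baseline * enrichment
    ch_cell = np.clip(ch_cell + rng.normal(0.0, noise_sd, (h, w)), 0.0, None)
    ch_signal = np.clip(ch_signal + rng.normal(0.0, noise_sd, (h, w)), 0.0, None)

    return SyntheticImageTruth(
        cell_channel=ch_cell,
        signal_channel=ch_signal,
        organ_mask=organ,
        cell_masks=cell_masks,
        positive_ids=positive_ids,
        enrichment=enrichment,
        seed=seed,
    )


def synth_counts(
    n_cells_in: int = 50,
    n_cells_out: int = 150,
    n_genes: int = 100,
    n_planted: int = 10,
    fold_range: tuple = (20.0, 100.0),
    nb_dispersion: float = 2.0,
    depth: float = 10000.0,
    depth_sigma: float = 0.3,
    base_sigma: float = 1.0,
    seed: int = 0,
) -> SyntheticCountTruth:
    """Negative-binomial UMI matrix with planted in-group-enriched genes.

    Per-gene base expression weights are log-normal (sigma ``base_sigma``);
    ``n_planted`` genes, drawn from the mid-expressed band (30th-60th base
    percentile: usable markers are expressed, but a marker carrying a large
    share of the library would distort per-cell normalization), receive an
    in-group fold change log-uniform in ``fold_range``.  Per-cell depth is
    log-normal around ``depth``.
    Counts are gamma-Poisson (negative binomial) with shape
    ``nb_dispersion``; variance = mu + mu^2 / nb_dispersion.
    """
    for name, v in (("n_cells_in", n_cells_in), ("n_cells_out", n_cells_out),
                    ("n_genes", n_genes), ("nb_dispersion", nb_dispersion), ("depth", depth)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if n_planted < 0 or n_planted > n_genes:
        raise ValueError("n_planted must be in [0, n_genes]")
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"g{j:03d}" for j in range(n_genes))

    base_w = rng.lognormal(mean=0.0, sigma=base_sigma, size=n_genes)
    order = np.argsort(base_w)
    expressed = order[int(0.3 * n_genes) : max(int(0.6 * n_genes), int(0.3 * n_genes) + n_planted)]
    planted_idx = rng.choice(expressed, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    folds = np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1]), size=n_planted)) if n_planted else np.array([])

    w_out = base_w
    w_in = base_w.copy()
    w_in[planted_idx] *= folds
    p_out = w_out / w_out.sum()
    p_in = w_in / w_in.sum()

    n_cells = n_cells_in + n_cells_out
    group = np.zeros(n_cells, dtype=bool)
    group[:n_cells_in] = True
    depths = rng.lognormal(mean=np.log(depth), sigma=depth_sigma, size=n_cells)
    probs = np.where(group[:, None], p_in[None, :], p_out[None, :])
    mu = depths[:, None] * probs
    lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
    counts = rng.poisson(lam)

    planted = {gene_ids[j]: float(f) for j, f in zip(planted_idx, folds)}
    return SyntheticCountTruth(
        counts=counts,
        group=group,
        gene_ids=gene_ids,
        planted_genes=planted,
        nb_dispersion=nb_dispersion,
        seed=seed,
    )
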