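"""Spatial concordance battery for gridded ANPP products.

Four statistics quantify how well two maps agree in space:

* five-class percentile classification + Cohen's kappa — chance-corrected
  co-location of productivity levels (kappa > 0.6 is conventionally
  "substantial" agreement);
* Taylor-diagram statistics — (SD_ref, SD_test, Pearson r, centred RMSD),
  linked by the law-of-cosines identity cRMSD^2 = s_a^2 + s_b^2 - 2 s_a s_b r;
* global Moran's I — overall spatial autocorrelation under row-standardised
  queen-contiguity weights on the raster lattice (NaN cells dropped from the
  graph);
* local Moran's I with LISA labels — per-cell clusters HH/LL/HL/LH, judged
  significant by seeded conditional randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

LISA_CODES = {"ns": 0, "HH": 1, "LL": 2, "HL": 3, "LH": 4}


def percentile_classify(raster: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Classify a raster into quantile classes 1..n by its own distribution.

    Breaks at the 20/40/60/80th percentiles (for 5 classes); intervals closed
    on the left, the last closed on both sides; NaN preserved.
    """
    raster = np.asarray(raster, dtype=float)
    valid = np.isfinite(raster)
    vals = raster[valid]
    if vals.size < n_classes:
        raise ValueError(f"need at least {n_classes} valid cells")
    breaks = np.percentile(vals, np.linspace(0, 100, n_classes + 1)[1:-1])
    if np.unique(breaks).size < breaks.size:
        raise ValueError("degenerate percentile breaks (near-constant raster)")
    out = np.full(raster.shape, np.nan)
    out[valid] = np.searchsorted(breaks, vals, side="right") + 1
    return out


def cohen_kappa(class_a: np.ndarray, class_b: np.ndarray) -> float:
    """Chance-corrected agreement of two class rasters on jointly valid cells."""
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("class rasters must share a grid")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no jointly valid cells")
    ai = a[ok].astype(int)
    bi = b[ok].astype(int)
    labels = np.union1d(ai, bi)
    la = np.searchsorted(labels, ai)
    lb = np.searchsorted(labels, bi)
    m = labels.size
    conf = np.bincount(la * m + lb, minlength=m * m).reshape(m, m).astype(float)
    n = conf.sum()
    po = np.trace(conf) / n
    pe = float(conf.sum(axis=1) @ conf.sum(axis=0)) / n**2
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class TaylorStats:
    sd_ref: float
    sd_test: float
    r: float
    crmsd: float


def taylor_stats(ref: np.ndarray, test: np.ndarray) -> TaylorStats:
    """Taylor-diagram triple over jointly valid cells (population SDs)."""
    a = np.asarray(ref, dtype=float).ravel()
    b = np.asarray(test, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly valid cells")
    a, b = a[ok], b[ok]
    sa = float(a.std())
    sb = float(b.std())
    if sa == 0 or sb == 0:
        raise ValueError("zero variance in one of the maps")
    r = float(np.corrcoef(a, b)[0, 1])
    crmsd = float(np.sqrt(np.mean(((a - a.mean()) - (b - b.mean())) ** 2)))
    return TaylorStats(sd_ref=sa, sd_test=sb, r=r, crmsd=crmsd)


def lattice_weights(
    valid: np.ndarray, scheme: str = "queen", row_standardize: bool = True
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Contiguity weights over the valid cells of a raster lattice.

    Returns the (optionally row-standardised) sparse weight matrix and the
    flat indices of valid cells in raster order.
    """
    valid = np.asarray(valid, dtype=bool)
    rows, cols = valid.shape
    idx = -np.ones(valid.shape, dtype=int)
    flat = np.flatnonzero(valid.ravel())
    idx[valid] = np.arange(flat.size)
    if scheme == "queen":
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    src, dst = [], []
    for di, dj in offsets:
        a_sl = (slice(max(0, -di), rows - max(0, di)), slice(max(0, -dj), cols - max(0, dj)))
        b_sl = (slice(max(0, di), rows - max(0, -di)), slice(max(0, dj), cols - max(0, -dj)))
        pair = valid[a_sl] & valid[b_sl]
        src.append(idx[a_sl][pair])
        dst.append(idx[b_sl][pair])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    w = sparse.csr_matrix(
        (np.ones(src.size), (src, dst)), shape=(flat.size, flat.size)
    )
    if row_standardize:
        deg = np.asarray(w.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        w = sparse.diags(1.0 / deg) @ w
    return w.tocsr(), flat


def global_morans_i(
    raster: np.ndarray, scheme: str = "queen", row_standardize: bool = True
) -> float:
    """Global Moran's I: (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    raster = np.asarray(raster, dtype=float)
    valid = np.isfinite(raster)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    w, flat = lattice_weights(valid, scheme, row_standardize)
    z = raster.ravel()[flat]
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance raster")
    s0 = float(w.sum())
    if s0 == 0:
        raise ValueError("no neighbour links among valid cells")
    return float(len(z) / s0 * (z @ (w @ z)) / denom)


def local_morans_lisa(
    raster: np.ndarray,
    scheme: str = "queen",
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Local Moran's I and a LISA cluster raster.

    Returns ``(local_i, labels)`` where ``labels`` holds the integer codes of
    :data:`LISA_CODES`: significant cells are typed HH/LL/HL/LH by the signs
    of their deviation and spatial lag; the rest (and NaN cells) are ns/NaN.
    Significance is a two-sided pseudo-p from seeded conditional
    randomisation, drawing neighbour values from the remaining cells.
    """
    raster = np.asarray(raster, dtype=float)
    valid = np.isfinite(raster)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    w, flat = lattice_weights(valid, scheme, row_standardize=True)
    z = raster.ravel()[flat]
    z = z - z.mean()
    n = z.size
    m2 = float(z @ z) / n
    if m2 == 0:
        raise ValueError("zero variance raster")
    lag = w @ z
    local = z * lag / m2

    rng = np.random.default_rng(seed)
    indptr, indices, data = w.indptr, w.indices, w.data
    p = np.ones(n)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k == 0:
            continue
        wi = data[indptr[i] : indptr[i + 1]]
        # conditional randomisation: neighbour slots filled from all other
        # cells (with replacement; degree << n on a lattice)
        draw = rng.integers(0, n - 1, size=(n_perm, k))
        draw[draw >= i] += 1
        sim = z[i] * (z[draw] @ wi) / m2
        greater = int(np.count_nonzero(sim >= local[i]))
        one_sided = (min(greater, n_perm - greater) + 1) / (n_perm + 1)
        p[i] = min(1.0, 2.0 * one_sided)

    codes = np.zeros(n, dtype=float)
    sig = p <= alpha
    hi = z > 0
    hilag = lag > 0
    codes[sig & hi & hilag] = LISA_CODES["HH"]
    codes[sig & ~hi & ~hilag] = LISA_CODES["LL"]
    codes[sig & hi & ~hilag] = LISA_CODES["HL"]
    codes[sig & ~hi & hilag] = LISA_CODES["LH"]

    local_r = np.full(raster.shape, np.nan)
    labels = np.full(raster.shape, np.nan)
    local_r.ravel()[flat] = local
    labels.ravel()[flat] = codes
    return local_r, labels


@dataclass(frozen=True)
class SpatialConcordance:
    """Summary of the spatial battery between a test map and a reference."""

    kappa: float
    taylor: TaylorStats
    morans_i_ref: float
    morans_i_test: float


def spatial_concordance(
    ref: np.ndarray, test: np.ndarray, scheme: str = "queen"
) -> SpatialConcordance:
    """Run the full battery: per-map percentile classes + kappa, Taylor
    statistics, and global Moran's I of both maps."""
    kappa = cohen_kappa(percentile_classify(ref), percentile_classify(test))
    return SpatialConcordance(
        kappa=kappa,
        taylor=taylor_stats(ref, test),
        morans_i_ref=global_morans_i(ref, scheme),
        morans_i_test=global_morans_i(test, scheme),
    )
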